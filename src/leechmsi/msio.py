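"""Data model for MSI datasets plus continuous-mode imzML read/write.

An :class:`MSIDataset` is a pixel-indexed collection of spectra acquired on a
regular grid over one or more serial tissue sections. Continuous-mode imzML
(one shared m/z axis for every pixel) is the only interchange format the
pipeline writes: segmentation needs a common axis anyway, so datasets are
resampled before export. The section index is stored as the third (z) position
coordinate. Pixel coordinates are 0-based internally and 1-based in imzML;
the converters in this module are the only place that mapping occurs.
"""

from __future__ import annotations

import hashlib
import uuid as _uuid
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["Spectrum", "MSIDataset", "write_imzml", "read_imzml", "save_npz", "load_npz"]


@dataclass
class Spectrum:
    """One mass spectrum at one pixel of one section.

    mz must be strictly increasing, intensities finite and the two arrays the
    same length; ``section`` is 1-based (serial sections are counted from the
    anterior face), ``pixel`` is a 0-based (x, y) grid coordinate.
    """

    mz: np.ndarray
    intensity: np.ndarray
    pixel: tuple[int, int]
    section: int = 1

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if self.section < 1:
            raise ValueError("section index is 1-based")

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


@dataclass
class MSIDataset:
    """Collection of spectra on a (width x height) grid across ordered sections.

    ``roi_mask`` is a boolean (n_sections, height, width) array marking pixels
    that carry a spectrum; ``region_labels`` optionally carries the generating
    phantom's ground-truth region image (height x width, same for each
    section), used only for validation. ``shared_axis`` is set when every
    spectrum uses one common m/z axis (continuous mode).
    """

    spectra: list[Spectrum]
    width: int
    height: int
    pixel_size: float = 50.0
    sections: list[int] = field(default_factory=list)
    condition: str = "unknown"
    roi_mask: np.ndarray | None = None
    shared_axis: np.ndarray | None = None
    region_labels: np.ndarray | None = None

    def __post_init__(self):
        if not self.sections:
            self.sections = sorted({s.section for s in self.spectra})
        seen = set()
        for s in self.spectra:
            key = (s.section, s.pixel)
            if key in seen:
                raise ValueError(f"duplicate pixel {s.pixel} in section {s.section}")
            seen.add(key)
        if self.shared_axis is not None:
            self.shared_axis = np.asarray(self.shared_axis, dtype=float)
            for s in self.spectra:
                if s.mz.shape != self.shared_axis.shape or not np.allclose(
                    s.mz, self.shared_axis
                ):
                    raise ValueError("spectrum axis differs from shared_axis")

    def __len__(self) -> int:
        return len(self.spectra)

    def sorted_spectra(self) -> list[Spectrum]:
        """Spectra in canonical (section, y, x) acquisition order."""
        return sorted(self.spectra, key=lambda s: (s.section, s.pixel[1], s.pixel[0]))

    def with_spectra(self, spectra: list[Spectrum]) -> "MSIDataset":
        return replace(self, spectra=spectra)


def _content_uuid(dataset: MSIDataset) -> _uuid.UUID:
    """Deterministic UUID derived from the dataset content.

    Keeps write -> read -> write byte-stable, which a randomly drawn UUID
    would break.
    """
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(dataset.shared_axis).tobytes())
    for s in dataset.sorted_spectra():
        h.update(np.int64([s.section, s.pixel[0], s.pixel[1]]).tobytes())
        h.update(np.asarray(s.intensity, dtype=np.float32).tobytes())
    return _uuid.UUID(bytes=h.digest()[:16])


def write_imzml(dataset: MSIDataset, path: str | Path) -> Path:
    """Write a continuous-mode .imzML/.ibd pair; returns the .imzML path.

    m/z is stored float64, intensities float32. Requires a shared axis; a
    dataset on heterogeneous axes must first go through
    :func:`leechmsi.preprocess.resample_to_shared_axis`.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if len(dataset) == 0:
        raise ValueError("cannot write an empty dataset")
    if dataset.shared_axis is None:
        raise ValueError(
            "dataset has no shared m/z axis; resample with "
            "preprocess.resample_to_shared_axis before writing continuous imzML"
        )
    path = Path(path)
    if path.suffix.lower() != ".imzml":
        path = path.with_suffix(".imzML")
    writer = ImzMLWriter(
        str(path.with_suffix("")),
        mode="continuous",
        spec_type="profile",
        mz_dtype=np.float64,
        intensity_dtype=np.float32,
    )
    # Replace the writer's random UUID (already written as the 16-byte ibd
    # header) with a content-derived one, before any spectrum bytes follow.
    fixed = _content_uuid(dataset)
    writer.uuid = fixed
    writer.ibd.seek(0)
    writer.ibd.write(fixed.bytes)
    writer.sha1 = hashlib.sha1(fixed.bytes)
    mz = np.asarray(dataset.shared_axis, dtype=np.float64)
    for s in dataset.sorted_spectra():
        x, y = s.pixel
        writer.addSpectrum(mz, np.asarray(s.intensity, dtype=np.float32), (x + 1, y + 1, s.section))
    writer.close()
    # The writer embeds the absolute output path as the run id / source file
    # location; normalize to the file stem so identical datasets serialize to
    # identical bytes wherever they are written.
    run_id = str(path.with_suffix(""))
    xml = path.read_text()
    path.write_text(xml.replace(run_id, path.stem))
    return path


def _xml_mode_and_uuid(path: Path) -> tuple[str, str]:
    from xml.etree import ElementTree

    ns = "{http://psi.hupo.org/ms/mzml}"
    mode = ""
    xml_uuid = ""
    for _, elem in ElementTree.iterparse(str(path)):
        if elem.tag == f"{ns}cvParam":
            acc = elem.get("accession", "")
            if acc in ("IMS:1000030", "IMS:1000031"):
                mode = elem.get("name", "")
            elif acc == "IMS:1000080":
                xml_uuid = elem.get("value", "").strip("{}")
        if elem.tag == f"{ns}fileDescription":
            break
    return mode, xml_uuid


def read_imzml(path: str | Path) -> MSIDataset:
    """Read a continuous-mode imzML file written by :func:`write_imzml`.

    Processed-mode files are rejected; a UUID mismatch between the XML and the
    binary header (corrupt or mispaired files) is an error. Grid dimensions
    are the acquisition bounding box recorded in the file (imzML stores pixel
    counts, not the original scan-area frame).
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mode, xml_uuid = _xml_mode_and_uuid(path)
    if mode == "processed":
        raise ValueError(
            "processed-mode imzML is not supported; this pipeline reads only "
            "continuous-mode files (one shared m/z axis)"
        )
    ibd_path = path.with_suffix(".ibd")
    if not ibd_path.exists():
        raise FileNotFoundError(ibd_path)
    with open(ibd_path, "rb") as fh:
        ibd_uuid = _uuid.UUID(bytes=fh.read(16))
    if xml_uuid and _uuid.UUID(xml_uuid) != ibd_uuid:
        raise ValueError(
            f"UUID mismatch between {path.name} ({xml_uuid}) and "
            f"{ibd_path.name} ({ibd_uuid}); the pair is corrupt or mispaired"
        )
    parser = ImzMLParser(str(path))
    spectra = []
    shared = None
    for i, coords in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        mz = np.asarray(mz, dtype=float)
        if shared is None:
            shared = mz
        x, y = int(coords[0]) - 1, int(coords[1]) - 1
        z = int(coords[2]) if len(coords) > 2 else 1
        spectra.append(Spectrum(mz=shared, intensity=np.asarray(inten, float), pixel=(x, y), section=max(z, 1)))
    width = int(parser.imzmldict.get("max count of pixels x", 0)) or (
        max(s.pixel[0] for s in spectra) + 1
    )
    height = int(parser.imzmldict.get("max count of pixels y", 0)) or (
        max(s.pixel[1] for s in spectra) + 1
    )
    spectra.sort(key=lambda s: (s.section, s.pixel[1], s.pixel[0]))
    sections = sorted({s.section for s in spectra})
    roi = np.zeros((len(sections), height, width), dtype=bool)
    sec_idx = {sec: i for i, sec in enumerate(sections)}
    for s in spectra:
        roi[sec_idx[s.section], s.pixel[1], s.pixel[0]] = True
    return MSIDataset(
        spectra=spectra,
        width=width,
        height=height,
        sections=sections,
        roi_mask=roi,
        shared_axis=shared,
    )


def save_npz(dataset: MSIDataset, path: str | Path) -> Path:
    """Lossless compressed-archive cache of a shared-axis dataset."""
    if dataset.shared_axis is None:
        raise ValueError("npz caching requires a shared axis")
    path = Path(path)
    spectra = dataset.sorted_spectra()
    inten = np.stack([s.intensity for s in spectra])
    coords = np.array([(s.section, s.pixel[0], s.pixel[1]) for s in spectra], dtype=np.int64)
    extra = {}
    if dataset.region_labels is not None:
        extra["region_labels"] = dataset.region_labels
    if dataset.roi_mask is not None:
        extra["roi_mask"] = dataset.roi_mask
    np.savez_compressed(
        path,
        axis=dataset.shared_axis,
        intensity=inten,
        coords=coords,
        dims=np.array([dataset.width, dataset.height]),
        pixel_size=np.float64(dataset.pixel_size),
        condition=np.str_(dataset.condition),
        **extra,
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_npz(path: str | Path) -> MSIDataset:
    with np.load(path, allow_pickle=False) as z:
        axis = z["axis"]
        inten = z["intensity"]
        coords = z["coords"]
        width, height = (int(v) for v in z["dims"])
        pixel_size = float(z["pixel_size"])
        condition = str(z["condition"])
        labels = z["region_labels"] if "region_labels" in z else None
        roi = z["roi_mask"] if "roi_mask" in z else None
    spectra = [
        Spectrum(mz=axis, intensity=inten[i], pixel=(int(c[1]), int(c[2])), section=int(c[0]))
        for i, c in enumerate(coords)
    ]
    return MSIDataset(
        spectra=spectra,
        width=width,
        height=height,
        pixel_size=pixel_size,
        condition=condition,
        roi_mask=roi,
        shared_axis=axis,
        region_labels=labels,
    )
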
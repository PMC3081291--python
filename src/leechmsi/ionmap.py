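"""Ion-image extraction with explicit count conventions.

An ion image maps each pixel to the summed intensity inside an m/z window.
Two numbers annotate every image, following ToF-SIMS reporting practice:
``mc``, the maximum number of counts in a single pixel (the amplitude of the
color scale, read as [0, mc]), and ``tc``, the total number of counts
recorded for the window (the sum over all pixels). No smoothing is applied:
mc is a raw pixel maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msio import MSIDataset

__all__ = ["IonImage", "ion_image", "assemble_strip"]


@dataclass
class IonImage:
    """2-D intensity grid for one m/z window of one section."""

    grid: np.ndarray
    mz_center: float
    tolerance: float
    section: int
    missing: np.ndarray | None = None  # True where no spectrum was acquired

    @property
    def mc(self) -> float:
        """Maximum pixel count — the color-scale amplitude [0, mc]."""
        return float(self.grid.max(initial=0.0))

    @property
    def tc(self) -> float:
        """Total counts over all pixels for this window."""
        return float(self.grid.sum())


def default_tolerance(mz_center: float) -> float:
    """0.5% of center m/z in the protein range, 0.05 Th in the lipid range."""
    return 0.005 * mz_center if mz_center >= 1000.0 else 0.05


def ion_image(
    dataset: MSIDataset,
    mz_center: float,
    tolerance: float | None = None,
    section: int = 1,
    lo: float | None = None,
    hi: float | None = None,
) -> IonImage:
    """Per-pixel summed intensity over [center - tol, center + tol] (both
    ends inclusive). Pixels without a spectrum are zero and flagged in
    ``missing``. An asymmetric window may be given explicitly via lo/hi."""
    if lo is None or hi is None:
        if tolerance is None:
            tolerance = default_tolerance(mz_center)
        if tolerance <= 0:
            raise ValueError("tolerance must be positive")
        lo, hi = mz_center - tolerance, mz_center + tolerance
    else:
        tolerance = (hi - lo) / 2.0
    if section not in dataset.sections:
        raise ValueError(f"section {section} not present in dataset")
    spectra = [s for s in dataset.spectra if s.section == section]
    axis_lo = min(s.mz[0] for s in spectra)
    axis_hi = max(s.mz[-1] for s in spectra)
    if hi < axis_lo or lo > axis_hi:
        raise ValueError(
            f"window [{lo:g}, {hi:g}] lies outside the m/z axis [{axis_lo:g}, {axis_hi:g}]"
        )
    grid = np.zeros((dataset.height, dataset.width))
    missing = np.ones((dataset.height, dataset.width), dtype=bool)
    for s in spectra:
        sel = (s.mz >= lo) & (s.mz <= hi)
        x, y = s.pixel
        grid[y, x] = float(s.intensity[sel].sum())
        missing[y, x] = False
    return IonImage(grid=grid, mz_center=mz_center, tolerance=tolerance, section=section, missing=missing)


def assemble_strip(images: list[IonImage]) -> tuple[np.ndarray, list[dict]]:
    """Concatenate adjacent ion images end-to-end into one horizontal strip.

    All tiles must share a height. Returns the composite grid and per-tile
    metadata (section, mc, tc) in order.
    """
    if not images:
        raise ValueError("no images to assemble")
    heights = {im.grid.shape[0] for im in images}
    if len(heights) != 1:
        raise ValueError(f"mismatched tile heights: {sorted(heights)}")
    composite = np.hstack([im.grid for im in images])
    meta = [{"section": im.section, "mc": im.mc, "tc": im.tc} for im in images]
    return composite, meta
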
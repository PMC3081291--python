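"""Synthetic "ganglion phantom" MSI datasets.

The real imaging data behind this pipeline (MALDI protein-range images of
nine serial sections through a regenerating leech midbody ganglion, ToF-SIMS
lipid-range images, and single-spectrum endocannabinoid dilution series) was
never deposited, so every downstream stage is exercised on phantoms that
reproduce the *structure* the analysis assumes:

* a circular ganglion cross-section on a rectangular raster, split into an
  anterior and a posterior half-disc with partly disjoint peak panels;
* an optional blood-sinus annulus around the ganglion whose peptide profile
  is disjoint from the core's;
* a regeneration marker peak (default m/z 2475) present only in the
  "regenerating" condition, with an anterior-to-posterior intensity gradient
  across sections;
* hot-spot pixels (e.g. a large matrix crystal hit by the laser) whose whole
  spectrum is multiplied by a gain, and pure-noise pixels with no analyte
  signal — the two artifacts TIC normalization with a noise cutoff exists for.

Peaks are Gaussian in m/z with sigma = mz / (2.355 R) at constant nominal
resolving power R; amplitudes are log-normal with configured mean and CV;
noise is additive Gaussian truncated at zero; the baseline decays
exponentially with m/z. A single integer seed drives all randomness through
per-section substreams, so identical specs give bit-identical datasets.
"""

from __future__ import annotations

import enum
from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .msio import MSIDataset, Spectrum

__all__ = [
    "RegionLabel",
    "PeakSpec",
    "PhantomSpec",
    "make_geometry",
    "simulate_dataset",
    "protein_phantom",
    "sinus_phantom",
    "lipid_phantom",
    "dilution_spectrum",
    "timecourse_measurements",
    "MARKER_MZ",
]

#: m/z of the regeneration marker peptide planted in regenerating phantoms
MARKER_MZ = 2475.0


class RegionLabel(enum.IntEnum):
    """Spatial class of a phantom pixel; every pixel carries exactly one."""

    BACKGROUND = 0
    SINUS_ANNULUS = 1
    GANGLION_ANTERIOR = 2
    GANGLION_POSTERIOR = 3
    NEUROPIL = 4


@dataclass(frozen=True)
class PeakSpec:
    """One planted Gaussian peak.

    ``regions`` limits the peak to pixels of those labels; ``conditions``
    limits it to phantoms of those conditions (the marker peak uses
    ``("regenerating",)``). ``anterior_bias`` g scales the expected amplitude
    by g**(section-1), modeling expression that fades from the anterior
    (section 1) toward the posterior (section 9). ``resolving_power``
    overrides the phantom-wide value when set.
    """

    mz_center: float
    amplitude_mean: float
    amplitude_cv: float = 0.0
    regions: tuple[RegionLabel, ...] = (
        RegionLabel.GANGLION_ANTERIOR,
        RegionLabel.GANGLION_POSTERIOR,
        RegionLabel.NEUROPIL,
    )
    conditions: tuple[str, ...] = ("control", "regenerating")
    anterior_bias: float = 1.0
    resolving_power: float | None = None

    def __post_init__(self):
        if self.amplitude_mean < 0 or self.amplitude_cv < 0:
            raise ValueError("amplitude mean and cv must be non-negative")
        if self.anterior_bias <= 0:
            raise ValueError("anterior_bias must be positive")

    def sigma(self, default_rp: float) -> float:
        rp = self.resolving_power or default_rp
        s = self.mz_center / (2.355 * rp)
        if s <= 0:
            raise ValueError("peak sigma must be positive")
        return s


@dataclass(frozen=True)
class PhantomSpec:
    """Full generative description of a synthetic MSI dataset."""

    width: int = 24
    height: int = 24
    pixel_size: float = 50.0
    n_sections: int = 9
    mz_range: tuple[float, float] = (2000.0, 20000.0)
    n_points: int = 8000
    disc_center: tuple[float, float] = (11.5, 11.5)
    disc_radius: float = 8.0
    annulus_inner: float | None = None
    annulus_outer: float | None = None
    neuropil_radius: float | None = None
    peak_panel: tuple[PeakSpec, ...] = ()
    resolving_power: float = 500.0
    baseline_b0: float = 0.0
    baseline_tau: float = 3000.0
    noise_sd: float = 0.0
    hotspot_fraction: float = 0.0
    hotspot_gain: float = 5.0
    noise_pixel_fraction: float = 0.0
    condition: str = "regenerating"
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.mz_range
        if not lo < hi:
            raise ValueError("mz_range must satisfy lo < hi")
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")
        for name in ("hotspot_fraction", "noise_pixel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.annulus_inner is not None:
            if self.annulus_outer is None or self.annulus_outer < self.annulus_inner:
                raise ValueError("annulus_outer must be >= annulus_inner")
            if self.annulus_inner < self.disc_radius:
                raise ValueError("annulus inner radius must be >= disc radius")
        if self.condition not in ("control", "regenerating"):
            raise ValueError("condition must be 'control' or 'regenerating'")

    @property
    def axis(self) -> np.ndarray:
        return np.linspace(self.mz_range[0], self.mz_range[1], self.n_points)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["peak_panel"] = [
            {**asdict(p), "regions": [r.name for r in p.regions]} for p in self.peak_panel
        ]
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PhantomSpec":
        d = yaml.safe_load(text)
        panel = []
        for p in d.pop("peak_panel", []):
            p = dict(p)
            p["regions"] = tuple(RegionLabel[r] for r in p["regions"])
            p["conditions"] = tuple(p.get("conditions", ("control", "regenerating")))
            panel.append(PeakSpec(**p))
        for key in ("mz_range", "disc_center"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(peak_panel=tuple(panel), **d)


def make_geometry(spec: PhantomSpec) -> np.ndarray:
    """Per-pixel :class:`RegionLabel` image (height x width), deterministic.

    The ganglion disc is split into anterior/posterior half-discs by the
    horizontal line through the disc center (anterior = smaller y); the
    optional neuropil is a concentric inner disc and the optional blood-sinus
    annulus lies between the configured radii. Raises if a requested region
    receives zero pixels.
    """
    cx, cy = spec.disc_center
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    r = np.hypot(xx - cx, yy - cy)
    labels = np.full((spec.height, spec.width), RegionLabel.BACKGROUND, dtype=np.int8)
    disc = r <= spec.disc_radius
    labels[disc & (yy < cy)] = RegionLabel.GANGLION_ANTERIOR
    labels[disc & (yy >= cy)] = RegionLabel.GANGLION_POSTERIOR
    if spec.neuropil_radius:
        labels[r <= spec.neuropil_radius] = RegionLabel.NEUROPIL
    if spec.annulus_inner is not None:
        labels[(r >= spec.annulus_inner) & (r <= spec.annulus_outer)] = RegionLabel.SINUS_ANNULUS
    requested = [RegionLabel.GANGLION_ANTERIOR, RegionLabel.GANGLION_POSTERIOR]
    if spec.neuropil_radius:
        requested.append(RegionLabel.NEUROPIL)
    if spec.annulus_inner is not None and spec.annulus_outer > spec.annulus_inner:
        requested.append(RegionLabel.SINUS_ANNULUS)
    for reg in requested:
        if not np.any(labels == reg):
            raise ValueError(f"geometry leaves zero pixels in region {reg.name}")
    return labels


def _lognormal_amplitudes(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    """Positive amplitude draws with the requested mean and CV."""
    if mean == 0:
        return np.zeros(n)
    if cv == 0:
        return np.full(n, mean)
    s2 = np.log1p(cv * cv)
    mu = np.log(mean) - s2 / 2.0
    return rng.lognormal(mu, np.sqrt(s2), n)


def simulate_dataset(spec: PhantomSpec) -> MSIDataset:
    """Draw one dataset from a :class:`PhantomSpec`.

    One spectrum per non-background pixel per section. Hot-spot pixels have
    the whole spectrum (signal, baseline and noise) multiplied by
    ``hotspot_gain``; noise-only pixels carry baseline + noise but no peaks.
    The ground-truth label image is attached as ``dataset.region_labels``.
    """
    if spec.n_points < 2:
        raise ValueError("n_points must be >= 2")
    labels = make_geometry(spec)
    axis = spec.axis
    ys, xs = np.nonzero(labels != RegionLabel.BACKGROUND)
    npix = len(ys)
    pixel_labels = labels[ys, xs]
    baseline = (
        spec.baseline_b0 * np.exp(-axis / spec.baseline_tau)
        if spec.baseline_b0
        else np.zeros_like(axis)
    )
    active = [p for p in spec.peak_panel if spec.condition in p.conditions]
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_sections)
    spectra: list[Spectrum] = []
    roi = np.zeros((spec.n_sections, spec.height, spec.width), dtype=bool)
    for s_idx in range(spec.n_sections):
        rng = np.random.default_rng(streams[s_idx])
        signal = np.zeros((npix, spec.n_points))
        for peak in active:
            amps = _lognormal_amplitudes(
                rng, peak.amplitude_mean, peak.amplitude_cv, npix
            ) * peak.anterior_bias ** s_idx
            in_region = np.isin(pixel_labels, np.asarray(peak.regions, dtype=np.int8))
            sig = peak.sigma(spec.resolving_power)
            lo = np.searchsorted(axis, peak.mz_center - 6 * sig)
            hi = np.searchsorted(axis, peak.mz_center + 6 * sig)
            if hi <= lo:
                continue
            shape = np.exp(-0.5 * ((axis[lo:hi] - peak.mz_center) / sig) ** 2)
            signal[:, lo:hi] += np.where(in_region, amps, 0.0)[:, None] * shape[None, :]
        # per-pixel artifact draws (after peak amplitudes, same substream)
        noise_only = rng.random(npix) < spec.noise_pixel_fraction
        hotspot = rng.random(npix) < spec.hotspot_fraction
        signal[noise_only] = 0.0
        inten = signal + baseline[None, :]
        if spec.noise_sd > 0:
            inten = inten + rng.normal(0.0, spec.noise_sd, inten.shape)
        np.maximum(inten, 0.0, out=inten)
        inten[hotspot] *= spec.hotspot_gain
        for i in range(npix):
            spectra.append(
                Spectrum(
                    mz=axis,
                    intensity=inten[i],
                    pixel=(int(xs[i]), int(ys[i])),
                    section=s_idx + 1,
                )
            )
        roi[s_idx, ys, xs] = True
    return MSIDataset(
        spectra=spectra,
        width=spec.width,
        height=spec.height,
        pixel_size=spec.pixel_size,
        sections=list(range(1, spec.n_sections + 1)),
        condition=spec.condition,
        roi_mask=roi,
        shared_axis=axis,
        region_labels=labels,
    )


# ---------------------------------------------------------------------------
# Study-condition presets
# ---------------------------------------------------------------------------

def _protein_panel() -> tuple[PeakSpec, ...]:
    A = RegionLabel.GANGLION_ANTERIOR
    P = RegionLabel.GANGLION_POSTERIOR
    both = (A, P)
    shared = [
        PeakSpec(3200.0, 900.0, 0.25, regions=both),
        PeakSpec(4800.0, 700.0, 0.25, regions=both),
        PeakSpec(6500.0, 1000.0, 0.25, regions=both),
        PeakSpec(9000.0, 500.0, 0.25, regions=both),
        PeakSpec(12000.0, 400.0, 0.3, regions=both),
    ]
    anterior = [
        PeakSpec(2800.0, 800.0, 0.25, regions=(A,)),
        PeakSpec(5300.0, 900.0, 0.25, regions=(A,)),
        PeakSpec(7600.0, 600.0, 0.25, regions=(A,)),
    ]
    posterior = [
        PeakSpec(3600.0, 800.0, 0.25, regions=(P,)),
        PeakSpec(6100.0, 900.0, 0.25, regions=(P,)),
        PeakSpec(8400.0, 600.0, 0.25, regions=(P,)),
    ]
    marker = PeakSpec(
        MARKER_MZ,
        800.0,
        0.3,
        regions=(A,),
        conditions=("regenerating",),
        anterior_bias=0.85,
    )
    return tuple(shared + anterior + posterior + [marker])


def protein_phantom(condition: str = "regenerating", seed: int = 0, **overrides) -> PhantomSpec:
    """Default MALDI protein-range phantom mirroring the study's acquisition.

    Nine 50-um-raster serial sections through a circular ganglion
    cross-section, m/z 2000-20000, anterior/posterior half-discs with partly
    disjoint peptide panels, the m/z 2475 regeneration marker (anterior only,
    fading toward posterior sections, absent in the control condition),
    hot-spot and pure-noise pixels.
    """
    return PhantomSpec(
        peak_panel=_protein_panel(),
        baseline_b0=5.0,
        baseline_tau=2000.0,
        noise_sd=2.0,
        hotspot_fraction=0.02,
        hotspot_gain=5.0,
        noise_pixel_fraction=0.05,
        condition=condition,
        seed=seed,
        **overrides,
    )


def sinus_phantom(condition: str = "regenerating", seed: int = 0, **overrides) -> PhantomSpec:
    """Ganglion-plus-blood-sinus phantom: a sinus annulus with a peptide
    panel disjoint from the ganglion core's, for the annulus-vs-core
    segmentation contrast."""
    S = (RegionLabel.SINUS_ANNULUS,)
    sinus_panel = (
        PeakSpec(2300.0, 900.0, 0.25, regions=S),
        PeakSpec(4100.0, 800.0, 0.25, regions=S),
        PeakSpec(5700.0, 1000.0, 0.25, regions=S),
        PeakSpec(8800.0, 700.0, 0.25, regions=S),
        PeakSpec(11000.0, 500.0, 0.3, regions=S),
    )
    return PhantomSpec(
        width=32,
        height=32,
        disc_center=(15.5, 15.5),
        disc_radius=8.0,
        annulus_inner=10.0,
        annulus_outer=13.0,
        peak_panel=_protein_panel() + sinus_panel,
        baseline_b0=5.0,
        baseline_tau=2000.0,
        noise_sd=2.0,
        hotspot_fraction=0.02,
        hotspot_gain=5.0,
        noise_pixel_fraction=0.05,
        condition=condition,
        seed=seed,
        **overrides,
    )


def lipid_phantom(seed: int = 0, **overrides) -> PhantomSpec:
    """ToF-SIMS-style lipid-range phantom (m/z 100-1000) on a finer raster.

    Defaults to a 64x64 grid (a down-scaled stand-in for the instrument's
    256x256 field of view, which simulates in seconds rather than minutes);
    pass width/height overrides for the full raster. The panel plants the
    ion assignments the study reads off SIMS images: phosphocholine 184.1
    (somata / outer areas: anterior+posterior), the cholesterol fragment
    369.32 (also neuropil), and the fatty-acid carboxylates 281.2 / 283.2.
    """
    A = RegionLabel.GANGLION_ANTERIOR
    P = RegionLabel.GANGLION_POSTERIOR
    N = RegionLabel.NEUROPIL
    panel = (
        PeakSpec(184.07, 400.0, 0.2, regions=(A, P)),
        PeakSpec(369.35, 300.0, 0.2, regions=(A, P, N)),
        PeakSpec(281.25, 250.0, 0.2, regions=(A, N)),
        PeakSpec(283.26, 250.0, 0.2, regions=(P,)),
    )
    return PhantomSpec(
        width=64,
        height=64,
        pixel_size=2.0,
        n_sections=1,
        mz_range=(100.0, 1000.0),
        n_points=12000,
        disc_center=(31.5, 31.5),
        disc_radius=24.0,
        neuropil_radius=10.0,
        peak_panel=panel,
        resolving_power=10000.0,
        baseline_b0=0.0,
        noise_sd=1.0,
        condition="control",
        seed=seed,
        **overrides,
    )


# ---------------------------------------------------------------------------
# Single-spectrum endocannabinoid phantoms (stable-isotope dilution)
# ---------------------------------------------------------------------------

def dilution_spectrum(
    analyte_mz: float,
    standard_mz: float,
    ratio: float,
    *,
    standard_amplitude: float = 1000.0,
    resolving_power: float = 10000.0,
    mz_range: tuple[float, float] = (330.0, 400.0),
    n_points: int = 9000,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Spectrum:
    """One MALDI reflector spectrum with an analyte peak and its deuterated
    internal standard, planted at a known area ratio.

    Peak areas are proportional to amplitude x sigma; both peaks share the
    resolving power, so the apex-amplitude ratio is scaled by sigma_std /
    sigma_analyte to make the *area* ratio come out at ``ratio``.
    """
    rng = np.random.default_rng(seed)
    axis = np.linspace(mz_range[0], mz_range[1], n_points)
    sig_a = analyte_mz / (2.355 * resolving_power)
    sig_s = standard_mz / (2.355 * resolving_power)
    amp_a = standard_amplitude * ratio * (sig_s / sig_a)
    inten = standard_amplitude * np.exp(-0.5 * ((axis - standard_mz) / sig_s) ** 2)
    inten = inten + amp_a * np.exp(-0.5 * ((axis - analyte_mz) / sig_a) ** 2)
    if noise_sd > 0:
        inten = np.maximum(inten + rng.normal(0.0, noise_sd, inten.shape), 0.0)
    return Spectrum(mz=axis, intensity=inten, pixel=(0, 0), section=1)


def timecourse_measurements(
    *,
    times_min: tuple[float, ...] = (0.0, 15.0, 30.0, 60.0, 120.0, 240.0),
    peak_time_min: float = 15.0,
    peak_ratio: float = 1.2,
    baseline_ratio: float = 0.1,
    n_replicates: int = 3,
    replicate_cv: float = 0.1,
    analyte_mz: float = 385.29,
    standard_mz: float = 393.34,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[float, list[Spectrum]]:
    """Replicate dilution spectra over a 0-240 min post-lesion time course.

    The planted analyte/standard area ratio follows a gamma-shaped release
    profile peaking at ``peak_time_min`` (endocannabinoid release after nerve
    crush is fast: 2-AG within minutes, AEA around an hour) on top of a
    resting baseline ratio. Returns ``{time_min: [replicate spectra]}``.
    """
    rng = np.random.default_rng(seed)
    out: dict[float, list[Spectrum]] = {}
    for t in times_min:
        pulse = (t / peak_time_min) * np.exp(1.0 - t / peak_time_min) if peak_time_min > 0 else 0.0
        ratio_t = baseline_ratio + (peak_ratio - baseline_ratio) * pulse
        reps = []
        for _ in range(n_replicates):
            drawn = ratio_t * max(1.0 + replicate_cv * rng.standard_normal(), 0.05)
            reps.append(
                dilution_spectrum(
                    analyte_mz,
                    standard_mz,
                    drawn,
                    noise_sd=noise_sd,
                    seed=int(rng.integers(2**31)),
                )
            )
        out[float(t)] = reps
    return out
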
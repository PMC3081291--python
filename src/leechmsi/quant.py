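"""Stable-isotope-dilution quantification and marker presence calls.

Relative quantification of endocannabinoids (2-AG, AEA) uses deuterated
internal standards (2-AGd8, AEAd8) spiked at a known amount: the analyte
level is the analyte/standard peak-area ratio times the spiked amount, which
cancels extraction and ionization efficiency. Areas are trapezoidal
integrals over an m/z window after subtracting a local linear baseline drawn
between the window endpoints.

The marker call turns the "present in regenerating / absent in control"
contrast into an explicit rule: a marker is present in a region when at
least ``min_fraction`` of its pixels show a picked peak in the window with
S/N above threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msio import MSIDataset, Spectrum
from .preprocess import pick_peaks

__all__ = [
    "IsotopeDilutionConfig",
    "MarkerCall",
    "peak_area",
    "isotope_dilution",
    "build_time_course",
    "marker_presence",
]


@dataclass(frozen=True)
class IsotopeDilutionConfig:
    """Analyte and internal-standard windows plus the spiked amount.

    Windows are (center m/z, tolerance) pairs and must not overlap;
    ``spiked_amount`` is in the units the result should carry (the study
    spiked 4 ug/mL of each deuterated standard).
    """

    analyte_window: tuple[float, float]
    standard_window: tuple[float, float]
    spiked_amount: float = 4.0

    def __post_init__(self):
        if self.spiked_amount <= 0:
            raise ValueError("spiked_amount must be positive")
        (ac, at), (sc, st) = self.analyte_window, self.standard_window
        if at <= 0 or st <= 0:
            raise ValueError("window tolerances must be positive")
        if abs(ac - sc) <= at + st:
            raise ValueError("analyte and internal-standard windows overlap")


def peak_area(spectrum: Spectrum, window: tuple[float, float]) -> float:
    """Trapezoidal peak area (counts x Th) over ``window = (center, tol)``
    after subtracting a local linear baseline drawn between the window
    endpoints.

    Each endpoint's baseline value is the median of the outermost three
    window points on that side, which keeps a single noisy sample at the
    edge from tilting the whole baseline.
    """
    center, tol = window
    lo, hi = center - tol, center + tol
    x, y = spectrum.mz, spectrum.intensity
    if lo < x[0] or hi > x[-1]:
        raise ValueError(f"window [{lo:g}, {hi:g}] outside axis [{x[0]:g}, {x[-1]:g}]")
    sel = (x >= lo) & (x <= hi)
    if sel.sum() < 2:
        return 0.0
    xs, ys = x[sel], y[sel]
    k = min(3, ys.size // 2) or 1
    left = float(np.median(ys[:k]))
    right = float(np.median(ys[-k:]))
    baseline = np.interp(xs, [xs[0], xs[-1]], [left, right])
    return float(np.trapezoid(ys - baseline, xs))


def isotope_dilution(
    analyte_area: float, standard_area: float, config: IsotopeDilutionConfig
) -> float:
    """Relative level = (analyte area / standard area) x spiked amount."""
    if standard_area <= 0:
        raise ValueError(
            "internal-standard area is non-positive: the spiked standard was "
            "not detected, the measurement cannot be quantified"
        )
    return (analyte_area / standard_area) * config.spiked_amount


def quantify_spectrum(spectrum: Spectrum, config: IsotopeDilutionConfig) -> float:
    """Full pipeline for one spectrum: two areas, then the dilution ratio."""
    a = peak_area(spectrum, config.analyte_window)
    s = peak_area(spectrum, config.standard_window)
    return isotope_dilution(a, s, config)


def build_time_course(levels_by_time: dict[float, list[float | None]]) -> pd.DataFrame:
    """Per-time mean and SD over replicates.

    ``levels_by_time`` maps time (minutes) to replicate levels; a ``None``
    replicate marks a failed internal standard and sets the time point's
    ``flag`` instead of silently dropping it. Returns a DataFrame with
    columns time_min, mean, sd, n, flag, sorted by time.
    """
    if not levels_by_time:
        raise ValueError("no time points")
    rows = []
    for t in sorted(levels_by_time):
        if t < 0:
            raise ValueError("times must be non-negative")
        reps = levels_by_time[t]
        good = [v for v in reps if v is not None]
        flagged = len(good) < len(reps)
        if not good:
            rows.append((t, np.nan, np.nan, 0, True))
            continue
        arr = np.asarray(good, float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        rows.append((t, float(arr.mean()), sd, arr.size, flagged))
    return pd.DataFrame(rows, columns=["time_min", "mean", "sd", "n", "flag"])


def time_course_from_spectra(
    spectra_by_time: dict[float, list[Spectrum]], config: IsotopeDilutionConfig
) -> pd.DataFrame:
    """Quantify replicate spectra at each time point and assemble the course."""
    levels: dict[float, list[float | None]] = {}
    for t, reps in spectra_by_time.items():
        vals: list[float | None] = []
        for sp in reps:
            try:
                vals.append(quantify_spectrum(sp, config))
            except ValueError:
                vals.append(None)
        levels[t] = vals
    return build_time_course(levels)


@dataclass
class MarkerCall:
    """Presence/absence verdict for a marker ion in a spatial region."""

    region: str
    mz_center: float
    tolerance: float
    fraction: float
    n_pixels: int
    verdict: str  # "present" | "absent"

    @property
    def present(self) -> bool:
        return self.verdict == "present"


def marker_presence(
    dataset: MSIDataset,
    region_mask: np.ndarray,
    mz_center: float,
    tolerance: float,
    snr_threshold: float = 3.0,
    min_fraction: float = 0.25,
    region_name: str = "region",
) -> MarkerCall:
    """Call a marker present when >= ``min_fraction`` of region pixels show a
    picked peak with S/N >= ``snr_threshold`` inside the window.

    ``region_mask`` is (height, width), applied to every section. With
    ``min_fraction=0`` the verdict is present as soon as one pixel
    qualifies (and even with zero qualifying pixels, since 0 >= 0 — a
    documented boundary; use a positive fraction for a meaningful call).
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("empty region")
    lo, hi = mz_center - tolerance, mz_center + tolerance
    n_hit = 0
    n_tot = 0
    for s in dataset.spectra:
        x, y = s.pixel
        if not region_mask[y, x]:
            continue
        n_tot += 1
        for apex, _height, _area in pick_peaks(s, snr_threshold=snr_threshold):
            if lo <= apex <= hi:
                n_hit += 1
                break
    if n_tot == 0:
        raise ValueError("region contains no acquired pixels")
    frac = n_hit / n_tot
    return MarkerCall(
        region=region_name,
        mz_center=mz_center,
        tolerance=tolerance,
        fraction=frac,
        n_pixels=n_tot,
        verdict="present" if frac >= min_fraction else "absent",
    )
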
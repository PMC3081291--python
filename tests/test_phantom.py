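"""Geometry, determinism and planted statistical structure of the synthetic
ganglion phantoms."""

import dataclasses

import numpy as np
import pytest

from leechmsi import phantom
from leechmsi.phantom import MARKER_MZ, PeakSpec, PhantomSpec, RegionLabel

from .oracles import classify_pixels


def _counts(labels):
    return {r.name: int((labels == r).sum()) for r in RegionLabel}


class TestGeometry:
    def test_counts_match_per_pixel_oracle(self):
        spec = PhantomSpec(
            width=64,
            height=64,
            disc_center=(31.5, 31.5),
            disc_radius=20.0,
            annulus_inner=22.0,
            annulus_outer=28.0,
        )
        labels = phantom.make_geometry(spec)
        assert _counts(labels) == classify_pixels(spec)

    def test_labels_partition_the_grid(self):
        spec = PhantomSpec(width=64, height=64, disc_center=(31.5, 31.5), disc_radius=20.0)
        labels = phantom.make_geometry(spec)
        assert sum(_counts(labels).values()) == 64 * 64

    def test_degenerate_annulus_yields_zero_pixels(self):
        # inner == outer: a zero-width annulus is allowed and simply empty
        spec = PhantomSpec(
            width=24,
            height=24,
            disc_center=(11.43, 11.41),
            disc_radius=8.0,
            annulus_inner=10.05,
            annulus_outer=10.05,
        )
        labels = phantom.make_geometry(spec)
        assert _counts(labels)["SINUS_ANNULUS"] == 0

    def test_empty_requested_annulus_is_an_error(self):
        # a genuine (outer > inner) annulus placed in a radial band that no
        # pixel center falls into -> error naming the region
        spec = PhantomSpec(
            width=24,
            height=24,
            disc_center=(11.43, 11.41),
            disc_radius=8.0,
            annulus_inner=10.25,
            annulus_outer=10.39,
        )
        with pytest.raises(ValueError, match="SINUS_ANNULUS"):
            phantom.make_geometry(spec)

    def test_half_discs_split_by_center_line(self):
        spec = PhantomSpec()
        labels = phantom.make_geometry(spec)
        ys, _ = np.nonzero(labels == RegionLabel.GANGLION_ANTERIOR)
        assert ys.max() < spec.disc_center[1]
        ys, _ = np.nonzero(labels == RegionLabel.GANGLION_POSTERIOR)
        assert ys.min() >= spec.disc_center[1]

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(mz_range=(100.0, 100.0))
        with pytest.raises(ValueError):
            PhantomSpec(n_sections=0)
        with pytest.raises(ValueError):
            PhantomSpec(hotspot_fraction=1.5)
        with pytest.raises(ValueError):
            PhantomSpec(annulus_inner=5.0, annulus_outer=4.0)


class TestSimulate:
    def test_silent_phantom_is_all_zero(self):
        spec = PhantomSpec(n_sections=1, n_points=100, noise_sd=0.0, baseline_b0=0.0)
        ds = phantom.simulate_dataset(spec)
        assert all(not s.intensity.any() for s in ds.spectra)

    def test_same_seed_bit_identical(self, tiny_spec):
        a = phantom.simulate_dataset(tiny_spec)
        b = phantom.simulate_dataset(tiny_spec)
        for sa, sb in zip(a.sorted_spectra(), b.sorted_spectra()):
            assert np.array_equal(sa.intensity, sb.intensity)

    def test_different_seed_differs(self, tiny_spec):
        a = phantom.simulate_dataset(tiny_spec)
        b = phantom.simulate_dataset(dataclasses.replace(tiny_spec, seed=99))
        assert any(
            not np.array_equal(sa.intensity, sb.intensity)
            for sa, sb in zip(a.sorted_spectra(), b.sorted_spectra())
        )

    def test_one_spectrum_per_tissue_pixel_per_section(self, tiny_spec, tiny_dataset):
        labels = phantom.make_geometry(tiny_spec)
        n_tissue = int((labels != RegionLabel.BACKGROUND).sum())
        assert len(tiny_dataset) == n_tissue * tiny_spec.n_sections

    def test_too_short_axis_rejected(self):
        with pytest.raises(ValueError, match="n_points"):
            phantom.simulate_dataset(PhantomSpec(n_points=1))

    def test_mean_apex_intensity_recovers_configured_amplitude(self):
        # Monte-Carlo across seeds: one anterior-only peak with the center on
        # the sampling grid; mean apex over anterior pixels ~ A
        base = PhantomSpec(
            width=8,
            height=8,
            disc_center=(3.5, 3.5),
            disc_radius=2.5,
            n_sections=1,
            mz_range=(2000.0, 2999.5),
            n_points=2000,
            peak_panel=(
                PeakSpec(2500.0, 100.0, 0.1, regions=(RegionLabel.GANGLION_ANTERIOR,)),
            ),
            resolving_power=200.0,
        )
        apexes = []
        for seed in range(200):
            ds = phantom.simulate_dataset(dataclasses.replace(base, seed=seed))
            lab = ds.region_labels
            for s in ds.spectra:
                x, y = s.pixel
                if lab[y, x] == RegionLabel.GANGLION_ANTERIOR:
                    apexes.append(s.intensity.max())
        apexes = np.array(apexes)
        se = apexes.std(ddof=1) / np.sqrt(len(apexes))
        assert abs(apexes.mean() - 100.0) < 3 * se

    def test_anterior_bias_decays_geometrically_across_sections(self):
        g = 0.8
        spec = PhantomSpec(
            width=8,
            height=8,
            disc_center=(3.5, 3.5),
            disc_radius=2.5,
            n_sections=6,
            mz_range=(2000.0, 2999.5),
            n_points=2000,
            peak_panel=(PeakSpec(2500.0, 100.0, 0.0, anterior_bias=g),),
            resolving_power=200.0,
        )
        ds = phantom.simulate_dataset(spec)
        apex = {}
        for s in ds.spectra:
            apex.setdefault(s.section, []).append(s.intensity.max())
        means = np.array([np.mean(apex[s]) for s in sorted(apex)])
        slope = np.polyfit(np.arange(6), np.log(means), 1)[0]
        assert slope == pytest.approx(np.log(g), rel=1e-6)

    def test_condition_gated_marker_absent_in_control(self, control_dataset):
        axis = control_dataset.shared_axis
        window = (axis >= MARKER_MZ - 10) & (axis <= MARKER_MZ + 10)
        # control spectra carry only baseline + noise there: nothing close to
        # the marker's planted amplitude
        peak_amp = max(s.intensity[window].max() for s in control_dataset.spectra)
        assert peak_amp < 100.0

    def test_marker_present_in_regenerating(self, protein_dataset):
        axis = protein_dataset.shared_axis
        window = (axis >= MARKER_MZ - 10) & (axis <= MARKER_MZ + 10)
        peak_amp = max(s.intensity[window].max() for s in protein_dataset.spectra)
        assert peak_amp > 300.0

    def test_disabling_hotspots_removes_tic_outliers(self):
        base = phantom.protein_phantom(seed=5, n_sections=1)
        with_h = phantom.simulate_dataset(dataclasses.replace(base, hotspot_fraction=0.05))
        without = phantom.simulate_dataset(dataclasses.replace(base, hotspot_fraction=0.0))

        def max_rel_dev(ds):
            tics = np.array([s.tic for s in ds.spectra])
            tics = tics[tics > np.median(tics) / 2]  # drop noise-only pixels
            return float(tics.max() / np.median(tics))

        assert max_rel_dev(with_h) > 3.0  # gain-multiplied outliers stand out
        assert max_rel_dev(without) < 2.0  # unimodal without them


class TestSpecSerialization:
    def test_yaml_round_trip(self):
        spec = phantom.sinus_phantom(seed=7)
        again = PhantomSpec.from_yaml(spec.to_yaml())
        assert again == spec


class TestDilutionPhantoms:
    def test_planted_area_ratio_is_exact_in_the_noiseless_limit(self):
        sp = phantom.dilution_spectrum(385.29, 393.34, 0.5)
        # integrate each peak over +-0.15 Th directly
        a = np.trapezoid(
            np.where(np.abs(sp.mz - 385.29) <= 0.15, sp.intensity, 0.0), sp.mz
        )
        s = np.trapezoid(
            np.where(np.abs(sp.mz - 393.34) <= 0.15, sp.intensity, 0.0), sp.mz
        )
        assert a / s == pytest.approx(0.5, rel=1e-3)

    def test_timecourse_is_deterministic_given_seed(self):
        a = phantom.timecourse_measurements(seed=4)
        b = phantom.timecourse_measurements(seed=4)
        assert list(a) == list(b)
        for t in a:
            for sa, sb in zip(a[t], b[t]):
                assert np.array_equal(sa.intensity, sb.intensity)
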
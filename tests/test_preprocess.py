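"""TIC normalization with the Ymean/Ymax noise cutoff, resampling, binning
and peak picking."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from leechmsi import preprocess as pp
from leechmsi.msio import MSIDataset, Spectrum


def _dataset(intensities, axis=None):
    axis = np.asarray(axis if axis is not None else np.arange(1.0, len(intensities[0]) + 1))
    spectra = [
        Spectrum(mz=axis, intensity=np.asarray(y, float), pixel=(i, 0))
        for i, y in enumerate(intensities)
    ]
    return MSIDataset(spectra=spectra, width=len(spectra), height=1, shared_axis=axis)


class TestSpectrumStats:
    def test_constant_spectrum(self):
        s = Spectrum(mz=np.arange(5.0), intensity=np.full(5, 3.0), pixel=(0, 0))
        st_ = pp.spectrum_stats(s)
        assert (st_.ymean, st_.ymax, st_.tic) == (3.0, 3.0, 15.0)

    def test_all_zero(self):
        s = Spectrum(mz=np.arange(4.0), intensity=np.zeros(4), pixel=(0, 0))
        st_ = pp.spectrum_stats(s)
        assert (st_.ymean, st_.ymax, st_.tic) == (0.0, 0.0, 0.0)

    def test_matches_elementwise_summation(self, rng):
        y = rng.uniform(0, 10, 10)
        s = Spectrum(mz=np.arange(10.0), intensity=y, pixel=(0, 0))
        st_ = pp.spectrum_stats(s)
        total = 0.0
        biggest = 0.0
        for v in y:
            total += v
            biggest = max(biggest, v)
        assert st_.tic == pytest.approx(total, rel=1e-12)
        assert st_.ymax == biggest
        assert st_.ymean == pytest.approx(total / 10, rel=1e-12)
        assert st_.ymean == pytest.approx(st_.tic / st_.n, rel=1e-12)


class TestNormalizeDataset:
    def test_hand_computed_scale_factors(self):
        # TICs 10 and 30, threshold 0 -> both included, target = mean = 20
        ds = _dataset([[1, 2, 3, 4], [3, 6, 9, 12]])
        norm, excluded = pp.normalize_dataset(
            ds, pp.NormalizationParams(threshold_factor=0.0)
        )
        assert not excluded.any()
        np.testing.assert_allclose(norm.spectra[0].intensity, [2, 4, 6, 8])
        np.testing.assert_allclose(norm.spectra[1].intensity, np.array([3, 6, 9, 12]) * 2 / 3)

    def test_single_spectrum_scaled_to_target_shape_preserved(self):
        ds = _dataset([[1, 0, 3]])
        norm, _ = pp.normalize_dataset(
            ds, pp.NormalizationParams(threshold_factor=0.0, target_tic="unit")
        )
        y = norm.spectra[0].intensity
        assert y.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(y / y.max(), [1 / 3, 0, 1.0])

    def test_zero_tic_spectrum_excluded_without_nan(self):
        ds = _dataset([[1, 2, 3, 4], [0, 0, 0, 0]])
        norm, excluded = pp.normalize_dataset(ds, pp.NormalizationParams(threshold_factor=0.0))
        assert list(excluded) == [False, True]
        assert np.isfinite(norm.spectra[1].intensity).all()

    def test_included_spectra_share_tic_to_1e9(self, protein_dataset):
        norm, excluded = pp.normalize_dataset(protein_dataset)
        tics = np.array([s.tic for s, e in zip(norm.spectra, excluded) if not e])
        assert np.ptp(tics) / tics.mean() < 1e-9

    def test_noise_spectra_fall_below_default_cutoff(self, protein_dataset):
        # ~5% of tissue pixels are pure-noise; the default cutoff catches them
        _, excluded = pp.normalize_dataset(protein_dataset)
        frac = excluded.mean()
        assert 0.02 < frac < 0.10

    def test_idempotent(self):
        ds = _dataset([[1, 2, 3, 4], [3, 6, 9, 12], [0.5, 1, 1.5, 2]])
        params = pp.NormalizationParams(threshold_factor=0.0)
        once, _ = pp.normalize_dataset(ds, params)
        twice, _ = pp.normalize_dataset(once, params)
        for a, b in zip(once.spectra, twice.spectra):
            np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-12)

    def test_literal_text_mode_scales_only_below_cutoff(self):
        # the verbatim reading: "if Ymean < cutoff the spectrum IS normalized"
        ds = _dataset([[10, 10, 10, 10], [1, 1, 1, 1]])
        params = pp.NormalizationParams(threshold_factor=0.5, literal_text_mode=True)
        norm, excluded = pp.normalize_dataset(ds, params)
        # spectrum 0: ymean 10 >= 0.5*10 -> NOT scaled (flagged); spectrum 1 scaled
        assert list(excluded) == [True, False]
        np.testing.assert_array_equal(norm.spectra[0].intensity, [10, 10, 10, 10])
        assert norm.spectra[1].intensity.sum() == pytest.approx(4.0)  # own-mean target

    def test_default_mode_excludes_below_cutoff(self):
        ds = _dataset([[10, 10, 10, 10], [1, 1, 1, 1]])
        params = pp.NormalizationParams(threshold_factor=0.5)
        norm, excluded = pp.normalize_dataset(ds, params)
        assert list(excluded) == [False, True]
        np.testing.assert_array_equal(norm.spectra[1].intensity, [1, 1, 1, 1])

    def test_zero_out_policy(self):
        ds = _dataset([[10, 10, 10, 10], [1, 1, 1, 1]])
        params = pp.NormalizationParams(threshold_factor=0.5, excluded_policy="zero_out")
        norm, _ = pp.normalize_dataset(ds, params)
        assert not norm.spectra[1].intensity.any()

    def test_all_excluded_is_an_error(self):
        ds = _dataset([[0, 0, 0]])
        with pytest.raises(ValueError, match="excluded"):
            pp.normalize_dataset(ds)

    def test_negative_intensities_rejected(self):
        ds = _dataset([[1.0, 2.0, 3.0]])
        ds.spectra[0].intensity[1] = -1.0  # e.g. an upstream baseline subtraction
        with pytest.raises(ValueError, match="negative"):
            pp.normalize_dataset(ds)


class TestResample:
    def test_own_axis_is_identity(self):
        ds = _dataset([[1, 5, 2, 8]])
        out = pp.resample_to_shared_axis(ds, axis=ds.shared_axis)
        np.testing.assert_allclose(out.spectra[0].intensity, [1, 5, 2, 8])

    def test_triangle_area_conserved_at_double_density(self):
        axis = np.linspace(0.0, 10.0, 51)
        y = np.maximum(0.0, 1.0 - np.abs(axis - 5.0) / 2.0)
        ds = _dataset([y], axis=axis)
        out = pp.resample_to_shared_axis(ds, axis=np.linspace(0.0, 10.0, 101))
        a0 = np.trapezoid(y, axis)
        a1 = np.trapezoid(out.spectra[0].intensity, out.shared_axis)
        assert a1 == pytest.approx(a0, rel=0.01)

    def test_descending_axis_rejected(self):
        ds = _dataset([[1, 2, 3]])
        with pytest.raises(ValueError, match="increasing"):
            pp.resample_to_shared_axis(ds, axis=np.array([3.0, 2.0, 1.0]))

    def test_axis_outside_range_rejected(self):
        ds = _dataset([[1, 2, 3]])
        with pytest.raises(ValueError, match="outside"):
            pp.resample_to_shared_axis(ds, axis=np.array([0.5, 1.0, 2.0]))


class TestBinning:
    def test_single_bin_equals_tic(self):
        ds = _dataset([[1, 2, 3, 4], [5, 5, 5, 5]])
        mat = pp.bin_to_matrix(ds, bin_width=100.0)
        np.testing.assert_allclose(mat.values[:, 0], [10.0, 20.0])

    def test_single_nonzero_point_lands_in_correct_bin(self):
        axis = np.arange(10.0, 20.0)  # 10..19
        y = np.zeros(10)
        y[4] = 7.0  # m/z 14 -> bin [14, 16) with width 2
        mat = pp.bin_to_matrix(_dataset([y], axis=axis), bin_width=2.0)
        assert np.count_nonzero(mat.values) == 1
        assert mat.values[0, 2] == 7.0

    def test_matches_per_point_assignment_loop(self, rng):
        axis = np.sort(rng.uniform(100, 200, 64))
        y = rng.uniform(0, 5, 64)
        ds = _dataset([y], axis=axis)
        mat = pp.bin_to_matrix(ds, bin_width=5.0)
        manual = np.zeros_like(mat.values[0])
        for mz, v in zip(axis, y):
            manual[int((mz - axis[0]) // 5.0)] += v
        np.testing.assert_allclose(mat.values[0], manual, rtol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_binning_conserves_counts(self, seed):
        r = np.random.default_rng(seed)
        axis = np.sort(r.uniform(0, 100, 50))
        axis += np.arange(50) * 1e-9  # enforce strictly increasing
        y = r.uniform(0, 10, 50)
        ds = _dataset([y], axis=axis)
        mat = pp.bin_to_matrix(ds, bin_width=float(r.uniform(0.5, 30)))
        assert mat.values[0].sum() == pytest.approx(y.sum(), rel=1e-12)

    def test_row_order_and_include_mask(self, tiny_dataset):
        include = np.zeros(len(tiny_dataset), dtype=bool)
        include[:5] = True
        mat = pp.bin_to_matrix(tiny_dataset, 50.0, include=include)
        assert mat.values.shape[0] == 5
        assert mat.row_index == sorted(mat.row_index, key=lambda t: (t[0], t[2], t[1]))

    def test_nonpositive_width_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            pp.bin_to_matrix(tiny_dataset, 0.0)


class TestPickPeaks:
    def test_flat_spectrum_yields_nothing(self):
        s = Spectrum(mz=np.arange(100.0), intensity=np.full(100, 2.0), pixel=(0, 0))
        assert pp.pick_peaks(s) == []

    def test_noiseless_gaussian_apex_within_tolerance(self):
        axis = np.linspace(2400.0, 2550.0, 3000)
        y = 100.0 * np.exp(-0.5 * ((axis - 2475.0) / 1.0) ** 2)
        peaks = pp.pick_peaks(Spectrum(mz=axis, intensity=y, pixel=(0, 0)))
        assert len(peaks) == 1
        assert abs(peaks[0][0] - 2475.0) < 0.05

    def test_separated_gaussian_areas_match_closed_form(self):
        axis = np.linspace(2400.0, 2550.0, 3000)
        y = 50.0 * np.exp(-0.5 * ((axis - 2430.0) / 1.5) ** 2)
        y += 80.0 * np.exp(-0.5 * ((axis - 2520.0) / 2.0) ** 2)
        peaks = pp.pick_peaks(Spectrum(mz=axis, intensity=y, pixel=(0, 0)))
        assert len(peaks) == 2
        expected = {2430.0: 50.0 * 1.5, 2520.0: 80.0 * 2.0}
        for apex, _h, area in peaks:
            a = expected[min(expected, key=lambda c: abs(c - apex))] * np.sqrt(2 * np.pi)
            assert area == pytest.approx(a, rel=0.02)
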
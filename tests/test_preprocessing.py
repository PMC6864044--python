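"""Spectral extraction chain: window bank, STFT, segmentation, averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dslox.preprocessing import (
    DepthSpectra,
    PartialWindowError,
    WindowBank,
    align_and_shuffle,
    build_window_bank,
    extract_depth_spectra,
    normalize_and_concat,
    rolling_average,
    segment_vessels,
    stft_bands,
)


class TestWindowBank:
    def test_default_bandwidth_at_585nm_is_about_17nm(self, bank):
        assert bank.bandwidth_nm(585.0) == pytest.approx(17.0, abs=0.5)

    def test_two_windows_sit_exactly_at_the_wavelength_bounds(self):
        b = build_window_bank(n=2, lam_min=523.4, lam_max=604.5)
        np.testing.assert_allclose(b.centres_nm, [523.4, 604.5], rtol=1e-12)

    def test_centres_equally_spaced_in_k(self, bank):
        spacing = np.diff(bank.k_centres)
        np.testing.assert_allclose(spacing, spacing[0], rtol=1e-12)

    def test_first_and_last_centres_hit_configured_bounds(self, bank):
        assert bank.centres_nm[0] == pytest.approx(bank.lam_min, rel=1e-12)
        assert bank.centres_nm[-1] == pytest.approx(bank.lam_max, rel=1e-12)

    def test_realized_window_fwhm_matches_configuration(self, bank):
        k = np.linspace(bank.k_centres[6] - 1.0, bank.k_centres[6] + 1.0, 20001)
        w = bank.window(k, 6)
        above = k[w >= 0.5]
        measured = above[-1] - above[0]
        assert measured == pytest.approx(bank.fwhm_k, rel=0.02)

    def test_wavelength_k_round_trip_is_bijective(self, bank):
        back = np.sort(2.0 * np.pi / (bank.centres_nm * 1e-3))
        np.testing.assert_allclose(back, bank.k_centres, rtol=1e-12)

    def test_invalid_bank_parameters_rejected(self):
        with pytest.raises(ValueError):
            build_window_bank(fwhm_k=-0.1)
        with pytest.raises(ValueError):
            build_window_bank(n=1)


def _k_axis(bank, n=4096):
    return np.linspace(bank.k_centres[0] - 0.8, bank.k_centres[-1] + 0.8, n)


class TestStftBands:
    def test_flat_reflector_peaks_at_common_depth_with_equal_amplitudes(self, bank):
        k = _k_axis(bank)
        z0 = 60.0  # um
        bands, depth = stft_bands(np.cos(2.0 * k * z0), k, bank)
        peaks = bands.argmax(axis=1)
        assert len(set(peaks.tolist())) == 1
        assert depth[peaks[0]] == pytest.approx(z0, rel=0.02)
        amps = bands[:, peaks[0]]
        np.testing.assert_allclose(amps, amps.mean(), rtol=0.01)

    def test_linear_reflector_spectrum_recovered_at_window_centres(self, bank):
        # amplitude linear in k passes unchanged through a symmetric window
        k = _k_axis(bank)
        z0 = 55.0
        k_mid = bank.k_centres.mean()
        amp = 1.0 + 0.4 * (k - k_mid)
        bands, depth = stft_bands(amp * np.cos(2.0 * k * z0), k, bank)
        peak = bands[0].argmax()
        got = bands[:, peak]
        expect = 1.0 + 0.4 * (bank.k_centres - k_mid)
        np.testing.assert_allclose(got / got.mean(), expect / expect.mean(), rtol=0.02)

    def test_zero_interferogram_gives_zero_everywhere(self, bank):
        k = _k_axis(bank)
        bands, _ = stft_bands(np.zeros_like(k), k, bank)
        assert np.all(bands == 0)

    def test_insufficient_k_coverage_is_an_error(self, bank):
        k = np.linspace(bank.k_centres[3], bank.k_centres[-4], 512)
        with pytest.raises(ValueError, match="cover"):
            stft_bands(np.ones_like(k), k, bank)


class TestSegmentVessels:
    def test_bright_vessel_recovered_exactly(self):
        img = np.ones((32, 32))
        img[10:14, :] = 2.0
        mask = segment_vessels(img, threshold=1.5)
        expect = np.zeros((32, 32), dtype=bool)
        expect[10:14, :] = True
        np.testing.assert_array_equal(mask, expect)

    def test_threshold_above_max_warns_and_returns_empty(self):
        img = np.ones((8, 8))
        with pytest.warns(UserWarning, match="empty"):
            mask = segment_vessels(img, threshold=5.0)
        assert not mask.any()

    def test_quantile_threshold_selects_top_decile(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(40, 40))
        mask = segment_vessels(img, threshold=("quantile", 0.9))
        brute = int(np.sum(img >= np.quantile(img, 0.9)))
        assert int(mask.sum()) == brute


class TestAlignAndShuffle:
    def _alines(self, surfaces, n_depth=40, n_bands=3):
        # wall feature 5 samples below each A-line's surface
        x = np.zeros((len(surfaces), n_depth, n_bands))
        for i, s in enumerate(surfaces):
            x[i, s + 5, :] = 1.0
        return x

    def test_equal_surfaces_shift_nothing(self):
        surf = np.full(6, 4)
        x = self._alines(surf)
        out, _, shifts = align_and_shuffle(x, surf, seed=0)
        assert np.all(shifts == 0)
        np.testing.assert_array_equal(np.sort(out, axis=0), np.sort(x, axis=0))

    def test_same_seed_same_permutation(self):
        surf = np.arange(5)
        x = self._alines(surf)
        _, p1, _ = align_and_shuffle(x, surf, seed=42)
        _, p2, _ = align_and_shuffle(x, surf, seed=42)
        np.testing.assert_array_equal(p1, p2)

    def test_staircase_offsets_align_wall_depths(self):
        surf = np.array([0, 2, 4, 6, 8])
        x = self._alines(surf)
        out, _, _ = align_and_shuffle(x, surf, seed=1)
        walls = out.argmax(axis=1)[:, 0]
        assert len(set(walls.tolist())) == 1
        assert walls[0] == 5  # surface aligned at index 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            align_and_shuffle(np.zeros((3, 10, 2)), np.zeros(4, dtype=int), seed=0)


class TestRollingAverage:
    def test_single_window_equals_global_mean(self):
        x = np.random.default_rng(0).random((250, 4))
        out = rolling_average(x, window=250, step=125)
        assert out.shape[0] == 1
        np.testing.assert_allclose(out[0], x.mean(axis=0))

    def test_protocol_count_formula(self):
        x = np.zeros((200, 2))
        assert rolling_average(x, window=100, step=50).shape[0] == 3

    def test_constant_input_preserved(self):
        x = np.full((60, 3), 7.5)
        out = rolling_average(x, window=20, step=10)
        np.testing.assert_allclose(out, 7.5)

    def test_window_larger_than_input_rejected(self):
        with pytest.raises(ValueError):
            rolling_average(np.zeros((10, 2)), window=11, step=5)

    @settings(deadline=None, max_examples=40)
    @given(st.integers(2, 400), st.integers(1, 100), st.integers(1, 60))
    def test_output_count_matches_brute_force(self, n, window, step):
        window = min(window, n)
        x = np.arange(n, dtype=float)[:, None]
        out = rolling_average(x, window, step)
        brute = [x[j:j + window].mean() for j in range(0, n - window + 1, step)]
        assert out.shape[0] == len(brute)
        np.testing.assert_allclose(out[:, 0], brute)


class TestDepthSpectraExtraction:
    depth = np.arange(0.0, 160.0, 1.0)

    def test_depth_constant_bands_give_the_constant(self):
        x = np.full((160, 14), 3.0)
        ds = extract_depth_spectra(x, self.depth, bottom_wall_depth_um=90.0)
        for spec in (ds.bottom, ds.centre, ds.top):
            np.testing.assert_allclose(spec, 3.0)

    def test_linear_depth_profile_averages_to_midpoint(self):
        x = np.tile(self.depth[:, None], (1, 14))
        ds = extract_depth_spectra(x, self.depth, bottom_wall_depth_um=90.0)
        np.testing.assert_allclose(ds.bottom, 90.0, atol=0.5)
        np.testing.assert_allclose(ds.centre, 65.0, atol=0.5)
        np.testing.assert_allclose(ds.top, 48.4, atol=0.5)

    def test_clipped_window_is_an_error(self):
        x = np.ones((160, 14))
        with pytest.raises(PartialWindowError):
            extract_depth_spectra(x, self.depth, bottom_wall_depth_um=150.0)


class TestNormalizeAndConcat:
    def _ds(self, b, c, t):
        return DepthSpectra(np.full(14, b), np.full(14, c), np.full(14, t))

    def test_output_length_is_28(self):
        sample = normalize_and_concat(self._ds(1.0, 2.0, 3.0))
        assert sample.values.shape == (28,)

    def test_constant_spectra_normalize_to_ones(self):
        sample = normalize_and_concat(self._ds(5.0, 5.0, 5.0))
        np.testing.assert_allclose(sample.values, 1.0)

    @settings(deadline=None, max_examples=30)
    @given(st.floats(1e-3, 1e3))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(7)
        b, ce, t = rng.random(14) + 0.1, rng.random(14) + 0.1, rng.random(14) + 0.1
        base = normalize_and_concat(DepthSpectra(b, ce, t))
        scaled = normalize_and_concat(DepthSpectra(c * b, c * ce, c * t))
        np.testing.assert_allclose(scaled.values, base.values, rtol=1e-9)

    def test_zero_combined_mean_is_an_error(self):
        with pytest.raises(ValueError):
            normalize_and_concat(self._ds(0.0, 0.0, 0.0))
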
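"""PLI estimation, windowing, Welch band power and feature vectorization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fatiguefc.bands import ALPHA, BETA, DELTA, DEFAULT_BANDS, BandDefinition
from fatiguefc.connectivity import (
    ConnectivityMatrix,
    connectivity_matrix,
    cross_spectrum,
    lower_triangle,
    pli,
    pli_brute_force,
    psd_features,
    relative_band_power,
    split_windows,
    welch_psd,
    window_length_seconds,
)
from fatiguefc.recording import Recording

FS = 256.0


def _windows(x, win_seconds=0.5):
    return split_windows(np.atleast_2d(x), FS, win_seconds)[:, 0]


def _sine(freq, seconds=20.0, phase=0.0):
    t = np.arange(int(seconds * FS)) / FS
    return np.sin(2 * np.pi * freq * t + phase)


class TestWindowRule:
    def test_minimum_length_is_cycles_over_center(self):
        assert window_length_seconds(BETA, 5) == pytest.approx(5 / 21.5)
        assert window_length_seconds(DELTA, 5) == pytest.approx(5 / 2.25)

    def test_zero_cycles_rejected(self):
        with pytest.raises(ValueError):
            window_length_seconds(BETA, 0)

    def test_window_counts(self):
        x = np.zeros((3, int(20 * FS)))
        assert split_windows(x, FS, 2.5).shape == (8, 3, 640)
        assert split_windows(x, FS, 0.25).shape[0] == 80

    def test_window_longer_than_recording_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            split_windows(np.zeros((1, int(20 * FS))), FS, 21.0)


class TestCrossSpectrum:
    def test_self_spectrum_is_real(self, rng):
        w = _windows(rng.standard_normal(int(20 * FS)))
        S, _ = cross_spectrum(w, w, FS)
        assert np.abs(S.imag).max() <= 1e-12 * np.abs(S).max()

    def test_quarter_cycle_lag_has_constant_imag_sign(self):
        x = _sine(10.0)
        y = _sine(10.0, phase=-np.pi / 2)
        S, freqs = cross_spectrum(_windows(x), _windows(y), FS)
        bin10 = int(np.argmin(np.abs(freqs - 10.0)))
        signs = np.sign(S[:, bin10].imag)
        assert np.all(signs == signs[0]) and signs[0] != 0

    def test_swap_conjugates(self, rng):
        a = _windows(rng.standard_normal(int(5 * FS)))
        b = _windows(rng.standard_normal(int(5 * FS)))
        S1, _ = cross_spectrum(a, b, FS)
        S2, _ = cross_spectrum(b, a, FS)
        np.testing.assert_allclose(S1, np.conj(S2), rtol=1e-12)


class TestPLI:
    def test_identical_signals_give_zero(self, rng):
        x = rng.standard_normal(int(20 * FS))
        assert pli(_windows(x), _windows(x), FS, ALPHA) == 0.0

    def test_proportional_signals_give_zero(self, rng):
        """Zero-lag (volume-conducted) coupling is invisible by design."""
        x = rng.standard_normal(int(20 * FS))
        for c in (3.0, -2.0, 0.5):
            assert pli(_windows(x), _windows(c * x), FS, ALPHA) == 0.0

    def test_constant_quarter_cycle_lag_gives_one(self):
        x = _sine(10.0)
        y = _sine(10.0, phase=-np.pi / 2)
        assert pli(_windows(x, 0.5), _windows(y, 0.5), FS, ALPHA) == 1.0

    def test_independent_noise_small(self):
        """Null PLI scales like 1/sqrt(n_windows): with 400 windows the
        value stays below 0.2 in nearly every run."""
        rng = np.random.default_rng(7)
        n_exceed = 0
        runs = 200
        for _ in range(runs):
            x = rng.standard_normal(400 * 64)
            y = rng.standard_normal(400 * 64)
            w = split_windows(np.vstack([x, y]), FS, 0.25)
            if pli(w[:, 0], w[:, 1], FS, ALPHA) > 0.2:
                n_exceed += 1
        assert n_exceed <= runs * 0.01

    def test_matches_brute_force_small_cases(self, rng):
        """Vectorized estimator equals the per-bin sign-count oracle."""
        for n_nodes, n_win in ((2, 4), (3, 8), (4, 16)):
            d = rng.standard_normal((n_nodes, n_win * 64))
            cm = connectivity_matrix(d, ALPHA, window_seconds=0.25, fs=FS)
            w = split_windows(d, FS, 0.25)
            for i in range(n_nodes):
                for j in range(i):
                    expect = pli_brute_force(w[:, i], w[:, j], FS, ALPHA)
                    assert abs(cm.values[i, j] - expect) < 1e-12

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           seed=st.integers(min_value=0, max_value=2**16))
    def test_amplitude_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(8 * 64)
        y = rng.standard_normal(8 * 64)
        base = pli(_windows(x, 0.25), _windows(y, 0.25), FS, ALPHA)
        scaled = pli(_windows(scale * x, 0.25), _windows(y, 0.25), FS, ALPHA)
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_symmetry(self, rng):
        x = rng.standard_normal(8 * 64)
        y = rng.standard_normal(8 * 64)
        assert pli(_windows(x, 0.25), _windows(y, 0.25), FS, ALPHA) == \
            pli(_windows(y, 0.25), _windows(x, 0.25), FS, ALPHA)

    def test_no_bin_in_band_reported(self):
        x = np.zeros((2, 128))
        with pytest.raises(ValueError, match="bin"):
            # 0.05 s windows -> 20 Hz spacing, no bin inside delta
            connectivity_matrix(x, DELTA, window_seconds=0.05, fs=FS)


class TestConnectivityMatrix:
    def test_shapes(self, rng):
        d = rng.standard_normal((32, int(20 * FS)))
        cm = connectivity_matrix(d, BETA, fs=FS)
        assert cm.values.shape == (32, 32)
        assert np.array_equal(cm.values, cm.values.T)
        assert np.all(np.diagonal(cm.values) == 0)
        assert 0 <= cm.values.min() and cm.values.max() <= 1

    def test_node_permutation_permutes_matrix(self, rng):
        d = rng.standard_normal((4, 8 * 64))
        perm = [2, 0, 3, 1]
        cm1 = connectivity_matrix(d, ALPHA, window_seconds=0.25, fs=FS,
                                  node_names=list("abcd"))
        cm2 = connectivity_matrix(d[perm], ALPHA, window_seconds=0.25, fs=FS,
                                  node_names=[list("abcd")[p] for p in perm])
        np.testing.assert_allclose(cm2.values, cm1.values[np.ix_(perm, perm)],
                                   atol=1e-15)

    def test_default_window_is_band_minimum(self, rng):
        d = rng.standard_normal((2, int(20 * FS)))
        cm = connectivity_matrix(d, BETA, fs=FS)  # must not raise
        assert cm.band.name == "beta"


class TestLowerTriangle:
    @pytest.mark.parametrize("n,expected", [(68, 2278), (32, 496), (2, 1)])
    def test_feature_counts(self, n, expected):
        vals = np.zeros((n, n))
        cm = ConnectivityMatrix(vals, ALPHA, "source",
                                [f"r{i}" for i in range(n)])
        fv = lower_triangle(cm)
        assert len(fv.values) == expected
        assert len(set(fv.labels)) == expected

    def test_row_major_order_and_values(self):
        vals = np.array([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]])
        cm = ConnectivityMatrix(vals, ALPHA, "sensor", ["a", "b", "c"])
        fv = lower_triangle(cm)
        np.testing.assert_allclose(fv.values, [0.1, 0.2, 0.3])
        assert fv.labels == ["b~a", "c~a", "c~b"]


class TestWelchPower:
    def test_sine_peak_at_its_frequency(self):
        rec = Recording(np.atleast_2d(_sine(10.0)), FS)
        spec = welch_psd(rec)
        peak = spec.frequencies[int(np.argmax(spec.power[0]))]
        df = spec.frequencies[1] - spec.frequencies[0]
        assert abs(peak - 10.0) <= df

    def test_zero_signal_zero_power(self):
        spec = welch_psd(Recording(np.zeros((2, 5120)), FS))
        assert np.all(spec.power == 0)

    def test_white_noise_flat_in_band(self):
        rng = np.random.default_rng(0)
        rec = Recording(rng.standard_normal((1, 200 * 256)), FS)
        spec = welch_psd(rec, segment_seconds=2.0)
        mask = (spec.frequencies >= 1) & (spec.frequencies < 45)
        band = spec.power[0, mask]
        assert band.max() / band.min() < 3.0

    def test_segment_too_long_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(Recording(np.zeros((1, 256)), FS), segment_seconds=2.0)


class TestRelativeBandPower:
    def test_pure_alpha_sine_concentrated(self):
        rec = Recording(np.atleast_2d(_sine(10.0)), FS)
        spec = welch_psd(rec)
        assert relative_band_power(spec, ALPHA)[0] >= 0.95
        assert relative_band_power(spec, BETA)[0] <= 0.05

    def test_full_range_is_one(self, rng):
        rec = Recording(rng.standard_normal((3, 5120)), FS)
        spec = welch_psd(rec)
        full = BandDefinition("full", 0.5, 45.0)
        np.testing.assert_allclose(relative_band_power(spec, full), 1.0)

    def test_zero_total_power_rejected(self):
        spec = welch_psd(Recording(np.zeros((1, 5120)), FS))
        with pytest.raises(ValueError, match="zero total power"):
            relative_band_power(spec, ALPHA)


class TestPsdFeatures:
    @pytest.mark.parametrize("n_channels,n_bands,expected",
                             [(32, 1, 32), (32, 5, 160), (2, 1, 2)])
    def test_feature_counts(self, rng, n_channels, n_bands, expected):
        rec = Recording(rng.standard_normal((n_channels, 5120)), FS,
                        channel_names=[f"ch{i}" for i in range(n_channels)])
        bands = list(DEFAULT_BANDS.values())[:n_bands]
        fv = psd_features(rec, bands)
        assert len(fv.values) == expected
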
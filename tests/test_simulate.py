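"""Synthetic dataset generator: planted couplings and their recovery."""

import numpy as np
import pytest

from fatiguefc.bands import ALPHA, BETA, DELTA
from fatiguefc.connectivity import connectivity_matrix, pli, split_windows
from fatiguefc.inverse import apply_inverse
from fatiguefc.parcellation import sign_flip_average
from fatiguefc.simulate import (
    CouplingSpec,
    SimulationConfig,
    generate_dataset,
    one_over_f_noise,
    project_sources,
    simulate_roi_sources,
)

FS = 256.0


def _config(**kw):
    defaults = dict(n_subjects=2, couplings_alert=[], couplings_fatigue=[])
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestCouplingSpec:
    @pytest.mark.parametrize("lag", [0.0, np.pi, -0.1, 4.0])
    def test_invisible_lags_rejected(self, lag):
        with pytest.raises(ValueError, match="phase_lag"):
            CouplingSpec("a", "b", BETA, phase_lag=lag)

    def test_strength_bounds(self):
        with pytest.raises(ValueError, match="strength"):
            CouplingSpec("a", "b", BETA, strength=1.5)


class TestRoiSources:
    def test_full_strength_quarter_lag_gives_pli_one(self):
        cfg = _config(
            couplings_fatigue=[CouplingSpec("a", "b", ALPHA, np.pi / 2, 1.0)],
            background_exponent=1.0, strength_jitter=0.0,
            oscillation_amplitude=1e6,  # oscillation dominates background
        )
        sig = simulate_roi_sources(cfg, ["a", "b"], "fatigue", 5)
        wl = 0.5
        wa = split_windows(sig["a"], FS, wl)[:, 0]
        wb = split_windows(sig["b"], FS, wl)[:, 0]
        assert pli(wa, wb, FS, ALPHA) >= 0.98

    def test_zero_strength_is_null(self):
        """Uncoupled pairs have PLI at the binomial-null level."""
        cfg = _config(
            couplings_fatigue=[CouplingSpec("a", "b", ALPHA, np.pi / 2, 0.0)],
            strength_jitter=0.0, duration=100.0,
        )
        vals = []
        for seed in range(200):
            sig = simulate_roi_sources(cfg, ["a", "b"], "fatigue", seed)
            wa = split_windows(sig["a"], FS, 0.25)[:, 0]  # 400 windows
            wb = split_windows(sig["b"], FS, 0.25)[:, 0]
            vals.append(pli(wa, wb, FS, ALPHA))
        assert np.mean(vals) < 0.15

    def test_deterministic_per_seed(self):
        cfg = _config(couplings_fatigue=[CouplingSpec("a", "b", BETA)])
        s1 = simulate_roi_sources(cfg, ["a", "b"], "fatigue", 9)
        s2 = simulate_roi_sources(cfg, ["a", "b"], "fatigue", 9)
        for roi in s1:
            np.testing.assert_array_equal(s1[roi], s2[roi])

    def test_unknown_roi_rejected(self):
        cfg = _config(couplings_fatigue=[CouplingSpec("a", "nope", BETA)])
        with pytest.raises(KeyError, match="nope"):
            simulate_roi_sources(cfg, ["a", "b"], "fatigue", 0)

    def test_background_spectrum_slopes_down(self):
        x = one_over_f_noise(1 << 16, FS, 1.0, np.random.default_rng(0))
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(1 << 16, 1 / FS)
        lo = spec[(freqs > 0.5) & (freqs < 2)].mean()
        hi = spec[(freqs > 30) & (freqs < 45)].mean()
        assert lo > 5 * hi


class TestProjection:
    def test_zero_sources_zero_recording(self, small_space, small_leadfield, small_atlas):
        signals = {r: np.zeros(256) for r in small_atlas.roi_names}
        rec = project_sources(signals, small_atlas, small_space, small_leadfield,
                              sensor_snr=np.inf, seed=0)
        assert np.all(rec.data == 0)

    def test_noiseless_projection_linear(self, small_space, small_leadfield,
                                         small_atlas, rng):
        signals = {r: rng.standard_normal(128) for r in small_atlas.roi_names}
        doubled = {r: 2.0 * s for r, s in signals.items()}
        r1 = project_sources(signals, small_atlas, small_space, small_leadfield,
                             np.inf, seed=4)
        r2 = project_sources(doubled, small_atlas, small_space, small_leadfield,
                             np.inf, seed=4)
        np.testing.assert_allclose(r2.data, 2.0 * r1.data, rtol=1e-12)

    def test_infinite_snr_is_noiseless(self, small_space, small_leadfield,
                                       small_atlas, rng):
        signals = {r: rng.standard_normal(128) for r in small_atlas.roi_names}
        a = project_sources(signals, small_atlas, small_space, small_leadfield,
                            np.inf, seed=1)
        b = project_sources(signals, small_atlas, small_space, small_leadfield,
                            1e12, seed=1)
        # noise amplitude ~ rms/snr: vanishing at extreme snr
        assert np.abs(a.data - b.data).max() < 1e-9 * np.abs(a.data).max()


class TestDataset:
    def test_study_scale_shapes(self, small_space, small_leadfield, small_atlas):
        cfg = _config(n_subjects=48)
        ds = generate_dataset(cfg, small_atlas, small_space, small_leadfield)
        assert len(ds.recordings) == 96
        assert all(r.data.shape == (32, 5120) for r in ds.recordings)
        assert len(ds.by_condition("alert")) == 48

    def test_single_subject(self, small_space, small_leadfield, small_atlas):
        ds = generate_dataset(_config(n_subjects=1), small_atlas, small_space,
                              small_leadfield)
        assert len(ds.recordings) == 2

    def test_deterministic_for_config_seed(self, small_space, small_leadfield,
                                           small_atlas):
        cfg = _config(n_subjects=2, seed=11)
        d1 = generate_dataset(cfg, small_atlas, small_space, small_leadfield)
        d2 = generate_dataset(cfg, small_atlas, small_space, small_leadfield)
        for a, b in zip(d1.recordings, d2.recordings):
            np.testing.assert_array_equal(a.data, b.data)

    def test_write_and_reload(self, small_space, small_leadfield, small_atlas,
                              tmp_path):
        from fatiguefc.io import read_dataset_manifest

        ds = generate_dataset(_config(n_subjects=1), small_atlas, small_space,
                              small_leadfield)
        ds.write(tmp_path / "data")
        back = read_dataset_manifest(tmp_path / "data" / "manifest.json")
        assert len(back) == 2
        np.testing.assert_allclose(back[0].data, ds.recordings[0].data,
                                   rtol=1e-6, atol=1e-9 * np.abs(ds.recordings[0].data).max())


class TestPlantedCouplingRecovery:
    def test_planted_pair_recovered_band_specifically(
        self, small_space, small_leadfield, small_atlas, small_inverse
    ):
        """With a strong planted beta coupling, the planted pair's
        source-space PLI exceeds the null 95th percentile in >= 90% of
        seeds, and shows no elevation in delta (band specificity)."""
        pair = ("roi02-lh", "roi05-rh")
        i = small_atlas.roi_index(pair[0])
        j = small_atlas.roi_index(pair[1])
        hits_beta = hits_delta = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = _config(
                n_subjects=1, sensor_snr=5.0, strength_jitter=0.0, seed=seed,
                couplings_fatigue=[CouplingSpec(*pair, BETA, np.pi / 2, 0.9)],
            )
            ds = generate_dataset(cfg, small_atlas, small_space, small_leadfield)
            rec = ds.by_condition("fatigue")[0]
            est = apply_inverse(small_inverse, rec, small_space)
            roi = sign_flip_average(est, small_atlas, small_space)
            for band, counter in ((BETA, "beta"), (DELTA, "delta")):
                cm = connectivity_matrix(roi, band)
                others = [cm.values[a, b]
                          for a in range(cm.n_nodes) for b in range(a)
                          if {a, b} != {i, j}]
                hit = cm.values[i, j] > np.percentile(others, 95)
                if counter == "beta":
                    hits_beta += hit
                else:
                    hits_delta += hit
        assert hits_beta >= 0.9 * n_seeds
        assert hits_delta <= 0.25 * n_seeds  # at/near the 5% null rate
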
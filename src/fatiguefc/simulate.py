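"""Synthetic paired alert/fatigue EEG with known phase-lag couplings.

Every downstream stage of the pipeline is validated against data whose
ground truth is planted here: per-ROI source signals consisting of a 1/f
background plus band-limited oscillations, with condition-specific lagged
couplings between chosen ROI pairs, projected through the forward model to
the scalp with additive sensor noise.

The coupling model: the target ROI's band-limited component is the mixture
(1 - strength) * independent + strength * (source ROI's component delayed
by phase_lag at the band's central frequency).  The delay realizes the
phase lag exactly at the band center and approximately across the band —
sufficient for PLI, which only needs a consistent lead/lag sign.

Default study conditions mirror the emulated experiment: 48 subjects, two
20 s recordings each (alert / fatigue), 32 channels at 256 Hz.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .bands import BandDefinition, get_band
from .headmodel import Leadfield, SourceSpace
from .parcellation import Atlas
from .recording import Recording

__all__ = [
    "CouplingSpec",
    "SimulationConfig",
    "SimulatedDataset",
    "default_study_config",
    "simulate_roi_sources",
    "project_sources",
    "generate_dataset",
    "inject_artifacts",
    "one_over_f_noise",
]


@dataclass(frozen=True)
class CouplingSpec:
    """A planted lagged coupling from roi_a to roi_b in one band.

    phase_lag must avoid 0 and pi: zero-lag and anti-phase coupling have a
    real cross-spectrum and are invisible to PLI by design.
    """

    roi_a: str
    roi_b: str
    band: BandDefinition
    phase_lag: float = np.pi / 2
    strength: float = 0.8

    def __post_init__(self) -> None:
        object.__setattr__(self, "band", get_band(self.band))
        if not (0.0 < self.phase_lag < np.pi):
            raise ValueError(
                f"phase_lag must lie strictly inside (0, pi); got {self.phase_lag} "
                "(0 and pi give a purely real cross-spectrum, invisible to PLI)"
            )
        if not (0.0 <= self.strength <= 1.0):
            raise ValueError(f"strength must lie in [0, 1], got {self.strength}")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset."""

    n_subjects: int = 48
    fs: float = 256.0
    duration: float = 20.0
    couplings_alert: list[CouplingSpec] = field(default_factory=list)
    couplings_fatigue: list[CouplingSpec] = field(default_factory=list)
    sensor_snr: float = 5.0  # amplitude ratio; inf = noiseless
    background_exponent: float = 1.0  # 1/f^exponent spectral slope
    oscillation_amplitude: float = 1.0  # band component amplitude vs unit background
    strength_jitter: float = 0.2  # per-subject +-20% coupling-strength jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        top = max(
            (c.band.f_high for c in self.couplings_alert + self.couplings_fatigue),
            default=0.0,
        )
        if self.fs <= 2 * top:
            raise ValueError(
                f"fs = {self.fs} Hz must exceed twice the highest coupled band "
                f"edge ({top} Hz)"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass
class SimulatedDataset:
    recordings: list[Recording]  # 2 per subject, alert then fatigue
    ground_truth: dict  # condition -> list[CouplingSpec]
    roi_source_signals: dict  # (subject_id, condition) -> {roi: series}

    def __post_init__(self) -> None:
        subjects = {}
        for rec in self.recordings:
            subjects.setdefault(rec.subject_id, set()).add(rec.condition)
        for sid, conds in subjects.items():
            if conds != {"alert", "fatigue"}:
                raise ValueError(f"subject {sid} does not have exactly one "
                                 f"alert and one fatigue recording: {conds}")

    @property
    def n_subjects(self) -> int:
        return len(self.recordings) // 2

    def by_condition(self, condition: str) -> list[Recording]:
        return [r for r in self.recordings if r.condition == condition]

    def write(self, out_dir, delimiter: str = "\t") -> None:
        """One delimited text file per recording plus a JSON manifest."""
        from pathlib import Path

        from .io import write_recording_text

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        entries = []
        for rec in self.recordings:
            name = f"{rec.subject_id}_{rec.condition}.tsv"
            write_recording_text(rec, out / name, delimiter=delimiter)
            entries.append({"file": name, "subject_id": rec.subject_id,
                            "condition": rec.condition, "fs": rec.fs})
        manifest = {
            "recordings": entries,
            "ground_truth": {
                cond: [
                    {**asdict(c), "band": c.band.name}
                    for c in specs
                ]
                for cond, specs in self.ground_truth.items()
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def default_study_config(
    seed: int = 0,
    n_subjects: int = 48,
    band: str = "beta",
    sensor_snr: float = 5.0,
    strength: float = 0.9,
) -> SimulationConfig:
    """The canonical synthetic study: a condition-specific rewiring contrast.

    Two distant homologous ROI pairs carry band-limited oscillations in
    both conditions (so the band-power topography is identical); in the
    alert state the first pair is phase-coupled and the second is not, and
    fatigue swaps which pair is coupled.  Only the phase structure
    distinguishes the conditions — the kind of difference source-space
    connectivity exists to detect.
    """
    pair1 = ("roi02-lh", "roi05-rh")
    pair2 = ("roi03-lh", "roi06-rh")
    return SimulationConfig(
        n_subjects=n_subjects,
        sensor_snr=sensor_snr,
        couplings_alert=[
            CouplingSpec(*pair1, band, strength=strength),
            CouplingSpec(*pair2, band, strength=0.0),
        ],
        couplings_fatigue=[
            CouplingSpec(*pair1, band, strength=0.0),
            CouplingSpec(*pair2, band, strength=strength),
        ],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# signal primitives


def one_over_f_noise(n_samples: int, fs: float, exponent: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with a 1/f^exponent amplitude spectrum."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    out = np.fft.irfft(spec * shaping, n=n_samples)
    sd = out.std()
    return out / sd if sd > 0 else out


def _band_limited_noise(n_samples: int, fs: float, band: BandDefinition,
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise restricted to [f_low, f_high) by FFT masking."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    spec[(freqs < band.f_low) | (freqs >= band.f_high)] = 0.0
    out = np.fft.irfft(spec, n=n_samples)
    sd = out.std()
    return out / sd if sd > 0 else out


def _delay(x: np.ndarray, fs: float, seconds: float) -> np.ndarray:
    """Exact (fractional-sample) circular delay via FFT phase shift."""
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    return np.fft.irfft(np.fft.rfft(x) * np.exp(-2j * np.pi * freqs * seconds),
                        n=len(x))


# ---------------------------------------------------------------------------
# operations


def simulate_roi_sources(
    config: SimulationConfig,
    roi_names: list[str],
    condition: str,
    subject_seed: int,
) -> dict[str, np.ndarray]:
    """Per-ROI source time series for one subject and condition.

    Each ROI carries a 1/f background; for every coupling of the condition
    the pair additionally carries band-limited components with the planted
    lag.  Deterministic for a fixed subject_seed.
    """
    couplings = {
        "alert": config.couplings_alert,
        "fatigue": config.couplings_fatigue,
    }.get(condition)
    if couplings is None:
        raise ValueError(f"condition must be 'alert' or 'fatigue', got {condition!r}")
    for c in couplings:
        for roi in (c.roi_a, c.roi_b):
            if roi not in roi_names:
                raise KeyError(f"coupling references unknown ROI {roi!r}")

    rng = np.random.default_rng(subject_seed)
    n = config.n_samples
    signals = {
        roi: one_over_f_noise(n, config.fs, config.background_exponent, rng)
        for roi in roi_names
    }
    amp = config.oscillation_amplitude
    for c in couplings:
        strength = c.strength
        if config.strength_jitter > 0:
            strength *= 1.0 + rng.uniform(-config.strength_jitter,
                                          config.strength_jitter)
        strength = float(np.clip(strength, 0.0, 1.0))
        src = _band_limited_noise(n, config.fs, c.band, rng)
        indep = _band_limited_noise(n, config.fs, c.band, rng)
        lag_seconds = c.phase_lag / (2.0 * np.pi * c.band.center)
        lagged = _delay(src, config.fs, lag_seconds)
        target = (1.0 - strength) * indep + strength * lagged
        # normalize to unit variance: the planted coupling changes the phase
        # structure only, never the band power topography (a zero-strength
        # coupling is then an exact power-matched control)
        target /= np.sqrt((1.0 - strength) ** 2 + strength**2)
        signals[c.roi_a] = signals[c.roi_a] + amp * src
        signals[c.roi_b] = signals[c.roi_b] + amp * target
    return signals


def project_sources(
    roi_signals: dict[str, np.ndarray],
    atlas: Atlas,
    sources: SourceSpace,
    leadfield: Leadfield,
    sensor_snr: float,
    seed: int,
    fs: float = 256.0,
    channel_names: "list[str] | None" = None,
    subject_id: str = "sim",
    condition: str = "unknown",
) -> Recording:
    """Scalp projection of ROI source signals plus white sensor noise.

    Every vertex of an ROI carries the ROI's signal along its first
    orientation axis, scaled by a per-vertex gain drawn once per call; the
    sensor noise standard deviation is set from the projected signal RMS
    and ``sensor_snr`` (amplitude ratio; ``inf`` for noiseless).
    """
    rng = np.random.default_rng(seed)
    n_sens = leadfield.n_sensors
    sig_lens = {len(s) for s in roi_signals.values()}
    if len(sig_lens) != 1:
        raise ValueError("ROI signals differ in length")
    n_samp = sig_lens.pop()

    sensor = np.zeros((n_sens, n_samp))
    for roi, series in roi_signals.items():
        verts = atlas.vertices_of(roi)
        if verts.size == 0:
            raise ValueError(f"ROI {roi!r} maps to no vertices")
        gains = rng.uniform(0.5, 1.5, size=verts.size)
        # sum_v gain_v * leadfield column of the vertex's first orientation
        cols = leadfield.gain[:, 3 * verts]  # (n_sens, n_verts)
        sensor += np.outer(cols @ gains, series)
    rms = sensor.std()
    if np.isfinite(sensor_snr):
        if sensor_snr <= 0:
            raise ValueError("sensor_snr must be positive")
        sensor = sensor + rng.standard_normal(sensor.shape) * (rms / sensor_snr)
    names = channel_names or (leadfield.sensor_names
                              if leadfield.sensor_names else None)
    return Recording(data=sensor, fs=fs, channel_names=names or [],
                     subject_id=subject_id, condition=condition)


def generate_dataset(
    config: SimulationConfig,
    atlas: Atlas,
    sources: SourceSpace,
    leadfield: Leadfield,
) -> SimulatedDataset:
    """The full paired dataset: n_subjects x {alert, fatigue} recordings.

    Per-subject, per-condition seeds are derived deterministically from
    ``config.seed`` via a seed sequence, so the dataset is reproducible and
    subjects are mutually independent.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_subjects * 4)
    recordings = []
    roi_store = {}
    for s in range(config.n_subjects):
        sid = f"S{s + 1:02d}"
        for k, condition in enumerate(("alert", "fatigue")):
            source_rng_seed = int(children[4 * s + 2 * k].generate_state(1)[0] % (2**31))
            noise_seed = int(children[4 * s + 2 * k + 1].generate_state(1)[0] % (2**31))
            signals = simulate_roi_sources(config, atlas.roi_names, condition,
                                           source_rng_seed)
            rec = project_sources(
                signals, atlas, sources, leadfield, config.sensor_snr,
                noise_seed, fs=config.fs, subject_id=sid, condition=condition,
            )
            recordings.append(rec)
            roi_store[(sid, condition)] = signals
    return SimulatedDataset(
        recordings=recordings,
        ground_truth={"alert": list(config.couplings_alert),
                      "fatigue": list(config.couplings_fatigue)},
        roi_source_signals=roi_store,
    )


def inject_artifacts(
    rec: Recording,
    seed: int = 0,
    ramp_amplitude: float = 5.0,
    burst_amplitude: float = 5.0,
    burst_duration: float = 0.5,
) -> tuple[Recording, np.ndarray]:
    """Add a low-frequency frontal ramp and a broadband burst component.

    A deliberately crude artifact injector for exercising the removal
    stage: a slow drift loaded on frontal channels (ocular-like) and a
    short broadband burst with a random topography (muscle-like).  Returns
    the contaminated recording and the injected component waveforms
    (2, n_samples) for before/after comparisons.
    """
    rng = np.random.default_rng(seed)
    n = rec.n_samples
    t = np.arange(n) / rec.fs
    ramp = np.sin(2 * np.pi * 0.3 * t) * ramp_amplitude * rec.data.std()
    frontal = np.array([
        1.0 if c.upper().startswith(("FP", "AF", "F")) else 0.1
        for c in rec.channel_names
    ])
    burst = np.zeros(n)
    start = rng.integers(0, max(1, n - int(burst_duration * rec.fs)))
    stop = start + int(burst_duration * rec.fs)
    burst[start:stop] = rng.standard_normal(stop - start)
    burst *= burst_amplitude * rec.data.std()
    topo = rng.standard_normal(rec.n_channels)
    topo /= np.linalg.norm(topo)
    data = rec.data + np.outer(frontal, ramp) + np.outer(topo, burst)
    contaminated = rec.with_data(data)
    return contaminated, np.vstack([ramp, burst])
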
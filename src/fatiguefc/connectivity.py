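"""Phase-lag-index connectivity, Welch band power and feature vectorization.

The phase lag index (PLI) between two signals is

    PLI = | E[ sign( Im S_xy ) ] |

where S_xy is the cross-spectrum of a data window and E averages over
windows: 0 when x leads and lags y equally often (including all zero-lag
coupling, the volume-conduction case), 1 when one signal consistently
leads.  It is computed per frequency bin and averaged over the bins whose
center falls in the analysis band (half-open [f_low, f_high)).

Window length follows the minimum-cycles rule: at least
n_cycles / central-frequency seconds (5 cycles by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .bands import TOTAL_RANGE, BandDefinition
from .recording import Recording

__all__ = [
    "ConnectivityMatrix",
    "SpectralEstimate",
    "FeatureVector",
    "window_length_seconds",
    "split_windows",
    "cross_spectrum",
    "pli",
    "pli_brute_force",
    "connectivity_matrix",
    "lower_triangle",
    "welch_psd",
    "relative_band_power",
    "psd_features",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ConnectivityMatrix:
    """Symmetric PLI matrix with zero diagonal, entries in [0, 1]."""

    values: np.ndarray  # (n, n)
    band: BandDefinition
    space: str  # "sensor" | "source"
    node_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.node_names)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("connectivity matrix must be exactly symmetric")
        if np.any(np.diagonal(self.values) != 0):
            raise ValueError("diagonal must be exactly zero")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("PLI values must lie in [0, 1]")
        if self.space not in ("sensor", "source"):
            raise ValueError(f"space must be 'sensor' or 'source', got {self.space!r}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def to_text(self, path, delimiter: str = "\t") -> None:
        header = delimiter.join(self.node_names)
        np.savetxt(path, self.values, delimiter=delimiter, header=header, fmt="%.10g")

    def plot(self, ax=None):
        """Heatmap of the matrix (returns the matplotlib Axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.values, vmin=0, vmax=1, cmap="viridis")
        ax.set_title(f"PLI ({self.band.name}, {self.space} space)")
        ax.figure.colorbar(im, ax=ax, label="PLI")
        return ax


@dataclass
class SpectralEstimate:
    frequencies: np.ndarray  # (n_freqs,) ascending Hz
    power: np.ndarray  # (n_channels, n_freqs), >= 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly ascending")
        if self.power.min() < 0:
            raise ValueError("power densities must be non-negative")


@dataclass
class FeatureVector:
    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels),):
            raise ValueError("values/labels length mismatch")
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("feature labels must be unique")


# ---------------------------------------------------------------------------
# windows


def window_length_seconds(band: BandDefinition, n_cycles: int = 5) -> float:
    """Minimum admissible window length: n_cycles / central frequency."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    return n_cycles / band.center


def split_windows(
    series: np.ndarray,
    fs: float,
    window_seconds: float,
    overlap_fraction: float = 0.0,
) -> np.ndarray:
    """Cut a (n_channels, T) array into (n_windows, n_channels, n_samples).

    Windows are contiguous and non-overlapping by default; a trailing
    partial window is discarded.
    """
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must lie in [0, 1)")
    series = np.atleast_2d(np.asarray(series, dtype=float))
    n_samp = int(round(window_seconds * fs))
    if n_samp < 2:
        raise ValueError(f"window of {window_seconds} s is shorter than 2 samples")
    if n_samp > series.shape[1]:
        raise ValueError(
            f"window of {n_samp} samples exceeds the recording length "
            f"{series.shape[1]}"
        )
    step = max(1, int(round(n_samp * (1 - overlap_fraction))))
    starts = range(0, series.shape[1] - n_samp + 1, step)
    return np.stack([series[:, s : s + n_samp] for s in starts], axis=0)


# ---------------------------------------------------------------------------
# PLI


def _tapered_fft(windows: np.ndarray) -> np.ndarray:
    """Hann-tapered rFFT of (n_windows, n_samples) -> (n_windows, n_bins)."""
    taper = scipy.signal.windows.hann(windows.shape[-1], sym=False)
    return np.fft.rfft(windows * taper, axis=-1)


def cross_spectrum(
    x_windows: np.ndarray, y_windows: np.ndarray, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window tapered cross-spectra X(f) conj(Y(f)).

    Returns (spectra (n_windows, n_bins) complex, frequencies (n_bins,) Hz).
    """
    x_windows = np.atleast_2d(x_windows)
    y_windows = np.atleast_2d(y_windows)
    if x_windows.shape != y_windows.shape:
        raise ValueError(
            f"window arrays differ in shape: {x_windows.shape} vs {y_windows.shape}"
        )
    X = _tapered_fft(x_windows)
    Y = _tapered_fft(y_windows)
    freqs = np.fft.rfftfreq(x_windows.shape[-1], d=1.0 / fs)
    return X * np.conj(Y), freqs


#: imaginary parts below this fraction of the cross-spectral magnitude are
#: treated as exactly zero (sign contributes 0) — without the deadband,
#: floating-point roundoff in Im(X conj(Y)) for proportional signals would
#: produce random signs where the true imaginary part is identically zero.
_IMAG_DEADBAND = 1e-12


def _im_signs(spectra: np.ndarray) -> np.ndarray:
    """sign(Im S) with numerically-zero imaginary parts mapped to 0."""
    im = spectra.imag
    signs = np.sign(im)
    signs[np.abs(im) <= _IMAG_DEADBAND * np.abs(spectra)] = 0.0
    return signs


def _band_bins(freqs: np.ndarray, band: BandDefinition) -> np.ndarray:
    mask = (freqs >= band.f_low) & (freqs < band.f_high)
    if not np.any(mask):
        df = freqs[1] - freqs[0] if len(freqs) > 1 else float("nan")
        raise ValueError(
            f"no frequency bin inside band {band.name!r} "
            f"[{band.f_low}, {band.f_high}) Hz with bin spacing {df:.4g} Hz; "
            "use longer windows"
        )
    return mask


def pli(
    x_windows: np.ndarray,
    y_windows: np.ndarray,
    fs: float,
    band: BandDefinition,
) -> float:
    """Phase lag index between two windowed signals in one band.

    Per in-band bin the signs of Im S_xy are averaged over windows and the
    absolute value taken; the band value is the unweighted mean over bins.
    sign(0) contributes 0 (an exactly-real bin is neither lead nor lag).
    """
    S, freqs = cross_spectrum(x_windows, y_windows, fs)
    if S.shape[0] < 2:
        raise ValueError("PLI requires at least 2 windows")
    mask = _band_bins(freqs, band)
    signs = _im_signs(S[:, mask])
    return float(np.abs(signs.mean(axis=0)).mean())


def pli_brute_force(
    x_windows: np.ndarray,
    y_windows: np.ndarray,
    fs: float,
    band: BandDefinition,
) -> float:
    """Direct per-bin sign-count PLI (independent check route).

    Loops over windows and bins, tallying lead/lag counts explicitly.
    """
    x_windows = np.atleast_2d(x_windows)
    y_windows = np.atleast_2d(y_windows)
    n_win, n_samp = x_windows.shape
    if n_win < 2:
        raise ValueError("PLI requires at least 2 windows")
    taper = scipy.signal.windows.hann(n_samp, sym=False)
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    bins = [i for i, f in enumerate(freqs) if band.f_low <= f < band.f_high]
    if not bins:
        raise ValueError("no in-band frequency bin")
    per_bin = []
    for b in bins:
        tally = 0.0
        for w in range(n_win):
            X = np.fft.rfft(x_windows[w] * taper)[b]
            Y = np.fft.rfft(y_windows[w] * taper)[b]
            S = X * np.conj(Y)
            im = S.imag if abs(S.imag) > _IMAG_DEADBAND * abs(S) else 0.0
            tally += int(im > 0) - int(im < 0)
        per_bin.append(abs(tally / n_win))
    return float(np.mean(per_bin))


def connectivity_matrix(
    series: "ROITimeSeriesLike | Recording | np.ndarray",
    band: BandDefinition,
    window_seconds: "float | None" = None,
    fs: "float | None" = None,
    node_names: "list[str] | None" = None,
    space: "str | None" = None,
    n_cycles: int = 5,
) -> ConnectivityMatrix:
    """All-pairs PLI matrix for a multichannel series.

    Accepts a Recording (sensor space), an ROITimeSeries (source space) or
    a bare array with ``fs``/``node_names`` given.  The window length
    defaults to the band's minimum admissible length rounded up to a whole
    number of samples.
    """
    from .parcellation import ROITimeSeries  # local import to avoid a cycle

    if isinstance(series, Recording):
        data, fs_, names, space_ = series.data, series.fs, series.channel_names, "sensor"
    elif isinstance(series, ROITimeSeries):
        data, fs_, names, space_ = series.data, series.fs, series.roi_names, "source"
    else:
        if fs is None:
            raise ValueError("fs is required for a bare array input")
        data = np.atleast_2d(np.asarray(series, dtype=float))
        fs_ = fs
        names = node_names or [f"node{i}" for i in range(data.shape[0])]
        space_ = space or "sensor"
    if space is not None:
        space_ = space
    n_nodes = data.shape[0]
    if n_nodes < 2:
        raise ValueError("connectivity needs at least 2 nodes")

    if window_seconds is None:
        min_len = window_length_seconds(band, n_cycles)
        window_seconds = np.ceil(min_len * fs_) / fs_
    windows = split_windows(data, fs_, window_seconds)  # (n_win, n_nodes, n_samp)
    if windows.shape[0] < 2:
        raise ValueError("recording too short for 2 analysis windows")
    spectra = _tapered_fft(windows.transpose(1, 0, 2))  # (n_nodes, n_win, n_bins)
    freqs = np.fft.rfftfreq(windows.shape[-1], d=1.0 / fs_)
    mask = _band_bins(freqs, band)
    A = spectra[:, :, mask]

    values = np.zeros((n_nodes, n_nodes))
    for i in range(n_nodes - 1):
        # Im(X_i conj(X_j)) for all j > i, vectorized over windows and bins
        S = A[i, None, :, :] * np.conj(A[i + 1 :, :, :])
        v = np.abs(_im_signs(S).mean(axis=1)).mean(axis=1)
        values[i, i + 1 :] = v
        values[i + 1 :, i] = v
    return ConnectivityMatrix(values=values, band=band, space=space_, node_names=list(names))


def lower_triangle(cm: ConnectivityMatrix) -> FeatureVector:
    """Strict lower triangle in row-major order (i > j) with pair labels."""
    n = cm.n_nodes
    vals, labels = [], []
    for i in range(n):
        for j in range(i):
            vals.append(cm.values[i, j])
            labels.append(f"{cm.node_names[i]}~{cm.node_names[j]}")
    return FeatureVector(values=np.array(vals), labels=labels)


def lower_triangle_pairs(n: int) -> list[tuple[int, int]]:
    """(i, j) index pairs of the strict lower triangle, row-major."""
    return [(i, j) for i in range(n) for j in range(i)]


# ---------------------------------------------------------------------------
# spectral features


def welch_psd(
    rec: Recording,
    segment_seconds: float = 2.0,
    overlap_fraction: float = 0.5,
) -> SpectralEstimate:
    """Welch power spectral density: mean of tapered segment periodograms."""
    nperseg = int(round(segment_seconds * rec.fs))
    if nperseg > rec.n_samples:
        raise ValueError(
            f"segment of {segment_seconds} s exceeds the {rec.duration:.3g} s recording"
        )
    freqs, power = scipy.signal.welch(
        rec.data,
        fs=rec.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap_fraction)),
        axis=-1,
    )
    return SpectralEstimate(
        frequencies=freqs,
        power=power,
        params={"segment_seconds": segment_seconds, "overlap_fraction": overlap_fraction,
                "taper": "hann"},
    )


def relative_band_power(
    spec: SpectralEstimate,
    band: BandDefinition,
    total_low: float = TOTAL_RANGE[0],
    total_high: float = TOTAL_RANGE[1],
) -> np.ndarray:
    """Band power normalized by total power over [total_low, total_high).

    Returns one value in [0, 1] per channel.
    """
    if not (total_low <= band.f_low and band.f_high <= total_high):
        raise ValueError(
            f"band {band.name!r} not inside total range [{total_low}, {total_high}]"
        )
    f = spec.frequencies
    band_mask = (f >= band.f_low) & (f < band.f_high)
    total_mask = (f >= total_low) & (f < total_high)
    total = spec.power[:, total_mask].sum(axis=1)
    if np.any(total == 0):
        raise ValueError("zero total power in the analysis range")
    return spec.power[:, band_mask].sum(axis=1) / total


def psd_features(
    rec: Recording,
    bands: list[BandDefinition],
    segment_seconds: float = 2.0,
    overlap_fraction: float = 0.5,
) -> FeatureVector:
    """Relative band power per channel per band (blocks of n_channels)."""
    spec = welch_psd(rec, segment_seconds, overlap_fraction)
    values, labels = [], []
    for band in bands:
        rp = relative_band_power(spec, band)
        values.extend(rp)
        labels.extend(f"{ch}:{band.name}" for ch in rec.channel_names)
    return FeatureVector(values=np.array(values), labels=labels)
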
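"""Resampling, band decomposition and blind-source-separation denoising.

Artifact handling follows the two-stage convention: SOBI (joint
diagonalization of time-lagged covariances) isolates stereotyped artifact
components for removal, and BSS-CCA zeroes components whose lag-1
autocorrelation is low (broadband, muscle-like activity).  Artifact removal
operates on broadband data; band decomposition comes after.

The automatic component-flagging heuristics are this package's own
(low autocorrelation, or low-frequency-dominated power with a frontal
topography); a manual index list is always accepted instead.
"""

from __future__ import annotations

import numpy as np

from .bands import BandDefinition
from .recording import Recording

__all__ = [
    "resample",
    "bandpass",
    "sobi",
    "joint_diagonalize",
    "bss_cca_denoise",
    "remove_components",
    "flag_artifact_components",
]


def resample(rec: Recording, target_fs: float) -> Recording:
    """Anti-aliased polyphase resampling to a lower rate.

    Upsampling is not supported (the pipeline only ever decimates).
    """
    if target_fs > rec.fs:
        raise ValueError(
            f"upsampling not supported: target {target_fs} Hz > {rec.fs} Hz"
        )
    if target_fs == rec.fs:
        return rec.with_data(rec.data.copy())
    from fractions import Fraction

    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    import scipy.signal

    out = scipy.signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=-1)
    return rec.with_data(out, fs=target_fs)


def bandpass(rec: Recording, band: BandDefinition) -> Recording:
    """Zero-phase FIR (Hamming) band-pass into one analysis band."""
    band.validate_for_fs(rec.fs)
    import mne.filter

    out = mne.filter.filter_data(
        rec.data,
        sfreq=rec.fs,
        l_freq=band.f_low,
        h_freq=band.f_high,
        method="fir",
        fir_window="hamming",
        fir_design="firwin",
        phase="zero",
        verbose="error",
    )
    return rec.with_data(out)


# ---------------------------------------------------------------------------
# SOBI


def joint_diagonalize(
    matrices: np.ndarray, tol: float = 1e-8, max_sweeps: int = 100
) -> np.ndarray:
    """Approximate joint diagonalization of symmetric matrices.

    Jacobi (Givens) rotation sweeps maximizing the summed squared
    diagonals; returns the orthogonal matrix V such that V' M V is as
    diagonal as possible for every M.  Converged when every rotation angle
    in a sweep satisfies |sin theta| < tol.
    """
    M = np.array(matrices, dtype=float, copy=True)
    if M.ndim != 3 or M.shape[1] != M.shape[2]:
        raise ValueError("expected a stack of square matrices (k, n, n)")
    n = M.shape[1]
    V = np.eye(n)
    for _ in range(max_sweeps):
        biggest = 0.0
        for p in range(n - 1):
            for q in range(p + 1, n):
                ton = M[:, p, p] - M[:, q, q]
                toff = M[:, p, q] + M[:, q, p]
                # principal axis of sum_k [ton, toff][ton, toff]'
                g11 = ton @ ton
                g22 = toff @ toff
                g12 = ton @ toff
                theta = 0.25 * np.arctan2(2 * g12, g11 - g22)
                c, s = np.cos(theta), np.sin(theta)
                if abs(s) < tol:
                    continue
                biggest = max(biggest, abs(s))
                rot_p = c * M[:, :, p] + s * M[:, :, q]
                rot_q = -s * M[:, :, p] + c * M[:, :, q]
                M[:, :, p], M[:, :, q] = rot_p, rot_q
                rot_p = c * M[:, p, :] + s * M[:, q, :]
                rot_q = -s * M[:, p, :] + c * M[:, q, :]
                M[:, p, :], M[:, q, :] = rot_p, rot_q
                vp = c * V[:, p] + s * V[:, q]
                vq = -s * V[:, p] + c * V[:, q]
                V[:, p], V[:, q] = vp, vq
        if biggest < tol:
            break
    return V


def sobi(
    rec: Recording,
    lags: "list[int] | None" = None,
    rank_rtol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Second-order blind identification.

    Whitening followed by joint diagonalization of symmetrized time-lagged
    covariance matrices.  Components are ordered by the variance they
    explain in the sensor data.

    Returns
    -------
    unmixing : ndarray (n_components, n_channels)
        Sources = unmixing @ data (after mean removal).
    sources : ndarray (n_components, n_samples)
    """
    X = rec.data - rec.data.mean(axis=1, keepdims=True)
    n_ch, T = X.shape
    if n_ch < 2:
        raise ValueError("SOBI needs at least 2 channels")
    if lags is None:
        lags = list(range(1, min(51, T // 2)))
    if max(lags) >= T // 2:
        raise ValueError(f"max lag {max(lags)} must be below n_samples/2 = {T // 2}")

    C0 = X @ X.T / T
    evals, evecs = np.linalg.eigh(C0)
    if evals.max() <= 0 or evals.min() < rank_rtol * evals.max():
        raise ValueError(
            "rank-deficient channel covariance; reduce dimensionality "
            "(drop linearly dependent channels) before SOBI"
        )
    whitener = (evecs / np.sqrt(evals)).T  # (n_ch, n_ch)
    Z = whitener @ X

    lagged = []
    for lag in lags:
        C = Z[:, :-lag] @ Z[:, lag:].T / (T - lag)
        lagged.append(0.5 * (C + C.T))
    V = joint_diagonalize(np.stack(lagged))

    unmixing = V.T @ whitener
    sources = unmixing @ X
    # order by explained sensor variance: mixing column norms (unit-variance
    # whitened sources make this || pinv(unmixing) column ||^2)
    mixing = np.linalg.pinv(unmixing)
    order = np.argsort(-(mixing**2).sum(axis=0) * sources.var(axis=1))
    return unmixing[order], sources[order]


def remove_components(
    rec: Recording, unmixing: np.ndarray, drop: "list[int]"
) -> Recording:
    """Zero the listed components and back-project to sensor space."""
    n_comp = unmixing.shape[0]
    drop = list(drop)
    for idx in drop:
        if not (0 <= idx < n_comp):
            raise IndexError(f"component index {idx} out of range 0..{n_comp - 1}")
    mean = rec.data.mean(axis=1, keepdims=True)
    X = rec.data - mean
    S = unmixing @ X
    S[drop] = 0.0
    mixing = np.linalg.pinv(unmixing)
    return rec.with_data(mixing @ S + mean)


def flag_artifact_components(
    rec: Recording,
    unmixing: np.ndarray,
    sources: np.ndarray,
    autocorr_threshold: float = 0.6,
    low_freq_fraction: float = 0.6,
    frontal_channels: "list[str] | None" = None,
) -> list[int]:
    """Automatic artifact-component heuristics.

    Flags components with lag-1 autocorrelation below ``autocorr_threshold``
    (muscle-like broadband), or with more than ``low_freq_fraction`` of
    their power below 4 Hz *and* a frontal-dominated mixing topography
    (ocular-like).  Heuristics are this package's own convention.
    """
    flags = []
    mixing = np.linalg.pinv(unmixing)
    if frontal_channels is None:
        frontal_channels = [c for c in rec.channel_names
                            if c.upper().startswith(("FP", "AF"))]
    frontal_idx = [rec.channel_names.index(c) for c in frontal_channels]
    freqs = np.fft.rfftfreq(sources.shape[1], d=1.0 / rec.fs)
    for i, s in enumerate(sources):
        s0 = s - s.mean()
        denom = float(s0 @ s0)
        ac1 = float(s0[:-1] @ s0[1:]) / denom if denom > 0 else 0.0
        if ac1 < autocorr_threshold:
            flags.append(i)
            continue
        psd = np.abs(np.fft.rfft(s0)) ** 2
        low = psd[freqs < 4.0].sum() / psd.sum() if psd.sum() > 0 else 0.0
        if low > low_freq_fraction and frontal_idx:
            topo = np.abs(mixing[:, i])
            if topo[frontal_idx].mean() > topo.mean():
                flags.append(i)
    return flags


# ---------------------------------------------------------------------------
# BSS-CCA


def _inv_sqrt_sym(C: np.ndarray, rtol: float = 1e-12) -> np.ndarray:
    w, V = np.linalg.eigh(C)
    keep = w > rtol * w.max()
    inv_sqrt = np.zeros_like(w)
    inv_sqrt[keep] = 1.0 / np.sqrt(w[keep])
    return (V * inv_sqrt) @ V.T


def bss_cca_denoise(
    rec: Recording, autocorr_threshold: float = 0.6
) -> Recording:
    """Remove low-autocorrelation canonical components.

    Canonical correlation analysis between the signal and its one-sample
    delayed copy yields components ordered by lag-1 autocorrelation;
    components whose canonical correlation falls below the threshold are
    zeroed before back-projection (they carry broadband, muscle-like
    activity).
    """
    if not (0 <= autocorr_threshold < 1):
        raise ValueError(
            "autocorr_threshold must lie in [0, 1); a threshold of 1 would "
            "remove every component"
        )
    mean = rec.data.mean(axis=1, keepdims=True)
    X = rec.data - mean
    Y, Z = X[:, :-1], X[:, 1:]
    T = Y.shape[1]
    Cyy = Y @ Y.T / T
    Czz = Z @ Z.T / T
    Cyz = Y @ Z.T / T
    Wy = _inv_sqrt_sym(Cyy)
    Wz = _inv_sqrt_sym(Czz)
    U, svals, _ = np.linalg.svd(Wy @ Cyz @ Wz.T)
    A = Wy @ U  # canonical projection vectors, columns
    unmixing = A.T
    sources = unmixing @ X
    keep = svals >= autocorr_threshold
    mixing = np.linalg.pinv(unmixing)
    clean = mixing[:, keep] @ sources[keep] + mean
    return rec.with_data(clean)
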
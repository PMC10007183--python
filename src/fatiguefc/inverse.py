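"""sLORETA source estimation.

The minimum-norm kernel K = G' (G G' + lambda C)^+ maps average-referenced
sensor data to raw dipole currents; sLORETA standardizes each vertex's
3-vector estimate by the inverse matrix square root of its 3x3 diagonal
block of the resolution matrix R = K G.  In the noiseless single-source
case the standardized power peaks exactly at the generating vertex (zero
localization error), the property that motivates the method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .headmodel import Leadfield, SourceSpace
from .recording import Recording

__all__ = [
    "InverseOperator",
    "SourceEstimate",
    "default_lambda",
    "compute_inverse_operator",
    "apply_inverse",
    "localization_error",
    "save_inverse_operator",
    "load_inverse_operator",
]


@dataclass
class InverseOperator:
    kernel: np.ndarray  # (n_dipoles, n_sensors)
    standardizer: np.ndarray  # (n_vertices, 3, 3) inverse-sqrt factors W_v
    lam: float
    resolution_blocks: np.ndarray  # (n_vertices, 3, 3) R_vv, kept for diagnostics

    @property
    def n_sensors(self) -> int:
        return self.kernel.shape[1]

    @property
    def n_vertices(self) -> int:
        return self.kernel.shape[0] // 3


@dataclass
class SourceEstimate:
    """Standardized dipole activations, 3 rows per vertex."""

    activations: np.ndarray  # (n_dipoles, n_times)
    fs: float
    source_space: "SourceSpace | None" = None

    @property
    def n_vertices(self) -> int:
        return self.activations.shape[0] // 3

    @property
    def n_times(self) -> int:
        return self.activations.shape[1]

    def vertex_power(self) -> np.ndarray:
        """Time-averaged standardized power per vertex."""
        sq = self.activations**2
        return sq.reshape(self.n_vertices, 3, -1).sum(axis=1).mean(axis=1)


def default_lambda(lf: Leadfield, snr: float = 3.0) -> float:
    """Conventional minimum-norm regularization heuristic.

    lambda = trace(G G') / (n_sensors * snr^2), with an assumed data SNR
    (amplitude ratio) of 3 by default.
    """
    G = lf.gain
    return float(np.einsum("ij,ij->", G, G) / (G.shape[0] * snr**2))


def compute_inverse_operator(
    lf: Leadfield,
    noise_cov: "np.ndarray | None" = None,
    lam: "float | None" = None,
    rank_rtol: float = 1e-10,
) -> InverseOperator:
    """Build the sLORETA inverse operator from a leadfield.

    Parameters
    ----------
    lf : Leadfield
        Forward gain matrix (average-referenced or not; referencing is
        applied if missing).
    noise_cov : ndarray (n_sensors, n_sensors), optional
        Symmetric PSD noise covariance; identity if omitted.
    lam : float, optional
        Regularization scalar >= 0; the SNR-3 heuristic if omitted.
    rank_rtol : float
        Relative eigenvalue cutoff of the pseudo-inverse (average-referenced
        data have rank n_sensors - 1).
    """
    if not lf.referenced:
        lf = lf.average_referenced()
    G = lf.gain
    n_sensors = G.shape[0]
    if noise_cov is None:
        C = np.eye(n_sensors)
    else:
        C = np.asarray(noise_cov, dtype=float)
        if C.shape != (n_sensors, n_sensors):
            raise ValueError(
                f"noise covariance shape {C.shape} does not match "
                f"{n_sensors} sensors"
            )
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("noise covariance must be symmetric")
    if lam is None:
        lam = default_lambda(lf)
    if lam < 0:
        raise ValueError("lambda must be non-negative")

    M = G @ G.T + lam * C
    M = 0.5 * (M + M.T)
    # eigendecomposition pseudo-inverse with relative cutoff
    evals, evecs = np.linalg.eigh(M)
    keep = evals > rank_rtol * evals.max()
    Minv = (evecs[:, keep] / evals[keep]) @ evecs[:, keep].T
    K = G.T @ Minv

    n_vert = G.shape[1] // 3
    blocks = np.empty((n_vert, 3, 3))
    standardizer = np.empty((n_vert, 3, 3))
    for v in range(n_vert):
        Rvv = K[3 * v : 3 * v + 3] @ G[:, 3 * v : 3 * v + 3]
        Rvv = 0.5 * (Rvv + Rvv.T)
        blocks[v] = Rvv
        standardizer[v] = _inv_sqrt_psd(Rvv)
    return InverseOperator(kernel=K, standardizer=standardizer, lam=float(lam),
                           resolution_blocks=blocks)


def _inv_sqrt_psd(A: np.ndarray, rtol: float = 1e-12) -> np.ndarray:
    """Pseudo inverse square root of a symmetric PSD 3x3 block."""
    w, V = np.linalg.eigh(A)
    wmax = max(w.max(), 0.0)
    inv_sqrt = np.where(w > rtol * wmax if wmax > 0 else w > 0, 1.0 / np.sqrt(np.abs(w)), 0.0)
    return (V * inv_sqrt) @ V.T


def apply_inverse(
    op: InverseOperator,
    rec: Recording,
    source_space: "SourceSpace | None" = None,
) -> SourceEstimate:
    """Standardized source time series from sensor data.

    The recording is average-referenced (a no-op if it already is), passed
    through the kernel, and each vertex's 3-vector time series is whitened
    by the inverse square root of its resolution block.
    """
    if rec.n_channels != op.n_sensors:
        raise ValueError(
            f"recording has {rec.n_channels} channels but the inverse "
            f"operator expects {op.n_sensors}"
        )
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    raw = op.kernel @ data  # (n_dipoles, T)
    n_vert = op.n_vertices
    blocks = raw.reshape(n_vert, 3, -1)
    standardized = np.einsum("vij,vjt->vit", op.standardizer, blocks)
    return SourceEstimate(
        activations=standardized.reshape(3 * n_vert, -1),
        fs=rec.fs,
        source_space=source_space,
    )


def save_inverse_operator(op: InverseOperator, path,
                          leadfield_checksum: str = "") -> None:
    """Serialize to a compressed array container with a small header."""
    np.savez_compressed(
        path, kernel=op.kernel, standardizer=op.standardizer,
        resolution_blocks=op.resolution_blocks,
        header=np.array([op.lam, op.kernel.shape[0], op.kernel.shape[1]]),
        leadfield_checksum=np.array(leadfield_checksum),
    )


def load_inverse_operator(path,
                          expect_leadfield_checksum: "str | None" = None
                          ) -> InverseOperator:
    with np.load(path, allow_pickle=False) as z:
        lam, n_dip, n_sens = z["header"]
        kernel = z["kernel"]
        if kernel.shape != (int(n_dip), int(n_sens)):
            raise ValueError(
                f"inverse operator header declares shape "
                f"({int(n_dip)}, {int(n_sens)}) but kernel is {kernel.shape}"
            )
        stored = str(z["leadfield_checksum"])
        if expect_leadfield_checksum is not None and stored \
                and stored != expect_leadfield_checksum:
            raise ValueError(
                "inverse operator was built from a different leadfield "
                f"(checksum {stored} != {expect_leadfield_checksum})"
            )
        return InverseOperator(kernel=kernel, standardizer=z["standardizer"],
                               lam=float(lam),
                               resolution_blocks=z["resolution_blocks"])


def localization_error(
    estimate: SourceEstimate,
    true_vertex: int,
    sources: SourceSpace,
) -> float:
    """Distance (m) from the peak standardized-power vertex to the truth."""
    if not (0 <= true_vertex < sources.n_vertices):
        raise IndexError(f"vertex index {true_vertex} out of range")
    peak = int(np.argmax(estimate.vertex_power()))
    return float(
        np.linalg.norm(
            sources.vertex_positions[peak] - sources.vertex_positions[true_vertex]
        )
    )
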
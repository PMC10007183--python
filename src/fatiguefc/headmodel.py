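"""Forward modelling: sensor montage, source space and spherical leadfield.

The scalp potential generated by a current dipole is computed analytically
for a three-shell concentric-spheres volume conductor (inner skull, outer
skull, scalp) via a truncated Legendre-series expansion.  A realistic
(BEM/FEM) leadfield computed elsewhere can be imported from delimited text
instead, so the analytic model is a default, not a limitation.

Geometry conventions: head-centered coordinates with +x to the right ear,
+y to the nasion, +z to the vertex; the sagittal plane is x = 0.  All
lengths in meters, conductivities in S/m, potentials in volts per unit
dipole moment (A*m).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SensorArray",
    "SourceSpace",
    "HeadModelParams",
    "Leadfield",
    "build_sensor_array",
    "load_sensor_array",
    "build_source_space",
    "compute_leadfield",
    "save_leadfield",
    "load_leadfield",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class SensorArray:
    """EEG electrodes on the scalp sphere."""

    names: list[str]
    positions: np.ndarray  # (n_sensors, 3), meters, all at scalp radius

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.names) != len(set(self.names)):
            raise ValueError("duplicate channel names in sensor array")
        if self.positions.shape != (len(self.names), 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.names)} names"
            )
        radii = np.linalg.norm(self.positions, axis=1)
        if radii.size and not np.allclose(radii, radii[0], rtol=1e-9):
            raise ValueError("sensors are not all at the same scalp radius")

    @property
    def n_sensors(self) -> int:
        return len(self.names)

    @property
    def radius(self) -> float:
        return float(np.linalg.norm(self.positions[0]))


@dataclass
class SourceSpace:
    """Candidate dipole locations on a cortical shell.

    Each vertex carries an orthonormal triad of dipole orientations
    (3 dipoles per vertex); the first axis is the outward radial direction,
    playing the role of the cortical normal.
    """

    vertex_positions: np.ndarray  # (n_vertices, 3) meters
    orientations: np.ndarray  # (n_vertices, 3, 3); [v, k] = k-th axis
    hemispheres: np.ndarray  # (n_vertices,) of "lh" / "rh"

    def __post_init__(self) -> None:
        self.vertex_positions = np.asarray(self.vertex_positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        n = self.vertex_positions.shape[0]
        if self.orientations.shape != (n, 3, 3):
            raise ValueError("orientations must have shape (n_vertices, 3, 3)")
        gram = np.einsum("vik,vjk->vij", self.orientations, self.orientations)
        if not np.allclose(gram, np.eye(3), atol=1e-9):
            raise ValueError("orientation triads are not orthonormal")

    @property
    def n_vertices(self) -> int:
        return self.vertex_positions.shape[0]

    @property
    def n_dipoles(self) -> int:
        return 3 * self.n_vertices


@dataclass(frozen=True)
class HeadModelParams:
    """Three-shell concentric-spheres conductor.

    Default radii / conductivities are standard literature values for
    inner skull, outer skull (bone) and scalp.
    """

    radii: tuple[float, float, float] = (0.087, 0.092, 0.100)
    conductivities: tuple[float, float, float] = (0.33, 0.0042, 0.33)
    series_terms: int = 80

    def __post_init__(self) -> None:
        if not (0 < self.radii[0] < self.radii[1] < self.radii[2]):
            raise ValueError(f"shell radii must be strictly increasing: {self.radii}")
        if any(s <= 0 for s in self.conductivities):
            raise ValueError("conductivities must be positive")
        if self.series_terms < 20:
            raise ValueError("series_terms must be at least 20")


@dataclass
class Leadfield:
    """Gain matrix: scalp potential per unit dipole moment.

    ``gain[i, 3*v + k]`` is the potential at sensor ``i`` produced by a unit
    dipole at vertex ``v`` along its ``k``-th orientation axis.
    """

    gain: np.ndarray  # (n_sensors, n_dipoles)
    referenced: bool = False
    sensor_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.ndim != 2:
            raise ValueError("gain must be a 2-D matrix")
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("leadfield contains non-finite entries")

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_dipoles(self) -> int:
        return self.gain.shape[1]

    def average_referenced(self) -> "Leadfield":
        """Return a copy with the average reference applied (idempotent)."""
        gain = self.gain - self.gain.mean(axis=0, keepdims=True)
        return Leadfield(gain=gain, referenced=True, sensor_names=list(self.sensor_names))


# ---------------------------------------------------------------------------
# montage

#: the 32-channel cap of the study, in recording order
STANDARD_32_CHANNELS = [
    "FP1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3",
    "CP1", "CP5", "P7", "P3", "PZ", "PO3", "O1", "OZ",
    "O2", "PO4", "P4", "P8", "CP6", "CP2", "C4", "T8",
    "FC6", "FC2", "F4", "F8", "AF4", "FP2", "FZ", "CZ",
]


def _standard_32_positions() -> np.ndarray:
    """Idealized unit-sphere positions for the 32-channel 10-20 cap.

    Taken from MNE's packaged idealized montage (same electrode set),
    re-centered on the sphere's origin and projected to unit radius.
    """
    import mne

    montage = mne.channels.make_standard_montage("biosemi32")
    pos = montage.get_positions()["ch_pos"]
    lookup = {name.upper(): np.asarray(p, dtype=float) for name, p in pos.items()}
    pts = np.array([lookup[name] for name in STANDARD_32_CHANNELS])
    # center on the least-squares best-fit sphere (the centroid of a cap
    # is biased downward), then project radially
    center = _fit_sphere_center(pts)
    pts = pts - center
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def _fit_sphere_center(pts: np.ndarray) -> np.ndarray:
    # linear least-squares sphere fit: |p - c|^2 = r^2
    A = np.c_[2 * pts, np.ones(len(pts))]
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:3]


def build_sensor_array(montage_name: str = "standard_32", scalp_radius: float = 0.100) -> SensorArray:
    """Build the electrode array for a named montage, projected to the scalp.

    Parameters
    ----------
    montage_name : str
        Currently ``"standard_32"``, the study's 32-channel 10-20 cap.
    scalp_radius : float
        Scalp sphere radius in meters; all electrodes are placed at this
        radius.
    """
    if montage_name != "standard_32":
        raise ValueError(
            f"unknown montage {montage_name!r}; supported montages: ['standard_32']"
        )
    unit = _standard_32_positions()
    return SensorArray(names=list(STANDARD_32_CHANNELS), positions=unit * scalp_radius)


def load_sensor_array(path, scalp_radius: "float | None" = None) -> SensorArray:
    """Read a custom montage file with one ``name x y z`` line per sensor.

    Delimiters may be whitespace or commas.  If ``scalp_radius`` is given,
    positions are projected radially onto that sphere; otherwise they are
    projected onto the sphere of their mean radius.
    """
    names, rows = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 'name x y z', got {line!r}")
            names.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    pts = np.asarray(rows)
    radii = np.linalg.norm(pts, axis=1)
    if np.any(radii == 0):
        raise ValueError("sensor at the origin cannot be projected to the scalp")
    target = scalp_radius if scalp_radius is not None else float(radii.mean())
    pts = pts / radii[:, None] * target
    return SensorArray(names=names, positions=pts)


# ---------------------------------------------------------------------------
# source space


def build_source_space(
    n_vertices_per_hemisphere: int,
    inner_radius_fraction: float = 0.75,
    seed: int = 0,
    inner_skull_radius: float = 0.087,
) -> SourceSpace:
    """Quasi-uniform cortical-shell source space, split at the sagittal plane.

    Vertices are laid out per hemisphere with an area-uniform Fibonacci
    lattice on the half-sphere (poles at the ears), at radius
    ``inner_radius_fraction * inner_skull_radius``.  A seeded azimuthal
    offset decorrelates the two hemispheres so the space is not exactly
    mirror-symmetric; the layout is deterministic for a fixed seed.

    Each vertex gets an orthonormal triad: axis 0 radial (outward), axes
    1-2 tangential.
    """
    n = int(n_vertices_per_hemisphere)
    if n < 1:
        raise ValueError("n_vertices_per_hemisphere must be >= 1")
    if not (0 < inner_radius_fraction < 1):
        raise ValueError("inner_radius_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    radius = inner_radius_fraction * inner_skull_radius

    golden = np.pi * (3.0 - np.sqrt(5.0))
    k = np.arange(n)
    # polar angle from the +x axis, area-uniform on the open half-sphere
    cos_alpha = 1.0 - (k + 0.5) / n  # in (0, 1): strictly right of x=0
    sin_alpha = np.sqrt(1.0 - cos_alpha**2)

    hemis_pts = []
    for sign in (+1.0, -1.0):  # rh (x>0) then lh (x<0)
        phi = k * golden + rng.uniform(0, 2 * np.pi)
        x = sign * cos_alpha
        y = sin_alpha * np.cos(phi)
        z = sin_alpha * np.sin(phi)
        hemis_pts.append(np.c_[x, y, z] * radius)

    positions = np.vstack([hemis_pts[1], hemis_pts[0]])  # lh block first
    hemispheres = np.array(["lh"] * n + ["rh"] * n)

    orientations = _radial_triads(positions)
    return SourceSpace(
        vertex_positions=positions, orientations=orientations, hemispheres=hemispheres
    )


def _radial_triads(positions: np.ndarray) -> np.ndarray:
    """Per-vertex orthonormal triad with axis 0 along the outward radial."""
    r = positions / np.linalg.norm(positions, axis=1, keepdims=True)
    # pick a helper axis not parallel to r
    helper = np.tile(np.array([0.0, 0.0, 1.0]), (len(r), 1))
    near_pole = np.abs(r[:, 2]) > 0.9
    helper[near_pole] = [0.0, 1.0, 0.0]
    t1 = np.cross(helper, r)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(r, t1)
    return np.stack([r, t1, t2], axis=1)


# ---------------------------------------------------------------------------
# analytic three-shell forward solution


def _shell_surface_factors(params: HeadModelParams, n_terms: int) -> np.ndarray:
    """Series coefficients F_n of the three-shell conductor.

    For each harmonic degree n, F_n is the potential on the outer (scalp)
    surface per unit source coefficient, i.e. the multiplier replacing the
    infinite-medium surface term rho^-(n+1) = 1.  For a single homogeneous
    sphere F_n = (2n+1)/n (the classical result), which the shell solve
    reproduces when all conductivities are equal.
    """
    R = params.radii[2]
    rho1, rho2 = params.radii[0] / R, params.radii[1] / R
    s1, s2, s3 = params.conductivities

    F = np.empty(n_terms + 1)
    F[0] = 0.0
    for n in range(1, n_terms + 1):
        # unknowns: A1, A2, B2, A3, B3 (source coefficient in shell 1 is 1)
        a = np.zeros((5, 5))
        b = np.zeros(5)
        p1n, p1m = rho1**n, rho1 ** -(n + 1)
        p2n, p2m = rho2**n, rho2 ** -(n + 1)
        d1n, d1m = n * rho1 ** (n - 1), -(n + 1) * rho1 ** -(n + 2)
        d2n, d2m = n * rho2 ** (n - 1), -(n + 1) * rho2 ** -(n + 2)
        # potential continuity at rho1:  1*p1m + A1 p1n = A2 p1n + B2 p1m
        a[0] = [p1n, -p1n, -p1m, 0, 0]
        b[0] = -p1m
        # current continuity at rho1
        a[1] = [s1 * d1n, -s2 * d1n, -s2 * d1m, 0, 0]
        b[1] = -s1 * d1m
        # potential continuity at rho2
        a[2] = [0, p2n, p2m, -p2n, -p2m]
        # current continuity at rho2
        a[3] = [0, s2 * d2n, s2 * d2m, -s3 * d2n, -s3 * d2m]
        # insulating outer boundary at rho = 1
        a[4] = [0, 0, 0, n, -(n + 1)]
        sol = np.linalg.solve(a, b)
        F[n] = sol[3] + sol[4]  # A3 + B3 at the scalp surface
    return F


def _legendre_tables(x: np.ndarray, n_terms: int) -> tuple[np.ndarray, np.ndarray]:
    """P_n(x) and P'_n(x) for n = 0..n_terms via stable recurrences."""
    P = np.empty((n_terms + 1,) + x.shape)
    dP = np.empty_like(P)
    P[0], P[1] = 1.0, x
    dP[0], dP[1] = 0.0, 1.0
    for n in range(1, n_terms):
        P[n + 1] = ((2 * n + 1) * x * P[n] - n * P[n - 1]) / (n + 1)
        dP[n + 1] = dP[n - 1] + (2 * n + 1) * P[n]
    return P, dP


def compute_leadfield(
    sensors: SensorArray,
    sources: SourceSpace,
    params: HeadModelParams = HeadModelParams(),
) -> Leadfield:
    """Analytic leadfield of the three-shell spherical conductor.

    The potential of a dipole ``q`` at position ``r0`` (|r0| = b) observed
    at scalp point ``rs`` (|rs| = R) is the truncated series

        V = 1/(4 pi sigma_1 R^2) * sum_n F_n beta^(n-1)
            q . [ n P_n(c) r0_hat + P'_n(c) (rs_hat - c r0_hat) ]

    with beta = b/R, c = cos of the angle between dipole and sensor, and
    F_n the shell factors (F_n = (2n+1)/n for a homogeneous sphere).  The
    average reference is applied to the result.
    """
    R = params.radii[2]
    if not np.allclose(np.linalg.norm(sensors.positions, axis=1), R, rtol=1e-6):
        raise ValueError(
            f"sensors must sit on the outermost shell (radius {R} m); "
            f"got radius {np.linalg.norm(sensors.positions[0]):.6g} m"
        )
    b = np.linalg.norm(sources.vertex_positions, axis=1)
    if np.any(b >= params.radii[0]):
        raise ValueError(
            "all source vertices must lie strictly inside the inner skull "
            f"radius {params.radii[0]} m (max vertex radius {b.max():.6g} m)"
        )

    n_terms = params.series_terms
    F = _shell_surface_factors(params, n_terms)
    ns = np.arange(1, n_terms + 1, dtype=float)

    rs_hat = sensors.positions / R  # (S, 3)
    n_sens = sensors.n_sensors
    gain = np.empty((n_sens, sources.n_dipoles))
    sigma1 = params.conductivities[0]
    scale = 1.0 / (4.0 * np.pi * sigma1 * R * R)

    for v in range(sources.n_vertices):
        beta = b[v] / R
        r0_hat = sources.vertex_positions[v] / b[v] if b[v] > 0 else np.array([0.0, 0.0, 1.0])
        c = rs_hat @ r0_hat  # (S,)
        P, dP = _legendre_tables(c, n_terms)
        # weights per degree: F_n * beta^(n-1)
        w = F[1:] * beta ** (ns - 1.0)
        # radial part: sum_n w_n * n * P_n(c)  -> coefficient of r0_hat
        rad = (w * ns) @ P[1:]  # (S,)
        # tangential part: sum_n w_n * P'_n(c) -> coefficient of (rs_hat - c r0_hat)
        tan = w @ dP[1:]  # (S,)
        # lead vectors L (S, 3): V = L . q
        L = scale * (rad[:, None] * r0_hat[None, :] + tan[:, None] * (rs_hat - c[:, None] * r0_hat[None, :]))
        gain[:, 3 * v : 3 * v + 3] = L @ sources.orientations[v].T

    lf = Leadfield(gain=gain, referenced=False, sensor_names=list(sensors.names))
    return lf.average_referenced()


# ---------------------------------------------------------------------------
# leadfield I/O


def save_leadfield(lf: Leadfield, path, delimiter: str = "\t") -> None:
    """Write the gain matrix as delimited text, one sensor per row."""
    header = delimiter.join(
        f"d{j}" for j in range(lf.n_dipoles)
    )
    np.savetxt(path, lf.gain, delimiter=delimiter, header=header, fmt="%.18e")


def load_leadfield(path, n_sensors: int, n_dipoles: int) -> Leadfield:
    """Read a delimited leadfield and verify its declared shape.

    Accepts comma or tab/whitespace delimited numeric text with an optional
    ``#``-prefixed header row.  The average reference is applied if the
    matrix is not already referenced.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                bad = next(i for i, p in enumerate(parts) if not _is_float(p))
                raise ValueError(
                    f"{path}: non-numeric value {parts[bad]!r} at row {lineno}, "
                    f"column {bad + 1}"
                ) from None
    mat = np.asarray(rows, dtype=float) if rows else np.empty((0, 0))
    if mat.shape != (n_sensors, n_dipoles):
        raise ValueError(
            f"leadfield shape mismatch: expected {n_sensors} sensors x "
            f"{n_dipoles} dipoles, found {mat.shape[0]} x "
            f"{mat.shape[1] if mat.ndim == 2 else 0}"
        )
    col_means = mat.mean(axis=0) if mat.size else np.zeros(0)
    norms = np.linalg.norm(mat, axis=0) if mat.size else np.zeros(0)
    already = np.all(np.abs(col_means) <= 1e-9 * np.maximum(norms, 1e-300))
    lf = Leadfield(gain=mat, referenced=bool(already))
    return lf if already else lf.average_referenced()


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
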
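"""Parcellation of the source space into ROIs and sign-flip averaging.

A geometric atlas (seeded spatial clustering into contiguous parcels, 34
per hemisphere by default, 68 total) stands in for a surface-based
anatomical parcellation, which would require subject MRI data.  ROI time
series are formed by collapsing each vertex's three dipole components onto
one orientation, flipping vertices whose orientation opposes the ROI's
dominant orientation (so that anti-parallel sources do not cancel), and
averaging across the ROI's vertices.

"Orientation more than 90 degrees away from the dominant orientation"
(negative dot product) is the flip criterion — the standard convention for
sign-flip ROI aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .headmodel import SourceSpace
from .inverse import SourceEstimate

__all__ = [
    "Atlas",
    "ROITimeSeries",
    "LOBES",
    "APARC_LOBE_TABLE",
    "build_synthetic_atlas",
    "dominant_orientation",
    "sign_flip_average",
    "map_roi_to_lobe",
]

LOBES = ("frontal", "parietal", "temporal", "occipital", "cingulate", "insula")

#: Desikan-Killiany cortical parcel -> lobe, 34 parcels per hemisphere.
APARC_LOBE_TABLE: dict[str, str] = {
    # frontal (11)
    "superiorfrontal": "frontal", "rostralmiddlefrontal": "frontal",
    "caudalmiddlefrontal": "frontal", "parsopercularis": "frontal",
    "parstriangularis": "frontal", "parsorbitalis": "frontal",
    "lateralorbitofrontal": "frontal", "medialorbitofrontal": "frontal",
    "precentral": "frontal", "paracentral": "frontal", "frontalpole": "frontal",
    # parietal (5)
    "superiorparietal": "parietal", "inferiorparietal": "parietal",
    "supramarginal": "parietal", "postcentral": "parietal", "precuneus": "parietal",
    # temporal (9)
    "superiortemporal": "temporal", "middletemporal": "temporal",
    "inferiortemporal": "temporal", "bankssts": "temporal", "fusiform": "temporal",
    "transversetemporal": "temporal", "entorhinal": "temporal",
    "temporalpole": "temporal", "parahippocampal": "temporal",
    # occipital (4)
    "lateraloccipital": "occipital", "lingual": "occipital",
    "cuneus": "occipital", "pericalcarine": "occipital",
    # cingulate (4)
    "rostralanteriorcingulate": "cingulate", "caudalanteriorcingulate": "cingulate",
    "posteriorcingulate": "cingulate", "isthmuscingulate": "cingulate",
    # insula (1)
    "insula": "insula",
}


@dataclass
class Atlas:
    """A total partition of source-space vertices into labelled ROIs."""

    roi_names: list[str]
    vertex_to_roi: np.ndarray  # (n_vertices,) int index into roi_names
    roi_to_lobe: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertex_to_roi = np.asarray(self.vertex_to_roi, dtype=int)
        n_rois = len(self.roi_names)
        if len(self.roi_names) != len(set(self.roi_names)):
            raise ValueError("duplicate ROI names")
        counts = np.bincount(self.vertex_to_roi, minlength=n_rois)
        if self.vertex_to_roi.size and (
            self.vertex_to_roi.min() < 0 or self.vertex_to_roi.max() >= n_rois
        ):
            raise ValueError("vertex_to_roi index out of range")
        if np.any(counts == 0):
            empty = [self.roi_names[i] for i in np.flatnonzero(counts == 0)]
            raise ValueError(f"empty ROIs: {empty}")
        missing = [r for r in self.roi_names if r not in self.roi_to_lobe]
        if missing:
            raise ValueError(f"ROIs without a lobe label: {missing}")

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    def roi_index(self, roi: str) -> int:
        try:
            return self.roi_names.index(roi)
        except ValueError:
            raise KeyError(f"unknown ROI {roi!r}") from None

    def vertices_of(self, roi: str) -> np.ndarray:
        return np.flatnonzero(self.vertex_to_roi == self.roi_index(roi))

    def to_text(self, path) -> None:
        """Serialize as `vertex_index<TAB>roi<TAB>lobe` lines."""
        with open(path, "w") as fh:
            for v, ri in enumerate(self.vertex_to_roi):
                name = self.roi_names[ri]
                fh.write(f"{v}\t{name}\t{self.roi_to_lobe[name]}\n")


@dataclass
class ROITimeSeries:
    """Aggregated per-ROI activation series."""

    data: np.ndarray  # (n_rois, n_times)
    roi_names: list[str]
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[0] != len(self.roi_names):
            raise ValueError("row count does not match roi_names")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite ROI series")


def _assign_lobe(centroid: np.ndarray, shell_radius: float) -> str:
    """Heuristic lobe label from a parcel centroid on the cortical shell.

    +y anterior, +z superior, x lateral.  Medial bands go to cingulate
    (superior) / insula (inferior); the lateral surface is split into
    frontal / occipital / parietal / temporal by anterior-posterior and
    superior-inferior position.
    """
    x, y, z = centroid / shell_radius
    if abs(x) < 0.22 and abs(y) < 0.55:
        return "cingulate" if z >= 0 else "insula"
    if y > 0.25:
        return "frontal"
    if y < -0.55:
        return "occipital"
    if z > 0.15:
        return "parietal"
    return "temporal"


def build_synthetic_atlas(
    sources: SourceSpace,
    n_rois_per_hemisphere: int = 34,
    seed: int = 0,
) -> Atlas:
    """Cluster each hemisphere's vertices into contiguous spatial parcels.

    Seeded k-means on vertex coordinates, per hemisphere; parcels are
    relabelled in a deterministic spatial order (anterior to posterior,
    then superior to inferior) and named ``roi<k>-lh`` / ``roi<k>-rh``.
    Lobe labels are assigned from parcel centroids.
    """
    from sklearn.cluster import KMeans

    k = int(n_rois_per_hemisphere)
    if k < 1:
        raise ValueError("n_rois_per_hemisphere must be >= 1")
    shell_radius = float(np.linalg.norm(sources.vertex_positions, axis=1).mean())

    vertex_to_roi = np.full(sources.n_vertices, -1, dtype=int)
    roi_names: list[str] = []
    roi_to_lobe: dict[str, str] = {}
    for h_idx, hemi in enumerate(("lh", "rh")):
        mask = sources.hemispheres == hemi
        pts = sources.vertex_positions[mask]
        if k > len(pts):
            raise ValueError(
                f"requested {k} parcels for hemisphere {hemi!r} with only "
                f"{len(pts)} vertices"
            )
        if k == len(pts):
            labels = np.arange(len(pts))
            centers = pts.copy()
        else:
            km = KMeans(n_clusters=k, n_init=4, random_state=seed + h_idx)
            labels = km.fit_predict(pts)
            centers = km.cluster_centers_
        # deterministic spatial relabeling: anterior first, ties by z then x
        order = np.lexsort((centers[:, 0], -centers[:, 2], -centers[:, 1]))
        rank = np.empty(k, dtype=int)
        rank[order] = np.arange(k)
        base = h_idx * k
        vertex_to_roi[mask] = base + rank[labels]
        for new_idx in range(k):
            name = f"roi{new_idx + 1:02d}-{hemi}"
            roi_names.append(name)
            roi_to_lobe[name] = _assign_lobe(centers[order[new_idx]], shell_radius)
    return Atlas(roi_names=roi_names, vertex_to_roi=vertex_to_roi, roi_to_lobe=roi_to_lobe)


def dominant_orientation(vectors: np.ndarray, tie_tol: float = 1e-9) -> np.ndarray:
    """Dominant orientation of a set of per-vertex vectors.

    The first right singular vector of the stacked (n, 3) vectors, with the
    sign fixed so the majority of vertices project non-negatively onto it
    (ties resolved toward a positive first nonzero component).  Warns when
    the leading singular values tie within ``tie_tol`` (ambiguous dominant
    direction).
    """
    V = np.atleast_2d(np.asarray(vectors, dtype=float))
    if V.shape[0] == 0 or not np.any(V):
        raise ValueError("cannot determine dominant orientation of empty/zero input")
    _, s, vt = np.linalg.svd(V, full_matrices=False)
    if len(s) > 1 and s[0] - s[1] <= tie_tol * max(s[0], 1e-300):
        warnings.warn("dominant orientation ambiguous: leading singular values tie",
                      RuntimeWarning, stacklevel=2)
    u = vt[0]
    proj = V @ u
    pos, neg = np.sum(proj > 0), np.sum(proj < 0)
    if neg > pos:
        u = -u
    elif neg == pos:
        nz = np.flatnonzero(np.abs(u) > 0)
        if nz.size and u[nz[0]] < 0:
            u = -u
    return u


def _collapse_vertices(
    est: SourceEstimate,
    sources: SourceSpace,
    mode: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse 3 dipole components per vertex onto one axis.

    Returns (scalar series (n_vertices, T), world orientation (n_vertices, 3)).

    mode "anatomical": project onto the vertex's first (radial/normal)
    orientation axis.  mode "data": first principal component of the
    vertex's 3xT activation block.
    """
    n_vert = est.n_vertices
    blocks = est.activations.reshape(n_vert, 3, -1)
    if mode == "anatomical":
        scalars = blocks[:, 0, :]
        world = sources.orientations[:, 0, :].copy()
    elif mode == "data":
        scalars = np.empty((n_vert, blocks.shape[2]))
        world = np.empty((n_vert, 3))
        for v in range(n_vert):
            B = blocks[v]
            norm = np.linalg.norm(B)
            if norm == 0:
                scalars[v] = 0.0
                world[v] = sources.orientations[v, 0]
                continue
            _, _, vt = np.linalg.svd(B.T, full_matrices=False)
            u = vt[0]
            scalars[v] = u @ B
            world[v] = u @ sources.orientations[v]
    else:
        raise ValueError(f"unknown collapse mode {mode!r}")
    return scalars, world


def sign_flip_average(
    est: SourceEstimate,
    atlas: Atlas,
    sources: "SourceSpace | None" = None,
    collapse: str = "anatomical",
) -> ROITimeSeries:
    """Aggregate a source estimate into per-ROI series with sign flipping.

    Per vertex, the three dipole components are collapsed onto one
    orientation axis; within each ROI, vertices whose orientation has a
    negative dot product with the ROI's dominant orientation are negated,
    and the ROI series is the mean over its vertices.
    """
    if sources is None:
        sources = est.source_space
    if sources is None:
        raise ValueError("a SourceSpace is required (pass sources=...)")
    if atlas.vertex_to_roi.shape[0] != est.n_vertices:
        raise ValueError(
            f"atlas covers {atlas.vertex_to_roi.shape[0]} vertices but the "
            f"estimate has {est.n_vertices}"
        )
    scalars, world = _collapse_vertices(est, sources, collapse)
    out = np.empty((atlas.n_rois, scalars.shape[1]))
    for ri, name in enumerate(atlas.roi_names):
        verts = np.flatnonzero(atlas.vertex_to_roi == ri)
        ori = world[verts]
        if not np.any(ori):
            raise ValueError(f"ROI {name!r} has all-zero orientations")
        dom = dominant_orientation(ori)
        signs = np.where(ori @ dom < 0, -1.0, 1.0)
        out[ri] = (signs[:, None] * scalars[verts]).mean(axis=0)
    return ROITimeSeries(data=out, roi_names=list(atlas.roi_names), fs=est.fs)


def map_roi_to_lobe(atlas: "Atlas | None", roi: str) -> str:
    """Lobe of an ROI: from the atlas table, else the built-in DK table.

    Anatomical names may carry a ``-lh`` / ``-rh`` hemisphere suffix.
    """
    if atlas is not None and roi in atlas.roi_to_lobe:
        return atlas.roi_to_lobe[roi]
    base = roi.rsplit("-", 1)[0] if roi.endswith(("-lh", "-rh")) else roi
    try:
        return APARC_LOBE_TABLE[base]
    except KeyError:
        raise KeyError(f"unknown ROI {roi!r}") from None
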
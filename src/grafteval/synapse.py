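"""Host-graft ribbon-synapse detection in 3D puncta data.

A host-graft synapse is a presynaptic ribbon (CtBP2 spot) lying within
1.5 um of both a postsynaptic mGluR6 spot and a rod-bipolar-cell (RBC)
dendrite. This module detects such triplets from spot centroids and dendrite
skeleton polylines, selects the RBCs whose dendrites approach the
photoreceptor-rosette surface within 10 um, and summarises per-RBC synapse
counts and the density of synapse-forming RBCs per grafted area.

Conventions: coordinates and distances in micrometres. Raster volumes are
(z, y, x) arrays with ``voxel_size`` given in the same axis order
(dz, dy, dx); spot tables expose x/y/z columns in physical units. All
"within" thresholds are inclusive (<=).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "PunctaScene",
    "DendriteSkeleton",
    "RosetteSurface",
    "SynapseRecord",
    "RBCSummary",
    "detect_spots",
    "detect_synapses",
    "select_rbcs_near_rosette",
    "synapses_per_rbc",
    "forming_rbc_density",
    "dendrite_distances",
]


@dataclass
class DendriteSkeleton:
    """Traced dendritic arbor of one RBC: one or more 3D polylines."""

    cell_id: str
    polylines: list[np.ndarray]  # each (k, 3), k >= 2, columns x, y, z (um)

    def __post_init__(self) -> None:
        self.polylines = [np.asarray(p, float).reshape(-1, 3) for p in self.polylines]
        for p in self.polylines:
            if len(p) < 2:
                raise ValueError("each polyline needs at least 2 vertices")
            if np.any(np.linalg.norm(np.diff(p, axis=0), axis=1) <= 0):
                raise ValueError("polyline segments must have positive length")

    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """Stacked segment endpoints (P0, P1), each (n_segments, 3)."""
        p0 = np.concatenate([p[:-1] for p in self.polylines])
        p1 = np.concatenate([p[1:] for p in self.polylines])
        return p0, p1


@dataclass
class PunctaScene:
    """CtBP2 and mGluR6 spot centroids plus RBC dendrite skeletons."""

    ctbp2: pd.DataFrame  # columns id, x_um, y_um, z_um
    mglur6: pd.DataFrame
    dendrites: list[DendriteSkeleton] = field(default_factory=list)
    voxel_size: tuple[float, float, float] | None = None  # (dz, dy, dx)

    def __post_init__(self) -> None:
        for name in ("ctbp2", "mglur6"):
            df = getattr(self, name)
            df = df.sort_values("id").reset_index(drop=True)
            if df["id"].duplicated().any():
                raise ValueError(f"duplicate ids in {name} channel")
            if not np.isfinite(df[["x_um", "y_um", "z_um"]].to_numpy()).all():
                raise ValueError(f"non-finite coordinates in {name} channel")
            setattr(self, name, df)

    @staticmethod
    def spots_frame(coords: np.ndarray, ids: Sequence | None = None) -> pd.DataFrame:
        coords = np.asarray(coords, float).reshape(-1, 3)
        if ids is None:
            ids = np.arange(len(coords))
        return pd.DataFrame({"id": list(ids), "x_um": coords[:, 0],
                             "y_um": coords[:, 1], "z_um": coords[:, 2]})


@dataclass(frozen=True)
class SynapseRecord:
    ctbp2_id: object
    mglur6_id: object
    rbc_id: str
    d_ctbp2_mglur6: float
    d_ctbp2_dendrite: float


@dataclass
class RBCSummary:
    counts: dict[str, int]
    forming: set[str]
    mean_per_rbc: float


class RosetteSurface:
    """Photoreceptor-rosette surface given as a binary raster mask.

    Distance-to-surface queries interpolate the Euclidean distance transform
    of the background, computed with per-axis voxel spacing (anisotropic
    voxels supported). Points inside the mask have distance 0.
    """

    def __init__(self, mask: np.ndarray, voxel_size: tuple[float, float, float]):
        mask = np.asarray(mask, bool)
        if mask.ndim != 3 or not mask.any():
            raise ValueError("mask must be a nonempty 3D raster")
        vs = tuple(float(v) for v in voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be three positive spacings (dz, dy, dx)")
        self.mask = mask
        self.voxel_size = vs
        self._edt = ndimage.distance_transform_edt(~mask, sampling=vs)
        self._tree: cKDTree | None = None  # built on first out-of-bounds query

    def _mask_tree(self) -> cKDTree:
        if self._tree is None:
            zz, yy, xx = np.nonzero(self.mask)
            dz, dy, dx = self.voxel_size
            self._tree = cKDTree(np.stack([xx * dx, yy * dy, zz * dz], axis=1))
        return self._tree

    def distance(self, points_xyz: np.ndarray) -> np.ndarray:
        """Distance (um) from each (x, y, z) point to the rosette surface.

        In-bounds points interpolate the distance transform; points outside
        the raster are resolved exactly against the mask voxel centers.
        """
        pts = np.asarray(points_xyz, float).reshape(-1, 3)
        dz, dy, dx = self.voxel_size
        idx = np.stack([pts[:, 2] / dz, pts[:, 1] / dy, pts[:, 0] / dx])
        d = ndimage.map_coordinates(self._edt, idx, order=1, mode="nearest")
        shape = np.array(self.mask.shape, float)
        outside = np.any((idx.T < 0) | (idx.T > shape - 1), axis=1)
        if outside.any():
            d[outside], _ = self._mask_tree().query(pts[outside])
        return np.maximum(d, 0.0)


# ---------------------------------------------------------------------------
# Spot detection from raster volumes
# ---------------------------------------------------------------------------

def detect_spots(
    volume: np.ndarray,
    voxel_size: tuple[float, float, float],
    sigma: float,
    min_intensity: float,
) -> pd.DataFrame:
    """Detect punctate spots as scale-normalised LoG maxima.

    The volume (z, y, x) is filtered with a Laplacian-of-Gaussian at physical
    scale ``sigma`` um (converted to per-axis voxel sigmas, so anisotropic
    stacks are handled), normalised by sigma^2; local maxima of the negated
    response above ``min_intensity`` are reported as spot centroids in um.
    """
    vol = np.asarray(volume, float)
    if vol.ndim != 3 or vol.size == 0:
        raise ValueError("volume must be a nonempty 3D array")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if min_intensity <= 0:
        raise ValueError("min_intensity must be positive")
    vs = tuple(float(v) for v in voxel_size)
    if len(vs) != 3 or any(v <= 0 for v in vs):
        raise ValueError("voxel_size must give positive (dz, dy, dx) spacings")
    sig_vox = [sigma / v for v in vs]
    resp = -(sigma**2) * ndimage.gaussian_laplace(vol, sigma=sig_vox)
    is_max = resp == ndimage.maximum_filter(resp, size=3, mode="nearest")
    zz, yy, xx = np.nonzero(is_max & (resp > min_intensity))
    coords = np.stack([xx * vs[2], yy * vs[1], zz * vs[0]], axis=1)
    df = PunctaScene.spots_frame(coords)
    df["response"] = resp[zz, yy, xx]
    return df


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _point_segment_distances(points: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Distance matrix (n_points, n_segments) from points to line segments."""
    d = p1 - p0  # (S, 3)
    seg_len2 = np.einsum("ij,ij->i", d, d)
    # projection parameter clipped to [0, 1]
    w = points[:, None, :] - p0[None, :, :]  # (P, S, 3)
    t = np.einsum("psj,sj->ps", w, d) / seg_len2[None, :]
    t = np.clip(t, 0.0, 1.0)
    closest = p0[None, :, :] + t[:, :, None] * d[None, :, :]
    return np.linalg.norm(points[:, None, :] - closest, axis=2)


def dendrite_distances(
    points: np.ndarray, dendrites: Sequence[DendriteSkeleton]
) -> tuple[np.ndarray, np.ndarray]:
    """Exact distance from each point to the nearest dendrite segment.

    Returns (distances, cell indices); on exact ties the cell whose id sorts
    first wins. Cell index refers to ``sorted(dendrites, key=cell_id)``.
    """
    pts = np.asarray(points, float).reshape(-1, 3)
    order = sorted(range(len(dendrites)), key=lambda i: str(dendrites[i].cell_id))
    best_d = np.full(len(pts), np.inf)
    best_cell = np.full(len(pts), -1, dtype=int)
    for rank, i in enumerate(order):
        p0, p1 = dendrites[i].segments()
        d = _point_segment_distances(pts, p0, p1).min(axis=1)
        better = d < best_d  # strict: earlier-sorting id kept on exact ties
        best_d[better] = d[better]
        best_cell[better] = rank
    return best_d, best_cell


# ---------------------------------------------------------------------------
# Synapse detection and RBC statistics
# ---------------------------------------------------------------------------

def detect_synapses(scene: PunctaScene, radius: float = 1.5) -> list[SynapseRecord]:
    """Apply the triple-proximity synapse rule.

    For every CtBP2 spot, the nearest mGluR6 spot and the nearest point on
    any dendrite polyline are found; the spot is reported as a synapse iff
    both distances are <= ``radius`` (1.5 um). At most one record per CtBP2
    spot; the dendrite realising the minimum defines the synapse's RBC.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if len(scene.ctbp2) == 0 or len(scene.mglur6) == 0 or not scene.dendrites:
        return []
    c = scene.ctbp2[["x_um", "y_um", "z_um"]].to_numpy()
    m = scene.mglur6[["x_um", "y_um", "z_um"]].to_numpy()
    # nearest mGluR6 per CtBP2; mglur6 rows are id-sorted, and on exact ties
    # the brute-force argmin picks the first (smallest id)
    if len(c) * len(m) <= 4_000_000:
        dmat = np.linalg.norm(c[:, None, :] - m[None, :, :], axis=2)
        m_idx = np.argmin(dmat, axis=1)
        m_dist = dmat[np.arange(len(c)), m_idx]
    else:
        m_dist, m_idx = cKDTree(m).query(c)
    d_dist, d_cell = dendrite_distances(c, scene.dendrites)
    cells = sorted(scene.dendrites, key=lambda s: str(s.cell_id))

    records = []
    for k in range(len(c)):
        if m_dist[k] <= radius and d_dist[k] <= radius:
            records.append(SynapseRecord(
                ctbp2_id=scene.ctbp2["id"].iloc[k],
                mglur6_id=scene.mglur6["id"].iloc[int(m_idx[k])],
                rbc_id=str(cells[int(d_cell[k])].cell_id),
                d_ctbp2_mglur6=float(m_dist[k]),
                d_ctbp2_dendrite=float(d_dist[k]),
            ))
    return records


def select_rbcs_near_rosette(
    dendrites: Sequence[DendriteSkeleton],
    surface: RosetteSurface,
    reach: float = 10.0,
    sample_step: float | None = None,
) -> set[str]:
    """RBCs whose dendrites come within ``reach`` (10 um) of the rosette.

    Each polyline is sampled densely along its segments (default step: half
    the smallest voxel spacing) so that interior segment points, not only
    vertices, are tested against the surface distance field.
    """
    if sample_step is None:
        sample_step = min(surface.voxel_size) / 2.0
    selected: set[str] = set()
    for skel in dendrites:
        pts = []
        for poly in skel.polylines:
            for a, b in zip(poly[:-1], poly[1:]):
                seg_len = float(np.linalg.norm(b - a))
                n = max(2, int(np.ceil(seg_len / sample_step)) + 1)
                t = np.linspace(0.0, 1.0, n)[:, None]
                pts.append(a[None, :] * (1 - t) + b[None, :] * t)
        sample = np.concatenate(pts)
        if float(surface.distance(sample).min()) <= reach:
            selected.add(str(skel.cell_id))
    return selected


def synapses_per_rbc(
    records: Sequence[SynapseRecord], selected: Sequence[str] | set[str]
) -> RBCSummary:
    """Per-RBC synapse counts over the selected cells.

    Cells with at least one synapse are labelled "RBC with forming synapse";
    the mean count is over the selected cells (zeros included).
    """
    sel = sorted(set(map(str, selected)))
    counts = {cid: 0 for cid in sel}
    for rec in records:
        counts[str(rec.rbc_id)] = counts.get(str(rec.rbc_id), 0) + 1
    forming = {cid for cid, n in counts.items() if n > 0}
    mean = float(np.mean([counts[c] for c in sel])) if sel else 0.0
    return RBCSummary(counts=counts, forming=forming, mean_per_rbc=mean)


def forming_rbc_density(forming: Sequence[str] | set[str], graft_area_mm2: float) -> float:
    """Density of synapse-forming RBCs per grafted area (cells/mm^2)."""
    if graft_area_mm2 <= 0:
        raise ValueError("graft area must be positive")
    return len(set(forming)) / graft_area_mm2
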
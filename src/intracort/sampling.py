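"""Transcortical sampling: ray-voxel traversal and vertex/region averaging.

Each white-surface vertex receives an R value computed as a length-weighted
average of the ratio volume over the voxels traversed by the straight segment
from the vertex to its paired pial vertex, counting only gray-matter voxels
with valid ratios.  The traversal is an exact ray-box march in voxel space:
the segment is mapped through the inverse affine, every axis-plane crossing is
located analytically, and the in-voxel length of each sub-interval is the
world-mm arc length between consecutive crossings.

Voxel convention: a voxel ``(i, j, k)`` spans the half-open cube
``[i, i+1) x ...`` in voxel coordinates, so a crossing point belongs to the
voxel being entered, deterministically.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .surfaces import CorticalSurfacePair, Parcellation, VertexScalarMap, pair_vertices
from .volumes import GM, LabelVolume, ScalarVolume

__all__ = [
    "trace_segment_voxels",
    "sample_vertex_ratio",
    "sample_surface",
    "vertex_map_to_regions",
]


def _clip_to_grid(v0: np.ndarray, v1: np.ndarray, shape) -> tuple[np.ndarray, np.ndarray, bool]:
    """Clip a voxel-space segment to the grid box [0, shape] (slab method)."""
    d = v1 - v0
    tmin, tmax = 0.0, 1.0
    for ax in range(3):
        lo, hi = 0.0, float(shape[ax])
        if abs(d[ax]) < 1e-300:
            if v0[ax] < lo or v0[ax] >= hi:
                return v0, v0, True  # entirely outside along this axis
            continue
        t_a = (lo - v0[ax]) / d[ax]
        t_b = (hi - v0[ax]) / d[ax]
        if t_a > t_b:
            t_a, t_b = t_b, t_a
        tmin = max(tmin, t_a)
        tmax = min(tmax, t_b)
    if tmin > tmax:
        return v0, v0, True
    clipped = not (tmin == 0.0 and tmax == 1.0)
    return v0 + tmin * d, v0 + tmax * d, clipped


def trace_segment_voxels(
    white_point: np.ndarray,
    pial_point: np.ndarray,
    grid: ScalarVolume | LabelVolume,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxels traversed by a world-space segment, with in-voxel lengths (mm).

    Returns ``(indices, lengths)`` where ``indices`` is (k, 3) int and
    ``lengths`` sums to the (possibly clipped) segment length to within 1e-9.
    A zero-length segment yields its containing voxel with length 0.
    Endpoints outside the grid are clipped to the grid box with a warning.
    """
    p0 = np.asarray(white_point, dtype=float)
    p1 = np.asarray(pial_point, dtype=float)
    inv = np.linalg.inv(grid.affine)
    v0 = inv[:3, :3] @ p0 + inv[:3, 3]
    v1 = inv[:3, :3] @ p1 + inv[:3, 3]

    shape = grid.shape
    v0c, v1c, clipped = _clip_to_grid(v0, v1, shape)
    if clipped:
        if np.array_equal(v0c, v1c) and not np.array_equal(v0, v1):
            warnings.warn("segment lies entirely outside the grid", stacklevel=2)
            return np.empty((0, 3), dtype=np.int64), np.empty(0)
        warnings.warn("segment clipped to grid bounds", stacklevel=2)
    v0, v1 = v0c, v1c

    world_len = float(np.linalg.norm(p1 - p0))
    # arc length of the clipped part, in world mm
    seg_len = float(np.linalg.norm(grid.affine[:3, :3] @ (v1 - v0)))
    d = v1 - v0
    if seg_len == 0.0 or world_len == 0.0:
        idx = np.minimum(np.floor(v0).astype(np.int64), np.asarray(shape) - 1)
        return idx[None, :], np.zeros(1)

    # parameter values t in (0, 1) at which an integer plane is crossed
    crossings = [0.0, 1.0]
    for ax in range(3):
        if d[ax] == 0.0:
            continue
        lo = int(np.ceil(min(v0[ax], v1[ax])))
        hi = int(np.floor(max(v0[ax], v1[ax])))
        for plane in range(lo, hi + 1):
            t = (plane - v0[ax]) / d[ax]
            if 0.0 < t < 1.0:
                crossings.append(t)
    t_sorted = np.unique(np.asarray(crossings))

    mids = 0.5 * (t_sorted[:-1] + t_sorted[1:])
    pts = v0[None, :] + mids[:, None] * d[None, :]
    idx = np.floor(pts).astype(np.int64)
    np.clip(idx, 0, np.asarray(shape) - 1, out=idx)
    lengths = np.diff(t_sorted) * seg_len

    # merge consecutive duplicates (can arise from corner-grazing crossings)
    keep = np.ones(len(idx), dtype=bool)
    if len(idx) > 1:
        same = np.all(idx[1:] == idx[:-1], axis=1)
        if same.any():
            keep[1:] = ~same
            lengths = np.add.reduceat(lengths, np.flatnonzero(keep))
            idx = idx[keep]
    return idx, lengths


def sample_vertex_ratio(
    white_point: np.ndarray,
    pial_point: np.ndarray,
    r: ScalarVolume,
    gm: LabelVolume | None = None,
) -> tuple[float, bool]:
    """Length-weighted mean R along one transcortical segment.

    Only voxels labeled GM (if a label volume is given) with a valid ratio
    contribute; weights are renormalized over the contributing length.
    Returns ``(value, missing)``; ``missing`` is True when no voxel qualifies.
    """
    idx, lengths = trace_segment_voxels(white_point, pial_point, r)
    if len(idx) == 0:
        return np.nan, True
    i, j, k = idx[:, 0], idx[:, 1], idx[:, 2]
    ok = r.valid[i, j, k] & (lengths > 0)
    if gm is not None:
        ok &= gm.labels[i, j, k] == GM
    total = lengths[ok].sum()
    if not ok.any() or total <= 0.0:
        return np.nan, True
    value = float(np.dot(lengths[ok], r.values[i[ok], j[ok], k[ok]]) / total)
    return value, False


def sample_surface(
    surfaces: CorticalSurfacePair,
    r: ScalarVolume,
    gm: LabelVolume | None = None,
    search_ring: int = 0,
) -> VertexScalarMap:
    """Assign an R value to every white-surface vertex."""
    pial_idx = pair_vertices(surfaces, search_ring=search_ring)
    n = surfaces.n_vertices
    values = np.full(n, np.nan)
    missing = np.ones(n, dtype=bool)
    pial_pts = surfaces.pial_vertices[pial_idx]
    for v in range(n):
        values[v], missing[v] = sample_vertex_ratio(
            surfaces.white_vertices[v], pial_pts[v], r, gm
        )
    return VertexScalarMap(values, missing)


def vertex_map_to_regions(
    maps: dict[str, VertexScalarMap],
    parcellation: Parcellation,
    groups: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-subject vertex maps to regional means.

    Two outputs mirror the two uses of regional values:

    * group-level means, computed by averaging across subjects at each vertex
      FIRST and then across the vertices of each parcel (missing vertices are
      excluded from both averages) — used for cortical maps;
    * per-subject regional means (vertex average per subject, missing vertices
      excluded) — used for subject-level statistics.

    Parameters
    ----------
    maps
        subject id -> vertex map, all on the same template mesh.
    parcellation
        vertex -> region labels on that mesh.
    groups
        subject id -> group label; defaults to a single group ``"all"``.

    Returns
    -------
    (group_table, subject_table)
        ``group_table`` has columns group, region_id, region_name, mean_value,
        n_vertices; ``subject_table`` has subject_id, group, region_id,
        region_name, mean_value, n_vertices.
    """
    if not maps:
        raise ValueError("no vertex maps supplied")
    n_vert = len(parcellation.labels)
    for sid, m in maps.items():
        if len(m.values) != n_vert:
            raise ValueError(f"map for {sid!r} does not match the parcellation size")
    groups = groups or {sid: "all" for sid in maps}

    subj_rows = []
    values = {}
    for sid, m in maps.items():
        vals = np.where(m.missing, np.nan, m.values)
        values[sid] = vals
        for rid in parcellation.region_ids:
            sel = parcellation.labels == rid
            v = vals[sel]
            n_ok = int(np.isfinite(v).sum())
            subj_rows.append(
                {
                    "subject_id": sid,
                    "group": groups[sid],
                    "region_id": int(rid),
                    "region_name": parcellation.names[int(rid)],
                    "mean_value": float(np.nanmean(v)) if n_ok else np.nan,
                    "n_vertices": n_ok,
                }
            )
    subject_table = pd.DataFrame(subj_rows)

    group_rows = []
    for grp in sorted(set(groups.values())):
        stack = np.vstack([values[sid] for sid in maps if groups[sid] == grp])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vertex_mean = np.nanmean(stack, axis=0)  # across subjects first
        for rid in parcellation.region_ids:
            sel = parcellation.labels == rid
            v = vertex_mean[sel]
            n_ok = int(np.isfinite(v).sum())
            group_rows.append(
                {
                    "group": grp,
                    "region_id": int(rid),
                    "region_name": parcellation.names[int(rid)],
                    "mean_value": float(np.nanmean(v)) if n_ok else np.nan,
                    "n_vertices": n_ok,
                }
            )
    return pd.DataFrame(group_rows), subject_table
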
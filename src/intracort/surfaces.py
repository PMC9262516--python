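"""Cortical surface geometry: white/pial mesh pairs and parcellations.

The white (GM/WM interface) and pial surfaces are triangle meshes with
one-to-one vertex correspondence, as produced by FreeSurfer-style pipelines.
The transcortical segment joining a white vertex to its paired pial vertex is
the sampling ray along which voxelwise R values are averaged.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CorticalSurfacePair",
    "Parcellation",
    "VertexScalarMap",
    "pair_vertices",
    "segment_lengths",
    "normalize_by_icv",
]


@dataclass
class CorticalSurfacePair:
    """White and pial triangle meshes sharing triangulation and vertex order."""

    white_vertices: np.ndarray  # (n, 3) world mm
    pial_vertices: np.ndarray  # (n, 3) world mm
    triangles: np.ndarray  # (m, 3) int indices
    correspondence: np.ndarray | None = None  # white index -> pial index

    def __post_init__(self) -> None:
        self.white_vertices = np.asarray(self.white_vertices, dtype=float)
        self.pial_vertices = np.asarray(self.pial_vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        n = len(self.white_vertices)
        if self.pial_vertices.shape != self.white_vertices.shape:
            raise ValueError("white and pial surfaces must have equal vertex counts")
        if self.triangles.size and (self.triangles.min() < 0 or self.triangles.max() >= n):
            raise ValueError("triangles reference invalid vertex indices")
        if self.correspondence is None:
            self.correspondence = np.arange(n, dtype=np.int64)
        else:
            self.correspondence = np.asarray(self.correspondence, dtype=np.int64)
            if len(self.correspondence) != n or len(np.unique(self.correspondence)) != n:
                raise ValueError("correspondence must be a bijection on vertex indices")

    @property
    def n_vertices(self) -> int:
        return len(self.white_vertices)

    def vertex_adjacency(self) -> list[np.ndarray]:
        """Neighbor lists derived from the shared triangulation."""
        nbrs: list[set[int]] = [set() for _ in range(self.n_vertices)]
        for a, b, c in self.triangles:
            nbrs[a].update((b, c))
            nbrs[b].update((a, c))
            nbrs[c].update((a, b))
        return [np.fromiter(s, dtype=np.int64) for s in nbrs]


@dataclass
class Parcellation:
    """Vertex-to-region labels plus a region-id -> name table."""

    labels: np.ndarray  # (n,) int region id per vertex
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        present = set(np.unique(self.labels).tolist())
        if not self.names:
            self.names = {int(r): f"region_{int(r)}" for r in sorted(present)}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")

    @property
    def region_ids(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass
class VertexScalarMap:
    """Per-vertex scalar with an explicit missing mask."""

    values: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != self.values.shape:
            raise ValueError("values and missing mask have different shapes")
        if not np.all(np.isfinite(self.values[~self.missing])):
            raise ValueError("non-missing vertex values must be finite")


def _k_ring(adjacency: list[np.ndarray], start: int, k: int) -> np.ndarray:
    """Vertex indices within graph distance k of ``start`` (inclusive)."""
    seen = {start}
    frontier = deque([(start, 0)])
    while frontier:
        v, d = frontier.popleft()
        if d == k:
            continue
        for w in adjacency[v]:
            if w not in seen:
                seen.add(int(w))
                frontier.append((int(w), d + 1))
    return np.fromiter(seen, dtype=np.int64)


def pair_vertices(surfaces: CorticalSurfacePair, search_ring: int = 0) -> np.ndarray:
    """Choose, for each white vertex, the pial endpoint of its segment.

    With ``search_ring == 0`` the pairing is the stored index correspondence.
    With ``search_ring == k > 0`` the pial endpoint is the nearest pial vertex
    (Euclidean, world mm) within the k-ring mesh neighborhood of the
    index-corresponded pial vertex — a topological constraint that keeps the
    pairing local on the mesh while allowing the segment to shorten toward the
    true closest point of the pial surface.

    Returns the pial vertex index chosen for each white vertex.
    """
    corr = surfaces.correspondence
    if search_ring == 0:
        return corr.copy()
    if search_ring < 0:
        raise ValueError("search_ring must be >= 0")
    adjacency = surfaces.vertex_adjacency()
    out = np.empty(surfaces.n_vertices, dtype=np.int64)
    for i in range(surfaces.n_vertices):
        cand = _k_ring(adjacency, int(corr[i]), search_ring)
        d2 = np.sum((surfaces.pial_vertices[cand] - surfaces.white_vertices[i]) ** 2, axis=1)
        # ties broken toward the lowest vertex index for determinism
        best = cand[np.lexsort((cand, d2))[0]]
        out[i] = best
    return out


def segment_lengths(white_points: np.ndarray, pial_points: np.ndarray) -> np.ndarray:
    """Euclidean lengths (mm) of transcortical segments; the thickness proxy."""
    return np.linalg.norm(np.asarray(pial_points, float) - np.asarray(white_points, float), axis=-1)


def normalize_by_icv(value, icv: float):
    """Normalize a regional volume/thickness summary by intracranial volume."""
    if icv <= 0:
        raise ValueError("intracranial volume must be positive")
    return np.asarray(value, dtype=float) / icv
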
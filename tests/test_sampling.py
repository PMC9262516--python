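"""Ray-voxel traversal, vertex sampling and regional aggregation."""

import numpy as np
import pytest

from intracort.sampling import (
    sample_vertex_ratio,
    trace_segment_voxels,
    vertex_map_to_regions,
)
from intracort.surfaces import (
    CorticalSurfacePair,
    Parcellation,
    VertexScalarMap,
    normalize_by_icv,
    pair_vertices,
    segment_lengths,
)
from intracort.volumes import GM, WM, LabelVolume, ScalarVolume

EYE = np.eye(4)


def _grid(shape=(16, 16, 16), affine=None, values=None):
    vals = values if values is not None else np.ones(shape)
    return ScalarVolume(vals, EYE if affine is None else affine)


def dense_oracle(p0, p1, grid, n_points=10_000):
    """Nearest-voxel binning of densely sampled points along the segment."""
    t = (np.arange(n_points) + 0.5) / n_points
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    v = grid.world_to_voxel(pts)
    idx = np.floor(v).astype(int)
    length = np.linalg.norm(p1 - p0)
    counts = {}
    for row in idx:
        counts[tuple(row)] = counts.get(tuple(row), 0) + 1
    return {k: c * length / n_points for k, c in counts.items()}


class TestTraversal:
    def test_axis_aligned_plane_crossings(self):
        idx, lengths = trace_segment_voxels([0.5, 0.5, 0.5], [2.5, 0.5, 0.5], _grid())
        assert idx.tolist() == [[0, 0, 0], [1, 0, 0], [2, 0, 0]]
        assert np.allclose(lengths, [0.5, 1.0, 0.5], atol=1e-12)

    def test_length_conservation_random_segments(self, rng):
        grid = _grid()
        for _ in range(200):
            p0, p1 = rng.uniform(1.0, 15.0, (2, 3))
            idx, lengths = trace_segment_voxels(p0, p1, grid)
            assert abs(lengths.sum() - np.linalg.norm(p1 - p0)) < 1e-9

    def test_conservation_under_anisotropic_affine(self, rng):
        affine = np.eye(4)
        affine[:3, :3] = np.diag([0.7, 1.3, 2.0])
        affine[:3, 3] = [-3.0, 2.0, 1.0]
        grid = _grid((12, 12, 12), affine)
        for _ in range(100):
            v = rng.uniform(1, 11, (2, 3))
            p0, p1 = grid.voxel_to_world(v)
            idx, lengths = trace_segment_voxels(p0, p1, grid)
            assert abs(lengths.sum() - np.linalg.norm(p1 - p0)) < 1e-9

    def test_zero_length_segment(self):
        idx, lengths = trace_segment_voxels([3.2, 4.7, 5.1], [3.2, 4.7, 5.1], _grid())
        assert idx.tolist() == [[3, 4, 5]]
        assert lengths.tolist() == [0.0]

    def test_matches_dense_sampling_oracle(self, rng):
        grid = _grid()
        for _ in range(30):
            # transcortical-scale segments keep the oracle's own
            # discretization error well below the comparison bound
            p0 = rng.uniform(4.0, 12.0, 3)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            p1 = p0 + direction * rng.uniform(1.0, 3.5)
            idx, lengths = trace_segment_voxels(p0, p1, grid)
            oracle = dense_oracle(p0, p1, grid)
            got = {tuple(i): l for i, l in zip(idx, lengths)}
            for k in set(got) | set(oracle):
                assert abs(got.get(k, 0.0) - oracle.get(k, 0.0)) < 1e-3

    def test_out_of_bounds_clipped_with_warning(self):
        grid = _grid((8, 8, 8))
        with pytest.warns(UserWarning, match="clip"):
            idx, lengths = trace_segment_voxels([-2.0, 4.5, 4.5], [4.0, 4.5, 4.5], grid)
        assert abs(lengths.sum() - 4.0) < 1e-9  # only the in-grid part
        assert idx[:, 0].min() == 0


class TestVertexSampling:
    def test_constant_field_gives_constant_value(self):
        grid = _grid(values=np.full((16, 16, 16), 1.25))
        value, missing = sample_vertex_ratio([2.3, 7.1, 8.9], [6.8, 9.4, 3.2], grid)
        assert not missing
        assert abs(value - 1.25) < 1e-12

    def test_half_half_weighted_mean(self):
        vals = np.ones((4, 4, 4))
        vals[1, 0, 0] = 2.0
        grid = _grid((4, 4, 4), values=vals)
        value, missing = sample_vertex_ratio([0.5, 0.5, 0.5], [1.5, 0.5, 0.5], grid)
        assert not missing
        assert abs(value - 1.5) < 1e-12

    def test_segment_outside_gm_is_missing(self):
        grid = _grid((4, 4, 4))
        labels = LabelVolume(np.full((4, 4, 4), WM), EYE)
        value, missing = sample_vertex_ratio([0.5, 0.5, 0.5], [2.5, 0.5, 0.5], grid, labels)
        assert missing and np.isnan(value)

    def test_non_gm_voxels_excluded_and_renormalized(self):
        vals = np.ones((4, 4, 4))
        vals[1, 0, 0] = 99.0  # WM voxel in the middle of the path
        labels = np.full((4, 4, 4), GM)
        labels[1, 0, 0] = WM
        grid = _grid((4, 4, 4), values=vals)
        value, missing = sample_vertex_ratio(
            [0.5, 0.5, 0.5], [2.5, 0.5, 0.5], grid, LabelVolume(labels, EYE)
        )
        assert not missing
        assert abs(value - 1.0) < 1e-12


class TestVertexPairing:
    def test_concentric_spheres_segments_are_radial(self, small_geometry, small_spec):
        surfaces, _ = small_geometry
        pial_idx = pair_vertices(surfaces, search_ring=0)
        lengths = segment_lengths(surfaces.white_vertices, surfaces.pial_vertices[pial_idx])
        assert np.allclose(lengths, small_spec.thickness_mm, atol=1e-9)

    def test_ring_zero_equals_index_correspondence(self, small_geometry):
        surfaces, _ = small_geometry
        assert np.array_equal(pair_vertices(surfaces, 0), surfaces.correspondence)

    def test_ring_search_matches_brute_force(self, small_geometry, rng):
        surfaces, _ = small_geometry
        pial = surfaces.pial_vertices + rng.normal(0, 0.3, surfaces.pial_vertices.shape)
        perturbed = CorticalSurfacePair(surfaces.white_vertices, pial, surfaces.triangles)
        chosen = pair_vertices(perturbed, search_ring=2)
        adjacency = perturbed.vertex_adjacency()
        from intracort.surfaces import _k_ring

        for i in range(perturbed.n_vertices):
            cand = _k_ring(adjacency, i, 2)
            d = np.linalg.norm(pial[cand] - surfaces.white_vertices[i], axis=1)
            assert d[cand.tolist().index(chosen[i])] <= d.min() + 1e-12

    def test_non_bijective_correspondence_rejected(self, small_geometry):
        surfaces, _ = small_geometry
        bad = np.zeros(surfaces.n_vertices, dtype=int)
        with pytest.raises(ValueError, match="bijection"):
            CorticalSurfacePair(
                surfaces.white_vertices, surfaces.pial_vertices, surfaces.triangles, bad
            )


class TestRegionAggregation:
    def test_constant_maps_give_constant_regions(self):
        parc = Parcellation(np.array([0, 0, 1, 1]))
        maps = {s: VertexScalarMap(np.full(4, 2.5)) for s in ("a", "b")}
        group_table, subject_table = vertex_map_to_regions(maps, parc)
        assert np.allclose(group_table.mean_value, 2.5)
        assert np.allclose(subject_table.mean_value, 2.5)

    def test_linear_case_order_irrelevant(self):
        parc = Parcellation(np.array([0, 0, 1, 1]))
        c = np.array([1.0, 2.0, 3.0, 4.0])
        maps = {"a": VertexScalarMap(c), "b": VertexScalarMap(3 * c)}
        group_table, _ = vertex_map_to_regions(maps, parc)
        expected = {0: 2 * 1.5, 1: 2 * 3.5}
        for _, row in group_table.iterrows():
            assert abs(row.mean_value - expected[row.region_id]) < 1e-12

    def test_missing_vertices_match_two_stage_loop_oracle(self, rng):
        n_vert, n_subj = 30, 5
        labels = rng.integers(0, 3, n_vert)
        parc = Parcellation(labels)
        maps, groups = {}, {}
        for s in range(n_subj):
            vals = rng.uniform(0.8, 1.4, n_vert)
            miss = rng.random(n_vert) < 0.2
            maps[f"s{s}"] = VertexScalarMap(np.where(miss, np.nan, vals), miss)
            groups[f"s{s}"] = "g0" if s < 3 else "g1"
        group_table, _ = vertex_map_to_regions(maps, parc, groups)
        # explicit nested loops: subject average per vertex, then vertex average
        for _, row in group_table.iterrows():
            members = [sid for sid in maps if groups[sid] == row.group]
            vertex_means = []
            for v in np.flatnonzero(labels == row.region_id):
                vals = [maps[s].values[v] for s in members if not maps[s].missing[v]]
                if vals:
                    vertex_means.append(np.mean(vals))
            expected = np.mean(vertex_means)
            assert abs(row.mean_value - expected) < 1e-12

    def test_size_mismatch_rejected(self):
        parc = Parcellation(np.array([0, 1]))
        with pytest.raises(ValueError, match="parcellation"):
            vertex_map_to_regions({"a": VertexScalarMap(np.ones(3))}, parc)


class TestThicknessAndIcv:
    def test_concentric_thickness(self, small_geometry, small_spec):
        surfaces, _ = small_geometry
        lengths = segment_lengths(surfaces.white_vertices, surfaces.pial_vertices)
        assert np.allclose(lengths, small_spec.thickness_mm, atol=1e-9)

    def test_icv_normalization(self):
        assert normalize_by_icv(1500.0, 1.5e6) == pytest.approx(1e-3, abs=0)
        assert normalize_by_icv(3000.0, 3.0e6) == pytest.approx(1e-3, abs=0)
        with pytest.raises(ValueError):
            normalize_by_icv(1.0, 0.0)
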
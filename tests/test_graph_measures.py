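"""Degree, components, islet size classification and group comparison."""

import math

import numpy as np
import pytest

from isletgraph import (
    NeighborhoodParams,
    aggregate_measures,
    build_graph,
    classify_islet_size,
    compute_measures,
    degree,
    effective_diameter,
    group_compare,
)

from conftest import oracle_components


def star_with_pendant():
    """A hub with three spokes: hub degree 3, each spoke degree 1."""
    coords = np.array([[0.0, 0.0]] + [
        [9 * math.cos(a), 9 * math.sin(a)]
        for a in (0.0, 2 * math.pi / 3, 4 * math.pi / 3)
    ])
    return build_graph(coords, NeighborhoodParams(radius=10))


class TestDegree:
    def test_isolated_vertex(self):
        g = build_graph(np.array([[0.0, 0.0], [100.0, 0.0]]))
        assert degree(0, g) == 0

    def test_hub_and_leaf_degrees(self):
        g = star_with_pendant()
        assert degree(0, g) == 3
        assert degree(1, g) == 1

    def test_triangle_all_degree_two(self):
        tri = np.array([[0, 0], [9, 0], [4.5, 9 * math.sqrt(3) / 2]])
        g = build_graph(tri, NeighborhoodParams(radius=10))
        assert [degree(v, g) for v in g.cell_ids] == [2, 2, 2]

    def test_absent_vertex_is_lookup_error(self):
        g = star_with_pendant()
        with pytest.raises(KeyError):
            degree(99, g)


class TestComputeMeasures:
    def test_isolated_vertices(self):
        coords = np.arange(5)[:, None] * [100.0, 0.0]
        m = compute_measures(build_graph(coords))
        assert m.n_components == 5
        assert m.n_singular == 5
        assert m.mean_degree == 0
        assert m.cells_per_component == 1

    def test_path_of_four(self):
        coords = np.arange(4)[:, None] * [9.0, 0.0]
        m = compute_measures(build_graph(coords, NeighborhoodParams(radius=10)))
        assert m.mean_degree == pytest.approx(1.5)  # 2·3 edge ends / 4 cells
        assert m.n_nonsingular == 1
        assert m.cells_per_nonsingular == 4

    def test_invariants_on_random_graphs(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 16))
            coords = rng.uniform(0, 45, size=(n, 2))
            g = build_graph(coords, NeighborhoodParams(radius=10))
            m = compute_measures(g)
            assert m.n_components == m.n_singular + m.n_nonsingular
            assert m.mean_degree == pytest.approx(2 * g.n_edges / n)
            assert m.cells_per_component == pytest.approx(n / m.n_components)
            # traversal agrees with the reachability-closure oracle
            idx = {c: i for i, c in enumerate(g.cell_ids)}
            edges = {(idx[a], idx[b]) for a, b in g.edge_set()}
            assert m.n_components == oracle_components(n, edges)

    def test_bridging_edge_merges_two_components(self, rng):
        coords = np.vstack([rng.uniform(0, 30, size=(6, 2)),
                            rng.uniform(200, 230, size=(6, 2))])
        g = build_graph(coords, NeighborhoodParams(radius=12))
        before = compute_measures(g)
        far_pair = (int(g.cell_ids[0]), int(g.cell_ids[6]))
        g.graph.add_edge(*far_pair)
        after = compute_measures(g)
        assert after.n_components == before.n_components - 1


class TestEffectiveDiameter:
    def test_wide_islet_is_large(self, rng):
        coords = rng.uniform(0, 200, size=(30, 2))
        assert classify_islet_size(coords) == "large"

    def test_single_cell_is_small(self):
        assert classify_islet_size(np.array([[5.0, 5.0]])) == "small"
        assert effective_diameter(np.array([[5.0, 5.0]])) == 8.0  # one cell's extent

    def test_unpadded_equivalent_circle_closed_form(self):
        # a polygonal "disc": equivalent-circle diameter is 2·sqrt(A/π)
        # with A the shoelace area of the hull
        ang = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        pts = 40.0 * np.c_[np.cos(ang), np.sin(ang)]
        x, y = pts[:, 0], pts[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        expect = 2 * math.sqrt(area / math.pi)
        assert effective_diameter(pts, pad=False) == pytest.approx(expect, abs=1e-9)

    def test_padding_enlarges(self, rng):
        pts = rng.uniform(0, 50, size=(10, 2))
        assert effective_diameter(pts) > effective_diameter(pts, pad=False)

    def test_collinear_uses_extent(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [30.0, 0.0]])
        assert effective_diameter(pts) == pytest.approx(38.0)  # 30 + 2·4


class TestAggregateMeasures:
    def test_identical_graphs_unchanged(self):
        g = star_with_pendant()
        single = compute_measures(g)
        agg = aggregate_measures([g, g])
        assert agg.mean_degree == pytest.approx(single.mean_degree)
        assert agg.n_components == pytest.approx(single.n_components)

    def test_cell_weighted_degree(self):
        lone = build_graph(np.array([[0.0, 0.0]]))
        tri = build_graph(
            np.array([[0, 0], [9, 0], [4.5, 9 * math.sqrt(3) / 2]]),
            NeighborhoodParams(radius=10),
        )
        agg = aggregate_measures([lone, tri])
        assert agg.mean_degree == pytest.approx((0 + 2 + 2 + 2) / 4)

    def test_component_count_islet_mean(self):
        one = build_graph(np.array([[0.0, 0.0], [9.0, 0.0]]),
                          NeighborhoodParams(radius=10))
        three = build_graph(np.array([[0.0, 0.0], [100.0, 0.0], [200.0, 0.0]]))
        agg = aggregate_measures([one, three])
        assert agg.n_components == pytest.approx(2.0)

    def test_no_nonsingular_components_absent_not_zero(self):
        lone = build_graph(np.array([[0.0, 0.0], [100.0, 0.0]]))
        agg = aggregate_measures([lone])
        assert agg.cells_per_nonsingular is None

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            aggregate_measures([])


class TestGroupCompare:
    def test_identical_samples_no_significance(self):
        p, sig = group_compare([1.0, 1.0, 2.0], [1.0, 1.0, 2.0])
        assert p == 1.0
        assert not sig

    def test_fully_separated_triples_exact_p(self):
        # U = 0; exact two-sided p over the C(6,3)=20 rank arrangements
        p, _ = group_compare([1, 2, 3], [11, 12, 13])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_bonferroni_threshold(self):
        # p = 0.1 > 0.05 / 1 with n_tests=1 -> not significant either way;
        # check the corrected threshold arithmetic at n_tests = 64
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 40)
        b = rng.normal(2.0, 1, 40)
        p, sig64 = group_compare(a, b, n_tests=64)
        _, sig1 = group_compare(a, b, n_tests=1)
        assert sig1
        assert sig64 == (p < 0.05 / 64)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            group_compare([], [1.0])
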
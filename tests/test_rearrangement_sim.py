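"""RL kernels, biased selection, steric addition and the simulation driver."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from isletgraph import (
    CohortSpec,
    ModelSpec,
    NeighborhoodParams,
    RLSpec,
    SimulationConfig,
    add_vertex,
    build_graph,
    convergence_diagnostics,
    generate_islet,
    generate_cohort,
    rl_value,
    run_simulation,
    select_vertex,
)
from isletgraph.rearrangement_sim import (
    _weighted_draw,
    final_cohort_means,
    observed_d_min,
    run_family_sweep,
)


class TestRLKernels:
    def test_p_and_m_sum_to_one(self):
        x = np.linspace(-10, 10, 101)
        for rlp in range(0, 8):
            p = rl_value(x, RLSpec("P", rlp))
            m = rl_value(x, RLSpec("M", rlp))
            np.testing.assert_allclose(p + m, 1.0, atol=1e-14)

    def test_half_at_midpoint(self):
        for rlp in (0, 1, 3, 7):
            assert rl_value(rlp, RLSpec("P", rlp)) == pytest.approx(0.5)
            assert rl_value(rlp, RLSpec("M", rlp)) == pytest.approx(0.5)

    def test_two_above_midpoint(self):
        expect = 0.5 + 0.5 * np.tanh(2.0)
        assert rl_value(5.0, RLSpec("P", 3)) == pytest.approx(expect, abs=1e-12)

    def test_monotonicity(self):
        x = np.linspace(-5, 12, 200)
        assert np.all(np.diff(rl_value(x, RLSpec("P", 3))) >= 0)
        assert np.all(np.diff(rl_value(x, RLSpec("M", 3))) <= 0)


class TestModelSpec:
    def test_code_round_trip(self):
        spec = ModelSpec.from_code("MP01", basis="component_size")
        assert spec.add.direction == "M" and spec.add.rlp == 0
        assert spec.delete.direction == "P" and spec.delete.rlp == 1
        assert spec.code == "MP01"

    def test_bad_code_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec.from_code("XP01")


class TestSelectVertex:
    def test_uniform_when_quantities_equal(self, rng):
        tri = build_graph(
            np.array([[0.0, 0.0], [9.0, 0.0], [4.5, 7.8]]),
            NeighborhoodParams(radius=10),
        )
        draws = [select_vertex(tri, RLSpec("P", 2), rng) for _ in range(3000)]
        freq = np.bincount(draws, minlength=3) / 3000
        assert np.abs(freq - 1 / 3).max() < 0.04

    def test_weighted_draw_ratio(self, rng):
        w = np.array([0.1, 0.9])
        draws = [_weighted_draw(w, rng) for _ in range(20000)]
        assert np.mean(draws) == pytest.approx(0.9, abs=0.01)

    def test_selection_follows_rl_of_degree(self, rng):
        # hub degree 3, leaves degree 1; P with rlp=2 weights the hub by
        # 0.5+0.5·tanh(1) and each leaf by 0.5+0.5·tanh(-1)
        coords = np.array([[0.0, 0.0], [9.0, 0.0], [-9.0, 0.0], [0.0, 9.0]])
        g = build_graph(coords, NeighborhoodParams(radius=10))
        w_hub = 0.5 + 0.5 * np.tanh(1.0)
        w_leaf = 0.5 + 0.5 * np.tanh(-1.0)
        expect = w_hub / (w_hub + 3 * w_leaf)
        draws = [select_vertex(g, RLSpec("P", 2), rng) for _ in range(4000)]
        assert np.mean(np.array(draws) == 0) == pytest.approx(expect, abs=0.03)

    def test_far_midpoint_is_near_uniform(self, rng):
        coords = np.array([[0.0, 0.0], [9.0, 0.0], [-9.0, 0.0], [0.0, 9.0]])
        g = build_graph(coords, NeighborhoodParams(radius=10))
        draws = [select_vertex(g, RLSpec("P", 50), rng) for _ in range(4000)]
        freq = np.bincount(draws, minlength=4) / 4000
        assert np.abs(freq - 0.25).max() < 0.05


class TestAddVertex:
    def test_lonely_parent_gains_neighbor_in_band(self, rng):
        g = build_graph(np.array([[0.0, 0.0], [100.0, 0.0]]))
        cfg = SimulationConfig(n_iterations=1, n_replicates=1)
        out = add_vertex(g, parent=0, rng=rng, config=cfg, d_min=8.0)
        assert out.n_vertices == 3
        d = np.linalg.norm(out.coords[-1] - out.coords[0])
        assert 8.0 <= d <= 13.0
        np.testing.assert_allclose(out.coords[1], [100.0, 0.0])  # bystander unmoved

    def test_opposite_side_neighbor_not_displaced(self):
        # parent at origin, neighbor 8 μm east; forcing the new cell 8 μm
        # west leaves the east neighbor 16 μm away: no wave move
        from isletgraph.rearrangement_sim import _place_and_relax, nx_adjacency

        coords = np.array([[0.0, 0.0], [8.0, 0.0]])
        g = build_graph(coords, NeighborhoodParams(radius=10))
        adj = nx_adjacency(g)

        class ForcedAngle:
            """rng stub: first uniform call returns the westward angle."""

            def __init__(self):
                self.calls = 0

            def uniform(self, lo, hi, size=None):
                self.calls += 1
                if self.calls == 1:  # free-angle draw (measure offset)
                    return np.pi  # west is unoccupied
                return 8.0  # distance draw

            def random(self):
                return 0.0

        cfg = SimulationConfig(n_iterations=1, n_replicates=1)
        pts, moves = _place_and_relax(coords, 0, 8.0, ForcedAngle(), cfg, adj)
        assert moves == 0
        assert pts[-1][0] < 0  # landed west
        np.testing.assert_allclose(pts[1], [8.0, 0.0])

    def test_steric_invariant_after_many_additions(self, rng):
        spec = CohortSpec()
        islet = generate_islet(spec, rng, size="large")
        coords = islet[["x", "y"]].to_numpy(float)[:30]
        g = build_graph(coords, NeighborhoodParams(radius=13))
        cfg = SimulationConfig(n_iterations=1, n_replicates=1)
        d_min = observed_d_min(coords)
        for k in range(100):
            parent = int(rng.choice(g.cell_ids))
            g = add_vertex(g, parent, rng, cfg, d_min=d_min)
            assert pdist(g.coords).min() >= d_min - 1e-9


@pytest.fixture(scope="module")
def mini_cohort():
    return generate_cohort(CohortSpec(n_islets=15), np.random.default_rng(4))


class TestRunSimulation:
    def test_cell_count_conserved_every_iteration(self, mini_cohort):
        from isletgraph import filter_cells

        beta = filter_cells(mini_cohort, "beta")
        initial = {key: len(sub) for key, sub in beta.islets() if len(sub) >= 2}
        cfg = SimulationConfig(
            n_iterations=20, n_replicates=1, seed=9, audit=True,
            params=NeighborhoodParams(radius=13), record="trajectory",
        )
        res = run_simulation(mini_cohort, ModelSpec.from_code("MP31", "component_size"), cfg)
        for (subj, islet), sub in res.measures.groupby(["subject_id", "islet_id"]):
            assert (sub["n_vertices"] == initial[(subj, islet)]).all()

    def test_same_seed_bit_identical(self, mini_cohort):
        cfg = SimulationConfig(n_iterations=10, n_replicates=2, seed=21,
                               params=NeighborhoodParams(radius=13))
        model = ModelSpec.from_code("PM12", "degree")
        a = run_simulation(mini_cohort, model, cfg)
        b = run_simulation(mini_cohort, model, cfg)
        pd.testing.assert_frame_equal(a.measures, b.measures, check_exact=True)

    def test_sparse_islets_skipped(self, mini_cohort):
        cfg = SimulationConfig(n_iterations=2, n_replicates=1, seed=1,
                               params=NeighborhoodParams(radius=13))
        res = run_simulation(mini_cohort, ModelSpec.from_code("MM11", "component_size"), cfg)
        from isletgraph import filter_cells

        beta = filter_cells(mini_cohort, "beta")
        expected_skips = [k for k, sub in beta.islets() if len(sub) < 2]
        assert res.skipped == expected_skips

    def test_high_deletion_midpoint_fragments_more(self):
        # component-basis MP: raising rlp_d shifts deletions toward ever
        # larger clusters, leaving architectures of many small clusters
        table = generate_cohort(CohortSpec(n_islets=12, small_fraction=0.0),
                                np.random.default_rng(31))
        cfg = SimulationConfig(n_iterations=60, n_replicates=3, seed=3,
                               params=NeighborhoodParams(radius=13))
        comps = {}
        for rlp_d in (1, 5):
            model = ModelSpec.from_code(f"MP3{rlp_d}", "component_size")
            res = run_simulation(table, model, cfg)
            comps[rlp_d] = final_cohort_means(res)["n_components"].mean()
        assert comps[5] > comps[1]

    def test_family_sweep_shape(self, mini_cohort):
        cfg = SimulationConfig(n_iterations=5, n_replicates=2, seed=8,
                               params=NeighborhoodParams(radius=13))
        sweep = run_family_sweep(mini_cohort, "MP", "component_size",
                                 [1, 3], [1, 2, 3], cfg)
        assert set(sweep["rlp_a"]) == {1.0, 3.0}
        assert set(sweep["rlp_d"]) == {1.0, 2.0, 3.0}
        assert len(sweep) == 2 * 3 * 2  # rlp_a × rlp_d × replicates


class TestConvergenceDiagnostics:
    def test_identical_replicates_flat(self):
        values = np.ones((6, 4))
        diag = convergence_diagnostics(values)
        assert np.all(diag["max_sd"].to_numpy()[1:] == 0)
        assert np.all(diag["max_delta_mean"].to_numpy()[1:] == 0)

    def test_iid_mean_change_decays_like_one_over_n(self, rng):
        values = rng.normal(size=(3000, 2))
        diag = convergence_diagnostics(values)
        n = diag["n_replicates"].to_numpy()[1:]
        d = diag["max_delta_mean"].to_numpy()[1:]
        slope = np.polyfit(np.log(n), np.log(d + 1e-300), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.25)

    def test_max_dominates_each_pair(self, rng):
        values = rng.normal(size=(50, 3))
        diag = convergence_diagnostics(values)
        single = convergence_diagnostics(values[:, :1])
        assert np.all(diag["max_sd"].to_numpy()[1:] >= single["max_sd"].to_numpy()[1:] - 1e-12)
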
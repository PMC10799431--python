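import numpy as np
import pytest

import velogcn as vg
from velogcn.datamodel import VelocityEstimate
from velogcn.evaluate import (
    boundary_cells,
    celltype_consistency,
    continuity_error,
    cs_cell,
    cs_gene,
    correlation_score,
    direction_score,
    overall_consistency,
)
from velogcn.objective import candidate_target_probabilities
from velogcn.preprocess import build_knn_graph, compute_pca

from conftest import make_dataset, make_graph


class TestOverallConsistency:
    def test_uniform_field_scores_one(self):
        v = np.tile([1.0, 2.0], (5, 1))
        g = make_graph([[1, 2], [0, 2], [0, 1], [0, 1], [0, 1]])
        np.testing.assert_allclose(overall_consistency(VelocityEstimate(v=v), g), 1.0)

    def test_opposed_neighbors_score_minus_one(self):
        v = np.array([[1.0, 0.0], [-1.0, 0.0], [-1.0, 0.0]])
        g = make_graph([[1, 2], [0, 2], [0, 1]])
        scores = overall_consistency(VelocityEstimate(v=v), g)
        assert scores[0] == pytest.approx(-1.0)

    def test_three_cell_hand_example(self):
        # velocities (1,0), (0,1), (1,1); full neighbor graph
        v = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        g = make_graph([[1, 2], [0, 2], [0, 1]])
        scores = overall_consistency(VelocityEstimate(v=v), g)
        c45 = np.cos(np.pi / 4)
        np.testing.assert_allclose(scores, [(0 + c45) / 2, (0 + c45) / 2, c45], atol=1e-12)

    def test_zero_velocity_cell_is_nan(self):
        v = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 0.0]])
        g = make_graph([[1, 2], [0, 2], [0, 1]])
        scores = overall_consistency(VelocityEstimate(v=v), g)
        assert np.isnan(scores[0]) and not np.isnan(scores[1])

    def test_matches_bruteforce_double_loop(self, rng):
        n, d, k = 50, 4, 6
        v = rng.normal(size=(n, d))
        s = np.abs(rng.normal(size=(n, d))) + 0.5
        ds = make_dataset(s, s.copy())
        ds = compute_pca(ds, 3)
        g = build_knn_graph(ds, k)
        scores = overall_consistency(VelocityEstimate(v=v), g)
        for i in range(n):
            expected = np.mean(
                [
                    v[i] @ v[j] / (np.linalg.norm(v[i]) * np.linalg.norm(v[j]))
                    for j in g.indices[i]
                ]
            )
            assert scores[i] == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_positive_rescaling(self, rng):
        n, d = 20, 3
        v = rng.normal(size=(n, d))
        g = make_graph(np.array([[(i + 1) % n, (i + 2) % n] for i in range(n)]))
        a = overall_consistency(VelocityEstimate(v=v), g)
        scale = rng.uniform(0.5, 5.0, size=(n, 1))
        b = overall_consistency(VelocityEstimate(v=v * scale), g)
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestCelltypeConsistency:
    def test_singleton_type_scores_one_via_self_term(self):
        v = np.array([[1.0, 0.0], [0.0, 1.0]])
        labels = np.array(["a", "b"])
        scores = celltype_consistency(VelocityEstimate(v=v), labels)
        np.testing.assert_allclose(scores, 1.0)

    def test_opposite_pair_scores_zero(self):
        v = np.array([[1.0, 0.0], [-1.0, 0.0]])
        labels = np.array(["a", "a"])
        scores = celltype_consistency(VelocityEstimate(v=v), labels)
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)  # (1 + -1)/2

    def test_identical_velocities_score_one(self, rng):
        v = np.tile(rng.normal(size=3), (6, 1))
        labels = np.array(["a"] * 6)
        np.testing.assert_allclose(celltype_consistency(VelocityEstimate(v=v), labels), 1.0)

    def test_missing_labels_rejected(self):
        with pytest.raises(ValueError):
            celltype_consistency(VelocityEstimate(v=np.ones((2, 2))), None)


class TestContinuityScores:
    def _fixture(self, s_val, v_val, target_val):
        s = np.array([[s_val], [target_val]])
        ds = make_dataset(s, s.copy())
        graph = make_graph([[1], [0]])
        vel = VelocityEstimate(v=np.array([[v_val], [0.0]]))
        td = candidate_target_probabilities(ds, graph, vel, "forward")
        return ds, vel, td

    def test_perfect_extrapolation_gives_zero_error(self):
        ds, vel, td = self._fixture(1.0, 2.0, 3.0)
        eps = continuity_error(ds, vel, td)
        assert eps[0, 0] == 0.0

    def test_hand_computed_relative_error(self):
        # s=1, v=1, target 3 -> |1+1-3| / 1 = 1
        ds, vel, td = self._fixture(1.0, 1.0, 3.0)
        eps = continuity_error(ds, vel, td)
        assert eps[0, 0] == pytest.approx(1.0)

    def test_zero_spliced_uses_floor(self):
        s = np.array([[0.0], [1.0]])
        ds = make_dataset(s, s + 1)
        graph = make_graph([[1], [0]])
        vel = VelocityEstimate(v=np.array([[0.5], [0.0]]))
        td = candidate_target_probabilities(ds, graph, vel, "forward")
        eps = continuity_error(ds, vel, td, eps_floor=1e-3)
        assert np.isfinite(eps[0, 0])
        assert eps[0, 0] == pytest.approx(abs(0.0 + 0.5 - 1.0) / 1e-3)

    def test_cs_bounds_and_identities(self):
        assert cs_cell(np.zeros((3, 4)))[0] == 1.0
        assert cs_gene(np.zeros((3, 4)))[0] == 1.0
        big = np.full((3, 4), 1e6)
        assert cs_cell(big)[0] == pytest.approx(0.0, abs=1e-9)

    def test_cs_single_gene_tanh_value(self):
        # tanh(ln 3) = (3 - 1/3)/(3 + 1/3) = 0.8 -> CS = 0.2
        eps = np.array([[np.log(3.0)]])
        assert cs_cell(eps)[0] == pytest.approx(0.2)
        assert cs_gene(eps)[0] == pytest.approx(0.2)

    def test_cs_strictly_decreasing_in_eps(self, rng):
        eps = rng.uniform(0.1, 1.0, size=(5, 4))
        base = cs_cell(eps)
        bumped = eps.copy()
        bumped[2, 1] += 0.2
        out = cs_cell(bumped)
        assert out[2] < base[2]
        np.testing.assert_allclose(np.delete(out, 2), np.delete(base, 2))


class TestCorrelationScore:
    def test_velocity_tracking_unspliced(self, rng):
        u = np.abs(rng.normal(size=(30, 1))) + 1
        s = np.full((30, 1), 2.0)
        ds = make_dataset(s, u)
        scores = correlation_score(VelocityEstimate(v=u.copy()), ds)
        assert scores[0] == pytest.approx(1.0)  # corr(v,u)=1, s constant -> 0

    def test_worst_case_score(self, rng):
        # v anti-proportional to u and proportional to s
        base = np.abs(rng.normal(size=30)) + 1
        u = base.reshape(-1, 1)
        s = (base.max() - base + 0.1).reshape(-1, 1)
        ds = make_dataset(s, u)
        scores = correlation_score(VelocityEstimate(v=-u), ds)
        assert scores[0] == pytest.approx(-2.0)

    def test_independent_velocity_near_zero(self, rng):
        n = 500
        u = np.abs(rng.normal(size=(n, 1))) + 1
        s = np.abs(rng.normal(size=(n, 1))) + 1
        ds = make_dataset(s, u)
        v = rng.normal(size=(n, 1))
        scores = correlation_score(VelocityEstimate(v=v), ds)
        assert abs(scores[0]) < 0.5


class TestBoundaryCells:
    def _fixture(self):
        labels = np.array(["A", "A", "A", "B", "B"])
        s = np.arange(10.0).reshape(5, 2)
        ds = make_dataset(s, s.copy(), cell_type=labels)
        # cell 0: no B neighbor; cell 1: one B neighbor; cell 2: B neighbor
        graph = make_graph([[1, 2], [0, 3], [3, 4], [2, 4], [2, 3]])
        return ds, graph

    def test_membership_rules(self):
        ds, graph = self._fixture()
        cells = boundary_cells(ds, graph, ("A", "B"))
        np.testing.assert_array_equal(cells, [1, 2])

    def test_all_one_type_gives_empty_set(self):
        labels = np.array(["A", "A", "A"])
        s = np.arange(6.0).reshape(3, 2)
        ds = make_dataset(s, s.copy(), cell_type=labels)
        graph = make_graph([[1], [0], [1]])
        with pytest.raises(ValueError, match="unknown cell type"):
            boundary_cells(ds, graph, ("A", "B"))

    def test_unknown_label_rejected(self):
        ds, graph = self._fixture()
        with pytest.raises(ValueError, match="unknown cell type"):
            boundary_cells(ds, graph, ("A", "C"))


class TestDirectionScore:
    def test_parallel_velocities_score_one(self):
        s = np.array([[0.0], [1.0]])
        ds = make_dataset(s, s.copy(), cell_type=np.array(["A", "B"]))
        graph = make_graph([[1], [0]])
        v = np.array([[1.0], [1.0]])
        res = direction_score(ds, VelocityEstimate(v=v), graph, [("A", "B")])
        assert res.global_score == pytest.approx(1.0)

    def test_antiparallel_velocities_score_minus_one(self):
        s = np.array([[0.0], [1.0]])
        ds = make_dataset(s, s.copy(), cell_type=np.array(["A", "B"]))
        graph = make_graph([[1], [0]])
        v = np.array([[1.0], [-1.0]])
        res = direction_score(ds, VelocityEstimate(v=v), graph, [("A", "B")])
        assert res.global_score == pytest.approx(-1.0)

    def test_union_weighting_hand_fixture(self):
        """Global score averages over the union of boundary cells (0.8),
        not over per-pair means (which would give 0.0)."""
        # pair 1: 9 A1 cells each with one B1 neighbor, aligned (+1)
        # pair 2: 1 A2 cell with one B2 neighbor, anti-aligned (-1)
        n = 20
        s = np.zeros((n, 1))
        labels = np.array(["A1"] * 9 + ["B1"] * 9 + ["A2", "B2"])
        s[9:18] = 1.0  # B1 cells ahead of A1 cells
        s[18] = 0.0
        s[19] = 1.0
        v = np.zeros((n, 1))
        v[9:18] = 1.0   # B1 velocity along displacement
        v[19] = -1.0    # B2 velocity against displacement
        ds = make_dataset(np.abs(s), np.abs(s) + 1, cell_type=labels)
        indices = np.array([[i + 9] for i in range(9)] + [[0]] * 9 + [[19], [18]])
        graph = make_graph(indices)
        res = direction_score(
            ds, VelocityEstimate(v=v), graph, [("A1", "B1"), ("A2", "B2")]
        )
        assert res.global_score == pytest.approx((9 * 1.0 + 1 * (-1.0)) / 10)
        per_pair_mean = np.mean([1.0, -1.0])
        assert res.global_score != pytest.approx(per_pair_mean)

    def test_velocity_of_cell_variant(self):
        s = np.array([[0.0], [1.0]])
        ds = make_dataset(s, s.copy(), cell_type=np.array(["A", "B"]))
        graph = make_graph([[1], [0]])
        v = np.array([[1.0], [-1.0]])
        res = direction_score(
            ds, VelocityEstimate(v=v), graph, [("A", "B")], velocity_of="cell"
        )
        # uses v_i of the boundary cell (+1), not the neighbor's (-1)
        assert res.global_score == pytest.approx(1.0)

    def test_empty_union_raises(self):
        # A cells only neighbor other A cells; B is isolated from them
        ds = make_dataset(
            np.array([[0.0], [0.5], [1.0]]),
            np.array([[0.0], [0.5], [1.0]]),
            cell_type=np.array(["A", "A", "B"]),
        )
        graph = make_graph([[1], [0], [0]])
        with pytest.raises(ValueError, match="no boundary cells"):
            direction_score(ds, VelocityEstimate(v=np.ones((3, 1))), graph, [("A", "B")])

    def test_ground_truth_velocity_points_forward_in_time(self):
        """On a noise-free simulation the true velocity aligns with the
        displacement toward later pseudotime bins for >= 90% of boundary
        cells."""
        ds, truth = vg.simulate_population(400, 20, 2, 0.0, seed=1)
        ds = compute_pca(ds, 20)
        graph = build_knn_graph(ds, 30)
        from velogcn.protocols import pseudotime_bin_labels

        labels, pairs = pseudotime_bin_labels(ds.pseudotime)
        res = direction_score(
            ds, VelocityEstimate(v=truth.true_velocity), graph, pairs, cell_type=labels
        )
        per_cell = np.array(list(res.per_cell.values()))
        assert (per_cell > 0).mean() >= 0.9
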
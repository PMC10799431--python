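import numpy as np
import pytest

import velogcn as vg
from velogcn.datamodel import VelocityEstimate
from velogcn.model import GcnState, ModelConfig, _forward, compute_velocity, model_input
from velogcn.objective import (
    LossBreakdown,
    ObjectiveConfig,
    _backward,
    _loss_and_velocity_grad,
    candidate_target_probabilities,
    continuity_loss,
    pearson_loss,
    total_loss,
    train,
)
from velogcn.preprocess import build_knn_graph, compute_pca, smooth_by_neighbors

from conftest import make_dataset, make_graph


class TestTargetProbabilities:
    def _setup(self):
        # cell 0 at (1,1) with displacements (1,0), (-1,0), (0,1) to candidates
        s = np.array([[1.0, 1.0], [2.0, 1.0], [0.0, 1.0], [1.0, 2.0]])
        ds = make_dataset(s, s + 1.0)
        graph = make_graph([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])
        v = np.zeros((4, 2))
        v[0] = [1.0, 0.0]
        return ds, graph, VelocityEstimate(v=v)

    def test_forward_selects_positive_cosine_candidates(self):
        ds, graph, vel = self._setup()
        td = candidate_target_probabilities(ds, graph, vel, "forward")
        # cosines 1, -1, 0: only the first is strictly positive
        np.testing.assert_allclose(td.prob_forward[0], [1.0, 0.0, 0.0])
        assert td.z_forward[0] == 1

    def test_backward_flips_sign(self):
        ds, graph, vel = self._setup()
        td = candidate_target_probabilities(ds, graph, vel, "backward")
        np.testing.assert_allclose(td.prob_backward[0], [0.0, 1.0, 0.0])

    def test_zero_velocity_row_is_flagged_empty(self):
        ds, graph, vel = self._setup()
        td = candidate_target_probabilities(ds, graph, vel, "forward")
        # cells 1..3 have zero velocity
        assert np.all(td.z_forward[1:] == 0)
        np.testing.assert_array_equal(td.prob_forward[1:], 0.0)

    def test_rows_are_uniform_over_support(self, rng):
        n, d, k = 30, 4, 6
        s = rng.gamma(2, 1, (n, d))
        ds = make_dataset(s, s + 0.5)
        ds = compute_pca(ds, 3)
        graph = build_knn_graph(ds, k)
        vel = VelocityEstimate(v=rng.normal(size=(n, d)))
        td = candidate_target_probabilities(ds, graph, vel, "forward")
        for i in range(n):
            z = td.z_forward[i]
            row = td.prob_forward[i]
            if z == 0:
                np.testing.assert_array_equal(row, 0.0)
            else:
                support = row[row > 0]
                np.testing.assert_allclose(support, 1.0 / z)
                assert abs(row.sum() - 1.0) < 1e-8


class TestContinuityLoss:
    def test_perfect_extrapolation_gives_zero(self):
        s = np.array([[1.0], [3.0]])
        ds = make_dataset(s, s.copy())
        graph = make_graph([[1], [0]])
        vel = VelocityEstimate(v=np.array([[2.0], [-2.0]]))
        td = candidate_target_probabilities(ds, graph, vel, "forward")
        assert continuity_loss(ds, vel, td, "forward") == 0.0

    def test_hand_computed_value(self):
        # cell 0: s=1, v=1, single forward target s=3 -> (1+1-3)^2 = 1
        # cell 1: s=3, v=-1, single forward target s=1 -> (3-1-1)^2 = 1
        s = np.array([[1.0], [3.0]])
        ds = make_dataset(s, s.copy())
        graph = make_graph([[1], [0]])
        vel = VelocityEstimate(v=np.array([[1.0], [-1.0]]))
        td = candidate_target_probabilities(ds, graph, vel, "forward")
        assert continuity_loss(ds, vel, td, "forward") == pytest.approx(1.0)

    def test_two_candidate_mean_matches_extrapolation(self):
        # candidates at 2 and 4 with probability 1/2 each; s+v = 3
        s = np.array([[1.0], [2.0], [4.0]])
        ds = make_dataset(s, s.copy())
        graph = make_graph([[1, 2], [0, 2], [0, 1]])
        v = np.array([[2.0], [0.0], [0.0]])
        vel = VelocityEstimate(v=v)
        td = candidate_target_probabilities(ds, graph, vel, "forward")
        np.testing.assert_allclose(td.prob_forward[0], [0.5, 0.5])
        resid_cell0 = (1.0 + 2.0 - 3.0) ** 2
        assert resid_cell0 == 0.0
        # cells 1 and 2 have zero velocity -> contribute 0
        assert continuity_loss(ds, vel, td, "forward") == 0.0


class TestPearsonLoss:
    def test_perfectly_correlated_with_unspliced(self, rng):
        u = rng.normal(size=(20, 1)) + 5
        s = np.full((20, 1), 2.0)  # constant spliced -> that term guarded to 0
        ds = make_dataset(np.abs(s), np.abs(u))
        vel = VelocityEstimate(v=ds.unspliced.copy())
        assert pearson_loss(vel, ds, 1.0, 1.0) == pytest.approx(-1.0)

    def test_anticorrelated_with_unspliced(self, rng):
        u = np.abs(rng.normal(size=(20, 1))) + 1
        s = np.full((20, 1), 2.0)
        ds = make_dataset(s, u)
        vel = VelocityEstimate(v=-u)
        assert pearson_loss(vel, ds, 1.0, 1.0) == pytest.approx(1.0)

    def test_constant_velocity_gene_contributes_zero(self, rng):
        u = np.abs(rng.normal(size=(20, 2))) + 1
        s = np.abs(rng.normal(size=(20, 2))) + 1
        ds = make_dataset(s, u)
        v = np.column_stack([np.full(20, 3.0), u[:, 1]])
        # gene 0 constant -> only gene 1 contributes corr(v,u)=1
        got = pearson_loss(VelocityEstimate(v=v), ds, 1.0, 0.0)
        assert got == pytest.approx(-1.0)

    def test_fewer_than_two_cells_raises(self):
        ds = make_dataset([[1.0]], [[1.0]])
        with pytest.raises(ValueError):
            pearson_loss(VelocityEstimate(v=np.array([[1.0]])), ds)


class TestTotalLoss:
    def test_weighted_combination_arithmetic(self):
        cfg = ObjectiveConfig(weight_forward=1.0, weight_backward=1.0, weight_pearson=18.0)
        lb = LossBreakdown.combine(0.5, 0.5, -0.1, cfg)
        assert lb.total == pytest.approx(-0.8)

    def test_zero_components_give_zero_total(self):
        lb = LossBreakdown.combine(0.0, 0.0, 0.0, ObjectiveConfig())
        assert lb.total == 0.0

    def test_pearson_weight_zero_removes_term(self, rng, random_dataset):
        ds = compute_pca(random_dataset, 3)
        graph = build_knn_graph(ds, 5)
        ds = smooth_by_neighbors(ds, graph)
        vel = VelocityEstimate(v=rng.normal(size=ds.shape))
        a = total_loss(ds, graph, vel, ObjectiveConfig(weight_pearson=0.0))
        b = total_loss(ds, graph, vel, ObjectiveConfig(weight_pearson=5.0))
        assert a.loss_forward == b.loss_forward
        assert a.total == pytest.approx(a.loss_forward + a.loss_backward)

    def test_matches_loop_oracle(self, rng):
        """Vectorized objective equals a naive per-cell/per-gene loop."""
        n, d, k = 40, 5, 6
        s = rng.gamma(2, 1, (n, d))
        u = rng.gamma(2, 1, (n, d))
        ds = make_dataset(s, u)
        ds = compute_pca(ds, 4)
        graph = build_knn_graph(ds, k)
        ds = smooth_by_neighbors(ds, graph)
        vel = VelocityEstimate(v=rng.normal(size=(n, d)))
        cfg = ObjectiveConfig(weight_pearson=18.0)
        got = total_loss(ds, graph, vel, cfg)

        sm, um = ds.layers_for_model()
        v = vel.v

        def loop_direction(sign):
            acc = 0.0
            for i in range(n):
                vi = sign * v[i]
                cands = []
                for j in graph.indices[i]:
                    diff = sm[j] - sm[i]
                    nd, nv = np.linalg.norm(diff), np.linalg.norm(vi)
                    if nd > 0 and nv > 0 and float(diff @ vi) / (nd * nv) > 0:
                        cands.append(j)
                if not cands:
                    continue
                target = np.mean([sm[j] for j in cands], axis=0)
                resid = sm[i] + sign * v[i] - target
                acc += float(resid @ resid)
            return acc / (n * d)

        lf = loop_direction(+1.0)
        lb = loop_direction(-1.0)

        def corr(a, b):
            a = a - a.mean()
            b = b - b.mean()
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            return float(a @ b / (na * nb)) if na > 1e-12 and nb > 1e-12 else None

        cu = [corr(v[:, g], um[:, g]) for g in range(d)]
        cs = [corr(v[:, g], -sm[:, g]) for g in range(d)]
        cu = [c for c in cu if c is not None]
        cs = [c for c in cs if c is not None]
        lp = -(np.mean(cu) + np.mean(cs))
        assert got.loss_forward == pytest.approx(lf, abs=1e-8)
        assert got.loss_backward == pytest.approx(lb, abs=1e-8)
        assert got.loss_pearson == pytest.approx(lp, abs=1e-8)
        assert got.total == pytest.approx(lf + lb + 18.0 * lp, abs=1e-8)

    def test_sign_symmetry_broken_only_by_pearson(self, rng):
        """L+ + L- is invariant under v -> -v; the Pearson term is not."""
        n, d = 30, 4
        s = rng.gamma(2, 1, (n, d))
        u = rng.gamma(2, 1, (n, d))
        ds = make_dataset(s, u)
        ds = compute_pca(ds, 3)
        graph = build_knn_graph(ds, 6)
        ds = smooth_by_neighbors(ds, graph)
        v = rng.normal(size=(n, d))
        no_pearson = ObjectiveConfig(weight_pearson=0.0)
        a = total_loss(ds, graph, VelocityEstimate(v=v), no_pearson)
        b = total_loss(ds, graph, VelocityEstimate(v=-v), no_pearson)
        assert a.total == pytest.approx(b.total, abs=1e-10)
        with_pearson = ObjectiveConfig(weight_pearson=18.0)
        c = total_loss(ds, graph, VelocityEstimate(v=v), with_pearson)
        e = total_loss(ds, graph, VelocityEstimate(v=-v), with_pearson)
        assert abs(c.total - e.total) > 1e-6


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        n, d = 12, 3
        ds, _ = vg.simulate_population(n, d, 1, 0.2, seed=5)
        ds = compute_pca(ds, 3)
        graph = build_knn_graph(ds, 4)
        ds = smooth_by_neighbors(ds, graph)
        state = GcnState.initialize(d, graph, ModelConfig(hidden_sizes=(7, 5), dropout=0.0, seed=3))
        cfg = ObjectiveConfig(k_candidates=4)
        x = model_input(ds)
        s, u = ds.layers_for_model()

        cache = _forward(state, x, training=False)
        vel = compute_velocity(cache.rates, ds)
        fwd = candidate_target_probabilities(ds, graph, vel, "forward", 4)
        bwd = candidate_target_probabilities(ds, graph, vel, "backward", 4)
        _, grad_v = _loss_and_velocity_grad(s, u, vel.v, fwd, bwd, cfg)
        grads = _backward(state, cache, grad_beta=grad_v * u, grad_gamma=-grad_v * s)

        def loss_fixed_targets():
            c = _forward(state, x, training=False)
            v = compute_velocity(c.rates, ds)
            lb, _ = _loss_and_velocity_grad(s, u, v.v, fwd, bwd, cfg)
            return lb.total

        eps = 1e-6
        for p, g in zip(state.parameters(), grads):
            flat_p = p.ravel()
            flat_g = g.ravel()
            for idx in rng.choice(flat_p.size, size=min(10, flat_p.size), replace=False):
                orig = flat_p[idx]
                flat_p[idx] = orig + eps
                lp = loss_fixed_targets()
                flat_p[idx] = orig - eps
                lm = loss_fixed_targets()
                flat_p[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert fd == pytest.approx(flat_g[idx], rel=1e-4, abs=1e-7)


@pytest.fixture(scope="module")
def trained():
    ds, _ = vg.simulate_population(200, 8, 1, 0.1, seed=2)
    ds2, graph = vg.preprocess(
        ds, vg.PreprocessConfig(n_top_genes=8, n_pcs=8, k_neighbors=15, normalize_target="none")
    )
    state, log = train(ds2, graph, ModelConfig(seed=2), ObjectiveConfig(epochs=100), seed=2)
    return ds2, graph, state, log


class TestTraining:

    def test_loss_decreases_over_training(self, trained):
        _, _, _, log = trained
        totals = [lb.total for lb in log]
        assert np.median(totals[-10:]) < np.median(totals[:10])

    def test_training_is_seed_deterministic(self):
        ds, _ = vg.simulate_population(60, 5, 1, 0.1, seed=4)
        ds2, graph = vg.preprocess(
            ds, vg.PreprocessConfig(n_top_genes=5, n_pcs=5, k_neighbors=10, normalize_target="none")
        )
        s1, l1 = train(ds2, graph, ModelConfig(seed=4), ObjectiveConfig(epochs=10), seed=4)
        s2, l2 = train(ds2, graph, ModelConfig(seed=4), ObjectiveConfig(epochs=10), seed=4)
        np.testing.assert_array_equal(
            np.array([lb.total for lb in l1]), np.array([lb.total for lb in l2])
        )
        for a, b in zip(s1.parameters(), s2.parameters()):
            np.testing.assert_array_equal(a, b)

    def test_zero_learning_rate_freezes_loss(self):
        ds, _ = vg.simulate_population(50, 4, 0, 0.1, seed=6)
        ds2, graph = vg.preprocess(
            ds, vg.PreprocessConfig(n_top_genes=4, n_pcs=4, k_neighbors=8, normalize_target="none")
        )
        _, log = train(
            ds2, graph, ModelConfig(seed=6), ObjectiveConfig(epochs=5, learning_rate=0.0), seed=6
        )
        totals = [lb.total for lb in log]
        assert np.ptp(totals) == 0.0

    def test_total_matches_component_invariant(self, trained):
        _, _, _, log = trained
        cfg = ObjectiveConfig()
        for lb in log[::20]:
            expected = (
                cfg.weight_forward * lb.loss_forward
                + cfg.weight_backward * lb.loss_backward
                + cfg.weight_pearson * lb.loss_pearson
            )
            assert lb.total == pytest.approx(expected, rel=1e-12)
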
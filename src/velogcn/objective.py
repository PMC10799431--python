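"""Continuity training objective and the full-batch training loop.

The objective extrapolates each cell's spliced state one step along its
estimated velocity and penalizes the squared deviation from the
probability-weighted expression of candidate future cells (forward term),
and symmetrically one step backwards (backward term).  Candidate target
probabilities are uniform over the neighbors whose expression displacement
has positive cosine with the (signed) velocity; they are treated as
constants within each optimization step and recomputed every epoch.  A
negated Pearson-correlation term (velocity vs unspliced, velocity vs
negative spliced, per gene across cells) breaks the v -> -v symmetry of
the two extrapolation terms.

Training is full-batch gradient descent with Adam (AMSGrad) and a 0.97
per-epoch learning-rate decay; gradients are hand-derived (the network is
small) and verified against finite differences in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datamodel import ExpressionDataset, NeighborGraph, VelocityEstimate
from .model import (
    ForwardCache,
    GcnState,
    ModelConfig,
    _forward,
    compute_velocity,
    model_input,
    softplus_grad,
)

__all__ = [
    "TargetDistribution",
    "ObjectiveConfig",
    "LossBreakdown",
    "candidate_target_probabilities",
    "continuity_loss",
    "pearson_loss",
    "total_loss",
    "train",
]

logger = logging.getLogger(__name__)

_VAR_EPS = 1e-12  # variance guard for Pearson terms


@dataclass
class ObjectiveConfig:
    """Weights and optimizer settings of the continuity objective."""

    k_candidates: int = 30
    weight_forward: float = 1.0
    weight_backward: float = 1.0
    weight_pearson: float = 18.0
    lambda_u: float = 1.0
    lambda_s: float = 1.0
    epochs: int = 100
    learning_rate: float = 0.001
    lr_decay: float = 0.97
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        for name in ("weight_forward", "weight_backward", "weight_pearson"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TargetDistribution:
    """Per-cell probabilities over candidate future (or past) neighbors.

    Probabilities are exactly 1/Z over the candidates with positive cosine
    between the expression displacement and the (signed) velocity and 0
    elsewhere; Z is the count of such candidates.  Cells with Z = 0 are
    flagged and carry an all-zero row.
    """

    candidate_indices: np.ndarray                    # N x k
    prob_forward: Optional[np.ndarray] = None        # N x k
    prob_backward: Optional[np.ndarray] = None
    z_forward: Optional[np.ndarray] = None
    z_backward: Optional[np.ndarray] = None

    def prob(self, direction: str) -> np.ndarray:
        p = self.prob_forward if direction == "forward" else self.prob_backward
        if p is None:
            raise ValueError(f"{direction} probabilities not computed")
        return p

    def z(self, direction: str) -> np.ndarray:
        z = self.z_forward if direction == "forward" else self.z_backward
        if z is None:
            raise ValueError(f"{direction} normalizers not computed")
        return z


@dataclass
class LossBreakdown:
    """Components of the continuity objective and their weighted total."""

    loss_forward: float
    loss_backward: float
    loss_pearson: float
    total: float

    @classmethod
    def combine(
        cls, lf: float, lb: float, lp: float, config: ObjectiveConfig
    ) -> "LossBreakdown":
        total = (
            config.weight_forward * lf
            + config.weight_backward * lb
            + config.weight_pearson * lp
        )
        return cls(loss_forward=lf, loss_backward=lb, loss_pearson=lp, total=total)


def _candidate_masks(
    s: np.ndarray,
    indices: np.ndarray,
    v: np.ndarray,
    chunk: int = 512,
) -> np.ndarray:
    """Boolean N x k mask: candidate j has cos(s_j - s_i, v_i) > 0.

    Only the sign of the dot product matters for strict positivity, plus
    guards for zero displacement or zero velocity.
    """
    n, k = indices.shape
    mask = np.zeros((n, k), dtype=bool)
    v_norm = np.linalg.norm(v, axis=1)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        diffs = s[indices[start:stop]] - s[start:stop, None, :]
        dots = np.einsum("nkd,nd->nk", diffs, v[start:stop])
        diff_norm = np.linalg.norm(diffs, axis=2)
        mask[start:stop] = (
            (dots > 0) & (diff_norm > 0) & (v_norm[start:stop, None] > 0)
        )
    return mask


def candidate_target_probabilities(
    dataset: ExpressionDataset,
    graph: NeighborGraph,
    velocity: VelocityEstimate,
    direction: str = "forward",
    k_candidates: Optional[int] = None,
) -> TargetDistribution:
    """Uniform target probabilities over velocity-aligned candidate neighbors.

    ``direction="forward"`` selects candidates with positive cosine between
    the displacement ``s_j - s_i`` and ``v_i`` (possible future states);
    ``"backward"`` uses ``-v_i`` (possible past states).
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    s, _ = dataset.layers_for_model()
    k = graph.indices.shape[1] if k_candidates is None else min(k_candidates, graph.indices.shape[1])
    indices = graph.indices[:, :k]
    v = velocity.v if direction == "forward" else -velocity.v
    mask = _candidate_masks(s, indices, v)
    z = mask.sum(axis=1).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        prob = np.where(z[:, None] > 0, mask / np.maximum(z, 1.0)[:, None], 0.0)
    td = TargetDistribution(candidate_indices=indices)
    if direction == "forward":
        td.prob_forward, td.z_forward = prob, z
    else:
        td.prob_backward, td.z_backward = prob, z
    return td


def _weighted_target_expression(
    s: np.ndarray, targets: TargetDistribution, direction: str
) -> np.ndarray:
    """T[i] = sum_j P(i->j) s_j over the candidate set."""
    prob = targets.prob(direction)
    n, k = prob.shape
    out = np.zeros_like(s)
    chunk = 512
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        out[start:stop] = np.einsum(
            "nk,nkd->nd", prob[start:stop], s[targets.candidate_indices[start:stop]]
        )
    return out


def _continuity_residual(
    s: np.ndarray,
    v: np.ndarray,
    targets: TargetDistribution,
    direction: str,
) -> np.ndarray:
    """Residual of the extrapolated state against the expected target
    expression; rows with Z = 0 are zeroed (they contribute no loss)."""
    t_expr = _weighted_target_expression(s, targets, direction)
    sign = 1.0 if direction == "forward" else -1.0
    resid = s + sign * v - t_expr
    resid[targets.z(direction) == 0] = 0.0
    return resid


def continuity_loss(
    dataset: ExpressionDataset,
    velocity: VelocityEstimate,
    targets: TargetDistribution,
    direction: str = "forward",
) -> float:
    """Mean squared extrapolation error over cells and genes."""
    s, _ = dataset.layers_for_model()
    resid = _continuity_residual(s, velocity.v, targets, direction)
    return float(np.mean(resid**2))


def _pearson_terms(
    v: np.ndarray, other: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene Pearson correlation of v with `other` across cells.

    Returns (corr, valid mask, centered v, centered other); genes with zero
    variance in either argument are invalid and contribute 0.
    """
    vc = v - v.mean(axis=0)
    oc = other - other.mean(axis=0)
    sv = np.sqrt(np.sum(vc**2, axis=0))
    so = np.sqrt(np.sum(oc**2, axis=0))
    valid = (sv > _VAR_EPS) & (so > _VAR_EPS)
    corr = np.zeros(v.shape[1])
    corr[valid] = np.sum(vc[:, valid] * oc[:, valid], axis=0) / (sv[valid] * so[valid])
    return corr, valid, vc, oc


def pearson_loss(
    velocity: VelocityEstimate,
    dataset: ExpressionDataset,
    lambda_u: float = 1.0,
    lambda_s: float = 1.0,
) -> float:
    """Negated correlation heuristic: velocity should correlate positively
    with unspliced and negatively with spliced expression.

    Per-gene correlations across cells, averaged over genes with nonzero
    variance in both arguments; the negated weighted sum is returned.
    """
    s, u = dataset.layers_for_model()
    if s.shape[0] < 2:
        raise ValueError("pearson_loss requires at least 2 cells")
    corr_u, valid_u, _, _ = _pearson_terms(velocity.v, u)
    corr_s, valid_s, _, _ = _pearson_terms(velocity.v, -s)
    mean_u = float(corr_u[valid_u].mean()) if valid_u.any() else 0.0
    mean_s = float(corr_s[valid_s].mean()) if valid_s.any() else 0.0
    return -(lambda_u * mean_u + lambda_s * mean_s)


def total_loss(
    dataset: ExpressionDataset,
    graph: NeighborGraph,
    velocity: VelocityEstimate,
    config: Optional[ObjectiveConfig] = None,
) -> LossBreakdown:
    """Weighted combination of the three objective terms, with candidate
    probabilities computed from the supplied velocity."""
    config = config or ObjectiveConfig()
    fwd = candidate_target_probabilities(
        dataset, graph, velocity, "forward", config.k_candidates
    )
    bwd = candidate_target_probabilities(
        dataset, graph, velocity, "backward", config.k_candidates
    )
    lf = continuity_loss(dataset, velocity, fwd, "forward")
    lb = continuity_loss(dataset, velocity, bwd, "backward")
    lp = pearson_loss(velocity, dataset, config.lambda_u, config.lambda_s)
    return LossBreakdown.combine(lf, lb, lp, config)


# ---------------------------------------------------------------------------
# gradients


def _loss_and_velocity_grad(
    s: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    fwd: TargetDistribution,
    bwd: TargetDistribution,
    config: ObjectiveConfig,
) -> tuple[LossBreakdown, np.ndarray]:
    """Objective value and its exact gradient with respect to the velocity
    matrix, holding the target probabilities fixed."""
    n, d = v.shape
    resid_f = _continuity_residual(s, v, fwd, "forward")
    resid_b = _continuity_residual(s, v, bwd, "backward")
    lf = float(np.mean(resid_f**2))
    lb = float(np.mean(resid_b**2))
    grad = (2.0 / (n * d)) * (
        config.weight_forward * resid_f - config.weight_backward * resid_b
    )

    corr_u, valid_u, vc_u, uc = _pearson_terms(v, u)
    corr_s, valid_s, vc_s, sc = _pearson_terms(v, -s)
    mean_u = float(corr_u[valid_u].mean()) if valid_u.any() else 0.0
    mean_s = float(corr_s[valid_s].mean()) if valid_s.any() else 0.0
    lp = -(config.lambda_u * mean_u + config.lambda_s * mean_s)

    if config.weight_pearson > 0:
        # d corr_g / d v_i = (oc_i / (Sv So) - corr * vc_i / Sv^2); the
        # centering projection vanishes because both arguments are centered
        def add_corr_grad(valid, vc, oc, corr, lam):
            if not valid.any():
                return
            sv = np.sqrt(np.sum(vc[:, valid] ** 2, axis=0))
            so = np.sqrt(np.sum(oc[:, valid] ** 2, axis=0))
            g = oc[:, valid] / (sv * so) - corr[valid] * vc[:, valid] / sv**2
            scale = -config.weight_pearson * lam / valid.sum()
            grad[:, valid] += scale * g

        add_corr_grad(valid_u, vc_u, uc, corr_u, config.lambda_u)
        add_corr_grad(valid_s, vc_s, sc, corr_s, config.lambda_s)

    return LossBreakdown.combine(lf, lb, lp, config), grad


def _backward(
    state: GcnState,
    cache: ForwardCache,
    grad_beta: np.ndarray,
    grad_gamma: np.ndarray,
) -> list[np.ndarray]:
    """Backpropagate rate-block gradients through the head and GCN layers;
    returns gradients matching ``state.parameters()`` order."""
    cfg = state.config
    d = state.n_genes
    grad_head_pre = np.zeros_like(cache.head_pre)
    sp_grad = softplus_grad(cache.head_pre)
    grad_head_pre[:, :d] = grad_beta * sp_grad[:, :d]
    grad_head_pre[:, d : 2 * d] = grad_gamma * sp_grad[:, d : 2 * d]
    # alpha head (if present) receives no gradient from the objective

    grad_head_w = cache.acts[-1].T @ grad_head_pre
    grad_head_b = grad_head_pre.sum(axis=0)
    grad_h = grad_head_pre @ state.head_weight.T

    grad_weights: list[np.ndarray] = [None] * len(state.layer_weights)  # type: ignore
    for li in range(len(state.layer_weights) - 1, -1, -1):
        mask = cache.dropout_masks[li]
        if mask is not None:
            grad_h = grad_h * mask
        grad_pre = grad_h * (cache.pre_acts[li] > 0)
        grad_weights[li] = cache.propagated[li].T @ grad_pre
        if li > 0:
            # norm_adj is symmetric, so its transpose is itself
            grad_h = np.asarray(state.norm_adj @ (grad_pre @ state.layer_weights[li].T))
    return [*grad_weights, grad_head_w, grad_head_b]


class _AmsgradAdam:
    """Adam with the AMSGrad max-of-second-moment correction."""

    def __init__(self, params: list[np.ndarray], config: ObjectiveConfig) -> None:
        self.config = config
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.v_max = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float) -> None:
        b1, b2, eps = self.config.adam_beta1, self.config.adam_beta2, self.config.adam_eps
        self.t += 1
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v, vm in zip(params, grads, self.m, self.v, self.v_max):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            np.maximum(vm, v, out=vm)
            p -= lr * (m / bc1) / (np.sqrt(vm / bc2) + eps)


def train(
    dataset: ExpressionDataset,
    graph: NeighborGraph,
    model_config: Optional[ModelConfig] = None,
    objective_config: Optional[ObjectiveConfig] = None,
    seed: int = 0,
) -> tuple[GcnState, list[LossBreakdown]]:
    """Full-batch training of the rate-prediction GCN.

    Each epoch recomputes the candidate target probabilities from the
    current (inference-mode) velocity, then takes one Adam step on the
    dropout-active forward pass.  The returned log holds one inference-mode
    :class:`LossBreakdown` per epoch, so the trajectory is a deterministic
    function of the weights.
    """
    model_config = model_config or ModelConfig(seed=seed)
    objective_config = objective_config or ObjectiveConfig()
    state = GcnState.initialize(dataset.n_genes, graph, model_config)
    x = model_input(dataset)
    s, u = dataset.layers_for_model()
    rng = np.random.default_rng(seed + 1)
    optimizer = _AmsgradAdam(state.parameters(), objective_config)
    log: list[LossBreakdown] = []
    lr = objective_config.learning_rate
    kc = objective_config.k_candidates

    for epoch in range(objective_config.epochs):
        # targets from the current weights, dropout off (stop-gradient)
        eval_cache = _forward(state, x, training=False)
        v_eval = compute_velocity(eval_cache.rates, dataset)
        fwd = candidate_target_probabilities(dataset, graph, v_eval, "forward", kc)
        bwd = candidate_target_probabilities(dataset, graph, v_eval, "backward", kc)
        eval_loss, _ = _loss_and_velocity_grad(
            s, u, v_eval.v, fwd, bwd, objective_config
        )
        if not np.isfinite(eval_loss.total):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: "
                f"L+={eval_loss.loss_forward}, L-={eval_loss.loss_backward}, "
                f"Lp={eval_loss.loss_pearson}"
            )
        log.append(eval_loss)

        train_cache = _forward(state, x, training=True, rng=rng)
        v_train = compute_velocity(train_cache.rates, dataset)
        _, grad_v = _loss_and_velocity_grad(
            s, u, v_train.v, fwd, bwd, objective_config
        )
        grads = _backward(state, train_cache, grad_beta=grad_v * u, grad_gamma=-grad_v * s)
        optimizer.step(state.parameters(), grads, lr)
        lr *= objective_config.lr_decay

    return state, log
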
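"""Graph convolutional network mapping neighborhood expression to
cell-specific kinetic rates, and the velocity algebra built on them.

The network follows the standard GCN propagation rule

    H^(l+1) = sigma( D^-1/2 (A + I) D^-1/2  H^(l)  W^(l) )

with ReLU activations, two hidden layers (64 units each by default) and a
fully connected output head producing per-cell, per-gene rate blocks.
Nonnegativity of the rates is enforced by a softplus output activation.
The implementation is plain numpy: the forward pass caches intermediates
so :mod:`velogcn.objective` can run an exact hand-derived backward pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .datamodel import ExpressionDataset, KineticRates, NeighborGraph, VelocityEstimate

__all__ = [
    "ModelConfig",
    "GcnState",
    "normalized_adjacency",
    "gcn_layer_forward",
    "forward_rates",
    "compute_velocity",
    "compute_unspliced_velocity",
    "softplus",
]


@dataclass
class ModelConfig:
    """Architecture and initialization knobs of the rate-prediction GCN."""

    hidden_sizes: tuple[int, ...] = (64, 64)
    dropout: float = 0.2
    predict_alpha: bool = False
    rate_activation: str = "softplus"
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")

    @property
    def n_heads(self) -> int:
        return 3 if self.predict_alpha else 2


def softplus(x: np.ndarray) -> np.ndarray:
    # numerically stable log(1 + e^x)
    return np.logaddexp(0.0, x)


def softplus_grad(x: np.ndarray) -> np.ndarray:
    # sigmoid(x)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def normalized_adjacency(graph: NeighborGraph) -> sp.csr_matrix:
    """Symmetrically normalized adjacency D^-1/2 (A + I) D^-1/2.

    The kNN graph is symmetrized first (edge kept if present in either
    direction) because the normalization presumes an undirected graph.
    """
    a = graph.symmetric_adjacency()
    a = a + sp.identity(a.shape[0], format="csr")
    deg = np.asarray(a.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    d = sp.diags(d_inv_sqrt)
    return (d @ a @ d).tocsr()


@dataclass
class GcnState:
    """Trainable parameters plus the precomputed normalized adjacency."""

    layer_weights: list[np.ndarray]
    head_weight: np.ndarray
    head_bias: np.ndarray
    norm_adj: sp.csr_matrix
    config: ModelConfig
    n_genes: int
    fingerprint: dict = field(default_factory=dict)

    @classmethod
    def initialize(
        cls,
        n_genes: int,
        graph: NeighborGraph,
        config: Optional[ModelConfig] = None,
    ) -> "GcnState":
        """Glorot-style uniform initialization, seeded from the config."""
        config = config or ModelConfig()
        rng = np.random.default_rng(config.seed)
        sizes = [2 * n_genes, *config.hidden_sizes]
        weights = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        out_dim = config.n_heads * n_genes
        bound = np.sqrt(6.0 / (sizes[-1] + out_dim))
        head_w = rng.uniform(-bound, bound, size=(sizes[-1], out_dim))
        head_b = np.zeros(out_dim)
        return cls(
            layer_weights=weights,
            head_weight=head_w,
            head_bias=head_b,
            norm_adj=normalized_adjacency(graph),
            config=config,
            n_genes=n_genes,
        )

    def parameters(self) -> list[np.ndarray]:
        return [*self.layer_weights, self.head_weight, self.head_bias]


def gcn_layer_forward(
    h: np.ndarray,
    norm_adj: sp.spmatrix | np.ndarray,
    w: np.ndarray,
    use_activation: bool = True,
) -> np.ndarray:
    """One graph convolution: sigma(norm_adj @ h @ w), sigma = ReLU."""
    h = np.asarray(h, dtype=np.float64)
    if h.shape[1] != w.shape[0]:
        raise ValueError(f"feature dim {h.shape[1]} does not match W rows {w.shape[0]}")
    if norm_adj.shape[0] != h.shape[0]:
        raise ValueError("adjacency size does not match node count")
    out = np.asarray(norm_adj @ h) @ w
    if use_activation:
        out = np.maximum(out, 0.0)
    return out


@dataclass
class ForwardCache:
    """Intermediates of one forward pass, consumed by the backward pass."""

    x: np.ndarray
    propagated: list[np.ndarray]     # S @ H_in per layer (input to the W matmul)
    pre_acts: list[np.ndarray]       # S H W per layer, before ReLU
    acts: list[np.ndarray]           # after ReLU (and dropout if training)
    dropout_masks: list[Optional[np.ndarray]]
    head_pre: np.ndarray             # before softplus
    rates: "KineticRates"


def _forward(
    state: GcnState,
    x: np.ndarray,
    training: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> ForwardCache:
    cfg = state.config
    h = x
    propagated: list[np.ndarray] = []
    pre_acts: list[np.ndarray] = []
    acts: list[np.ndarray] = []
    masks: list[Optional[np.ndarray]] = []
    for li, w in enumerate(state.layer_weights):
        sh = np.asarray(state.norm_adj @ h)
        propagated.append(sh)
        pre = sh @ w
        pre_acts.append(pre)
        h = np.maximum(pre, 0.0)
        mask = None
        # dropout between hidden layers only, inverted scaling, off at eval
        if training and cfg.dropout > 0 and li < len(state.layer_weights) - 1:
            if rng is None:
                raise ValueError("training forward pass needs an RNG for dropout")
            mask = (rng.random(h.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            h = h * mask
        masks.append(mask)
        acts.append(h)
    head_pre = h @ state.head_weight + state.head_bias
    d = state.n_genes
    blocks = softplus(head_pre)
    beta = blocks[:, :d]
    gamma = blocks[:, d : 2 * d]
    alpha = blocks[:, 2 * d : 3 * d] if cfg.predict_alpha else None
    rates = KineticRates(beta=beta, gamma=gamma, alpha=alpha)
    return ForwardCache(
        x=x, propagated=propagated, pre_acts=pre_acts, acts=acts,
        dropout_masks=masks, head_pre=head_pre, rates=rates,
    )


def model_input(dataset: ExpressionDataset) -> np.ndarray:
    """Node features [spliced || unspliced] on the smoothed layers."""
    s, u = dataset.layers_for_model()
    return np.concatenate([s, u], axis=1)


def forward_rates(
    dataset: ExpressionDataset,
    graph: NeighborGraph,
    state: GcnState,
    config: Optional[ModelConfig] = None,
) -> KineticRates:
    """Evaluate the GCN in inference mode: deterministic, dropout off."""
    if graph.n_cells != dataset.n_cells:
        raise ValueError("graph size does not match dataset")
    if state.norm_adj.shape[0] != dataset.n_cells:
        raise ValueError("model state was built for a different cell count")
    return _forward(state, model_input(dataset), training=False).rates


def compute_velocity(rates: KineticRates, dataset: ExpressionDataset) -> VelocityEstimate:
    """Spliced velocity v = beta * u - gamma * s on the smoothed layers."""
    s, u = dataset.layers_for_model()
    if rates.shape != s.shape:
        raise ValueError(f"rates shape {rates.shape} != data shape {s.shape}")
    return VelocityEstimate(v=rates.beta * u - rates.gamma * s)


def compute_unspliced_velocity(
    rates: KineticRates, dataset: ExpressionDataset, spliced_form: bool = False
) -> np.ndarray:
    """Unspliced velocity du/dt.

    Default is ``alpha - beta * u`` (the transcription equation of the
    splicing ODE); ``spliced_form=True`` selects the alternative
    convention ``alpha - beta * s`` that substitutes the spliced level.
    """
    if rates.alpha is None:
        raise ValueError("model trained without alpha head; enable predict_alpha")
    s, u = dataset.layers_for_model()
    if spliced_form:
        return rates.alpha - rates.beta * s
    return rates.alpha - rates.beta * u
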
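"""Velocity graph, embedding projection and driver-gene ranking.

The velocity graph stores, on each kNN edge (i, j), the cosine similarity
between cell i's velocity and the expression displacement s_j - s_i,
restricted to a confidence-filtered gene subset.  Gaussian normalization
of these weights gives a row-stochastic transition matrix that projects
velocities onto a provided 2-D embedding as arrows.  Driver genes are
ranked per branch by positive Pearson correlation of (smoothed) spliced
expression with pseudotime.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datamodel import ExpressionDataset, NeighborGraph, VelocityEstimate
from .evaluate import ContinuityScores

__all__ = [
    "GeneFilterConfig",
    "VelocityGraph",
    "gene_confidence_filter",
    "velocity_graph",
    "project_velocity",
    "rank_driver_genes",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneFilterConfig:
    """Thresholds of the gene-confidence filter.

    A gene is kept when its gene-wise continuity score and correlation
    score clear the minima and the relative residual of its u-on-s linear
    regression lies strictly inside (residual_lower, residual_upper).
    ``min_cs_gene=None`` uses the dataset median CS-gene.
    """

    min_cs_gene: Optional[float] = None
    min_correlation_score: float = 0.0
    residual_lower: float = 0.0
    residual_upper: float = 0.95

    def __post_init__(self) -> None:
        if self.residual_lower >= self.residual_upper:
            raise ValueError("residual_lower must be < residual_upper")


@dataclass
class VelocityGraph:
    """Sparse cell-to-cell graph of velocity/displacement cosines."""

    weights: sp.csr_matrix              # w_ij on kNN edges, in [-1, 1]
    neighbor_indices: np.ndarray        # N x k
    genes_used: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def transition_matrix(self, sigma: float = 0.05) -> sp.csr_matrix:
        """Row-stochastic pi_ij = exp(w_ij / sigma), normalized per cell."""
        if sigma <= 0:
            raise ValueError("sigma must be > 0")
        n, k = self.neighbor_indices.shape
        w = np.asarray(
            self.weights[np.repeat(np.arange(n), k), self.neighbor_indices.ravel()]
        ).reshape(n, k)
        ex = np.exp(w / sigma)
        pi = ex / ex.sum(axis=1, keepdims=True)
        rows = np.repeat(np.arange(n), k)
        return sp.csr_matrix(
            (pi.ravel(), (rows, self.neighbor_indices.ravel())), shape=(n, n)
        )


def relative_regression_residuals(dataset: ExpressionDataset) -> np.ndarray:
    """Per-gene relative residual of the u-on-s linear fit.

    Ordinary least squares of unspliced on spliced (with intercept) per
    gene; the relative residual is RSS / TSS of the unspliced values about
    their mean.  A perfect linear relation gives 0; a fit no better than
    the mean gives 1.  Genes with constant u are assigned 0 (the line fits
    exactly).
    """
    s, u = dataset.layers_for_model()
    n, d = s.shape
    out = np.zeros(d)
    sc = s - s.mean(axis=0)
    uc = u - u.mean(axis=0)
    ss = np.sum(sc**2, axis=0)
    tss = np.sum(uc**2, axis=0)
    for g in range(d):
        if tss[g] <= 0:
            out[g] = 0.0
            continue
        if ss[g] <= 0:
            out[g] = 1.0  # s constant: the regression explains nothing
            continue
        slope = np.sum(sc[:, g] * uc[:, g]) / ss[g]
        rss = tss[g] - slope**2 * ss[g]
        rel = max(rss / tss[g], 0.0)
        # an exact linear relation leaves only float jitter; report it as 0
        out[g] = rel if rel > 1e-12 else 0.0
    return out


def gene_confidence_filter(
    dataset: ExpressionDataset,
    continuity: ContinuityScores,
    corr_scores: np.ndarray,
    config: Optional[GeneFilterConfig] = None,
) -> np.ndarray:
    """Indices of genes passing all three confidence filters."""
    config = config or GeneFilterConfig()
    cs = continuity.cs_gene
    min_cs = float(np.median(cs)) if config.min_cs_gene is None else config.min_cs_gene
    resid = relative_regression_residuals(dataset)
    keep = (
        (cs >= min_cs)
        & (np.asarray(corr_scores) >= config.min_correlation_score)
        & (resid > config.residual_lower)
        & (resid < config.residual_upper)
    )
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError(
            "no genes pass the confidence filters; relax min_cs_gene / "
            "min_correlation_score or the residual bounds"
        )
    return idx


def velocity_graph(
    dataset: ExpressionDataset,
    velocity: VelocityEstimate,
    graph: NeighborGraph,
    genes_used: Optional[Sequence[int]] = None,
) -> VelocityGraph:
    """Cosine similarity between v_i and s_j - s_i on each kNN edge,
    restricted to ``genes_used`` coordinates (all genes by default)."""
    s, _ = dataset.layers_for_model()
    if genes_used is None:
        genes_used = np.arange(dataset.n_genes)
    genes_used = np.asarray(genes_used, dtype=int)
    if genes_used.size == 0:
        raise ValueError("genes_used must be nonempty")
    sg = s[:, genes_used]
    vg = velocity.v[:, genes_used]
    n, k = graph.indices.shape
    w = np.zeros((n, k))
    v_norm = np.linalg.norm(vg, axis=1)
    chunk = 512
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        diffs = sg[graph.indices[start:stop]] - sg[start:stop, None, :]
        dots = np.einsum("nkd,nd->nk", diffs, vg[start:stop])
        dn = np.linalg.norm(diffs, axis=2)
        denom = v_norm[start:stop, None] * dn
        with np.errstate(divide="ignore", invalid="ignore"):
            cw = np.where(denom > 0, dots / np.maximum(denom, 1e-300), 0.0)
        w[start:stop] = cw
    rows = np.repeat(np.arange(n), k)
    weights = sp.csr_matrix((w.ravel(), (rows, graph.indices.ravel())), shape=(n, n))
    return VelocityGraph(weights=weights, neighbor_indices=graph.indices.copy(), genes_used=genes_used)


def project_velocity(
    vgraph: VelocityGraph,
    embedding: np.ndarray,
    sigma: float = 0.05,
    subtract_baseline: bool = True,
) -> np.ndarray:
    """Project velocities onto a 2-D embedding as per-cell arrows.

    arrow_i = sum_j (pi_ij - 1/k_i) * delta_ij with delta_ij the unit
    vector from i to j in the embedding.  Subtracting the uniform baseline
    1/k_i makes isotropic transition probabilities yield zero arrows
    (disable with ``subtract_baseline=False``).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    embedding = np.asarray(embedding, dtype=np.float64)
    n, k = vgraph.neighbor_indices.shape
    if embedding.shape[0] != n:
        raise ValueError("embedding rows must match cell count")
    # dense per-cell transition rows over the k neighbors
    w = np.asarray(
        vgraph.weights[np.repeat(np.arange(n), k), vgraph.neighbor_indices.ravel()]
    ).reshape(n, k)
    ex = np.exp(w / sigma)
    arrows = np.zeros((n, 2))
    for i in range(n):
        nbrs = vgraph.neighbor_indices[i]
        delta = embedding[nbrs] - embedding[i]
        norms = np.linalg.norm(delta, axis=1)
        ok = norms > 0
        if not ok.any():
            continue
        delta = delta[ok] / norms[ok, None]
        p = ex[i] / ex[i].sum()
        weightings = p[ok] - (1.0 / ok.sum() if subtract_baseline else 0.0)
        arrows[i] = weightings @ delta
    return arrows


def rank_driver_genes(
    dataset: ExpressionDataset,
    pseudotime: Optional[np.ndarray] = None,
    branch_labels: Optional[np.ndarray] = None,
    top_n: int = 100,
) -> pd.DataFrame:
    """Rank genes by positive correlation with pseudotime, per branch.

    Uses the smoothed spliced layer when available.  Genes with
    nonpositive correlation are excluded; the table holds at most
    ``top_n`` rows per branch with columns (branch, gene, correlation,
    rank).
    """
    pt = np.asarray(
        pseudotime if pseudotime is not None else dataset.pseudotime, dtype=np.float64
    )
    if pt is None or pt.ndim == 0:
        raise ValueError("pseudotime is required")
    s, _ = dataset.layers_for_model()
    if branch_labels is None:
        branch_labels = np.array(["all"] * dataset.n_cells)
    branch_labels = np.asarray(branch_labels)
    frames = []
    for branch in np.unique(branch_labels):
        cells = np.flatnonzero(branch_labels == branch)
        finite = cells[np.isfinite(pt[cells])]
        if finite.size < 3:
            raise ValueError(
                f"branch {branch!r} has fewer than 3 cells with finite pseudotime"
            )
        sb = s[finite]
        tb = pt[finite]
        tc = tb - tb.mean()
        st = np.sqrt(np.sum(tc**2))
        xc = sb - sb.mean(axis=0)
        sx = np.sqrt(np.sum(xc**2, axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.where(sx > 0, (xc.T @ tc) / np.maximum(sx * st, 1e-300), 0.0)
        pos = np.flatnonzero(corr > 0)
        if pos.size == 0:
            logger.warning("rank_driver_genes: no positively correlated genes in branch %r", branch)
            continue
        order = pos[np.lexsort((pos, -corr[pos]))][:top_n]
        frames.append(
            pd.DataFrame(
                {
                    "branch": branch,
                    "gene": [dataset.gene_names[g] for g in order],
                    "correlation": corr[order],
                    "rank": np.arange(1, len(order) + 1),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["branch", "gene", "correlation", "rank"])
    return pd.concat(frames, ignore_index=True)
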
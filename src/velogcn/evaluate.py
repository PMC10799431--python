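"""Evaluation metrics for velocity fields.

Four families of metrics:

* consistency — mean cosine similarity of a cell's velocity to its
  neighbors' (overall) or to all same-type cells' velocities (cell-type);
* continuity — relative extrapolation error per cell and gene, summarized
  as 1 - mean tanh(error) per cell (CS-cell) or per gene (CS-gene);
* correlation — per-gene corr(v, u) + corr(v, -s) across cells;
* direction — cosine alignment of velocities with displacement across
  annotated cell-type boundaries (A -> B), averaged over the union of
  boundary cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .datamodel import ExpressionDataset, NeighborGraph, VelocityEstimate
from .objective import TargetDistribution, _pearson_terms, _weighted_target_expression

__all__ = [
    "ConsistencyScores",
    "ContinuityScores",
    "DirectionScoreResult",
    "overall_consistency",
    "celltype_consistency",
    "continuity_error",
    "cs_cell",
    "cs_gene",
    "continuity_scores",
    "correlation_score",
    "boundary_cells",
    "direction_score",
]

EPS_FLOOR = 1e-3  # denominator floor for the relative continuity error


@dataclass
class ConsistencyScores:
    """Per-cell consistency values in [-1, 1]; NaN marks cells whose score
    is undefined (zero velocity everywhere in the comparison set)."""

    overall: Optional[np.ndarray] = None
    celltype: Optional[np.ndarray] = None


@dataclass
class ContinuityScores:
    """Relative extrapolation errors and their tanh-compressed summaries."""

    eps: np.ndarray          # N x D, >= 0
    cs_cell: np.ndarray      # length N, (0, 1]
    cs_gene: np.ndarray      # length D, (0, 1]


@dataclass
class DirectionScoreResult:
    """Direction scores across annotated cell-type transitions."""

    boundary_sets: dict      # (A, B) -> integer index array
    per_cell: dict           # cell index -> score (mean over pairs touching it)
    global_score: float


def _cosine_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cosine similarity; rows with a zero vector give NaN."""
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sum(a * b, axis=-1) / (na * nb)
    out[(na == 0) | (nb == 0)] = np.nan
    return out


def overall_consistency(velocity: VelocityEstimate, graph: NeighborGraph) -> np.ndarray:
    """Mean cosine similarity of each cell's velocity to its neighbors'.

    Zero-velocity terms are skipped (denominator reduced); a cell whose own
    velocity is zero, or whose neighbor terms are all skipped, scores NaN.
    """
    v = velocity.v
    n = v.shape[0]
    scores = np.full(n, np.nan)
    norms = np.linalg.norm(v, axis=1)
    for i in range(n):
        if norms[i] == 0:
            continue
        nbrs = graph.indices[i]
        cos = _cosine_rows(np.broadcast_to(v[i], (len(nbrs), v.shape[1])), v[nbrs])
        cos = cos[~np.isnan(cos)]
        if cos.size:
            scores[i] = cos.mean()
    return scores


def celltype_consistency(velocity: VelocityEstimate, cell_type: np.ndarray) -> np.ndarray:
    """Mean cosine of each cell's velocity to all same-type velocities,
    including the cell's own (self term)."""
    if cell_type is None:
        raise ValueError("cell_type labels are required")
    cell_type = np.asarray(cell_type)
    v = velocity.v
    n = v.shape[0]
    scores = np.full(n, np.nan)
    norms = np.linalg.norm(v, axis=1)
    for label in np.unique(cell_type):
        members = np.flatnonzero(cell_type == label)
        vm = v[members]
        for i in members:
            if norms[i] == 0:
                continue
            cos = _cosine_rows(np.broadcast_to(v[i], vm.shape), vm)
            cos = cos[~np.isnan(cos)]
            if cos.size:
                scores[i] = cos.mean()
    return scores


def continuity_error(
    dataset: ExpressionDataset,
    velocity: VelocityEstimate,
    targets: TargetDistribution,
    eps_floor: float = EPS_FLOOR,
) -> np.ndarray:
    """Relative absolute extrapolation error per cell and gene.

    eps[i, g] = |s + v - E[target s]| / max(s, eps_floor); the floor keeps
    the score finite where the spliced expression is zero.  Cells without
    any forward candidate (Z = 0) get eps = 0 (no evidence of violation).
    """
    s, _ = dataset.layers_for_model()
    t_expr = _weighted_target_expression(s, targets, "forward")
    eps = np.abs(s + velocity.v - t_expr) / np.maximum(s, eps_floor)
    eps[targets.z("forward") == 0] = 0.0
    return eps


def cs_cell(eps: np.ndarray) -> np.ndarray:
    """Cell-wise continuity score: 1 - mean over genes of tanh(eps)."""
    return 1.0 - np.tanh(eps).mean(axis=1)


def cs_gene(eps: np.ndarray) -> np.ndarray:
    """Gene-wise continuity score: 1 - mean over cells of tanh(eps)."""
    return 1.0 - np.tanh(eps).mean(axis=0)


def continuity_scores(
    dataset: ExpressionDataset,
    velocity: VelocityEstimate,
    targets: TargetDistribution,
    eps_floor: float = EPS_FLOOR,
) -> ContinuityScores:
    eps = continuity_error(dataset, velocity, targets, eps_floor)
    return ContinuityScores(eps=eps, cs_cell=cs_cell(eps), cs_gene=cs_gene(eps))


def correlation_score(velocity: VelocityEstimate, dataset: ExpressionDataset) -> np.ndarray:
    """Per-gene score corr(v, u) + corr(v, -s) across cells; zero-variance
    genes contribute 0 to the corresponding term."""
    s, u = dataset.layers_for_model()
    if s.shape[0] < 2:
        raise ValueError("correlation_score requires at least 2 cells")
    corr_u, _, _, _ = _pearson_terms(velocity.v, u)
    corr_s, _, _, _ = _pearson_terms(velocity.v, -s)
    return corr_u + corr_s


def boundary_cells(
    dataset: ExpressionDataset,
    graph: NeighborGraph,
    pair: tuple[str, str],
    cell_type: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Cells of type A having at least one neighbor of type B."""
    labels = np.asarray(cell_type if cell_type is not None else dataset.cell_type)
    if labels is None or labels.ndim == 0:
        raise ValueError("cell_type labels are required")
    type_a, type_b = pair
    for t in pair:
        if t not in labels:
            raise ValueError(f"unknown cell type {t!r}")
    in_a = np.flatnonzero(labels == type_a)
    b_mask = labels == type_b
    has_b = b_mask[graph.indices[in_a]].any(axis=1)
    return in_a[has_b]


def direction_score(
    dataset: ExpressionDataset,
    velocity: VelocityEstimate,
    graph: NeighborGraph,
    pairs: Sequence[tuple[str, str]],
    velocity_of: str = "neighbor",
    cell_type: Optional[np.ndarray] = None,
) -> DirectionScoreResult:
    """Alignment of velocities with annotated A -> B transitions.

    For each boundary cell i (type A with >= 1 type-B neighbor), the score
    averages the cosine between the velocity and the displacement s_j - s_i
    over the B-neighbors j.  ``velocity_of="neighbor"`` (default) uses the
    neighbor's velocity v_j; ``"cell"`` uses v_i (the conventional
    cross-boundary direction form).  The global score is the unweighted
    mean over the union of boundary cells across all pairs, not a mean of
    per-pair means; a cell that is a boundary cell for several pairs
    contributes the mean of its per-pair scores once.
    """
    if velocity_of not in ("neighbor", "cell"):
        raise ValueError("velocity_of must be 'neighbor' or 'cell'")
    labels = np.asarray(cell_type if cell_type is not None else dataset.cell_type)
    s, _ = dataset.layers_for_model()
    v = velocity.v
    boundary_sets: dict = {}
    per_cell_lists: dict[int, list[float]] = {}
    for pair in pairs:
        cells = boundary_cells(dataset, graph, pair, cell_type=labels)
        boundary_sets[tuple(pair)] = cells
        b_mask = labels == pair[1]
        for i in cells:
            nbrs = graph.indices[i]
            b_nbrs = nbrs[b_mask[nbrs]]
            diffs = s[b_nbrs] - s[i]
            vel = v[b_nbrs] if velocity_of == "neighbor" else np.broadcast_to(v[i], diffs.shape)
            cos = _cosine_rows(vel, diffs)
            cos = cos[~np.isnan(cos)]
            if cos.size:
                per_cell_lists.setdefault(int(i), []).append(float(cos.mean()))
    if not per_cell_lists:
        raise ValueError("no boundary cells for given pairs")
    per_cell = {i: float(np.mean(vals)) for i, vals in per_cell_lists.items()}
    global_score = float(np.mean(list(per_cell.values())))
    return DirectionScoreResult(
        boundary_sets=boundary_sets, per_cell=per_cell, global_score=global_score
    )
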
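"""Preprocessing chain: library-size normalization, highly variable gene
selection, PCA, kNN graph construction and neighbor smoothing.

The pipeline order is fixed: drop zero-total cells -> normalize -> HVG (on
spliced) -> log1p for PCA only -> PCA -> kNN -> smoothing of the normalized
(non-log) layers.  Every step is deterministic: PCA uses a fixed sign
convention and kNN ties break toward the lower cell index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp

from .datamodel import ExpressionDataset, NeighborGraph

__all__ = [
    "PreprocessConfig",
    "normalize_counts",
    "select_highly_variable_genes",
    "compute_pca",
    "build_knn_graph",
    "smooth_by_neighbors",
    "preprocess",
]

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Knobs of the preprocessing chain.

    ``normalize_target="median"`` scales every cell's spliced total to the
    median spliced library size; the same per-cell factor is applied to the
    unspliced layer so u/s ratios are preserved.  ``normalize_target="none"``
    skips library-size scaling (appropriate for simulated concentrations,
    which carry no count-depth variation); zero-total cells are still
    dropped.
    """

    n_top_genes: int = 2000
    n_pcs: int = 30
    k_neighbors: int = 30
    normalize_target: str = "median"
    log_for_pca: bool = True

    def __post_init__(self) -> None:
        for name in ("n_top_genes", "n_pcs", "k_neighbors"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")


def normalize_counts(
    dataset: ExpressionDataset, config: PreprocessConfig | None = None
) -> ExpressionDataset:
    """Scale each cell so its spliced total equals the target library size.

    Cells with a zero spliced total are excluded (logged).  Raw layers are
    preserved on the returned dataset.
    """
    config = config or PreprocessConfig()
    totals = dataset.spliced.sum(axis=1)
    keep = totals > 0
    if not np.all(keep):
        dropped = int((~keep).sum())
        logger.warning("normalize_counts: dropping %d cells with zero spliced total", dropped)
        dataset = dataset.subset_cells(keep)
        totals = totals[keep]
    if config.normalize_target == "none":
        return replace(
            dataset,
            raw_spliced=dataset.raw_spliced if dataset.raw_spliced is not None else dataset.spliced.copy(),
            raw_unspliced=dataset.raw_unspliced if dataset.raw_unspliced is not None else dataset.unspliced.copy(),
        )
    if config.normalize_target == "median":
        target = float(np.median(totals))
    else:
        target = float(config.normalize_target)
    factors = target / totals
    return replace(
        dataset,
        spliced=dataset.spliced * factors[:, None],
        unspliced=dataset.unspliced * factors[:, None],
        raw_spliced=dataset.raw_spliced if dataset.raw_spliced is not None else dataset.spliced.copy(),
        raw_unspliced=dataset.raw_unspliced if dataset.raw_unspliced is not None else dataset.unspliced.copy(),
    )


def _dispersion_scores(spliced: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Binned-dispersion HVG statistic on log1p spliced counts.

    Dispersion = var/mean per gene, z-scored within 20 equal-frequency mean
    bins.  Genes with zero mean or zero variance score -inf.
    """
    x = np.log1p(spliced)
    mean = x.mean(axis=0)
    var = x.var(axis=0)
    d = x.shape[1]
    scores = np.full(d, -np.inf)
    # tolerance absorbs float jitter in the variance of constant genes
    ok = (mean > 1e-12) & (var > 1e-12)
    if not np.any(ok):
        return scores
    disp = np.zeros(d)
    disp[ok] = var[ok] / mean[ok]
    n_bins = min(n_bins, max(1, int(ok.sum())))
    # equal-frequency bins over the means of usable genes
    quantiles = np.quantile(mean[ok], np.linspace(0, 1, n_bins + 1))
    bin_idx = np.clip(np.searchsorted(quantiles, mean, side="right") - 1, 0, n_bins - 1)
    for b in range(n_bins):
        members = ok & (bin_idx == b)
        if not np.any(members):
            continue
        mu = disp[members].mean()
        sd = disp[members].std()
        if sd < 1e-12:
            scores[members] = 0.0
        else:
            scores[members] = (disp[members] - mu) / sd
    return scores


def select_highly_variable_genes(dataset: ExpressionDataset, n_top: int) -> ExpressionDataset:
    """Keep the ``n_top`` genes with the highest binned dispersion of log1p
    spliced expression; both layers are subset identically.  Ties keep the
    lower gene index first; the original gene order is preserved."""
    d = dataset.n_genes
    if n_top >= d:
        if n_top > d:
            logger.warning(
                "select_highly_variable_genes: n_top=%d > %d genes; keeping all", n_top, d
            )
        return dataset
    scores = _dispersion_scores(dataset.spliced)
    order = np.lexsort((np.arange(d), -scores))  # score desc, index asc on ties
    chosen = np.sort(order[:n_top])
    return dataset.subset_genes(chosen)


def compute_pca(dataset: ExpressionDataset, n_pcs: int, log: bool = True) -> ExpressionDataset:
    """Attach PCA scores of the (optionally log1p) centered spliced matrix.

    Deterministic sign convention: within each component, the loading with
    the largest absolute value is made positive.
    """
    x = np.log1p(dataset.spliced) if log else dataset.spliced.copy()
    n, d = x.shape
    max_pcs = min(n, d)
    if n_pcs > max_pcs:
        logger.warning("compute_pca: n_pcs=%d reduced to %d", n_pcs, max_pcs)
        n_pcs = max_pcs
    x = x - x.mean(axis=0)
    u, sv, vt = np.linalg.svd(x, full_matrices=False)
    u, sv, vt = u[:, :n_pcs], sv[:n_pcs], vt[:n_pcs]
    # sign convention on loadings
    signs = np.ones(n_pcs)
    for c in range(n_pcs):
        j = np.argmax(np.abs(vt[c]))
        if vt[c, j] < 0:
            signs[c] = -1.0
    scores = u * sv[None, :] * signs[None, :]
    return replace(dataset, pca=scores)


def build_knn_graph(dataset: ExpressionDataset, k: int) -> NeighborGraph:
    """k nearest other cells by Euclidean distance in PC space.

    Falls back to log1p spliced coordinates if PCA is absent.  Ties are
    broken toward the lower cell index; self is always excluded.
    """
    n = dataset.n_cells
    if k >= n:
        raise ValueError(f"k must be < number of cells (k={k}, N={n})")
    if dataset.pca is not None:
        coords = dataset.pca
    else:
        logger.warning("build_knn_graph: PCA absent; using log1p spliced coordinates")
        coords = np.log1p(dataset.spliced)
    if k == 0:
        return NeighborGraph(
            indices=np.zeros((n, 0), dtype=np.int64),
            distances=np.zeros((n, 0)),
            k=0,
        )
    # brute force keeps the tie-break exact; N here is at most a few thousand
    sq = np.sum(coords**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * coords @ coords.T
    np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, np.inf)
    idx_base = np.arange(n)
    indices = np.empty((n, k), dtype=np.int64)
    distances = np.empty((n, k))
    for i in range(n):
        order = np.lexsort((idx_base, d2[i]))[:k]
        indices[i] = order
        distances[i] = np.sqrt(d2[i, order])
    return NeighborGraph(indices=indices, distances=distances, k=k)


def smoothing_operator(graph: NeighborGraph) -> sp.csr_matrix:
    """Row-stochastic matrix M averaging each cell with its k neighbors."""
    n, k = graph.indices.shape
    rows = np.repeat(np.arange(n), k + 1)
    cols = np.concatenate([np.arange(n)[:, None], graph.indices], axis=1).ravel()
    vals = np.full(rows.size, 1.0 / (k + 1))
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def smooth_by_neighbors(dataset: ExpressionDataset, graph: NeighborGraph) -> ExpressionDataset:
    """Replace each layer value by the mean over {cell plus its k neighbors};
    smoothed layers are stored separately from the normalized layers."""
    if graph.n_cells != dataset.n_cells:
        raise ValueError("graph size does not match dataset")
    m = smoothing_operator(graph)
    return replace(
        dataset,
        spliced_smooth=np.asarray(m @ dataset.spliced),
        unspliced_smooth=np.asarray(m @ dataset.unspliced),
    )


def preprocess(
    dataset: ExpressionDataset, config: PreprocessConfig | None = None
) -> tuple[ExpressionDataset, NeighborGraph]:
    """Full chain: normalize -> HVG -> PCA -> kNN -> smoothing."""
    config = config or PreprocessConfig()
    ds = normalize_counts(dataset, config)
    ds = select_highly_variable_genes(ds, config.n_top_genes)
    ds = compute_pca(ds, config.n_pcs, log=config.log_for_pca)
    graph = build_knn_graph(ds, min(config.k_neighbors, ds.n_cells - 1))
    ds = smooth_by_neighbors(ds, graph)
    return ds, graph
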
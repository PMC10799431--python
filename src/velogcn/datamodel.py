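"""Core in-memory containers for spliced/unspliced expression data.

The central object is :class:`ExpressionDataset`, a cells x genes container
holding a spliced and an unspliced count layer plus the optional annotations
(cell types, a 2-D embedding, pseudotime) consumed by the velocity model and
its evaluation metrics.  Matrices are dense ``float64`` numpy arrays in
cells x genes orientation with 0-based indexing throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ExpressionDataset",
    "NeighborGraph",
    "KineticRates",
    "VelocityEstimate",
]


def _as_dense_float(x) -> np.ndarray:
    if sp.issparse(x):
        x = x.toarray()
    return np.asarray(x, dtype=np.float64)


@dataclass
class ExpressionDataset:
    """Spliced/unspliced expression of N cells over D genes.

    ``spliced`` and ``unspliced`` hold the working (possibly normalized)
    layers; ``raw_spliced``/``raw_unspliced`` preserve the pre-normalization
    counts and ``spliced_smooth``/``unspliced_smooth`` the neighbor-averaged
    layers produced by preprocessing.
    """

    spliced: np.ndarray
    unspliced: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    cell_type: Optional[np.ndarray] = None
    embedding: Optional[np.ndarray] = None
    pseudotime: Optional[np.ndarray] = None
    pca: Optional[np.ndarray] = None
    raw_spliced: Optional[np.ndarray] = None
    raw_unspliced: Optional[np.ndarray] = None
    spliced_smooth: Optional[np.ndarray] = None
    unspliced_smooth: Optional[np.ndarray] = None
    uns: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spliced = _as_dense_float(self.spliced)
        self.unspliced = _as_dense_float(self.unspliced)
        if self.spliced.shape != self.unspliced.shape:
            raise ValueError(
                f"spliced shape {self.spliced.shape} != unspliced shape "
                f"{self.unspliced.shape}"
            )
        if self.spliced.min(initial=0.0) < 0 or self.unspliced.min(initial=0.0) < 0:
            raise ValueError("expression layers must be nonnegative")
        n, d = self.spliced.shape
        if len(self.gene_names) != d:
            raise ValueError(f"{len(self.gene_names)} gene names for {d} genes")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} cells")
        if len(set(self.gene_names)) != d:
            raise ValueError("gene_names must be unique")
        if self.cell_type is not None:
            self.cell_type = np.asarray(self.cell_type)
            if self.cell_type.shape[0] != n:
                raise ValueError("cell_type length mismatch")
        if self.embedding is not None:
            self.embedding = np.asarray(self.embedding, dtype=np.float64)
            if self.embedding.shape != (n, 2):
                raise ValueError("embedding must be N x 2")
        if self.pseudotime is not None:
            self.pseudotime = np.asarray(self.pseudotime, dtype=np.float64)
            if self.pseudotime.shape[0] != n:
                raise ValueError("pseudotime length mismatch")

    @property
    def n_cells(self) -> int:
        return self.spliced.shape[0]

    @property
    def n_genes(self) -> int:
        return self.spliced.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.spliced.shape

    def layers_for_model(self) -> tuple[np.ndarray, np.ndarray]:
        """Smoothed layers if present, else the working layers."""
        s = self.spliced_smooth if self.spliced_smooth is not None else self.spliced
        u = self.unspliced_smooth if self.unspliced_smooth is not None else self.unspliced
        return s, u

    def subset_cells(self, mask_or_idx) -> "ExpressionDataset":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)

        def take(arr):
            return None if arr is None else arr[idx]

        return replace(
            self,
            spliced=self.spliced[idx],
            unspliced=self.unspliced[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            cell_type=take(self.cell_type),
            embedding=take(self.embedding),
            pseudotime=take(self.pseudotime),
            pca=take(self.pca),
            raw_spliced=take(self.raw_spliced),
            raw_unspliced=take(self.raw_unspliced),
            spliced_smooth=take(self.spliced_smooth),
            unspliced_smooth=take(self.unspliced_smooth),
        )

    def subset_genes(self, idx: Sequence[int]) -> "ExpressionDataset":
        idx = np.asarray(idx, dtype=int)

        def take(arr):
            return None if arr is None else arr[:, idx]

        return replace(
            self,
            spliced=self.spliced[:, idx],
            unspliced=self.unspliced[:, idx],
            gene_names=[self.gene_names[i] for i in idx],
            raw_spliced=take(self.raw_spliced),
            raw_unspliced=take(self.raw_unspliced),
            spliced_smooth=take(self.spliced_smooth),
            unspliced_smooth=take(self.unspliced_smooth),
        )


@dataclass
class NeighborGraph:
    """k-nearest-neighbor graph over cells.

    ``indices[i]`` lists the k nearest other cells of cell i (self excluded)
    with ``distances[i]`` nondecreasing; ties are broken toward the lower
    cell index.
    """

    indices: np.ndarray
    distances: np.ndarray
    k: int
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.distances = np.asarray(self.distances, dtype=np.float64)
        if self.indices.shape != self.distances.shape:
            raise ValueError("indices/distances shape mismatch")
        n = self.indices.shape[0]
        if self.indices.size:
            if self.indices.min() < 0 or self.indices.max() >= n:
                raise ValueError("neighbor indices out of range")
            rows = np.arange(n)[:, None]
            if np.any(self.indices == rows):
                raise ValueError("self-neighbors are not allowed")

    @property
    def n_cells(self) -> int:
        return self.indices.shape[0]

    def symmetric_adjacency(self) -> sp.csr_matrix:
        """Undirected 0/1 adjacency: an edge is kept if present either way."""
        n, k = self.indices.shape
        if k == 0:
            return sp.csr_matrix((n, n))
        rows = np.repeat(np.arange(n), k)
        cols = self.indices.ravel()
        a = sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
        a = a.maximum(a.T)
        a.data[:] = 1.0
        return a


@dataclass
class KineticRates:
    """Per-cell, per-gene splicing kinetics: transcription alpha, splicing
    beta, degradation gamma.  All entries nonnegative, shapes N x D."""

    beta: np.ndarray
    gamma: np.ndarray
    alpha: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=np.float64)
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        if self.beta.shape != self.gamma.shape:
            raise ValueError("beta/gamma shape mismatch")
        if self.alpha is not None:
            self.alpha = np.asarray(self.alpha, dtype=np.float64)
            if self.alpha.shape != self.beta.shape:
                raise ValueError("alpha shape mismatch")
        for name in ("alpha", "beta", "gamma"):
            arr = getattr(self, name)
            if arr is not None and np.any(arr < 0):
                raise ValueError(f"{name} must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.beta.shape


@dataclass
class VelocityEstimate:
    """Estimated time derivatives: ``v`` for spliced mRNA (beta*u - gamma*s),
    optionally ``v_uns`` for unspliced mRNA."""

    v: np.ndarray
    v_uns: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=np.float64)
        if not np.all(np.isfinite(self.v)):
            raise ValueError("velocity must be finite")
        if self.v_uns is not None:
            self.v_uns = np.asarray(self.v_uns, dtype=np.float64)
            if self.v_uns.shape != self.v.shape:
                raise ValueError("v_uns shape mismatch")
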
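"""Readers and writers for the standard single-cell container formats.

H5AD is the native round-trip format (via :mod:`anndata`); loom files are
read directly through h5py (a loom file is plain HDF5 with ``/layers``,
``/row_attrs`` and ``/col_attrs`` groups); MTX directories hold one
MatrixMarket file per layer plus ``genes.tsv`` / ``barcodes.tsv`` sidecars.
"""

from __future__ import annotations

import os
from typing import Optional

import anndata as ad
import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datamodel import ExpressionDataset, KineticRates, VelocityEstimate

__all__ = ["load_dataset", "save_results", "from_anndata", "to_anndata"]

_EMBED_KEYS = ("X_umap", "X_tsne", "X_embedding")


def _dense(x) -> np.ndarray:
    if sp.issparse(x):
        x = x.toarray()
    return np.asarray(x, dtype=np.float64)


def from_anndata(
    adata: ad.AnnData, layer_names: tuple[str, str] = ("spliced", "unspliced")
) -> ExpressionDataset:
    s_name, u_name = layer_names
    for name in (s_name, u_name):
        if name not in adata.layers:
            raise KeyError(
                f"layer {name!r} not found; available layers: "
                f"{sorted(adata.layers.keys())}"
            )
    embedding = None
    for key in _EMBED_KEYS:
        if key in adata.obsm:
            embedding = np.asarray(adata.obsm[key], dtype=np.float64)[:, :2]
            break
    cell_type = (
        np.asarray(adata.obs["cell_type"]) if "cell_type" in adata.obs else None
    )
    pseudotime = (
        np.asarray(adata.obs["pseudotime"], dtype=np.float64)
        if "pseudotime" in adata.obs
        else None
    )
    pca = np.asarray(adata.obsm["X_pca"], dtype=np.float64) if "X_pca" in adata.obsm else None
    ds = ExpressionDataset(
        spliced=_dense(adata.layers[s_name]),
        unspliced=_dense(adata.layers[u_name]),
        gene_names=list(map(str, adata.var_names)),
        cell_ids=list(map(str, adata.obs_names)),
        cell_type=cell_type,
        embedding=embedding,
        pseudotime=pseudotime,
        pca=pca,
    )
    for extra in ("raw_spliced", "raw_unspliced", "spliced_smooth", "unspliced_smooth"):
        if extra in adata.layers:
            setattr(ds, extra, _dense(adata.layers[extra]))
    if "true_velocity" in adata.layers:
        ds.uns["true_velocity"] = _dense(adata.layers["true_velocity"])
    for key in ("true_pseudotime", "lineage"):
        if key in adata.obs:
            ds.uns[key] = np.asarray(adata.obs[key])
    return ds


def to_anndata(
    dataset: ExpressionDataset,
    rates: Optional[KineticRates] = None,
    velocity: Optional[VelocityEstimate] = None,
) -> ad.AnnData:
    adata = ad.AnnData(
        X=dataset.spliced.copy(),
        obs=pd.DataFrame(index=pd.Index(dataset.cell_ids, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(dataset.gene_names, name="gene")),
    )
    adata.layers["spliced"] = dataset.spliced.copy()
    adata.layers["unspliced"] = dataset.unspliced.copy()
    for extra in ("raw_spliced", "raw_unspliced", "spliced_smooth", "unspliced_smooth"):
        arr = getattr(dataset, extra)
        if arr is not None:
            adata.layers[extra] = arr.copy()
    if dataset.cell_type is not None:
        adata.obs["cell_type"] = pd.Categorical(dataset.cell_type)
    if dataset.pseudotime is not None:
        adata.obs["pseudotime"] = dataset.pseudotime
    if dataset.embedding is not None:
        adata.obsm["X_umap"] = dataset.embedding.copy()
    if dataset.pca is not None:
        adata.obsm["X_pca"] = dataset.pca.copy()
    if "true_velocity" in dataset.uns:
        adata.layers["true_velocity"] = np.asarray(dataset.uns["true_velocity"])
    if "true_pseudotime" in dataset.uns:
        adata.obs["true_pseudotime"] = np.asarray(dataset.uns["true_pseudotime"])
    if "lineage" in dataset.uns:
        adata.obs["lineage"] = pd.Categorical(np.asarray(dataset.uns["lineage"]))
    if rates is not None:
        n, d = dataset.shape
        if rates.shape != (n, d):
            raise ValueError(f"rates shape {rates.shape} != dataset shape {(n, d)}")
        adata.layers["beta"] = rates.beta.copy()
        adata.layers["gamma"] = rates.gamma.copy()
        if rates.alpha is not None:
            adata.layers["alpha"] = rates.alpha.copy()
    if velocity is not None:
        if velocity.v.shape != dataset.shape:
            raise ValueError(
                f"velocity shape {velocity.v.shape} != dataset shape {dataset.shape}"
            )
        adata.layers["velocity"] = velocity.v.copy()
        if velocity.v_uns is not None:
            adata.layers["velocity_unspliced"] = velocity.v_uns.copy()
    return adata


def _load_loom(path: str, layer_names: tuple[str, str]) -> ExpressionDataset:
    s_name, u_name = layer_names
    with h5py.File(path, "r") as f:
        layers = {}
        if "matrix" in f:
            layers["matrix"] = f["matrix"]
        if "layers" in f:
            for key in f["layers"]:
                layers[key] = f["layers"][key]
        for name in (s_name, u_name):
            if name not in layers:
                raise KeyError(
                    f"layer {name!r} not found in loom file; available layers: "
                    f"{sorted(layers.keys())}"
                )
        # loom stores genes x cells; transpose to cells x genes
        spliced = np.asarray(layers[s_name], dtype=np.float64).T
        unspliced = np.asarray(layers[u_name], dtype=np.float64).T

        def attr(group, *names):
            for nm in names:
                if nm in f.get(group, {}):
                    vals = np.asarray(f[group][nm])
                    if vals.dtype.kind in ("S", "O"):
                        vals = np.array([v.decode() if isinstance(v, bytes) else str(v) for v in vals])
                    return vals
            return None

        genes = attr("row_attrs", "Gene", "gene_names", "var_names")
        cells = attr("col_attrs", "CellID", "obs_names", "barcodes")
    n, d = spliced.shape
    gene_names = list(genes) if genes is not None else [f"gene_{i}" for i in range(d)]
    cell_ids = list(cells) if cells is not None else [f"cell_{i}" for i in range(n)]
    return ExpressionDataset(spliced, unspliced, gene_names, cell_ids)


def _load_mtx_dir(path: str, layer_names: tuple[str, str]) -> ExpressionDataset:
    s_name, u_name = layer_names
    mats = {}
    for name in (s_name, u_name):
        mtx_path = os.path.join(path, f"{name}.mtx")
        if not os.path.exists(mtx_path):
            available = sorted(
                fn[:-4] for fn in os.listdir(path) if fn.endswith(".mtx")
            )
            raise FileNotFoundError(
                f"{name} layer missing: no {name}.mtx in {path}; "
                f"available layers: {available}"
            )
        mats[name] = _dense(scipy.io.mmread(mtx_path))
    genes_path = os.path.join(path, "genes.tsv")
    barcodes_path = os.path.join(path, "barcodes.tsv")
    n, d = mats[s_name].shape
    if os.path.exists(genes_path):
        gene_names = list(pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str))
    else:
        gene_names = [f"gene_{i}" for i in range(d)]
    if os.path.exists(barcodes_path):
        cell_ids = list(pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str))
    else:
        cell_ids = [f"cell_{i}" for i in range(n)]
    return ExpressionDataset(mats[s_name], mats[u_name], gene_names, cell_ids)


def load_dataset(
    path: str,
    format: Optional[str] = None,
    layer_names: tuple[str, str] = ("spliced", "unspliced"),
) -> ExpressionDataset:
    """Load an :class:`ExpressionDataset` from H5AD, loom, or an MTX directory.

    Parameters
    ----------
    path
        File (h5ad/loom) or directory (mtx_dir) path.
    format
        One of ``"h5ad"``, ``"loom"``, ``"mtx_dir"``; inferred from the path
        when omitted.
    layer_names
        Names of the (spliced, unspliced) layers in the source file.
    """
    if format is None:
        if os.path.isdir(path):
            format = "mtx_dir"
        elif path.endswith(".loom"):
            format = "loom"
        else:
            format = "h5ad"
    if format == "h5ad":
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        return from_anndata(ad.read_h5ad(path), layer_names)
    if format == "loom":
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        return _load_loom(path, layer_names)
    if format == "mtx_dir":
        if not os.path.isdir(path):
            raise FileNotFoundError(path)
        return _load_mtx_dir(path, layer_names)
    raise ValueError(f"unknown format {format!r}")


def save_results(
    dataset: ExpressionDataset,
    rates: Optional[KineticRates],
    velocity: Optional[VelocityEstimate],
    path: str,
) -> None:
    """Write dataset + estimated rates and velocities to an H5AD file.

    Float64 payloads round-trip bit-identically through
    ``save_results`` / ``load_dataset``.
    """
    adata = to_anndata(dataset, rates=rates, velocity=velocity)
    try:
        adata.write_h5ad(path)
    except OSError as exc:
        raise OSError(f"cannot write results to {path!r}: {exc}") from exc
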
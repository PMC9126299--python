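"""Single-cell QC filters and pseudo-bulk collapse.

Filter order follows standard droplet-pipeline practice: per-cell filters
(detected features >= 500, mitochondrial fraction strictly < 10%), then the
cluster-size filter (labels with fewer than 30 surviving cells are
dropped), then the per-sample collapse.  "Features" are genes with count
>= 1 in the cell.  Genes are never dropped at collapse — zero rows are
retained so bulk and pseudo-bulk tables share one gene universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import DataError
from .io_formats import CountTable

logger = logging.getLogger("scdropout.qc")

__all__ = [
    "CellQCParams",
    "QCReport",
    "mito_fraction",
    "filter_cells",
    "filter_clusters",
    "collapse_pseudobulk",
    "run_qc",
]


@dataclass
class CellQCParams:
    """Study-standard QC thresholds."""

    min_features: int = 500
    min_cluster_size: int = 30
    max_mito_fraction: float = 0.10


@dataclass
class QCReport:
    """Removed-cell bookkeeping per filter reason."""

    n_input: int = 0
    removed_low_features: int = 0
    removed_high_mito: int = 0
    removed_small_cluster: int = 0
    n_retained: int = 0
    dropped_clusters: list = field(default_factory=list)

    def to_record(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed_low_features": self.removed_low_features,
            "removed_high_mito": self.removed_high_mito,
            "removed_small_cluster": self.removed_small_cluster,
            "dropped_clusters": list(self.dropped_clusters),
            "n_retained": self.n_retained,
        }


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def mito_fraction(cell_counts: np.ndarray, mito_mask: np.ndarray) -> float:
    """Share of a cell's counts on mitochondrial genes."""
    cell_counts = np.asarray(cell_counts, dtype=float).ravel()
    total = cell_counts.sum()
    if total <= 0:
        raise DataError("all-zero cell has no defined mito fraction")
    mask = np.asarray(mito_mask, dtype=bool)
    return float(cell_counts[mask].sum() / total)


def filter_cells(adata: ad.AnnData, params: CellQCParams,
                 mito_mask: np.ndarray | None = None
                 ) -> tuple[ad.AnnData, QCReport]:
    """Keep cells with >= min_features detected genes and mito fraction
    strictly below max_mito_fraction."""
    if adata.n_obs == 0:
        raise DataError("empty cell matrix")
    if mito_mask is None:
        mito_mask = adata.var["is_mito"].to_numpy() if "is_mito" in adata.var \
            else np.zeros(adata.n_vars, dtype=bool)
    X = _dense(adata.X)
    n_features = (X >= 1).sum(axis=1)
    totals = X.sum(axis=1).astype(float)
    mito = X[:, np.asarray(mito_mask, dtype=bool)].sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1.0), 1.0)
    ok_features = n_features >= params.min_features
    if params.max_mito_fraction >= 1.0:  # bound of 1 disables the filter
        ok_mito = np.ones(adata.n_obs, dtype=bool)
    else:
        ok_mito = mito_frac < params.max_mito_fraction  # strict "<10%"
    report = QCReport(
        n_input=int(adata.n_obs),
        removed_low_features=int((~ok_features).sum()),
        removed_high_mito=int((ok_features & ~ok_mito).sum()),
    )
    keep = ok_features & ok_mito
    out = adata[keep].copy()
    report.n_retained = int(out.n_obs)
    return out, report


def filter_clusters(adata: ad.AnnData, params: CellQCParams,
                    type_key: str = "cell_type",
                    report: QCReport | None = None) -> ad.AnnData:
    """Drop all cells whose cluster has fewer than min_cluster_size cells."""
    if type_key not in adata.obs:
        raise DataError(f"cells carry no {type_key!r} label")
    sizes = adata.obs[type_key].value_counts()
    small = sizes.index[sizes < params.min_cluster_size]
    keep = ~adata.obs[type_key].isin(small)
    out = adata[keep.to_numpy()].copy()
    if len(small):
        logger.warning("dropped %d cluster(s) under %d cells: %s",
                       len(small), params.min_cluster_size,
                       [str(s) for s in small])
    if out.n_obs == 0:
        logger.warning("all clusters below min_cluster_size; matrix empty")
    if report is not None:
        report.removed_small_cluster = int((~keep).sum())
        report.dropped_clusters = [str(s) for s in small if sizes[s] > 0]
        report.n_retained = int(out.n_obs)
    return out


def collapse_pseudobulk(adata: ad.AnnData,
                        sample_key: str = "sample") -> CountTable:
    """Sum counts over retained cells, per sample, keeping zero gene rows.

    Column sums equal the retained matrix totals exactly (integer
    conservation).
    """
    if sample_key not in adata.obs:
        raise DataError(f"cells carry no {sample_key!r} label")
    samples = adata.obs[sample_key].astype(str)
    columns = {}
    for s in sorted(samples.unique()):
        rows = (samples == s).to_numpy()
        if rows.sum() == 0:
            raise DataError(f"sample {s!r} has zero retained cells")
        columns[s] = np.asarray(_dense(adata.X[rows]).sum(axis=0)).ravel()
    empty = [s for s, v in columns.items() if v.sum() == 0]
    if empty:
        raise DataError(f"sample(s) with zero retained counts: {empty}")
    df = pd.DataFrame(columns, index=adata.var_names.copy())
    df.index.name = "gene_id"
    return CountTable(df.astype(np.int64))


def run_qc(adata: ad.AnnData, params: CellQCParams | None = None,
           label: str = "") -> tuple[CountTable, ad.AnnData, QCReport]:
    """Cell filters -> cluster filter -> pseudo-bulk collapse, in order."""
    params = params or CellQCParams()
    filtered, report = filter_cells(adata, params)
    filtered = filter_clusters(filtered, params, report=report)
    if filtered.n_obs == 0:
        raise DataError("no cells survive QC")
    table = collapse_pseudobulk(filtered)
    table.label = label
    return table, filtered, report
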
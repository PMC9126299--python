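"""Readers and writers for the count-matrix and gene-list formats.

On-disk dialects
----------------
* gene x sample count tables: TSV with a header row; first column is the gene
  identifier, remaining columns are non-negative integer counts (one per
  replicate).  Normalized tables use the same layout with real values.
* cell x gene matrices: Matrix Market coordinate format (1-based indices on
  disk) plus ``barcodes.tsv`` (one cell barcode per line) and
  ``features.tsv`` (one gene identifier per line).  In memory a cell matrix
  is an :class:`anndata.AnnData` with cells as observations.
* gene lists (e.g. a transcription-factor catalogue): one identifier per
  line, ``#`` comments allowed, duplicates dropped with a warning.

Internal indexing is always 0-based; raw counts stay integers everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import DataError, ParseError

logger = logging.getLogger("scdropout.io")

__all__ = [
    "CountTable",
    "GeneList",
    "read_count_table",
    "write_count_table",
    "read_cell_matrix",
    "write_cell_matrix",
    "read_gene_list",
    "write_gene_list",
]


@dataclass
class CountTable:
    """A dense genes x samples count table.

    Parameters
    ----------
    counts
        DataFrame indexed by gene identifier, one column per sample.
    label
        Dataset label, e.g. ``"CB"`` or ``"TBxCB"``.
    normalized
        True for real-valued (e.g. CPM) tables; raw tables are integer.
    """

    counts: pd.DataFrame
    label: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise DataError(f"duplicate gene identifiers: {list(dupes[:5])}")
        if (self.counts.to_numpy() < 0).any():
            raise DataError("negative values in count table")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def detected_genes(self) -> pd.Index:
        """Genes with total raw count >= 1 summed across all replicates."""
        return self.counts.index[self.counts.sum(axis=1) >= 1]


@dataclass
class GeneList:
    """An ordered, duplicate-free collection of gene identifiers."""

    identifiers: list[str]
    label: str = ""
    _set: set = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.identifiers:
            raise DataError("gene list is empty")
        if len(set(self.identifiers)) != len(self.identifiers):
            raise DataError("gene list contains duplicates")
        self._set = set(self.identifiers)

    def __len__(self) -> int:
        return len(self.identifiers)

    def __contains__(self, gene: str) -> bool:
        return gene in self._set

    def __iter__(self):
        return iter(self.identifiers)


def read_count_table(path: str | Path, label: str = "",
                     normalized: bool = False) -> CountTable:
    """Read a TSV count table (header row, gene-id first column)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # malformed TSV structure
        raise ParseError(f"{path}: cannot parse as TSV count table: {exc}") from exc
    if df.shape[1] == 0:
        raise DataError(f"{path}: no sample columns")
    for col in df.columns:
        values = df[col]
        bad = values.index[pd.to_numeric(values, errors="coerce").isna()]
        if len(bad):
            raise ParseError(
                f"{path}: malformed numeric cell at row {bad[0]!r}, column {col!r}"
            )
    df = df.astype(float if normalized else np.int64)
    df.index = df.index.astype(str)
    return CountTable(df, label=label or path.stem, normalized=normalized)


def write_count_table(table: CountTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.counts.to_csv(path, sep="\t", index_label="gene_id")
    return path


def read_cell_matrix(mtx_path: str | Path, barcodes_path: str | Path,
                     features_path: str | Path) -> ad.AnnData:
    """Load a cells x genes Matrix Market trio into an AnnData.

    MTX indices are 1-based on disk (coordinate integer dialect); scipy
    converts to 0-based internally.  Barcode/feature line counts must match
    the matrix dimensions.
    """
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:
        raise ParseError(f"{mtx_path}: cannot parse Matrix Market file: {exc}") from exc
    if not np.issubdtype(np.asarray(mat.data if sp.issparse(mat) else mat).dtype,
                         np.integer):
        data = mat.data if sp.issparse(mat) else np.asarray(mat)
        if not np.allclose(data, np.round(data)):
            raise ParseError(f"{mtx_path}: non-integer entries in count matrix")
    mat = sp.csr_matrix(mat, dtype=np.int64)
    if (mat.data < 0).any():
        raise DataError(f"{mtx_path}: negative counts")
    barcodes = _read_lines(barcodes_path)
    features = _read_lines(features_path)
    if len(barcodes) != mat.shape[0]:
        raise DataError(
            f"{barcodes_path}: {len(barcodes)} barcodes but matrix has "
            f"{mat.shape[0]} rows"
        )
    if len(features) != mat.shape[1]:
        raise DataError(
            f"{features_path}: {len(features)} features but matrix has "
            f"{mat.shape[1]} columns"
        )
    adata = ad.AnnData(
        X=mat,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(features, name="gene_id")),
    )
    return adata


def write_cell_matrix(adata: ad.AnnData, directory: str | Path,
                      prefix: str = "") -> dict[str, Path]:
    """Write an AnnData as <prefix>matrix.mtx / barcodes.tsv / features.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": directory / f"{prefix}matrix.mtx",
        "barcodes": directory / f"{prefix}barcodes.tsv",
        "features": directory / f"{prefix}features.tsv",
    }
    mat = sp.coo_matrix(adata.X)
    scipy.io.mmwrite(str(paths["mtx"]), mat, field="integer")
    paths["barcodes"].write_text("\n".join(adata.obs_names) + "\n")
    paths["features"].write_text("\n".join(adata.var_names) + "\n")
    return paths


def read_gene_list(path: str | Path, label: str = "") -> GeneList:
    """Read a one-identifier-per-line gene list; dedups with a warning."""
    seen: set[str] = set()
    identifiers: list[str] = []
    n_dupes = 0
    for line in Path(path).read_text().splitlines():
        token = line.split("#", 1)[0].strip()
        if not token:
            continue
        if token in seen:
            n_dupes += 1
            continue
        seen.add(token)
        identifiers.append(token)
    if n_dupes:
        logger.warning("%s: dropped %d duplicate identifiers", path, n_dupes)
    if not identifiers:
        raise DataError(f"{path}: gene list empty after comment/blank filtering")
    return GeneList(identifiers, label=label or Path(path).stem)


def write_gene_list(genes: GeneList, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(genes.identifiers) + "\n")
    return path


def _read_lines(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
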
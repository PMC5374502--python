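"""Domain containers, readers/writers and validation shared by all pipeline stages.

All matrices are oriented genes x cells (rows x columns), matching the
gene-sample heatmaps the analysis produces. Gene identity is ``gene_id``;
symbols are display-only.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

__all__ = [
    "ValidationError",
    "DuplicateIdError",
    "DimensionMismatchError",
    "NonIntegerCountError",
    "GeneTable",
    "CellTable",
    "CountMatrix",
    "ExpressionMatrix",
    "read_count_matrix",
    "write_count_matrix",
    "read_expression_matrix",
    "write_table",
    "read_config",
]


class ValidationError(ValueError):
    """Base class for container validation failures."""


class DuplicateIdError(ValidationError):
    """A gene or cell identifier occurs more than once."""


class DimensionMismatchError(ValidationError):
    """Matrix dimensions disagree with the annotation tables."""


class NonIntegerCountError(ValidationError):
    """A count matrix contains negative or non-integral entries."""


GENE_COLUMNS = ("symbol", "length_bp", "is_mitochondrial")
CELL_COLUMNS = ("condition", "total_mapped_reads")


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise DuplicateIdError(f"duplicate {what} ids: {dups[:5]}")


def validate_gene_table(genes: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene annotation table (index gene_id; symbol, length_bp, is_mitochondrial)."""
    _check_unique(genes.index, "gene")
    for col in GENE_COLUMNS:
        if col not in genes.columns:
            raise ValidationError(f"gene table missing column {col!r}")
    if (genes["length_bp"] < 1).any():
        raise ValidationError("gene lengths must be >= 1 bp")
    genes = genes.copy()
    genes["is_mitochondrial"] = genes["is_mitochondrial"].astype(bool)
    if genes["is_mitochondrial"].all():
        raise ValidationError("need at least one non-mitochondrial gene")
    return genes


def validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Validate a cell metadata table (index cell_id; condition, total_mapped_reads)."""
    _check_unique(cells.index, "cell")
    for col in CELL_COLUMNS:
        if col not in cells.columns:
            raise ValidationError(f"cell table missing column {col!r}")
    if (cells["total_mapped_reads"] < 0).any():
        raise ValidationError("total_mapped_reads must be non-negative")
    return cells


# Aliases so call sites can speak the domain vocabulary: both tables are
# plain DataFrames indexed by their id column.
GeneTable = pd.DataFrame
CellTable = pd.DataFrame


@dataclass
class CountMatrix:
    """Raw gene x cell counts plus gene/cell annotation.

    Parameters
    ----------
    values : DataFrame
        genes x cells, non-negative integers (reads or molecules).
    genes : DataFrame
        indexed by gene_id with symbol, length_bp, is_mitochondrial.
    cells : DataFrame
        indexed by cell_id with condition, total_mapped_reads.
    unit : {"reads", "molecules"}
    """

    values: pd.DataFrame
    genes: pd.DataFrame
    cells: pd.DataFrame
    unit: str = "reads"

    def __post_init__(self) -> None:
        self.genes = validate_gene_table(self.genes)
        self.cells = validate_cell_table(self.cells)
        if self.unit not in ("reads", "molecules"):
            raise ValidationError(f"unknown count unit {self.unit!r}")
        v = self.values
        if v.shape != (len(self.genes), len(self.cells)):
            raise DimensionMismatchError(
                f"matrix is {v.shape}, annotation implies "
                f"({len(self.genes)}, {len(self.cells)})"
            )
        if not v.index.equals(self.genes.index) or not v.columns.equals(self.cells.index):
            raise DimensionMismatchError("matrix index/columns disagree with annotation ids")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise NonIntegerCountError("count matrix has non-integral entries")
            self.values = v.round().astype(np.int64)
            arr = self.values.to_numpy()
        if (arr < 0).any():
            raise NonIntegerCountError("count matrix has negative entries")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def subset_cells(self, cell_ids) -> "CountMatrix":
        """Restrict to the given cells, preserving their order."""
        return CountMatrix(
            self.values.loc[:, cell_ids], self.genes, self.cells.loc[cell_ids], self.unit
        )

    def to_anndata(self):
        """Convenience export to an AnnData (cells x genes), if anndata is available."""
        import anndata

        return anndata.AnnData(
            X=self.values.to_numpy().T, obs=self.cells.copy(), var=self.genes.copy()
        )


@dataclass
class ExpressionMatrix:
    """Normalized gene x cell values tagged with the transform that produced them."""

    values: pd.DataFrame
    transform: str
    floor_applied: Optional[float] = None
    meta: dict = field(default_factory=dict)

    _TRANSFORMS = ("nRPKM", "norm_mRNA_mol", "log2p1", "vst", "zscore", "delta_ct")

    def __post_init__(self) -> None:
        if self.transform not in self._TRANSFORMS:
            raise ValidationError(f"unknown transform {self.transform!r}")
        if self.transform in ("nRPKM", "norm_mRNA_mol"):
            if (self.values.to_numpy() < 0).any():
                raise ValidationError(f"{self.transform} values must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, cell_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[:, cell_ids], self.transform, self.floor_applied, dict(self.meta)
        )


def _read_tsv_indexed(path: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", index_col=0)


def read_count_matrix(path: str, genes_path: str, cells_path: str, unit: str = "reads") -> CountMatrix:
    """Read a count matrix (MTX or TSV) with its gene/cell annotation tables.

    MTX is Matrix Market coordinate format with 1-based indices and rows/columns
    ordered as in the annotation tables. TSV has genes as rows (first column
    gene_id) and a header of cell ids.
    """
    genes = validate_gene_table(_read_tsv_indexed(genes_path))
    cells = validate_cell_table(_read_tsv_indexed(cells_path))
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.endswith(".mtx"):
        mat = scipy.io.mmread(path)
        arr = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        if arr.shape != (len(genes), len(cells)):
            raise DimensionMismatchError(
                f"MTX is {arr.shape}, annotation implies ({len(genes)}, {len(cells)})"
            )
        values = pd.DataFrame(arr, index=genes.index, columns=cells.index)
    else:
        values = pd.read_csv(path, sep="\t", index_col=0)
        _check_unique(values.index, "gene")
        _check_unique(pd.Index(values.columns), "cell")
        if values.shape != (len(genes), len(cells)):
            raise DimensionMismatchError(
                f"TSV is {values.shape}, annotation implies ({len(genes)}, {len(cells)})"
            )
        if list(values.index) != list(genes.index) or list(values.columns) != list(cells.index):
            raise DimensionMismatchError("TSV gene/cell ids disagree with annotation tables")
        if not all(np.issubdtype(dt, np.number) for dt in values.dtypes):
            raise NonIntegerCountError("TSV count matrix has non-numeric entries")
    return CountMatrix(values, genes, cells, unit=unit)


def write_count_matrix(counts: CountMatrix, out_dir: str) -> None:
    """Write matrix.mtx + genes.tsv + cells.tsv into ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    sp = scipy.sparse.coo_matrix(counts.values.to_numpy())
    scipy.io.mmwrite(os.path.join(out_dir, "matrix.mtx"), sp, field="integer")
    counts.genes.to_csv(os.path.join(out_dir, "genes.tsv"), sep="\t", index_label="gene_id")
    counts.cells.to_csv(os.path.join(out_dir, "cells.tsv"), sep="\t", index_label="cell_id")


def read_expression_matrix(path: str, transform: str) -> ExpressionMatrix:
    """Read an expression TSV written by :func:`write_table`."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values, transform)


def write_table(obj, path: str) -> None:
    """Write a pipeline result table as TSV; round-trips ids and values.

    Accepts DataFrames, domain containers with a ``values`` DataFrame
    (ExpressionMatrix), dataclasses exposing a ``table`` DataFrame (DEResult,
    CellTypeCall, ...), and MarkerSet (written as long cell_type/gene_id rows).
    """
    from .celltype import MarkerSet  # local import to avoid a cycle

    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", index_label=obj.index.name or "id")
    elif isinstance(obj, ExpressionMatrix):
        obj.values.to_csv(path, sep="\t", index_label="gene_id")
    elif isinstance(obj, MarkerSet):
        rows = [
            {"cell_type": t, "gene_id": g} for t, gs in obj.markers.items() for g in gs
        ]
        pd.DataFrame(rows, columns=["cell_type", "gene_id"]).to_csv(path, sep="\t", index=False)
    elif dataclasses.is_dataclass(obj) and hasattr(obj, "table"):
        obj.table.to_csv(path, sep="\t", index_label=obj.table.index.name or "gene_id")
    else:
        raise TypeError(f"don't know how to write {type(obj).__name__}")


def read_config(path: str) -> dict:
    """Read a YAML run configuration (paths and thresholds)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError("run config must be a mapping")
    return cfg
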
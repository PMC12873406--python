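"""Core data containers and I/O for cell-by-gene UMI count data.

The universal input is a :class:`CellGeneDataset`: a sparse cells x genes UMI
count matrix aligned with three metadata tables (cells, samples, genes).
Cell barcodes and gene IDs are the only join keys; matrix row/column order is
preserved by I/O but never carries meaning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger("scrobust")

CELL_COLUMNS = ("sample_id", "cluster_label", "major_class")
SAMPLE_COLUMNS = ("diagnosis", "age", "sex")
GENE_COLUMNS = ("symbol", "is_protein_coding", "is_mito")


class SchemaError(ValueError):
    """A metadata table is missing a required column."""


class IntegrityError(ValueError):
    """Cross-table references or matrix/metadata alignment are broken."""


class EmptyDatasetError(ValueError):
    """An operation removed every cell."""


@dataclass
class CellGeneDataset:
    """Sparse UMI counts plus aligned cell, sample, and gene metadata.

    Attributes
    ----------
    counts
        CSR matrix of shape (n_cells, n_genes), non-negative integers.
    cell_meta
        Indexed by cell barcode; columns ``sample_id``, ``cluster_label``,
        ``major_class``.
    sample_meta
        Indexed by ``sample_id``; columns ``diagnosis`` (case|control),
        ``age``, ``sex`` (M|F), optionally ``pmi``, ``ph``, ``batch``.
    gene_meta
        Indexed by gene ID; columns ``symbol``, ``is_protein_coding``,
        ``is_mito``.
    """

    counts: sp.csr_matrix
    cell_meta: pd.DataFrame
    sample_meta: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.counts.eliminate_zeros()
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def barcodes(self) -> pd.Index:
        return self.cell_meta.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.gene_meta.index

    def validate(self) -> None:
        for col in CELL_COLUMNS:
            if col not in self.cell_meta.columns:
                raise SchemaError(f"cell_meta is missing column {col!r}")
        for col in SAMPLE_COLUMNS:
            if col not in self.sample_meta.columns:
                raise SchemaError(f"sample_meta is missing column {col!r}")
        for col in GENE_COLUMNS:
            if col not in self.gene_meta.columns:
                raise SchemaError(f"gene_meta is missing column {col!r}")
        if self.counts.shape[0] != len(self.cell_meta):
            raise IntegrityError(
                f"counts has {self.counts.shape[0]} rows but cell_meta has "
                f"{len(self.cell_meta)} cells"
            )
        if self.counts.shape[1] != len(self.gene_meta):
            raise IntegrityError(
                f"counts has {self.counts.shape[1]} columns but gene_meta has "
                f"{len(self.gene_meta)} genes"
            )
        dangling = set(self.cell_meta["sample_id"]) - set(self.sample_meta.index)
        if dangling:
            raise IntegrityError(
                f"cell_meta references sample_id(s) absent from sample_meta: "
                f"{sorted(dangling)}"
            )
        data = self.counts.data
        if data.size and (not np.all(np.isfinite(data)) or data.min() < 0):
            raise ValueError("counts must be finite and non-negative")

    def subset_cells(self, mask: np.ndarray) -> "CellGeneDataset":
        """Return a new dataset restricted to cells where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return CellGeneDataset(
            counts=self.counts[mask],
            cell_meta=self.cell_meta.loc[mask].copy(),
            sample_meta=self.sample_meta.copy(),
            gene_meta=self.gene_meta.copy(),
        )

    # -- per-cell summaries ---------------------------------------------
    def detected_genes(self) -> np.ndarray:
        """Number of genes with nonzero count per cell."""
        return np.asarray(self.counts.getnnz(axis=1))

    def total_counts(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def mito_fraction(self) -> np.ndarray:
        """Fraction of each cell's UMIs mapping to mitochondrial genes."""
        mito = np.asarray(self.gene_meta["is_mito"], dtype=bool)
        total = self.total_counts().astype(float)
        mito_counts = np.asarray(self.counts[:, mito].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito_counts / total, 0.0)
        return frac

    def expression_rate(self, cell_mask: np.ndarray | None = None) -> np.ndarray:
        """Per-gene fraction of (selected) cells with nonzero count."""
        m = self.counts if cell_mask is None else self.counts[np.asarray(cell_mask, bool)]
        n = m.shape[0]
        if n == 0:
            return np.zeros(self.n_genes)
        return np.asarray(m.getnnz(axis=0)) / n

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CellGeneDataset):
            return NotImplemented
        return (
            (self.counts != other.counts).nnz == 0
            and self.cell_meta.equals(other.cell_meta)
            and self.sample_meta.equals(other.sample_meta)
            and self.gene_meta.equals(other.gene_meta)
        )


@dataclass
class NormalizedMatrix:
    """Log library-size-normalized expression: ln(1 + count/total * scale).

    Zeros are preserved exactly: an entry is 0 iff the raw count is 0.
    """

    values: sp.csr_matrix
    scale_factor: float = 1e4
    log_base: str = "ln1p"


@dataclass
class CellQuality:
    """Detected-gene counts and their z-score (the cell-quality covariate)."""

    ngeneson: np.ndarray
    cngeneson: np.ndarray
    barcodes: pd.Index = field(default=None)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: tuple[str, ...], key: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={key: str})
    if key not in df.columns:
        raise SchemaError(f"{path}: missing key column {key!r}")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    return df.set_index(key)


def load_dataset(
    matrix_path: str | Path,
    cells_path: str | Path,
    samples_path: str | Path,
    genes_path: str | Path,
) -> CellGeneDataset:
    """Read a dataset from Matrix Market counts and three TSV metadata tables.

    Row/column order is preserved from the files; the cells TSV orders rows
    and the genes TSV orders columns.
    """
    counts = sp.csr_matrix(mmread(str(matrix_path)))
    cell_meta = _read_tsv(cells_path, CELL_COLUMNS, key="barcode")
    sample_meta = _read_tsv(samples_path, SAMPLE_COLUMNS, key="sample_id")
    gene_meta = _read_tsv(genes_path, GENE_COLUMNS, key="gene_id")
    for col in ("is_protein_coding", "is_mito"):
        gene_meta[col] = gene_meta[col].astype(bool)
    return CellGeneDataset(counts, cell_meta, sample_meta, gene_meta)


def write_dataset(dataset: CellGeneDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset as matrix.mtx + cells/samples/genes TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "cells": out / "cells.tsv",
        "samples": out / "samples.tsv",
        "genes": out / "genes.tsv",
    }
    mmwrite(str(paths["matrix"]), sp.coo_matrix(dataset.counts), field="integer")
    dataset.cell_meta.rename_axis("barcode").reset_index().to_csv(
        paths["cells"], sep="\t", index=False
    )
    dataset.sample_meta.rename_axis("sample_id").reset_index().to_csv(
        paths["samples"], sep="\t", index=False
    )
    dataset.gene_meta.rename_axis("gene_id").reset_index().to_csv(
        paths["genes"], sep="\t", index=False
    )
    return paths


# ---------------------------------------------------------------------------
# QC, normalization, cell quality
# ---------------------------------------------------------------------------

def qc_filter(
    dataset: CellGeneDataset,
    min_genes: int = 300,
    max_genes: int = 15000,
    max_mito_frac: float = 0.05,
) -> CellGeneDataset:
    """Retain cells with min_genes < detected genes < max_genes and
    mitochondrial read fraction < max_mito_frac (all strict).

    Returns a new dataset; the input is not modified.
    """
    detected = dataset.detected_genes()
    mito = dataset.mito_fraction()
    keep = (detected > min_genes) & (detected < max_genes) & (mito < max_mito_frac)
    if not keep.any():
        raise EmptyDatasetError("QC filter removed every cell")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("qc_filter removed %d of %d cells", n_drop, dataset.n_cells)
    return dataset.subset_cells(keep)


def normalize(dataset: CellGeneDataset, scale: float = 1e4) -> NormalizedMatrix:
    """ln(1 + count / cell_total * scale); sparsity pattern preserved."""
    total = dataset.total_counts().astype(float)
    if np.any(total <= 0):
        raise ValueError(
            "dataset contains cells with zero total count; run qc_filter first"
        )
    m = dataset.counts.tocoo(copy=True).astype(float)
    m.data = np.log1p(m.data / total[m.row] * scale)
    return NormalizedMatrix(values=m.tocsr(), scale_factor=scale)


def cell_quality(
    dataset: CellGeneDataset, scope_cells: np.ndarray | None = None
) -> CellQuality:
    """Detected-gene count per cell and its z-score over ``scope_cells``.

    ``cngeneson`` is the cell-quality covariate used by the hurdle model:
    within the fitting scope (conventionally the cluster under analysis),
    higher detected-gene counts indicate better nuclei quality.
    """
    if scope_cells is None:
        mask = np.ones(dataset.n_cells, dtype=bool)
    else:
        mask = np.asarray(scope_cells, dtype=bool)
    if not mask.any():
        raise ValueError("scope_cells selects no cells")
    ngeneson = dataset.detected_genes()[mask]
    sd = float(np.std(ngeneson, ddof=0))
    if sd == 0.0:
        logger.warning("cell_quality: zero variance in detected genes; cngeneson=0")
        cng = np.zeros(ngeneson.shape, dtype=float)
    else:
        cng = (ngeneson - ngeneson.mean()) / sd
    return CellQuality(
        ngeneson=ngeneson, cngeneson=cng, barcodes=dataset.barcodes[mask]
    )
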
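"""Post-processing QC: quality indicators, cell/gene filters, normalization.

Filters are applied in a fixed order — (1) drop genes expressed in too few
cells, (2) drop cells with too few genes (counted on the remaining genes),
(3) drop cells whose mitochondrial transcript rate exceeds the cap (computed
on the remaining genes) — and each rule's drop count is reported.

Normalization maps a cell's raw counts to counts-per-ten-thousand on a log2
scale: value = log2(10000 * X + 1) where X is the gene's fraction of the
cell's total transcripts.  Zeros map to zeros, so sparsity is preserved, and
the result is invariant to the cell's sequencing depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .errors import BarnyardQCError, EmptyResultError
from .model_io import CountMatrix, DistStats, QCIndicators


@dataclass(frozen=True)
class FilterParams:
    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 200
    max_mito_rate: float = 0.20

    def __post_init__(self) -> None:
        if self.min_cells_per_gene < 0 or self.min_genes_per_cell < 0:
            raise ValueError("filter minima must be >= 0")
        if not 0.0 <= self.max_mito_rate <= 1.0:
            raise ValueError("max_mito_rate outside [0, 1]")


@dataclass
class FilterReport:
    """Drop accounting, one entry per rule in application order."""

    genes_dropped_min_cells: int
    cells_dropped_min_genes: int
    cells_dropped_mito: int
    n_genes_kept: int
    n_cells_kept: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def compute_qc_indicators(m: CountMatrix) -> QCIndicators:
    """Median/quartile/mean of genes, transcripts and mito rate per cell.

    A cell with zero transcripts contributes a mito rate of 0 (with a
    warning) rather than NaN.
    """
    if m.n_barcodes == 0:
        raise BarnyardQCError("empty matrix: no cells to compute indicators on")
    genes = m.genes_per_barcode()
    totals = m.totals_per_barcode()
    mito = m.mito_counts()
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cells with zero transcripts; mito rate set to 0",
                      stacklevel=2)
    with np.errstate(invalid="ignore"):
        mito_rate = np.where(zero, 0.0, mito / np.where(zero, 1, totals))
    return QCIndicators(
        genes_per_cell=DistStats.from_values(genes),
        transcripts_per_cell=DistStats.from_values(totals),
        mito_rate_per_cell=DistStats.from_values(mito_rate),
        n_cells=m.n_barcodes,
    )


def filter_matrix(
    m: CountMatrix, p: FilterParams = FilterParams()
) -> tuple[CountMatrix, FilterReport]:
    """Apply the gene and cell filters in their fixed order; report drops."""
    csr = m.matrix.tocsr()

    cells_per_gene = np.asarray((csr > 0).sum(axis=1)).ravel()
    gene_keep = cells_per_gene >= p.min_cells_per_gene
    n_genes_dropped = int((~gene_keep).sum())
    csr = csr[gene_keep]
    features = m.features.loc[gene_keep].reset_index(drop=True)

    genes_per_cell = np.asarray((csr > 0).sum(axis=0)).ravel()
    cell_keep1 = genes_per_cell >= p.min_genes_per_cell
    n_cells_dropped_genes = int((~cell_keep1).sum())
    csr = csr[:, cell_keep1]

    totals = np.asarray(csr.sum(axis=0)).ravel().astype(float)
    mito_mask = features["mito"].to_numpy(bool)
    mito_counts = np.asarray(csr[mito_mask].sum(axis=0)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_rate = np.where(totals > 0, mito_counts / np.where(totals > 0, totals, 1), 0.0)
    cell_keep2 = mito_rate <= p.max_mito_rate
    n_cells_dropped_mito = int((~cell_keep2).sum())
    csr = csr[:, cell_keep2]

    keep_barcodes = m.barcodes[cell_keep1]
    keep_barcodes = keep_barcodes[cell_keep2]
    keep_raw = m.raw_reads[cell_keep1][cell_keep2]

    report = FilterReport(
        genes_dropped_min_cells=n_genes_dropped,
        cells_dropped_min_genes=n_cells_dropped_genes,
        cells_dropped_mito=n_cells_dropped_mito,
        n_genes_kept=csr.shape[0],
        n_cells_kept=csr.shape[1],
    )
    if csr.shape[0] == 0 or csr.shape[1] == 0:
        raise EmptyResultError(
            "filters removed every gene or cell", report=report.to_dict()
        )
    return CountMatrix(csr.tocsr(), features, keep_barcodes, keep_raw), report


def normalize_log(m: CountMatrix) -> sp.csr_matrix:
    """log2(10000 * X + 1) with X = gene count / cell total (a fraction).

    Every retained cell must have at least one transcript (filter first).
    Returns a real-valued sparse matrix with the same sparsity pattern.
    """
    totals = m.totals_per_barcode().astype(float)
    if np.any(totals == 0):
        raise BarnyardQCError(
            "cells with zero transcripts cannot be normalized; filter them first"
        )
    csc = m.matrix.tocsc().astype(float)
    # scale each column to fractions, then log-transform the nonzeros only
    inv = 1.0 / totals
    csc = csc.multiply(inv[np.newaxis, :]).tocsc()
    csc.data = np.log2(10000.0 * csc.data + 1.0)
    return csc.tocsr()
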
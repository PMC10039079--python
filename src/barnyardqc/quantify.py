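"""Tagged reads -> deduplicated count matrix, depth downsampling, tube splits.

Deduplication collapses reads sharing an exact ``(barcode, UMI, gene)`` key
into one transcript; no UMI error-collapsing is attempted (exact string
equality only).  Raw-read depth is accounted per barcode over *all* its
reads, assigned or not, because sequencing depth is quoted as raw reads per
cell.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cell_calling import CellCallResult
from .errors import BarnyardQCError, ConsistencyError
from .model_io import UNASSIGNED, CountMatrix


@dataclass(frozen=True)
class DownsampleSpec:
    """Target average raw-read depth per analyzed cell, with a thinning seed."""

    target_depth: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_depth <= 0:
            raise ValueError("target_depth must be > 0")


def build_count_matrix(
    reads: pd.DataFrame,
    cells: CellCallResult | None,
    features: pd.DataFrame,
) -> CountMatrix:
    """Deduplicate reads into a genes x cell-barcodes transcript matrix.

    One transcript per distinct (barcode, umi, gene) among reads whose
    barcode is cell-associated and whose gene is assigned.  Per-barcode
    raw-read counts include unassigned reads, for depth accounting.  If
    ``cells`` is None every barcode with at least one read is kept.
    """
    if cells is None:
        barcodes = np.array(sorted(reads["barcode"].unique()), dtype=object)
    else:
        barcodes = np.array(sorted(cells.cell_barcodes), dtype=object)
    bc_index = {b: i for i, b in enumerate(barcodes)}

    in_cells = reads["barcode"].isin(bc_index).to_numpy()
    raw_reads = np.zeros(len(barcodes), dtype=np.int64)
    raw_counts = reads.loc[in_cells, "barcode"].value_counts()
    for b, n in raw_counts.items():
        raw_reads[bc_index[b]] = n

    assigned = reads.loc[in_cells & (reads["gene"] != UNASSIGNED).to_numpy()]
    unknown = set(assigned["gene"].unique()) - set(features["gene_id"])
    if unknown:
        raise ConsistencyError(
            f"genes absent from feature table: {sorted(unknown)[:5]}"
        )
    dedup = assigned.drop_duplicates(subset=["barcode", "umi", "gene"])

    gene_index = {g: i for i, g in enumerate(features["gene_id"])}
    rows = dedup["gene"].map(gene_index).to_numpy(np.int64, na_value=-1)
    cols = dedup["barcode"].map(bc_index).to_numpy(np.int64)
    mat = sp.coo_matrix(
        (np.ones(len(dedup), np.int64), (rows, cols)),
        shape=(len(features), len(barcodes)),
    ).tocsr()
    return CountMatrix(mat, features, barcodes, raw_reads)


def downsample_reads(
    reads: pd.DataFrame,
    cells: CellCallResult,
    spec: DownsampleSpec,
) -> pd.DataFrame:
    """Binomial thinning of raw reads to a target average depth per cell.

    Every read is independently retained with probability
    ``p = target_depth * n_cells / total_raw_reads`` so that the retained
    total has expectation ``target_depth * n_cells``.  If the data are
    already shallower than the target the stream passes through unchanged
    with a warning.
    """
    total = len(reads)
    wanted = spec.target_depth * cells.n_cells
    if total <= wanted:
        warnings.warn(
            f"only {total} raw reads for a target of {wanted:.0f}; no downsampling applied",
            stacklevel=2,
        )
        return reads
    p = wanted / total
    rng = np.random.default_rng(spec.seed)
    keep = rng.random(total) < p
    return reads.loc[keep].reset_index(drop=True)


def split_tubes(
    m: CountMatrix, n_tubes: int = 8, seed: int = 0
) -> list[CountMatrix]:
    """Partition barcodes (beads) uniformly at random into PCR tubes.

    Physically the beads, not the reads, are split; each barcode lands in
    exactly one tube, so the tubes are pairwise disjoint and their union is
    the input matrix.
    """
    if n_tubes < 1:
        raise BarnyardQCError("n_tubes must be >= 1")
    if n_tubes > m.n_barcodes:
        raise BarnyardQCError(
            f"cannot split {m.n_barcodes} barcodes into {n_tubes} tubes"
        )
    rng = np.random.default_rng(seed)
    assignment = rng.integers(0, n_tubes, size=m.n_barcodes)
    return [m.select_barcodes(np.nonzero(assignment == t)[0]) for t in range(n_tubes)]
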
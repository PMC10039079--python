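"""Domain types and readers/writers for the formats the pipeline touches.

The pipeline's in-memory currency is two objects:

* a table of *tagged reads* — each sequencing read reduced to its
  ``(barcode, umi, gene, species)`` content, held as a :class:`pandas.DataFrame`
  with those four columns;
* a :class:`CountMatrix` — sparse genes x barcodes deduplicated transcript
  counts plus the feature table (species label, mitochondrial flag per gene),
  the barcode list and per-barcode raw-read counts.

On disk, count matrices use the Matrix Market convention of the single-cell
world (``matrix.mtx`` with ``features.tsv`` / ``barcodes.tsv`` sidecars, genes
as rows, 1-based coordinates), tagged reads use a four-column TSV, and raw
sequencing input is a pair of FASTQ files with a fixed read layout: R1 carries
the cell barcode and UMI, R2 carries the cDNA fragment.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import (
    ConsistencyError,
    FormatError,
    LayoutError,
    SynchronizationError,
)

UNASSIGNED = "UNASSIGNED"

READ_COLUMNS = ["barcode", "umi", "gene", "species"]

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class ReadLayout:
    """Fixed positional layout of the R1/R2 read pair.

    R1 (default 30 bases) carries the cell barcode and the UMI at fixed
    0-based half-open spans; R2 (default 70 bases) is cDNA. The default
    16-base barcode + 12-base UMI split mirrors prevalent bead designs; the
    last two R1 bases are ignored.
    """

    r1_length: int = 30
    r2_length: int = 70
    barcode_span: tuple[int, int] = (0, 16)
    umi_span: tuple[int, int] = (16, 28)

    def __post_init__(self) -> None:
        b0, b1 = self.barcode_span
        u0, u1 = self.umi_span
        if not (0 <= b0 < b1 <= self.r1_length):
            raise LayoutError(f"barcode span {self.barcode_span} outside R1[0,{self.r1_length})")
        if not (0 <= u0 < u1 <= self.r1_length):
            raise LayoutError(f"UMI span {self.umi_span} outside R1[0,{self.r1_length})")
        if max(b0, u0) < min(b1, u1):
            raise LayoutError("barcode and UMI spans overlap")

    @property
    def barcode_length(self) -> int:
        return self.barcode_span[1] - self.barcode_span[0]

    @property
    def umi_length(self) -> int:
        return self.umi_span[1] - self.umi_span[0]


@dataclass(frozen=True)
class TaggedRead:
    """One sequencing read reduced to (barcode, UMI, gene-or-unassigned)."""

    barcode: str
    umi: str
    gene: str = UNASSIGNED
    species: str = UNASSIGNED

    def __post_init__(self) -> None:
        for part in (self.barcode, self.umi):
            if not set(part) <= _VALID_BASES:
                raise ValueError(f"non-ACGTN characters in {part!r}")


def make_feature_table(
    gene_ids: list[str], species: list[str], mito: list[bool]
) -> pd.DataFrame:
    """Build a feature table: one row per gene with species label and mito flag."""
    ft = pd.DataFrame({"gene_id": gene_ids, "species": species, "mito": np.asarray(mito, bool)})
    if ft["gene_id"].duplicated().any():
        dup = ft.loc[ft["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ConsistencyError(f"duplicate gene id {dup!r} in feature table")
    return ft


@dataclass
class ParseReport:
    """Read accounting for one FASTQ-pair parse: input = emitted + dropped."""

    total_records: int = 0
    emitted: int = 0
    dropped_n: int = 0

    def reconciles(self) -> bool:
        return self.total_records == self.emitted + self.dropped_n


@dataclass
class DistStats:
    """Median-centred distribution summary of one per-cell metric."""

    median: float
    mean: float
    q25: float
    q75: float

    @classmethod
    def from_values(cls, values: np.ndarray) -> "DistStats":
        v = np.asarray(values, float)
        return cls(
            median=float(np.median(v)),
            mean=float(np.mean(v)),
            q25=float(np.quantile(v, 0.25)),
            q75=float(np.quantile(v, 0.75)),
        )

    def to_dict(self) -> dict:
        return {"median": self.median, "mean": self.mean, "q25": self.q25, "q75": self.q75}


@dataclass
class QCIndicators:
    """Per-sample quality indicators: genes/cell, transcripts/cell, mito rate."""

    genes_per_cell: DistStats
    transcripts_per_cell: DistStats
    mito_rate_per_cell: DistStats
    n_cells: int

    def to_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "genes_per_cell": self.genes_per_cell.to_dict(),
            "transcripts_per_cell": self.transcripts_per_cell.to_dict(),
            "mito_rate_per_cell": self.mito_rate_per_cell.to_dict(),
        }


@dataclass
class CountMatrix:
    """Sparse genes x barcodes deduplicated transcript counts with metadata.

    ``matrix``      CSR, nonnegative integers, shape (n_genes, n_barcodes)
    ``features``    DataFrame with columns gene_id, species, mito
    ``barcodes``    unique barcode strings, one per column
    ``raw_reads``   per-barcode raw (pre-deduplication) read counts, used for
                    depth accounting; always >= the barcode's transcript total
    """

    matrix: sp.csr_matrix
    features: pd.DataFrame
    barcodes: np.ndarray
    raw_reads: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.matrix.shape != (len(self.features), len(self.barcodes)):
            raise ConsistencyError(
                f"matrix shape {self.matrix.shape} != "
                f"({len(self.features)} features, {len(self.barcodes)} barcodes)"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ConsistencyError("barcodes are not unique")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ConsistencyError("negative entries in count matrix")
        totals = self.totals_per_barcode()
        if self.raw_reads is None:
            self.raw_reads = totals.copy()
        else:
            self.raw_reads = np.asarray(self.raw_reads, dtype=np.int64)
            if self.raw_reads.shape != (len(self.barcodes),):
                raise ConsistencyError("raw_reads length != number of barcodes")
            if np.any(self.raw_reads < totals):
                raise ConsistencyError("raw read count below transcript count for some barcode")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_barcodes(self) -> int:
        return self.matrix.shape[1]

    def totals_per_barcode(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel().astype(np.int64)

    def genes_per_barcode(self) -> np.ndarray:
        return np.asarray((self.matrix > 0).sum(axis=0)).ravel().astype(np.int64)

    def species_counts(self) -> pd.DataFrame:
        """Transcripts per (species, barcode): one column per species label."""
        out = {}
        for spc in self.features["species"].unique():
            mask = (self.features["species"] == spc).to_numpy()
            out[spc] = np.asarray(self.matrix[mask].sum(axis=0)).ravel().astype(np.int64)
        return pd.DataFrame(out, index=self.barcodes)

    def mito_counts(self) -> np.ndarray:
        mask = self.features["mito"].to_numpy(bool)
        return np.asarray(self.matrix[mask].sum(axis=0)).ravel().astype(np.int64)

    def select_barcodes(self, keep: np.ndarray) -> "CountMatrix":
        """Column subset (boolean mask or index array), raw reads carried along."""
        keep = np.asarray(keep)
        return CountMatrix(
            matrix=self.matrix[:, keep].tocsr(),
            features=self.features,
            barcodes=self.barcodes[keep],
            raw_reads=self.raw_reads[keep],
        )

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.matrix.shape == other.matrix.shape
            and (self.matrix != other.matrix).nnz == 0
            and self.features.reset_index(drop=True).equals(other.features.reset_index(drop=True))
            and list(self.barcodes) == list(other.barcodes)
            and np.array_equal(self.raw_reads, other.raw_reads)
        )

    def to_anndata(self):
        """Export as an AnnData (cells x genes) for downstream toolkits."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.matrix.T.tocsr().astype(np.float32),
            obs=pd.DataFrame({"raw_reads": self.raw_reads}, index=list(self.barcodes)),
            var=self.features.set_index("gene_id"),
        )
        return adata


# ---------------------------------------------------------------------------
# Matrix Market directory I/O
# ---------------------------------------------------------------------------

MTX_NAME = "matrix.mtx"
FEATURES_NAME = "features.tsv"
BARCODES_NAME = "barcodes.tsv"
RAW_READS_NAME = "raw_reads.tsv"


def write_count_matrix(m: CountMatrix, path: str | os.PathLike) -> None:
    """Write a CountMatrix as matrix.mtx + features.tsv + barcodes.tsv (+ raw_reads.tsv).

    Coordinate integer Matrix Market, 1-based, genes as rows — the de facto
    single-cell exchange dialect.
    """
    os.makedirs(path, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(path, MTX_NAME), m.matrix.tocoo(), field="integer", symmetry="general"
    )
    m.features.to_csv(
        os.path.join(path, FEATURES_NAME), sep="\t", header=False, index=False,
        columns=["gene_id", "species", "mito"],
    )
    with open(os.path.join(path, BARCODES_NAME), "w") as fh:
        for bc in m.barcodes:
            fh.write(f"{bc}\n")
    pd.DataFrame({"barcode": m.barcodes, "raw_reads": m.raw_reads}).to_csv(
        os.path.join(path, RAW_READS_NAME), sep="\t", header=False, index=False
    )


def read_count_matrix(path: str | os.PathLike) -> CountMatrix:
    """Read a Matrix Market directory back into a CountMatrix.

    Raises :class:`FormatError` naming the offending file on malformed headers,
    dimension mismatches between the matrix and its sidecars, or negative
    entries.
    """
    mtx_path = os.path.join(path, MTX_NAME)
    feat_path = os.path.join(path, FEATURES_NAME)
    bc_path = os.path.join(path, BARCODES_NAME)
    for p in (mtx_path, feat_path, bc_path):
        if not os.path.exists(p):
            raise FormatError(f"missing required file: {p}")
    try:
        mat = scipy.io.mmread(mtx_path)
    except ValueError as exc:
        raise FormatError(f"{mtx_path}: malformed Matrix Market file ({exc})") from exc
    mat = sp.csr_matrix(mat)
    if mat.nnz and mat.data.min() < 0:
        raise FormatError(f"{mtx_path}: negative entries are not valid transcript counts")
    features = pd.read_csv(
        feat_path, sep="\t", header=None, names=["gene_id", "species", "mito"],
        dtype={"gene_id": str, "species": str},
    )
    features["mito"] = features["mito"].astype(bool)
    with open(bc_path) as fh:
        barcodes = np.array([line.rstrip("\n") for line in fh if line.strip()], dtype=object)
    if mat.shape[0] != len(features):
        raise FormatError(
            f"{feat_path}: {len(features)} features but {mtx_path} declares {mat.shape[0]} rows"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"{bc_path}: {len(barcodes)} barcodes but {mtx_path} declares {mat.shape[1]} columns"
        )
    raw_path = os.path.join(path, RAW_READS_NAME)
    raw_reads = None
    if os.path.exists(raw_path):
        rr = pd.read_csv(raw_path, sep="\t", header=None, names=["barcode", "raw_reads"],
                         dtype={"barcode": str})
        if list(rr["barcode"]) != list(barcodes):
            raise FormatError(f"{raw_path}: barcode order differs from {bc_path}")
        raw_reads = rr["raw_reads"].to_numpy(np.int64)
    try:
        return CountMatrix(mat.astype(np.int64), features, barcodes, raw_reads)
    except ConsistencyError as exc:
        raise FormatError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Tagged-read TSV I/O
# ---------------------------------------------------------------------------

def write_tagged_reads(reads: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write tagged reads as headered TSV (barcode, umi, gene, species)."""
    reads[READ_COLUMNS].to_csv(path, sep="\t", index=False)


def read_tagged_reads(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in READ_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing tagged-read columns {missing}")
    return df[READ_COLUMNS]


# ---------------------------------------------------------------------------
# Transcript catalog and FASTQ parsing
# ---------------------------------------------------------------------------

class TranscriptCatalog:
    """Maps cDNA sequence prefixes to gene ids by exact k-mer lookup.

    Stands in for a genome aligner at the quantification stage: a read's gene
    is the unique catalog transcript whose leading ``k`` bases equal the
    read's leading ``k`` bases. Prefixes shared by several transcripts are
    ambiguous and resolve to no gene.
    """

    def __init__(self, transcripts: dict[str, str], k: int = 31):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.transcripts = dict(transcripts)
        index: dict[str, str | None] = {}
        for gene, seq in self.transcripts.items():
            if len(seq) < k:
                raise ValueError(f"transcript for {gene} shorter than k={k}")
            key = seq[:k]
            index[key] = None if key in index else gene
        self._index = index

    def assign(self, r2_sequence: str) -> str:
        gene = self._index.get(r2_sequence[: self.k])
        return gene if gene is not None else UNASSIGNED

    def to_fasta(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for gene, seq in self.transcripts.items():
                fh.write(f">{gene}\n{seq}\n")

    @classmethod
    def from_fasta(cls, path: str | os.PathLike, k: int = 31) -> "TranscriptCatalog":
        from Bio import SeqIO

        transcripts = {rec.id: str(rec.seq) for rec in SeqIO.parse(os.fspath(path), "fasta")}
        return cls(transcripts, k=k)


def parse_fastq_pair(
    r1: str | os.PathLike | io.TextIOBase,
    r2: str | os.PathLike | io.TextIOBase,
    layout: ReadLayout,
    catalog: TranscriptCatalog,
    species_of_gene: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, ParseReport]:
    """Slice barcodes/UMIs from R1 and assign genes to R2 against the catalog.

    Reads whose barcode or UMI contains any ``N`` are dropped and counted.
    Unmatched R2 sequences are kept with gene = ``UNASSIGNED`` (they still
    count toward raw sequencing depth downstream). R1/R2 must be
    record-synchronized; unequal record counts raise
    :class:`SynchronizationError`.

    Returns the tagged-read table and a :class:`ParseReport` satisfying
    ``total_records == emitted + dropped_n``.
    """

    def _open(f):
        if hasattr(f, "read"):
            return f, False
        return open(os.fspath(f)), True

    species_of_gene = species_of_gene or {}
    b0, b1 = layout.barcode_span
    u0, u1 = layout.umi_span
    need = max(b1, u1)

    f1, close1 = _open(r1)
    f2, close2 = _open(r2)
    report = ParseReport()
    rows: list[tuple[str, str, str, str]] = []
    try:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        sentinel = object()
        while True:
            rec1 = next(it1, sentinel)
            rec2 = next(it2, sentinel)
            if rec1 is sentinel and rec2 is sentinel:
                break
            if rec1 is sentinel or rec2 is sentinel:
                short = "R1" if rec1 is sentinel else "R2"
                raise SynchronizationError(
                    f"{short} ended after {report.total_records} records while the mate continues"
                )
            report.total_records += 1
            seq1 = rec1[1].upper()
            if len(seq1) < need:
                raise LayoutError(
                    f"R1 record {report.total_records} has {len(seq1)} bases; "
                    f"layout requires at least {need}"
                )
            barcode = seq1[b0:b1]
            umi = seq1[u0:u1]
            if "N" in barcode or "N" in umi:
                report.dropped_n += 1
                continue
            gene = catalog.assign(rec2[1].upper())
            species = species_of_gene.get(gene, UNASSIGNED)
            rows.append((barcode, umi, gene, species))
            report.emitted += 1
    finally:
        if close1:
            f1.close()
        if close2:
            f2.close()

    reads = pd.DataFrame(rows, columns=READ_COLUMNS)
    return reads, report
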
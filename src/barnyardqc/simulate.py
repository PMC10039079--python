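"""Synthetic barnyard (two-species) experiment generator with known ground truth.

The generator emulates the physical situation of bead-based single-cell
capture in a hydrogel: each cell–bead complex yields one barcode whose
transcripts come mostly from its own cell, a bead occasionally binds a second
cell (a doublet), a small fraction of every barcode's captured transcripts is
ambient material pooled from the whole lysate, and a background of bead-only
barcodes captures ambient transcripts exclusively.  Defaults describe an
equal-proportion human/mouse mixture of 5,000 complexes, matching the
mixed-species benchmarking design this toolkit is built to QC.

Two entry points share one generative model:

* :func:`simulate_count_matrix` — directly emits deduplicated transcript
  counts (fast; no reads, no UMIs);
* :func:`simulate_experiment` — additionally materializes every transcript as
  a (barcode, UMI, gene) record with Poisson PCR duplicates, optionally
  rendered as a FASTQ pair against a random transcript catalog.

Both are deterministic under a fixed seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import BarnyardQCError
from .model_io import (
    READ_COLUMNS,
    CountMatrix,
    ReadLayout,
    TranscriptCatalog,
    make_feature_table,
)

_BASES = np.array(list("ACGT"))

#: ground-truth content labels
EMPTY, SINGLET, DOUBLET = "none", "singlet", "doublet"


@dataclass
class SimConfig:
    """Full generative description of a synthetic barnyard experiment.

    ``transcripts_per_cell`` is the (mean, dispersion) of a negative binomial
    on the number of transcripts a barcode captures (dispersion is the gamma
    shape; variance = mean + mean^2/dispersion). ``ambient_rate`` is the
    fraction of a barcode's transcripts drawn from the pooled cross-cell
    ambient distribution, whose species composition is proportional to total
    cellular transcripts per species. A doublet bead draws its cellular
    transcripts from both member cells with equal weight.
    """

    n_cells_per_species: dict[str, int] = field(
        default_factory=lambda: {"human": 2500, "mouse": 2500}
    )
    doublet_prob: float = 0.06
    ambient_rate: float = 0.01
    transcripts_per_cell: tuple[float, float] = (5000.0, 2.0)
    genes_per_species: int = 500
    mito_fraction: float = 0.03
    dirichlet_alpha: float = 0.05
    reads_per_transcript: float | None = None
    target_raw_reads_per_cell: float | None = None
    n_empty_beads: int = 0
    empty_bead_mean: float = 20.0
    error_rate: float = 0.0
    transcript_length: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("doublet_prob", "ambient_rate", "mito_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if any(n < 0 for n in self.n_cells_per_species.values()):
            raise ValueError("negative cell count")
        if self.n_empty_beads < 0:
            raise ValueError("negative n_empty_beads")
        mean, disp = self.transcripts_per_cell
        if mean <= 0 or disp <= 0:
            raise ValueError("transcripts_per_cell mean and dispersion must be > 0")
        if self.genes_per_species < 1:
            raise ValueError("need at least one gene per species")

    @property
    def species(self) -> list[str]:
        return list(self.n_cells_per_species)

    @property
    def n_complexes(self) -> int:
        return sum(self.n_cells_per_species.values())

    def mean_duplication(self) -> float:
        """Poisson mean of PCR duplicates per transcript."""
        if self.reads_per_transcript is not None:
            return float(self.reads_per_transcript)
        if self.target_raw_reads_per_cell is not None:
            return float(self.target_raw_reads_per_cell) / self.transcripts_per_cell[0]
        return 2.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["transcripts_per_cell"] = list(self.transcripts_per_cell)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "transcripts_per_cell" in d:
            d["transcripts_per_cell"] = tuple(d["transcripts_per_cell"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-barcode truth: cell content and transcript provenance.

    ``table`` columns: barcode, content (none|singlet|doublet),
    species_primary, species_secondary, n_own, n_ambient.
    """

    table: pd.DataFrame

    def is_hetero_doublet(self) -> pd.Series:
        t = self.table
        return (t["content"] == DOUBLET) & (t["species_primary"] != t["species_secondary"])

    def n_cell_barcodes(self) -> int:
        return int((self.table["content"] != EMPTY).sum())

    def write_tsv(self, path: str | os.PathLike) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class SimulatedExperiment:
    """Read-level simulation output: tagged reads plus full provenance."""

    reads: pd.DataFrame  # columns: barcode, umi, gene, species (one row per raw read)
    ground_truth: GroundTruth
    features: pd.DataFrame
    catalog: TranscriptCatalog
    config: SimConfig

    @property
    def n_raw_reads(self) -> int:
        return len(self.reads)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _random_kmers(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """n distinct random k-mers (regenerates the rare duplicate)."""
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        batch = _BASES[rng.integers(0, 4, size=(n - len(out), k))]
        for row in batch:
            s = "".join(row)
            if s not in seen:
                seen.add(s)
                out.append(s)
    return np.array(out, dtype=object)


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    # NB as Gamma(shape=dispersion) mixture of Poissons
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size).astype(np.int64)


def _chunked_multinomial(
    rng: np.random.Generator,
    n_per_barcode: np.ndarray,
    pvals: np.ndarray,
    gene_index: np.ndarray,
    n_genes: int,
    n_barcodes_total: int,
    barcode_index: np.ndarray,
    chunk: int = 8192,
) -> sp.csr_matrix:
    """Multinomial gene draws for many barcodes, assembled sparsely.

    ``n_per_barcode[i]`` transcripts for barcode ``barcode_index[i]`` drawn
    over the genes listed in ``gene_index`` with probabilities ``pvals``.
    Chunked so the dense multinomial block stays small.
    """
    parts = []
    for start in range(0, len(n_per_barcode), chunk):
        ns = n_per_barcode[start : start + chunk]
        if ns.sum() == 0:
            continue
        block = rng.multinomial(ns, pvals)  # (len(ns), len(gene_index))
        rows_local, cols_local = np.nonzero(block)
        parts.append(
            sp.coo_matrix(
                (
                    block[rows_local, cols_local],
                    (gene_index[cols_local], barcode_index[start + rows_local]),
                ),
                shape=(n_genes, n_barcodes_total),
                dtype=np.int64,
            )
        )
    if not parts:
        return sp.csr_matrix((n_genes, n_barcodes_total), dtype=np.int64)
    total = parts[0]
    for p in parts[1:]:
        total = total + p
    return sp.csr_matrix(total)


def _make_features(cfg: SimConfig, rng: np.random.Generator):
    """Feature table, per-species expression profiles and gene index ranges."""
    gene_ids, species_labels, mito_flags = [], [], []
    profiles: dict[str, np.ndarray] = {}
    ranges: dict[str, np.ndarray] = {}
    offset = 0
    n_mito = int(round(cfg.mito_fraction * cfg.genes_per_species))
    for spc in cfg.species:
        for g in range(cfg.genes_per_species):
            is_mito = g < n_mito
            prefix = "MT" if is_mito else "G"
            gene_ids.append(f"{spc}_{prefix}{g:05d}")
            species_labels.append(spc)
            mito_flags.append(is_mito)
        profiles[spc] = rng.dirichlet(np.full(cfg.genes_per_species, cfg.dirichlet_alpha))
        ranges[spc] = np.arange(offset, offset + cfg.genes_per_species)
        offset += cfg.genes_per_species
    features = make_feature_table(gene_ids, species_labels, mito_flags)
    return features, profiles, ranges


def _assign_complexes(cfg: SimConfig, rng: np.random.Generator):
    """Primary/secondary species per complex (doublet = one extra cell)."""
    primary = np.repeat(cfg.species, [cfg.n_cells_per_species[s] for s in cfg.species])
    primary = rng.permutation(primary)
    is_doublet = rng.random(cfg.n_complexes) < cfg.doublet_prob
    secondary = np.where(
        is_doublet, rng.choice(cfg.species, size=cfg.n_complexes), None
    )
    return primary, secondary, is_doublet


# ---------------------------------------------------------------------------
# matrix-level generator
# ---------------------------------------------------------------------------

def simulate_count_matrix(cfg: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Directly emit deduplicated transcript counts under the generative model.

    Bypasses reads and UMIs; matches the read-level pipeline output at zero
    sequencing error up to UMI-collision losses. Raw-read counts are set to
    the transcript totals (the matrix-level shortcut has no duplicate reads).
    """
    if cfg.n_complexes == 0 and cfg.n_empty_beads == 0:
        raise BarnyardQCError("nothing to simulate: zero cells and zero empty beads")

    root = np.random.default_rng(cfg.seed)
    features, profiles, ranges = _make_features(cfg, root)
    n_genes = len(features)

    n_cells = cfg.n_complexes
    n_total = n_cells + cfg.n_empty_beads
    barcodes = _random_kmers(root, n_total, 16)

    primary, secondary, is_doublet = _assign_complexes(cfg, root)

    mean, disp = cfg.transcripts_per_cell
    t_total = _nb_draw(root, mean, disp, n_cells)

    # ambient pool composition: mass-action over total cellular transcripts
    species_mass = np.zeros(len(cfg.species))
    sp_idx = {s: i for i, s in enumerate(cfg.species)}
    for b in range(n_cells):
        if is_doublet[b]:
            species_mass[sp_idx[primary[b]]] += t_total[b] / 2
            species_mass[sp_idx[secondary[b]]] += t_total[b] / 2
        else:
            species_mass[sp_idx[primary[b]]] += t_total[b]
    if species_mass.sum() == 0:
        species_mass[:] = 1.0  # empty-beads-only run: uniform species pool
    ambient_profile = np.zeros(n_genes)
    for s in cfg.species:
        ambient_profile[ranges[s]] = species_mass[sp_idx[s]] * profiles[s]
    ambient_profile /= ambient_profile.sum()

    n_ambient = root.binomial(t_total, cfg.ambient_rate)
    n_own = t_total - n_ambient

    # split a doublet's own transcripts equally between its two member cells
    own_per_species: dict[str, np.ndarray] = {s: np.zeros(n_cells, np.int64) for s in cfg.species}
    half = root.binomial(n_own, 0.5)
    for b in range(n_cells):
        if is_doublet[b]:
            own_per_species[primary[b]][b] += half[b]
            own_per_species[secondary[b]][b] += n_own[b] - half[b]
        else:
            own_per_species[primary[b]][b] += n_own[b]

    cell_ids = np.arange(n_cells)
    mat = sp.csr_matrix((n_genes, n_total), dtype=np.int64)
    for s in cfg.species:
        mat = mat + _chunked_multinomial(
            root, own_per_species[s], profiles[s], ranges[s], n_genes, n_total, cell_ids
        )

    n_ambient_all = np.concatenate(
        [n_ambient, root.poisson(cfg.empty_bead_mean, size=cfg.n_empty_beads)]
    ).astype(np.int64)
    mat = mat + _chunked_multinomial(
        root, n_ambient_all, ambient_profile, np.arange(n_genes), n_genes, n_total,
        np.arange(n_total),
    )
    mat = sp.csr_matrix(mat)

    truth = GroundTruth(
        pd.DataFrame(
            {
                "barcode": barcodes,
                "content": np.concatenate(
                    [
                        np.where(is_doublet, DOUBLET, SINGLET),
                        np.full(cfg.n_empty_beads, EMPTY, dtype=object),
                    ]
                ),
                "species_primary": np.concatenate(
                    [primary, np.full(cfg.n_empty_beads, None, dtype=object)]
                ),
                "species_secondary": np.concatenate(
                    [secondary, np.full(cfg.n_empty_beads, None, dtype=object)]
                ),
                "n_own": np.concatenate([n_own, np.zeros(cfg.n_empty_beads, np.int64)]),
                "n_ambient": n_ambient_all,
            }
        )
    )
    cm = CountMatrix(mat, features, barcodes)
    return cm, truth


# ---------------------------------------------------------------------------
# read-level generator
# ---------------------------------------------------------------------------

def _make_catalog(cfg: SimConfig, features: pd.DataFrame, rng: np.random.Generator) -> TranscriptCatalog:
    transcripts = {
        gid: "".join(_BASES[rng.integers(0, 4, size=cfg.transcript_length)])
        for gid in features["gene_id"]
    }
    return TranscriptCatalog(transcripts)


def _umi_strings(rng: np.random.Generator, n: int, k: int = 12) -> np.ndarray:
    """n UMIs drawn uniformly over 4^k; collisions are allowed and realistic."""
    codes = rng.integers(0, 4 ** k, size=n, dtype=np.int64)
    out = np.empty(n, dtype=object)
    for i, c in enumerate(codes):
        chars = []
        for _ in range(k):
            chars.append("ACGT"[c & 3])
            c >>= 2
        out[i] = "".join(chars)
    return out


def simulate_experiment(cfg: SimConfig) -> SimulatedExperiment:
    """Materialize the experiment at read level.

    Every transcript of the matrix-level model becomes one distinct
    (barcode, UMI, gene) molecule emitted as ``max(1, Poisson(lambda))``
    duplicate reads, where lambda is :meth:`SimConfig.mean_duplication`.
    """
    cm, truth = simulate_count_matrix(cfg)
    # continuation stream, decoupled from the matrix draw but seeded from it
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    catalog = _make_catalog(cfg, cm.features, rng)

    coo = cm.matrix.tocoo()
    gene_ids = cm.features["gene_id"].to_numpy(object)
    # one row per transcript (pre-duplication)
    t_gene = np.repeat(coo.row, coo.data)
    t_bc = np.repeat(coo.col, coo.data)
    n_transcripts = len(t_gene)
    umis = _umi_strings(rng, n_transcripts)
    dup = np.maximum(1, rng.poisson(cfg.mean_duplication(), size=n_transcripts))

    r_gene = np.repeat(t_gene, dup)
    r_bc = np.repeat(t_bc, dup)
    r_umi = np.repeat(umis, dup)
    order = rng.permutation(len(r_gene))  # shuffle: real FASTQs are unsorted
    species = cm.features["species"].to_numpy(object)
    reads = pd.DataFrame(
        {
            "barcode": cm.barcodes[r_bc[order]],
            "umi": r_umi[order],
            "gene": gene_ids[r_gene[order]],
            "species": species[r_gene[order]],
        },
        columns=READ_COLUMNS,
    )
    return SimulatedExperiment(reads, truth, cm.features, catalog, cfg)


def write_fastq_pair(
    exp: SimulatedExperiment,
    r1_path: str | os.PathLike,
    r2_path: str | os.PathLike,
    layout: ReadLayout | None = None,
) -> None:
    """Render a simulated experiment as an R1/R2 FASTQ pair.

    R1 is barcode + UMI padded with 'A' to the layout length; R2 is the first
    ``r2_length`` bases of the gene's catalog transcript. Qualities are
    constant 'I' (Phred 40). A nonzero ``error_rate`` applies uniform random
    substitutions to R2.
    """
    layout = layout or ReadLayout()
    cfg = exp.config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[1])
    pad = "A" * (layout.r1_length - layout.umi_span[1])
    q1 = "I" * layout.r1_length
    q2 = "I" * layout.r2_length
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for i, row in enumerate(exp.reads.itertuples(index=False)):
            seq1 = f"{row.barcode}{row.umi}{pad}"
            seq2 = exp.catalog.transcripts[row.gene][: layout.r2_length]
            if cfg.error_rate > 0:
                seq2 = _mutate(seq2, cfg.error_rate, rng)
            f1.write(f"@read{i}\n{seq1}\n+\n{q1}\n")
            f2.write(f"@read{i}\n{seq2}\n+\n{q2}\n")


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    return "".join(arr)
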
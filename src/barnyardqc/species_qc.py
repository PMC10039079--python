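"""Species purity, assignment and multiplet statistics for barnyard designs.

The central statistic: for a barcode with transcript counts (a, b) over the
two species,

    minority_ratio = min(a, b) / (a + b)        in [0, 1/2]
    impurity       = 2 * minority_ratio         in [0, 1]
    purity         = 1 - impurity               in [0, 1]

Purity estimates the probability that a captured transcript came from the
bead's own main cell, assuming the two species contribute equal total
transcript mass to the ambient pool (the factor 2 corrects for the invisible
same-species half of the contamination).  Thresholds partition barcodes into
three classes:

* purity >= 0.95          -> assigned to the majority species
* 2/3 <= purity < 0.95    -> undefined (gray dots on the barnyard plot)
* purity < 2/3 (strict)   -> hetero-species multiplet

Because a multiplet is equally likely to pair same-species cells as
different-species cells in an equal mixture, the total multiplet rate is
extrapolated as twice the measured hetero-species rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import BarnyardQCError, UnsupportedDesignError
from .model_io import CountMatrix

ASSIGN_PURITY = 0.95
MULTIPLET_PURITY = 2.0 / 3.0
UNDEFINED = "undefined"


@dataclass
class SpeciesSummary:
    """Experiment-level species QC rates (percent of analyzed barcodes)."""

    n_barcodes: int
    class_percent: dict[str, float]  # species A, species B, undefined
    hetero_multiplet_rate: float  # percent
    extrapolated_total_multiplet_rate: float | None  # percent; None if proportions unequal
    species_balance: dict[str, float]  # share of total transcripts per species
    note: str | None = None

    def to_dict(self) -> dict:
        return {
            "n_barcodes": self.n_barcodes,
            "class_percent": self.class_percent,
            "hetero_multiplet_rate": self.hetero_multiplet_rate,
            "extrapolated_total_multiplet_rate": self.extrapolated_total_multiplet_rate,
            "species_balance": self.species_balance,
            "note": self.note,
        }


def purity_from_counts(a: int | float, b: int | float) -> float:
    """purity = 1 - 2 * min(a, b) / (a + b); requires a + b > 0."""
    total = a + b
    if total <= 0:
        raise BarnyardQCError("purity undefined for a barcode with zero transcripts")
    return 1.0 - 2.0 * min(a, b) / total


def purity_table(m: CountMatrix) -> pd.DataFrame:
    """Per-barcode purity records for a two-species count matrix.

    Columns: barcode, count_<speciesA>, count_<speciesB>, minority_ratio,
    impurity, purity, assignment, is_hetero_multiplet.  Barcodes with zero
    transcripts are excluded; their number is available via the DataFrame's
    ``attrs['n_excluded_zero']``.
    """
    species = list(m.features["species"].unique())
    if len(species) != 2:
        raise UnsupportedDesignError(
            f"species QC requires exactly 2 species, found {len(species)}: {species}"
        )
    sa, sb = species
    counts = m.species_counts()
    a = counts[sa].to_numpy(np.int64)
    b = counts[sb].to_numpy(np.int64)
    total = a + b
    nonzero = total > 0

    with np.errstate(invalid="ignore", divide="ignore"):
        minority = np.minimum(a, b) / total
    impurity = 2.0 * minority
    purity = 1.0 - impurity

    # threshold comparisons in exact integer arithmetic so the boundary cases
    # (purity exactly 0.95 -> assigned; exactly 2/3 -> not a multiplet) hold
    net = total - 2 * np.minimum(a, b)  # = purity * total
    assigned_mask = 20 * net >= 19 * total  # purity >= 0.95
    is_multi = 3 * net < 2 * total  # purity < 2/3, strict
    assignment = np.where(a >= b, sa, sb).astype(object)
    assignment[~assigned_mask] = UNDEFINED

    table = pd.DataFrame(
        {
            "barcode": m.barcodes,
            f"count_{sa}": a.astype(np.int64),
            f"count_{sb}": b.astype(np.int64),
            "minority_ratio": minority,
            "impurity": impurity,
            "purity": purity,
            "assignment": assignment,
            "is_hetero_multiplet": is_multi,
        }
    ).loc[nonzero].reset_index(drop=True)
    table.attrs["species"] = (sa, sb)
    table.attrs["n_excluded_zero"] = int((~nonzero).sum())
    return table


def summarize_species(
    records: pd.DataFrame, equal_proportions: bool = True
) -> SpeciesSummary:
    """Experiment-level rates from a purity table.

    With ``equal_proportions`` the total multiplet rate is extrapolated as
    exactly twice the hetero-species rate; for unequal designs no
    extrapolation formula is defined and the field is left empty with a note.
    All class percentages share one denominator: the analyzed barcodes.
    """
    if len(records) == 0:
        raise BarnyardQCError("no records to summarize")
    sa, sb = records.attrs.get(
        "species",
        tuple(c[len("count_"):] for c in records.columns if c.startswith("count_")),
    )
    n = len(records)
    class_percent = {
        label: 100.0 * float((records["assignment"] == label).sum()) / n
        for label in (sa, sb, UNDEFINED)
    }
    hetero = 100.0 * float(records["is_hetero_multiplet"].sum()) / n
    if equal_proportions:
        total_rate, note = 2.0 * hetero, None
    else:
        total_rate = None
        note = (
            "total multiplet rate not extrapolated: the x2 rule assumes equal "
            "species proportions"
        )
    totals = {
        sa: float(records[f"count_{sa}"].sum()),
        sb: float(records[f"count_{sb}"].sum()),
    }
    grand = totals[sa] + totals[sb]
    balance = {s: totals[s] / grand for s in totals}
    return SpeciesSummary(n, class_percent, hetero, total_rate, balance, note)


def barnyard_plot_data(records: pd.DataFrame) -> pd.DataFrame:
    """Scatter data for the barnyard plot: per barcode the two species counts
    and the display class (species label, or gray "undefined" below 95%)."""
    sa, sb = records.attrs.get(
        "species",
        tuple(c[len("count_"):] for c in records.columns if c.startswith("count_")),
    )
    out = pd.DataFrame(
        {
            "barcode": records["barcode"],
            f"count_{sa}": records[f"count_{sa}"],
            f"count_{sb}": records[f"count_{sb}"],
            "class": records["assignment"],
        }
    )
    out.attrs["species"] = (sa, sb)
    return out


def plot_barnyard(records: pd.DataFrame, path: str) -> None:
    """Render the barnyard scatter plot as a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = barnyard_plot_data(records)
    sa, sb = data.attrs["species"]
    colors = {sa: "tab:orange", sb: "teal", UNDEFINED: "gray"}
    fig, ax = plt.subplots(figsize=(5, 5))
    for label, sub in data.groupby("class"):
        ax.scatter(
            sub[f"count_{sa}"], sub[f"count_{sb}"], s=6, alpha=0.5,
            color=colors.get(label, "black"), label=str(label),
        )
    ax.set_xlabel(f"{sa} transcripts")
    ax.set_ylabel(f"{sb} transcripts")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
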
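"""Cell-associated barcode detection from the barcode rank curve.

Barcodes sorted by descending read count form a rank curve whose high plateau
is cell-associated barcodes and whose low plateau is empty-bead background.
The knee separating them is located with a distance-based method on the
cumulative count curve: plotting cumulative reads against barcode rank (both
axes scaled to [0, 1]), the knee is the point of maximum perpendicular
distance to the chord joining the curve's first and last points.  The
cumulative curve rises steeply while ranks still belong to cells and slowly
once only background remains, so the maximum-distance point sits at the
boundary between the two regimes.  Ties break toward smaller rank (more
conservative calling).  A rank curve that is straight on log-log axes
(identical counts, or an exact power law) has no cell/background structure
and is rejected as knee-less.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import BarnyardQCError, InsufficientDataError, NoKneeError

MIN_BARCODES = 100
_FLAT_TOL = 1e-6


@dataclass
class RankCurve:
    """Barcodes sorted by descending count, with log-log coordinates."""

    barcodes: np.ndarray
    counts: np.ndarray  # non-increasing, all >= 1
    log_rank: np.ndarray
    log_count: np.ndarray

    @classmethod
    def from_counts(
        cls, counts: dict[str, float] | pd.Series, min_barcodes: int = MIN_BARCODES
    ) -> "RankCurve":
        s = pd.Series(counts, dtype=float)
        s = s[s >= 1]
        if len(s) < min_barcodes:
            raise InsufficientDataError(
                f"{len(s)} barcodes with count >= 1; need at least {min_barcodes}"
            )
        # sort by (-count, barcode) for a deterministic order among ties
        s = s.sort_index().sort_values(ascending=False, kind="stable")
        cnt = s.to_numpy(float)
        ranks = np.arange(1, len(s) + 1, dtype=float)
        return cls(
            barcodes=s.index.to_numpy(object),
            counts=cnt,
            log_rank=np.log10(ranks),
            log_count=np.log10(cnt),
        )


@dataclass
class CellCallResult:
    """Outcome of cell calling: knee position, threshold, called barcode set."""

    knee_rank: int
    threshold: float
    cell_barcodes: frozenset[str]
    curve: RankCurve
    method: str = "knee"

    def __post_init__(self) -> None:
        assert len(self.cell_barcodes) == self.knee_rank

    @property
    def n_cells(self) -> int:
        return self.knee_rank

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "knee_rank": self.knee_rank,
            "threshold": self.threshold,
            "n_cells": self.n_cells,
            "cell_barcodes": sorted(self.cell_barcodes),
        }


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(y) < window:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(y, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + len(y)]
    return out


def _perpendicular_distances(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Distance of each curve point to the chord from first to last point."""
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    dx, dy = x1 - x0, y1 - y0
    norm = np.hypot(dx, dy)
    if norm == 0:
        return np.zeros_like(x)
    return np.abs(dy * (x - x0) - dx * (y - y0)) / norm


def call_cells(
    counts: dict[str, float] | pd.Series, smoothing_window: int = 15
) -> CellCallResult:
    """Distance-based knee calling on the barcode rank curve.

    Counts are moving-average smoothed (window in ranks) before the
    cumulative curve is formed; the threshold is the *unsmoothed* count at
    the knee rank. All barcodes with count strictly above the threshold are
    called, plus barcodes equal to it, in deterministic (count, barcode)
    order, up to the knee rank.

    Raises :class:`NoKneeError` when the log-log rank curve is straight to
    within tolerance (identical counts, or an exact power law): such curves
    carry no cell/background distinction for a knee to mark.
    """
    curve = RankCurve.from_counts(counts)
    raw_dist = _perpendicular_distances(curve.log_rank, curve.log_count)
    if raw_dist.max() < _FLAT_TOL:
        raise NoKneeError(
            "rank curve is straight on log-log axes (no knee); "
            "use manual_threshold with an expected cell count"
        )
    smoothed = _moving_average(curve.counts, smoothing_window)
    cum = np.cumsum(smoothed)
    # normalize both axes so the chord geometry is unit-free
    x = np.arange(1, len(cum) + 1, dtype=float) / len(cum)
    y = cum / cum[-1]
    dist = _perpendicular_distances(x, y)
    knee_idx = int(np.argmax(dist))  # argmax takes the first max: smaller rank wins ties
    knee_rank = knee_idx + 1
    threshold = float(curve.counts[knee_idx])
    called = frozenset(curve.barcodes[:knee_rank])
    return CellCallResult(knee_rank, threshold, called, curve, method="knee")


def manual_threshold(
    counts: dict[str, float] | pd.Series, n_expected_cells: int
) -> CellCallResult:
    """Call the top ``n_expected_cells`` barcodes by count.

    Fallback for experiments where an independent cell-number estimate exists
    (e.g. microscope counts of cell–bead complexes). Boundary ties break
    lexicographically by barcode.
    """
    if n_expected_cells < 1:
        raise BarnyardQCError("n_expected_cells must be >= 1")
    curve = RankCurve.from_counts(counts, min_barcodes=1)
    if n_expected_cells > len(curve.barcodes):
        raise BarnyardQCError(
            f"n_expected_cells={n_expected_cells} exceeds {len(curve.barcodes)} barcodes"
        )
    called = frozenset(curve.barcodes[:n_expected_cells])
    return CellCallResult(
        n_expected_cells,
        float(curve.counts[n_expected_cells - 1]),
        called,
        curve,
        method="manual",
    )


def plot_rank_curve(result: CellCallResult, path: str) -> None:
    """Diagnostic PNG: rank curve with the chosen knee point marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    c = result.curve
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(10 ** c.log_rank, c.counts, lw=1)
    ax.axvline(result.knee_rank, color="red", ls="--", lw=1,
               label=f"knee rank {result.knee_rank}")
    ax.axhline(result.threshold, color="gray", ls=":", lw=1,
               label=f"threshold {result.threshold:.0f}")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("barcode rank")
    ax.set_ylabel("count")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
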
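"""Experiment-design calculators for bead-based hydrogel single-cell prep.

Three small estimators used when planning or sanity-checking a run:

* expected cells in the sequencing data, from microscope-counted cell–bead
  complexes and the observed bead recovery rate of the sequenced PCR tubes;
* input cells represented per PCR tube after the amplification split;
* mean center-to-center spacing of complexes immobilized in the gel, which
  controls lysate crosstalk between neighbouring beads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import BarnyardQCError

#: mean nearest-neighbour distance of a homogeneous Poisson point process is
#: Gamma(4/3) / (4*pi*density/3)^(1/3) ~= 0.5539 * density^(-1/3)
POISSON_NN_CONSTANT = 0.5539

MM3_PER_ML = 1000.0
UM_PER_MM = 1000.0


@dataclass(frozen=True)
class BeadYieldModel:
    """Inputs of the expected-cells calculation.

    ``bead_recovery_rate`` is the observed per-tube recovery fraction; with
    the sample split across ``n_tubes`` PCR tubes a single tube can hold at
    most ``1/n_tubes`` of the beads (12.5% for the standard 8-tube split).
    """

    n_complexes: int
    bead_recovery_rate: float
    n_tubes: int = 8
    n_tubes_sequenced: int = 1

    def __post_init__(self) -> None:
        if self.n_complexes < 0:
            raise BarnyardQCError("n_complexes must be >= 0")
        if not 0.0 <= self.bead_recovery_rate <= 1.0:
            raise BarnyardQCError("bead_recovery_rate outside [0, 1]")
        if self.n_tubes < 1 or not 1 <= self.n_tubes_sequenced <= self.n_tubes:
            raise BarnyardQCError("need 1 <= n_tubes_sequenced <= n_tubes")
        cap = 1.0 / self.n_tubes
        if self.bead_recovery_rate > cap + 1e-12:
            raise BarnyardQCError(
                f"per-tube recovery rate {self.bead_recovery_rate} exceeds the "
                f"1/{self.n_tubes} = {cap:.4f} cap"
            )


@dataclass(frozen=True)
class GelGeometry:
    n_cells: int
    gel_volume_ml: float

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.gel_volume_ml <= 0:
            raise BarnyardQCError("n_cells and gel_volume_ml must be > 0")


def expected_cells_in_data(model: BeadYieldModel) -> dict:
    """Estimated number of cells the sequenced tubes will yield.

    The estimate is the product of the number of cell-coupled beads and the
    per-tube bead recovery rate, summed over the sequenced tubes; microscope
    counting error is not propagated.
    """
    estimate = model.n_complexes * model.bead_recovery_rate * model.n_tubes_sequenced
    return {
        "expected_cells": int(round(estimate)),
        "n_complexes": model.n_complexes,
        "bead_recovery_rate": model.bead_recovery_rate,
        "n_tubes_sequenced": model.n_tubes_sequenced,
    }


def tube_fraction(input_cells: int, n_tubes: int = 8) -> dict:
    """Input cells represented by each PCR tube after the amplification split."""
    if n_tubes < 1:
        raise BarnyardQCError("n_tubes must be >= 1")
    per_tube = input_cells / n_tubes
    return {
        "cells_per_tube": per_tube,
        "floor": math.floor(per_tube),
        "ceil": math.ceil(per_tube),
    }


def mean_complex_spacing(g: GelGeometry, estimator: str = "cube_root") -> float:
    """Mean center-to-center distance (µm) between complexes in the gel.

    ``cube_root``: lattice-like spacing (volume per cell)^(1/3).
    ``poisson_nn``: mean nearest-neighbour distance of a homogeneous Poisson
    process at the same density, 0.5539 * (n/volume)^(-1/3) — always
    0.5539x the cube-root figure.
    """
    volume_mm3 = g.gel_volume_ml * MM3_PER_ML
    cube = (volume_mm3 / g.n_cells) ** (1.0 / 3.0) * UM_PER_MM
    if estimator == "cube_root":
        return cube
    if estimator == "poisson_nn":
        return POISSON_NN_CONSTANT * cube
    raise BarnyardQCError(f"unknown spacing estimator {estimator!r}")
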
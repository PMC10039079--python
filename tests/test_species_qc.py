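from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from barnyardqc import (
    SimConfig,
    UnsupportedDesignError,
    barnyard_plot_data,
    purity_from_counts,
    purity_table,
    simulate_count_matrix,
    summarize_species,
)
from barnyardqc.species_qc import MULTIPLET_PURITY, UNDEFINED


def matrix_from_species_counts(make_toy_matrix, two_species_features, pairs, raw=None):
    """One barcode per (human_count, mouse_count) pair, using one gene per species."""
    dense = np.zeros((6, len(pairs)), dtype=int)
    for j, (a, b) in enumerate(pairs):
        dense[0, j] = a  # hA
        dense[3, j] = b  # mA
    barcodes = [f"BC{j:04d}" for j in range(len(pairs))]
    return make_toy_matrix(dense, two_species_features, barcodes, raw)


class TestPurityFormula:
    @pytest.mark.parametrize(
        "a,b,purity,multiplet",
        [
            (100, 0, 1.0, False),
            (75, 25, 0.5, True),
            (50, 50, 0.0, True),
            (95, 5, 0.9, False),   # undefined band, not a multiplet
        ],
    )
    def test_examples(self, a, b, purity, multiplet):
        assert purity_from_counts(a, b) == pytest.approx(purity)
        assert (purity_from_counts(a, b) < MULTIPLET_PURITY) == multiplet

    def test_exhaustive_against_brute_force(self):
        """purity == 1 - 2*min(a,b)/(a+b) exactly, for every a+b <= 50."""
        for a in range(51):
            for b in range(51 - a):
                if a + b == 0:
                    continue
                oracle = 1 - Fraction(2 * min(a, b), a + b)
                assert purity_from_counts(a, b) == pytest.approx(float(oracle), abs=1e-12)

    @given(
        a=st.integers(0, 10_000),
        b=st.integers(0, 10_000),
        c=st.integers(1, 100),
    )
    def test_label_swap_and_scale_invariance(self, a, b, c):
        if a + b == 0:
            return
        p = purity_from_counts(a, b)
        assert purity_from_counts(b, a) == pytest.approx(p)
        assert purity_from_counts(c * a, c * b) == pytest.approx(p)


class TestPurityTable:
    def test_thresholds_partition_barcodes(self, make_toy_matrix, two_species_features):
        # purities: 1.0 (pure), 0.95 (exactly assignable), 0.9 (undefined),
        # 2/3 exactly (undefined, NOT multiplet), 0.5 (multiplet)
        pairs = [(100, 0), (975, 25), (95, 5), (5, 1), (75, 25)]
        m = matrix_from_species_counts(make_toy_matrix, two_species_features, pairs)
        rec = purity_table(m)
        assert list(rec["assignment"]) == ["human", "human", UNDEFINED, UNDEFINED, UNDEFINED]
        assert list(rec["is_hetero_multiplet"]) == [False, False, False, False, True]
        assert rec["purity"].iloc[3] == pytest.approx(2 / 3)

    def test_zero_transcript_barcodes_excluded(self, make_toy_matrix, two_species_features):
        pairs = [(10, 0), (0, 0)]
        m = matrix_from_species_counts(make_toy_matrix, two_species_features, pairs)
        rec = purity_table(m)
        assert len(rec) == 1
        assert rec.attrs["n_excluded_zero"] == 1

    def test_three_species_design_rejected(self, make_toy_matrix):
        from barnyardqc import make_feature_table

        ft = make_feature_table(
            ["g1", "g2", "g3"], ["human", "mouse", "rat"], [False] * 3
        )
        m = make_toy_matrix([[1], [1], [1]], ft, ["BC1"])
        with pytest.raises(UnsupportedDesignError):
            purity_table(m)

    def test_label_symmetry_of_whole_table(self, make_toy_matrix, two_species_features):
        pairs = [(100, 3), (40, 60), (7, 7)]
        m = matrix_from_species_counts(make_toy_matrix, two_species_features, pairs)
        swapped = matrix_from_species_counts(
            make_toy_matrix, two_species_features, [(b, a) for a, b in pairs]
        )
        r1, r2 = purity_table(m), purity_table(swapped)
        assert np.allclose(r1["purity"], r2["purity"])
        assert (r1["is_hetero_multiplet"] == r2["is_hetero_multiplet"]).all()


class TestSummarize:
    def test_three_multiplets_of_hundred(self, make_toy_matrix, two_species_features):
        pairs = [(100, 0)] * 49 + [(0, 100)] * 48 + [(50, 50)] * 3
        m = matrix_from_species_counts(make_toy_matrix, two_species_features, pairs)
        s = summarize_species(purity_table(m), equal_proportions=True)
        assert s.hetero_multiplet_rate == pytest.approx(3.0)
        assert s.extrapolated_total_multiplet_rate == pytest.approx(6.0)
        assert s.class_percent["human"] == pytest.approx(49.0)

    def test_all_pure_gives_zero_rates(self, make_toy_matrix, two_species_features):
        pairs = [(10, 0)] * 60 + [(0, 10)] * 60
        s = summarize_species(purity_table(
            matrix_from_species_counts(make_toy_matrix, two_species_features, pairs)
        ))
        assert s.hetero_multiplet_rate == 0.0
        assert s.extrapolated_total_multiplet_rate == 0.0

    def test_unequal_proportions_omit_extrapolation(self, make_toy_matrix, two_species_features):
        pairs = [(10, 0)] * 100
        s = summarize_species(purity_table(
            matrix_from_species_counts(make_toy_matrix, two_species_features, pairs)
        ), equal_proportions=False)
        assert s.extrapolated_total_multiplet_rate is None
        assert "equal species proportions" in s.note

    def test_extrapolation_factor_exactly_two(self, make_toy_matrix, two_species_features):
        rng = np.random.default_rng(0)
        pairs = [(int(rng.integers(1, 100)), int(rng.integers(0, 100))) for _ in range(200)]
        s = summarize_species(purity_table(
            matrix_from_species_counts(make_toy_matrix, two_species_features, pairs)
        ))
        if s.hetero_multiplet_rate > 0:
            assert s.extrapolated_total_multiplet_rate / s.hetero_multiplet_rate == 2.0

    def test_recovers_doublet_rate_from_simulation(self):
        """Across seeds, measured hetero rate ~ doublet_prob/2 (equal species)."""
        rates, n_total = [], 0
        for seed in range(10):
            cfg = SimConfig(
                n_cells_per_species={"human": 500, "mouse": 500},
                transcripts_per_cell=(500.0, 2.0),
                genes_per_species=100,
                seed=seed,
            )
            cm, _ = simulate_count_matrix(cfg)
            s = summarize_species(purity_table(cm))
            rates.append(s.hetero_multiplet_rate / 100)
            n_total += cfg.n_complexes
        p = 0.06 * 0.5
        se = np.sqrt(p * (1 - p) / n_total)
        assert abs(np.mean(rates) - p) <= 3 * se


class TestBarnyardPlotData:
    def test_classes_follow_95_percent_rule(self, make_toy_matrix, two_species_features):
        pairs = [(100, 0), (0, 100), (90, 10)]
        data = barnyard_plot_data(purity_table(
            matrix_from_species_counts(make_toy_matrix, two_species_features, pairs)
        ))
        assert list(data["class"]) == ["human", "mouse", UNDEFINED]
        assert data["count_human"].iloc[0] == 100
        assert data["count_mouse"].iloc[0] == 0

    def test_gray_fraction_matches_generative_model(self):
        """Simulated gray (purity<95%) fraction ~ doublet + low-purity singlet share."""
        cfg = SimConfig(seed=5)
        cm, truth = simulate_count_matrix(cfg)
        rec = purity_table(cm)
        gray = (rec["assignment"] == UNDEFINED).mean()
        doublet_frac = (truth.table["content"] == "doublet").mean()
        hetero_frac = truth.is_hetero_doublet().mean()
        # every hetero doublet is gray; homo doublets and ambient singlets rarely are
        assert gray >= hetero_frac * 0.9
        assert gray <= doublet_frac + 0.02
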
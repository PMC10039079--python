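import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import settings

from barnyardqc import CountMatrix, SimConfig, make_feature_table, simulate_experiment

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A read-level simulation small enough for per-test use."""
    return SimConfig(
        n_cells_per_species={"human": 40, "mouse": 40},
        transcripts_per_cell=(300.0, 8.0),
        genes_per_species=60,
        n_empty_beads=400,
        empty_bead_mean=10.0,
        reads_per_transcript=2.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_experiment(small_cfg):
    return simulate_experiment(small_cfg)


@pytest.fixture()
def two_species_features() -> pd.DataFrame:
    return make_feature_table(
        ["hA", "hB", "hMT", "mA", "mB", "mMT"],
        ["human"] * 3 + ["mouse"] * 3,
        [False, False, True, False, False, True],
    )


def toy_matrix(dense, features, barcodes, raw_reads=None) -> CountMatrix:
    return CountMatrix(
        sp.csr_matrix(np.asarray(dense, dtype=np.int64)),
        features,
        np.asarray(barcodes, dtype=object),
        raw_reads,
    )


@pytest.fixture()
def make_toy_matrix():
    return toy_matrix
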
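import numpy as np
import pandas as pd
import pytest

from sortscan.pipeline import run_end_to_end
from sortscan.synthetic import SimConfig
from sortscan.variant_model import ProteinReference


@pytest.fixture(scope="session")
def toy_reference() -> ProteinReference:
    # M K R L T V  (no stops), mutagenized residues 2..5
    return ProteinReference(
        name="toy",
        coding_sequence="ATGAAACGGCTGACCGTG",
        mutagenized_range=(2, 5),
    )


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        seed=7,
        n_positions=30,
        tmd_segments=((8, 18),),
        n_synonymous=8,
        n_nonsense=6,
        cells_sorted=20_000,
        reads_per_bin=50_000,
        n_replicates=3,
    )


@pytest.fixture(scope="session")
def end_to_end(default_config):
    """Full-scale simulated experiment, scored for both assays."""
    return run_end_to_end(default_config, assays=("abundance", "activity"))


@pytest.fixture(scope="session")
def abundance_scores(end_to_end) -> pd.DataFrame:
    return end_to_end.merged("abundance")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
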
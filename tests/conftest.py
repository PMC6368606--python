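import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from springdiv.seqcluster import ProteinRecord
from springdiv.synthetic import SyntheticConfig, generate_study

#: Conditions for tiny clustering fixtures: few, well-separated families with
#: tight within-family identity, small enough for all-pairs oracles.
TINY_STUDY_KWARGS = dict(
    n_springs=2,
    pool_size=8,
    richness_intercept=4,
    richness_slope=0.0,
    richness_noise_sd=0.0,
    abundance_mu=0.3,
    abundance_shape=0.8,
    n_mags=4,
    tree_tips=10,
    n_genome_pairs=2,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_study():
    """A small deterministic study shared by read-only tests."""
    return generate_study(SyntheticConfig(seed=11, **TINY_STUDY_KWARGS))


@pytest.fixture(scope="session")
def default_study():
    """One full-size study at the default conditions (40 springs)."""
    return generate_study(SyntheticConfig(seed=5))


def make_records(seqs: dict[str, str], metagenome: str = "MG1") -> list[ProteinRecord]:
    return [ProteinRecord(pid, metagenome, s) for pid, s in seqs.items()]
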
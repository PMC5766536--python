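import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from ecrtmine.scoring import ScoringScheme
from ecrtmine.synthetic import DecayModel, make_benchmark_bundle, make_rt_references

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def scoring():
    return ScoringScheme()


@pytest.fixture(scope="session")
def refs():
    """Toy RT references: 8 caulimovirid leaves in 2 OTUs + 4 gypsy decoys."""
    return make_rt_references(seed=5)


@pytest.fixture(scope="session")
def small_bundle():
    """Two 60 kb genomes with lightly decayed insertions (substitutions only)."""
    return make_benchmark_bundle(
        seed=11,
        n_genomes=2,
        genome_length=60_000,
        n_caulimovirid=5,
        n_decoy=3,
        decay_model=DecayModel(sub_rate=0.05),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
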
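import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from cytopan.synthetic_data import SimParams, simulate_pangenome


@pytest.fixture(scope="session")
def small_pangenome():
    """A small simulated pangenome shared by clustering/curation/
    pangenome tests (6 genomes, fixed seed)."""
    params = SimParams(
        n_genomes=6,
        n_core=6,
        n_accessory=8,
        presence_prob=0.7,
        singleton_rate=2.0,
        dup_prob=0.15,
        gene_length_codons=(40, 80),
        seed=42,
    )
    return simulate_pangenome(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
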
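import numpy as np
import pytest

from paramatch.optim import OptimizerConfig
from paramatch.scoring import SyntheticCouplingScorer
from paramatch.synth import SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_problem():
    """A small planted benchmark: 4 species of 3, short alignments."""
    spec = SyntheticSpec(
        n_species=4,
        min_size=3,
        max_size=3,
        len_a=20,
        len_b=14,
        n_coevolving=6,
        leakage=0.05,
    )
    dataset, truth, coupling = generate_dataset(spec, np.random.default_rng(7))
    return dataset, truth, SyntheticCouplingScorer(coupling)


@pytest.fixture
def fast_config():
    """Shortened optimization schedule for unit tests."""
    return OptimizerConfig(n_probe_runs=3, probe_steps=8, main_steps=60, q=60)
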
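"""Shared fixtures: all test data is generated programmatically."""

import random

import pytest

from hybriseq.signatures import builtin_catalog
from hybriseq.simulate import (
    SimulationConfig,
    generate_read_pairs,
    simulate_transcriptome,
)


@pytest.fixture(scope="session")
def rat_catalog():
    return builtin_catalog("rat")


@pytest.fixture(scope="session")
def mouse_catalog():
    return builtin_catalog("mouse")


@pytest.fixture(scope="session")
def small_clone():
    """A modest rat IgG2b/kappa clone: 20k pairs, 60 background transcripts."""
    config = SimulationConfig(n_pairs=20000, n_background=60, seed=11)
    truth = simulate_transcriptome(config)
    pairs = generate_read_pairs(truth, config)
    return config, truth, pairs


@pytest.fixture(scope="session")
def default_clone():
    """The default study conditions: rat IgG2b/kappa, 100k pairs, seed 1."""
    config = SimulationConfig(n_pairs=100000, seed=1)
    truth = simulate_transcriptome(config)
    pairs = generate_read_pairs(truth, config)
    return config, truth, pairs


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))
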
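"""Shared fixtures: small synthetic cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from ribbonquant.synth import StackSpec, generate_neuromast_stack


@pytest.fixture(scope="session")
def noiseless_stack():
    """A small noiseless stack (3 cells, 10 complete + 1 + 1 per cell)."""
    spec = StackSpec(
        n_hair_cells=3,
        complete_per_cell=10,
        unpaired_pre_per_cell=1,
        unpaired_post_per_cell=1,
        photon_gain=0.0,
        read_noise_sd=0.0,
        seed=42,
    )
    stack, truth = generate_neuromast_stack(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def noisy_stack():
    """Same structure at default noise."""
    spec = StackSpec(
        n_hair_cells=3,
        complete_per_cell=10,
        unpaired_pre_per_cell=1,
        unpaired_post_per_cell=1,
        seed=43,
    )
    stack, truth = generate_neuromast_stack(spec)
    return spec, stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
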
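import numpy as np
import pytest

import genomesize as gs


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture(scope="session")
def bacterial_rates():
    return gs.MutationRates.bacterial_defaults()


@pytest.fixture(scope="session")
def indel40():
    return gs.IndelSizeModel.uniform(40)


@pytest.fixture(scope="session")
def uniform_rearr():
    return gs.RearrangementSizeModel.uniform()


@pytest.fixture(scope="session")
def lognormal_rearr():
    return gs.RearrangementSizeModel.truncated_lognormal()


@pytest.fixture(scope="session")
def ma_uniform():
    return gs.ExperimentConfig.mutation_accumulation("uniform")


@pytest.fixture(scope="session")
def ma_lognormal():
    return gs.ExperimentConfig.mutation_accumulation("lognormal")


@pytest.fixture(scope="session")
def scaled_rates():
    """Bacterial rate ratios (2:2:1:1) scaled up so that a few events occur
    per generation at window-sized genomes — used for chain numerics."""
    return gs.MutationRates(0.008, 0.008, 0.004, 0.004)
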
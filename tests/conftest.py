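import numpy as np
import pytest

from audenc.datasets import generate_stimulus_bank, random_ground_truth, simulate_neuron
from audenc.spectrogram import gammatone_center_frequencies


@pytest.fixture(scope="session")
def small_bank():
    """A small smooth-contrast bank shared by fitting tests."""
    return generate_stimulus_bank("smooth_contrast", n_stimuli=8, duration_s=1.5, seed=7)


@pytest.fixture(scope="session")
def ln_neuron(small_bank):
    return random_ground_truth("LN", seed=77, bank=small_bank)


@pytest.fixture(scope="session")
def ln_response(ln_neuron, small_bank):
    return simulate_neuron(ln_neuron, small_bank)


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.Philox(np.random.SeedSequence(1234)))


@pytest.fixture()
def centers18():
    return gammatone_center_frequencies(18)
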
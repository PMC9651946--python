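import numpy as np
import pytest

from flygaze import analysis, flysim


@pytest.fixture(scope="session")
def components() -> flysim.LoopComponents:
    return flysim.default_fly()


@pytest.fixture(scope="session")
def stim_freqs() -> np.ndarray:
    return np.array([0.7, 1.0, 1.5, 2.1, 3.5, 5.3, 10.6])


@pytest.fixture(scope="session")
def truth(components, stim_freqs) -> dict:
    return flysim.closed_loop_truth(components, stim_freqs)


@pytest.fixture(scope="session")
def population5(components):
    """Five synthetic flies, 0.25 deg tracking noise, full battery.

    Session-scoped because several recovery checks share it.
    """
    return analysis.identify_population(components, 5, noise_std=0.25, seed=0)


@pytest.fixture(scope="session")
def population1_clean(components):
    """One noise-free synthetic fly, full battery."""
    return analysis.identify_population(components, 1, noise_std=0.0, seed=11)
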
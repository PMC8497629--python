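import itertools

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def enumerate_boltzmann(J: np.ndarray, beta: float):
    """Exhaustive Boltzmann distribution of an N <= 14 spin system.

    Returns (states (2^N, N), probabilities) for
    P(s) ~ exp(beta/2 sum_ij J_ij s_i s_j) (full double sum).
    """
    N = J.shape[0]
    states = np.array(list(itertools.product([-1.0, 1.0], repeat=N)))
    energies = -0.5 * np.einsum("si,ij,sj->s", states, J, states)
    w = np.exp(-beta * (energies - energies.min()))
    return states, w / w.sum()


@pytest.fixture
def boltzmann_oracle():
    return enumerate_boltzmann
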
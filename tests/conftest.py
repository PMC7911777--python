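"""Shared fixtures: the oracle-checkable two-neuron network and cached
simulated ensembles (session-scoped; everything is generated at test time
from fixed seeds)."""

import numpy as np
import pytest

import lifresponse as lr
from lifresponse.experiments import tiny_network, tiny_pulse_stimulus


@pytest.fixture(scope="session")
def tiny_params():
    """Two-neuron, gamma=0 network: the spike process is exactly the
    memory-1 Markov chain with product-of-Gaussian-tails transitions, so
    every depth-D oracle is exact for the simulator."""
    return tiny_network()


@pytest.fixture(scope="session")
def tiny_chain(tiny_params):
    chain = lr.markov.build_block_chain(tiny_params, 2)
    p_inv = lr.markov.invariant_distribution(chain)
    return chain, p_inv


@pytest.fixture(scope="session")
def tiny_spont(tiny_params):
    """Spontaneous ensemble with ~4e5 pooled samples (kernel-grade)."""
    return lr.simulate_ensemble(tiny_params, None, t_steps=2000, burn_in=20,
                                m_trials=200, master_seed=11)


@pytest.fixture(scope="session")
def tiny_stimulus():
    return tiny_pulse_stimulus(0.3, t_steps=40)


@pytest.fixture(scope="session")
def random_raster():
    """Arbitrary (not dynamics-consistent) raster for definition-level tests."""
    rng = np.random.default_rng(5)
    return lr.SpikeRaster((rng.random((3, 20)) < 0.3).astype(np.uint8), n_min=0)


@pytest.fixture(scope="session")
def iid_ensemble():
    """Hand-built i.i.d. Bernoulli(0.3) trial ensemble (binomial oracle)."""
    rng = np.random.default_rng(77)
    p = 0.3
    spikes = (rng.random((400, 2, 250)) < p).astype(np.uint8)
    params = lr.NetworkParameters(2, np.zeros((2, 2)), 0.0, 1.0, 0.0, 1.0)
    ens = lr.simulate.TrialEnsemble(spikes=spikes, params=params, stimulus=None,
                                    burn_in=0, t_steps=250)
    ens.meta["p"] = p
    return ens
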
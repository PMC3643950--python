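import numpy as np
import pytest

import intentnet as inet


@pytest.fixture(scope="session")
def topo():
    return inet.make_topology(14, 10)


@pytest.fixture(scope="session")
def tiny_topo():
    """3 beliefs, 2 hidden per bank: small enough for brute-force oracles."""
    return inet.make_topology(3, 2)


@pytest.fixture(scope="session")
def tiny_weights(tiny_topo):
    return inet.init_weights(tiny_topo, seed=42, scale=0.3)


@pytest.fixture(scope="session")
def trained_f10v():
    """Weights learned from a synthetic belief survey calibrated to the
    10th-grade-virgin group, plus the survey itself."""
    w, pats, responses, trace = inet.train_group_weights(seed=456, group="F10V")
    return w, pats, responses


@pytest.fixture(scope="session")
def trained_p25():
    """A P25-trained weight set shared across simulation tests.

    Training is the expensive step (~3 s); session scope keeps the suite
    fast while every test still exercises the real pipeline.
    """
    w, pats, trace = inet.train_probabilistic_weights(seed=123)
    return w, pats, trace
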
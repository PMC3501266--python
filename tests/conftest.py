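"""Shared fixtures: the canonical direction-selectivity model instances."""

import numpy as np
import pytest

import pulsefield as pf

KAPPA = 4.0


@pytest.fixture(scope="session")
def kernel():
    return pf.presets.KERNEL


@pytest.fixture(scope="session")
def firing():
    return pf.FiringRule(kappa=KAPPA)


@pytest.fixture(scope="session")
def free_pulses(kernel):
    """Both traveling-pulse branches at kappa = 4 (slower/wider first)."""
    pulses = pf.solve_free_pulses(kernel, KAPPA)
    assert len(pulses) == 2
    return pulses


@pytest.fixture(scope="session")
def stable_pulse(free_pulses):
    return free_pulses[0]


@pytest.fixture(scope="session")
def fast_pulse(free_pulses):
    return free_pulses[1]


@pytest.fixture(scope="session")
def noise():
    """Standard multiplicative noise: eps=0.005, g(U)=U, lattice C(0)=10."""
    return pf.NoiseModel(eps=0.005, g0=1.0, g_kind="linear", C0=10.0)


@pytest.fixture(scope="session")
def effective(kernel, noise):
    return pf.effective_pulse(kernel, KAPPA, noise)


@pytest.fixture(scope="session")
def locked_strong(kernel):
    """Locked pulses for the strong slow stimulus (I0=8, d=5, v=3)."""
    s = pf.StimulusSpec(I0=8.0, width_d=5.0, v=3.0)
    return pf.solve_locked(kernel, s, KAPPA, classify=True)


@pytest.fixture(scope="session")
def locked_tongue_set(kernel):
    """Locked pulses for the in-tongue stimulus (I0=5, d=5, v=5)."""
    s = pf.StimulusSpec(I0=5.0, width_d=5.0, v=5.0)
    return pf.solve_locked(kernel, s, KAPPA, classify=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
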
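"""Named parameter presets for the standard direction-selectivity experiments.

All experiments in this model family are parameter sets, not data files;
the presets collect the canonical combinations (kernel, threshold, noise,
stimulus, grid) so that scans and reproductions are one call.
"""

from __future__ import annotations

from .kernels import WeightKernel
from .free_pulse import FiringRule
from .stimulus_locked import StimulusSpec
from .stochastic_sim import NoiseModel, SimGrid

__all__ = [
    "KERNEL",
    "FIRING",
    "NOISE",
    "STIMULUS_LOCKING",
    "STIMULUS_STRONG",
    "grid_for",
]

#: Offset Mexican-hat kernel of the direction-selectivity model
#: (a_e=5, a_i=1, sigma_e=0.42, sigma_i=0.1), offset x0=3.
KERNEL = WeightKernel(a_e=5.0, a_i=1.0, sigma_e=0.42, sigma_i=0.1, x0=3.0)

#: Heaviside firing with threshold kappa=4.
FIRING = FiringRule(kappa=4.0)

#: Multiplicative linear noise g(U)=U at strength eps=0.005 on the
#: standard lattice (C(0)=10 for dx=0.1).
NOISE = NoiseModel(eps=0.005, g0=1.0, g_kind="linear", C0=10.0)

#: Moving stimulus inside the stable locking tongue (I0=5, d=5, v=5).
STIMULUS_LOCKING = StimulusSpec(I0=5.0, width_d=5.0, v=5.0)

#: Stronger, slower stimulus (I0=8, d=5, v=3) used for locking demos.
STIMULUS_STRONG = StimulusSpec(I0=8.0, width_d=5.0, v=3.0)


def grid_for(speed: float, T: float, width: float = 20.0,
             dx: float = 0.1, dt: float = 0.01, margin: float = 40.0) -> SimGrid:
    """A lattice long enough that a pulse at the given speed never nears
    the boundary buffer within T."""
    lo = min(0.0, speed * T) - margin - width
    hi = max(0.0, speed * T) + margin + width
    return SimGrid(x_min=lo, x_max=hi, dx=dx, dt=dt, T=T)
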
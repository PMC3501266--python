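"""Wandering of a stimulus-locked pulse: Ornstein-Uhlenbeck saturation.

With a stimulus the displacement acquires a restoring force: the position
variance saturates at D/A instead of growing without bound, with A the
slowest relaxation rate of the locked linearization.  Locked pulses are
therefore far more robust to noise than free ones.
"""

import numpy as np

import pulsefield as pf

kernel = pf.presets.KERNEL
kappa = 4.0
noise = pf.NoiseModel(eps=0.005, g0=1.0, g_kind="linear", C0=10.0)
stim = pf.StimulusSpec(I0=5.0, width_d=5.0, v=5.0)

locked = pf.effective_locked_pulse(kernel, kappa, noise, stim)
V = pf.adjoint_null_vector(locked)
A = pf.ou_rate(V, locked)
D = pf.diffusivity(V, locked, noise)
print(
    f"locked pulse crossings: d1 = {locked.d1:.4f}, d2 = {locked.d2:.4f}\n"
    f"restoring rate A = {A:.4f} (slowest eigenvalue {V.eigenvalue:.4f}), "
    f"D = {D.D_theory:.4f}, saturation D/A = {D.D_theory / A:.4f}"
)

T = 36.0
grid = pf.SimGrid(x_min=-75.0, x_max=stim.v * T + 50.0, dx=0.1, dt=0.01, T=T)
rec = pf.integrate_langevin(
    grid, kernel, pf.FiringRule(kappa=kappa), noise,
    u0=pf.pulse_initial_condition(locked, grid), stimulus=stim,
    n_trials=96, record_every=0.5, seed=21,
)
tracks = pf.track_ensemble(rec, pf.default_levels(kappa))
for edge in ("trailing", "leading"):
    st = pf.ensemble_stats(tracks, edge=edge, model="ou")
    mid = st.variance[np.argmin(np.abs(st.times - T / 2))]
    end = st.variance[-1]
    print(
        f"{edge:>9} edge: slope = {st.speed:.4f} (stimulus speed {stim.v}), "
        f"variance {mid:.4f} @t={T/2:.0f} -> {end:.4f} @t={T:.0f}"
    )
print(
    "Both edges drift exactly at the stimulus speed and their variance\n"
    "saturates (OU wandering); the trailing edge saturates an order of\n"
    "magnitude higher, so width fluctuations are no longer negligible."
)
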
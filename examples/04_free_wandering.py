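"""Noise-induced wandering of a free pulse: theory vs simulation.

Multiplicative noise eps^(1/2) g(U) dW with g(U) = U shifts the mean pulse
(speed c_eps, width Delta) and makes its position diffuse with an effective
diffusivity D(eps) given by a solvability integral over the adjoint null
vector.  A modest Langevin ensemble reproduces both numbers.
"""

import pulsefield as pf

kernel = pf.presets.KERNEL
kappa = 4.0
noise = pf.NoiseModel(eps=0.005, g0=1.0, g_kind="linear", C0=10.0)

pulse = pf.effective_pulse(kernel, kappa, noise)
V = pf.adjoint_null_vector(pulse)
D = pf.diffusivity(V, pulse, noise)
print(
    f"noise-modified pulse: c_eps = {pulse.c_eps:.4f}, width = {pulse.width:.4f}\n"
    f"theoretical diffusivity D(eps) = {D.D_theory:.5f}"
)

T = 16.0
grid = pf.SimGrid(x_min=-40.0, x_max=pulse.c_eps * T + 60.0, dx=0.1, dt=0.01, T=T)
rec = pf.integrate_langevin(
    grid, kernel, pf.FiringRule(kappa=kappa), noise,
    u0=pf.pulse_initial_condition(pulse, grid),
    n_trials=128, record_every=0.5, seed=12,
)
tracks = pf.track_ensemble(rec, pf.default_levels(kappa))
st = pf.ensemble_stats(tracks, edge="leading", model="brownian")
print(
    f"128-trial ensemble, leading edge: measured speed = {st.speed:.4f}, "
    f"empirical D = {st.D:.5f} (linear-growth R^2 = {st.var_r2:.3f})"
)
print(
    "The level-set position variance grows linearly in t (Brownian\n"
    "wandering); its slope/2 estimates D and lands near the solvability\n"
    "prediction, while the mean position moves at c_eps."
)
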
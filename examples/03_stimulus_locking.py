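"""Pulses locked to a moving rectangular stimulus.

A stimulus of amplitude I0 and width 5 moving at speed v entrains the
pulse when v is close enough to the spontaneous speed; inside the tongue
several locked solutions coexist, at most one of them stable.
"""

import numpy as np

import pulsefield as pf

kernel = pf.presets.KERNEL
kappa = 4.0

for I0, v in ((8.0, 3.0), (5.0, 5.0)):
    s = pf.StimulusSpec(I0=I0, width_d=5.0, v=v)
    pulses = pf.solve_locked(kernel, s, kappa, classify=True)
    print(f"stimulus I0 = {I0}, v = {v}:")
    for p in pulses:
        print(
            f"  crossings d1 = {p.d1:8.4f}, d2 = {p.d2:8.4f} "
            f"(width {p.width:7.4f})  {p.stability}"
        )

c = pf.solve_free_pulses(kernel, kappa)[0].c
print(f"\nlocking-tongue slice near the spontaneous speed c = {c:.3f}:")
table = pf.locking_tongues(
    kernel, kappa, 5.0, v_grid=np.round([c - 0.6, c, c + 0.6], 3), I0_grid=[0.5, 2.0]
)
print(table[["v", "I0", "n_stable", "n_unstable", "n_invalid"]].to_string(index=False))
print("The stable tongue emerges from v = c at I0 = 0 and widens with I0.")
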
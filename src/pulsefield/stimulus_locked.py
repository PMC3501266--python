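"""Pulses locked to a moving rectangular stimulus, and the (v, I0) diagram.

A rectangular input of amplitude ``I0`` and width ``d`` moving at speed
``v`` breaks translation invariance; in the stimulus frame the profile
equation integrates exactly and both threshold crossings ``d1 < d2`` become
unknowns.  Locked pulses exist inside tongue-shaped regions of the
(v, I0) plane that emerge from the free-pulse speeds at I0 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .kernels import WeightKernel, half_line_transform, window_transform, window_integral
from .free_pulse import RESIDUAL_TOL, solve_free_pulses

__all__ = [
    "StimulusSpec",
    "LockedPulse",
    "stimulus_response",
    "locked_profile",
    "solve_locked",
    "locking_tongues",
]

DEDUPE_TOL = 1e-6
MAX_ROOTS = 8


@dataclass(frozen=True)
class StimulusSpec:
    """Rectangular traveling stimulus: I0 on [0, width_d] in the frame x - v t."""

    I0: float
    width_d: float
    v: float

    def __post_init__(self) -> None:
        if self.I0 < 0:
            raise ValueError("stimulus amplitude I0 must be >= 0")
        if self.width_d <= 0:
            raise ValueError("stimulus width must be positive")

    def value(self, xi):
        xi = np.asarray(xi, dtype=float)
        return np.where((xi >= 0.0) & (xi <= self.width_d), self.I0, 0.0)


def stimulus_response(xi, s: StimulusSpec, gamma: float | None = None):
    """Z(xi): the stimulus contribution to the locked profile.

    ``gamma`` is the profile decay rate; 1/|v| for the noiseless pulse,
    (1 - eps C(0) g0^2)/|v| for the noise-modified one.
    """
    if s.v == 0.0:
        raise ValueError("stationary stimuli (v = 0) are out of scope")
    g = abs(gamma) if gamma is not None else 1.0 / abs(s.v)
    xi = np.asarray(xi, dtype=float)
    d = s.width_d
    amp = s.I0 / (abs(s.v) * g)
    if s.v > 0:
        left = amp * np.exp(g * np.minimum(xi, 0.0)) * (1.0 - np.exp(-g * d))
        mid = amp * (1.0 - np.exp(g * (np.minimum(xi, d) - d)))
        out = np.where(xi < 0.0, left, np.where(xi <= d, mid, 0.0))
    else:
        mid = amp * (1.0 - np.exp(-g * np.maximum(xi, 0.0)))
        right = amp * np.exp(-g * np.maximum(xi - d, 0.0)) * (1.0 - np.exp(-g * d))
        out = np.where(xi < 0.0, 0.0, np.where(xi <= d, mid, right))
    return out if out.ndim else out[()]


@dataclass(frozen=True)
class LockedPulse:
    """Stimulus-locked pulse with threshold crossings at d1 < d2."""

    d1: float
    d2: float
    stimulus: StimulusSpec
    kernel: WeightKernel
    kappa: float
    stability: str = "unknown"
    #: profile decay rate; defaults to 1/v (noiseless), overridden by the
    #: noise-modified constant for effective locked pulses.
    gamma: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.d1 >= self.d2:
            raise ValueError("require d1 < d2")
        if self.gamma is None:
            object.__setattr__(self, "gamma", 1.0 / self.stimulus.v)

    @property
    def width(self) -> float:
        return self.d2 - self.d1

    def profile(self, xi):
        return locked_profile(self, xi)

    def profile_deriv(self, xi):
        """U'(xi) from the traveling-wave ODE (exact away from stimulus edges)."""
        xi = np.asarray(xi, dtype=float)
        v = self.stimulus.v
        decay_sum = self.gamma * v  # = 1 - eps C0 g0^2
        W = window_integral(xi, self.d1, self.d2, self.kernel)
        return (decay_sum * self.profile(xi) - W - self.stimulus.value(xi)) / v

    def window_mass(self, xi):
        return window_integral(xi, self.d1, self.d2, self.kernel)

    def with_stability(self, verdict: str) -> "LockedPulse":
        return replace(self, stability=verdict)


def locked_profile(p: LockedPulse, xi):
    """Closed-form locked profile U(xi); valid for either sign of v."""
    v = p.stimulus.v
    g = abs(p.gamma)
    side = 1 if v > 0 else -1
    core = window_transform(xi, p.d1, p.d2, g, p.kernel, side=side) / abs(v)
    return core + stimulus_response(xi, p.stimulus, gamma=p.gamma)


def _residuals(q, s, k, kappa, gamma):
    d1 = q[0]
    d2 = d1 + max(np.exp(min(q[1], 12.0)), 1e-10)
    side = 1 if s.v > 0 else -1
    g = abs(gamma)

    def u(xi):
        return window_transform(xi, d1, d2, g, k, side=side) / abs(s.v) + stimulus_response(
            xi, s, gamma=gamma
        )

    return [u(d1) - kappa, u(d2) - kappa]


def is_single_superthreshold(p: LockedPulse, n: int | None = None) -> bool:
    """Superthreshold set must be exactly (d1, d2); violation marks the
    multiple-superthreshold disqualifier of the locking diagram."""
    pad = p.kernel.x0 + 8.0 / p.kernel.sigma_i + p.width + p.stimulus.width_d
    if n is None:
        n = max(4000, int(1000 * (p.width + 2 * pad) / max(p.width, 1e-6)))
    n = min(n, 200_000)
    xi = np.linspace(p.d1 - pad, p.d2 + pad, n)
    u = p.profile(xi)
    above = u > p.kappa
    step = xi[1] - xi[0]
    inside = (xi > p.d1 + 1e-9) & (xi < p.d2 - 1e-9)
    strictly_inside = (xi > p.d1 + step) & (xi < p.d2 - step)
    return not np.any(above & ~inside) and not np.any(strictly_inside & ~above)


def solve_locked(
    k: WeightKernel,
    s: StimulusSpec,
    kappa: float,
    search: tuple[float, float] = (-60.0, 60.0),
    n_random: int = 40,
    gamma: float | None = None,
    rng=None,
    classify: bool = False,
    return_invalid: bool = False,
    free_seeds=None,
):
    """All stimulus-locked pulses (d1, d2) for the given stimulus.

    Multi-start 2D root finding in (d1, log(d2 - d1)).  Seeds combine the
    free pulses shifted across several widths with uniform random draws, as
    up to four roots can coexist.  Roots failing the single-superthreshold
    check are returned separately when ``return_invalid`` is set (they mark
    where solutions are lost in the locking diagram).
    """
    if s.v == 0.0:
        raise ValueError("stationary stimuli (v = 0) are out of scope")
    gamma = gamma if gamma is not None else 1.0 / s.v
    rng = np.random.default_rng(rng if rng is not None else 0)
    seeds: list[tuple[float, float]] = []
    if free_seeds is None:
        free_seeds = [(fp.c, fp.d) for fp in solve_free_pulses(k, kappa)]
    for _, fd in free_seeds:
        for shift in np.linspace(-2 * fd, 2 * fd, 9):
            seeds.append((shift, shift + fd))
    for _ in range(n_random):
        a = rng.uniform(search[0], search[1] / 2)
        width = np.exp(rng.uniform(np.log(0.2), np.log(40.0)))
        seeds.append((a, a + width))
    roots: list[tuple[float, float]] = []
    for d1, d2 in seeds:
        if len(roots) >= MAX_ROOTS:
            break
        sol = optimize.root(
            _residuals,
            [d1, np.log(max(d2 - d1, 1e-3))],
            args=(s, k, kappa, gamma),
            method="hybr",
        )
        if not sol.success:
            continue
        r1 = sol.x[0]
        r2 = r1 + np.exp(sol.x[1])
        if not (search[0] <= r1 < r2 <= search[1]):
            continue
        if max(abs(v) for v in _residuals(sol.x, s, k, kappa, gamma)) > RESIDUAL_TOL:
            continue
        if any(abs(r1 - a) < DEDUPE_TOL * (1 + abs(a)) and abs(r2 - b) < DEDUPE_TOL * (1 + abs(b)) for a, b in roots):
            continue
        roots.append((r1, r2))
    pulses = [
        LockedPulse(d1=a, d2=b, stimulus=s, kernel=k, kappa=kappa, gamma=gamma)
        for a, b in sorted(roots)
    ]
    valid = [p for p in pulses if is_single_superthreshold(p)]
    invalid = [p for p in pulses if not is_single_superthreshold(p)]
    if classify:
        from .evans import classify_stability

        classified = []
        for p in valid:
            try:
                classified.append(p.with_stability(classify_stability(p).verdict))
            except ValueError:
                classified.append(p.with_stability("degenerate"))
        valid = classified
    if return_invalid:
        return valid, invalid
    return valid


def locking_tongues(
    k: WeightKernel,
    kappa: float,
    s_width: float,
    v_grid,
    I0_grid,
    **solve_kwargs,
) -> pd.DataFrame:
    """Classify locked-pulse existence/stability over a (v, I0) grid.

    One row per cell with the number of stable, unstable, unknown and
    invalid (multiple-superthreshold) solutions.  Per-cell failures are
    recorded in the ``error`` column; the scan never aborts.
    """
    rows = []
    free_seeds = [(fp.c, fp.d) for fp in solve_free_pulses(k, kappa)]
    solve_kwargs.setdefault("free_seeds", free_seeds)
    for v in np.asarray(v_grid, dtype=float):
        if v == 0.0:
            raise ValueError("v_grid must exclude v = 0")
        for I0 in np.asarray(I0_grid, dtype=float):
            row = {"v": v, "I0": I0, "n_stable": 0, "n_unstable": 0,
                   "n_unknown": 0, "n_invalid": 0, "error": ""}
            try:
                s = StimulusSpec(I0=I0, width_d=s_width, v=v)
                valid, invalid = solve_locked(
                    k, s, kappa, classify=True, return_invalid=True, **solve_kwargs
                )
                for p in valid:
                    if p.stability == "stable":
                        row["n_stable"] += 1
                    elif p.stability == "unstable":
                        row["n_unstable"] += 1
                    else:
                        row["n_unknown"] += 1
                row["n_invalid"] = len(invalid)
            except Exception as exc:  # pragma: no cover - defensive
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)
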
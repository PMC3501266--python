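"""Freely propagating traveling pulses of the deterministic field.

With a Heaviside firing rate the traveling-wave equation

    -c U'(xi) = -U(xi) + int_{xi-d}^{xi} w(x) dx

integrates exactly, and the unknown speed ``c`` and width ``d`` are pinned
down by the two threshold conditions U(0) = U(d) = kappa.  These are a pair
of transcendental equations with (generically) multiple solution branches;
this module finds all of them by multi-start damped root finding in
log(c, d) space and validates each root against the single-superthreshold
-interval ansatz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .kernels import WeightKernel, half_line_transform, window_integral, window_transform

__all__ = [
    "FiringRule",
    "FreePulse",
    "profile",
    "threshold_residuals",
    "solve_free_pulses",
    "branch_scan",
]

RESIDUAL_TOL = 1e-9
DEDUPE_TOL = 1e-6


@dataclass(frozen=True)
class FiringRule:
    """Firing-rate nonlinearity: Heaviside step or sigmoid with gain gamma.

    The analytic pulse constructions require ``kind='heaviside'``; the
    sigmoid is supported only by the time-stepping simulator.
    """

    kappa: float
    kind: str = "heaviside"
    gamma: float = 20.0

    def __post_init__(self) -> None:
        if self.kind not in ("heaviside", "sigmoid"):
            raise ValueError(f"unknown firing rule kind {self.kind!r}")
        if self.kappa <= 0 or self.gamma <= 0:
            raise ValueError("require kappa > 0 and gamma > 0")

    def __call__(self, u):
        if self.kind == "heaviside":
            return (np.asarray(u) > self.kappa).astype(float)
        return 1.0 / (1.0 + np.exp(-self.gamma * (np.asarray(u) - self.kappa)))


@dataclass(frozen=True)
class FreePulse:
    """A traveling pulse in the canonical frame (threshold crossings at 0 and d)."""

    c: float
    d: float
    kernel: WeightKernel
    kappa: float
    stability: str = "unknown"
    #: decay rate of the profile integral; 1/c for the noiseless pulse, the
    #: noise-modified constant for effective pulses built on this chassis.
    gamma: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.gamma is None:
            object.__setattr__(self, "gamma", 1.0 / self.c)

    @property
    def window(self) -> tuple[float, float]:
        return (0.0, self.d)

    def profile(self, xi):
        """Closed-form wave profile U(xi)."""
        return window_transform(xi, 0.0, self.d, self.gamma, self.kernel) / self.c

    def profile_deriv(self, xi):
        """U'(xi), exact (equals b(xi) - b(xi - d) of the wandering theory)."""
        xi = np.asarray(xi, dtype=float)
        g = self.gamma
        return (
            half_line_transform(xi, g, self.kernel)
            - half_line_transform(xi - self.d, g, self.kernel)
        ) / self.c

    def window_mass(self, xi):
        """W(xi) = int_{xi-d}^{xi} w."""
        return window_integral(xi, 0.0, self.d, self.kernel)

    def with_stability(self, verdict: str) -> "FreePulse":
        return replace(self, stability=verdict)


def profile(p: FreePulse, xi):
    """Evaluate the pulse profile U(xi) (functional form of ``FreePulse.profile``)."""
    return p.profile(xi)


def threshold_residuals(c: float, d: float, k: WeightKernel, kappa: float):
    """(U(0) - kappa, U(d) - kappa) for trial speed/width, closed form."""
    g = 1.0 / c
    u0 = window_transform(0.0, 0.0, d, g, k) / c
    ud = window_transform(d, 0.0, d, g, k) / c
    return (u0 - kappa, ud - kappa)


def is_single_superthreshold(p: FreePulse, n: int | None = None) -> bool:
    """Check the ansatz: U > kappa exactly on (0, d), U < kappa outside.

    Samples the closed-form profile on a grid of spacing <= d/1000 extended
    by several kernel decay lengths on both sides.
    """
    pad = p.kernel.x0 + 8.0 / p.kernel.sigma_i + p.d
    if n is None:
        n = max(4000, int(1000 * (p.d + 2 * pad) / p.d))
    xi = np.linspace(-pad, p.d + pad, n)
    u = p.profile(xi)
    above = u > p.kappa
    inside = (xi > 1e-9) & (xi < p.d - 1e-9)
    # superthreshold samples must lie inside (0, d); all interior samples
    # (away from the crossings by one grid step) must be superthreshold
    step = xi[1] - xi[0]
    strictly_inside = (xi > step) & (xi < p.d - step)
    if np.any(above & ~inside):
        return False
    if np.any(strictly_inside & ~above):
        return False
    return True


def _log_residual(q, k, kappa):
    c, d = np.exp(np.clip(q, -30.0, 10.0))
    if c > 1e4 or d > 1e4:
        return [1e6, 1e6]
    return list(threshold_residuals(c, d, k, kappa))


def solve_free_pulses(
    k: WeightKernel,
    kappa: float,
    c_range: tuple[float, float] = (0.05, 20.0),
    d_range: tuple[float, float] = (0.1, 50.0),
    n_starts: tuple[int, int] = (10, 10),
    classify: bool = False,
    extra_seeds=(),
) -> list[FreePulse]:
    """Find all traveling-pulse solutions in the search box.

    Multi-start root finding on the two threshold conditions over a
    log-spaced (c, d) grid; roots are merged within ``DEDUPE_TOL`` and
    filtered by the single-superthreshold-interval check.  Returns pulses
    sorted by speed; empty list when no pulse exists (e.g. beyond the
    saddle-node threshold or for a symmetric kernel).
    """
    seeds = [
        (c0, d0)
        for c0 in np.geomspace(*c_range, n_starts[0])
        for d0 in np.geomspace(*d_range, n_starts[1])
    ]
    seeds.extend(extra_seeds)
    roots: list[tuple[float, float]] = []
    for c0, d0 in seeds:
        sol = optimize.root(
            _log_residual, np.log([c0, d0]), args=(k, kappa), method="hybr"
        )
        if not sol.success:
            continue
        c, d = np.exp(sol.x)
        if not (c_range[0] <= c <= c_range[1] and d_range[0] <= d <= d_range[1]):
            continue
        res = threshold_residuals(c, d, k, kappa)
        if max(abs(res[0]), abs(res[1])) > RESIDUAL_TOL:
            continue
        if any(
            abs(c - c1) < DEDUPE_TOL * (1 + c1) and abs(d - d1) < DEDUPE_TOL * (1 + d1)
            for c1, d1 in roots
        ):
            continue
        roots.append((c, d))
    pulses = [FreePulse(c=c, d=d, kernel=k, kappa=kappa) for c, d in sorted(roots)]
    pulses = [p for p in pulses if is_single_superthreshold(p)]
    if classify:
        from .evans import classify_stability

        pulses = [p.with_stability(classify_stability(p).verdict) for p in pulses]
    return pulses


def branch_scan(
    k: WeightKernel,
    kappa_grid,
    classify: bool = True,
    c_range: tuple[float, float] = (0.05, 20.0),
    d_range: tuple[float, float] = (0.1, 50.0),
) -> pd.DataFrame:
    """Trace all pulse branches over a threshold grid.

    Continuation with warm starts from the previous threshold's roots, plus
    a fresh multi-start at every point so that branches appearing mid-scan
    are not missed.  Branch terminations (saddle-nodes) are recorded as the
    absence of further rows, never as a failure.
    """
    kappa_grid = np.asarray(kappa_grid, dtype=float)
    if kappa_grid.size and np.any(np.diff(kappa_grid) <= 0):
        raise ValueError("kappa_grid must be strictly increasing")
    rows = []
    warm: list[tuple[float, float]] = []
    for kappa in kappa_grid:
        pulses = solve_free_pulses(
            k,
            kappa,
            c_range=c_range,
            d_range=d_range,
            classify=classify,
            extra_seeds=warm,
        )
        warm = [(p.c, p.d) for p in pulses]
        for p in pulses:
            rows.append(
                {"kappa": kappa, "c": p.c, "d": p.d, "stability": p.stability}
            )
    return pd.DataFrame(rows, columns=["kappa", "c", "d", "stability"])
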
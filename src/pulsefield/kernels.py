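"""Closed-form algebra for the offset Mexican-hat connectivity kernel.

The connectivity between local populations is a difference of exponentials
whose peak is shifted by an offset ``x0``:

    w(x) = a_e * exp(-sigma_e * |x - x0|) - a_i * exp(-sigma_i * |x - x0|)

With ``x0 > 0`` the kernel is asymmetric about the origin (while remaining
mirror-symmetric about ``x0``), which is what allows the field to support
freely propagating pulses instead of stationary bumps.

Everything the traveling-wave constructions need reduces to exponentially
weighted integrals of ``w``, all of which have exact antiderivatives.  The
central primitive is the half-line transform

    G(z; gamma) = int_z^inf exp(-gamma * (y - z)) w(y) dy,   Re(gamma) > 0,

together with its antiderivative in ``z``.  Pulse profiles, Evans functions
and the adjoint null vector of the wandering theory are all assembled from
``G``.  Numerical quadrature appears only in the test suite as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WeightKernel",
    "DivergentIntegralError",
    "weight",
    "cumulative_weight",
    "total_mass",
    "window_integral",
    "half_line_transform",
    "half_line_transform_antiderivative",
    "window_transform",
    "convolve_wP",
    "exp_weighted_window",
]

_DEGENERATE_TOL = 1e-10


class DivergentIntegralError(ValueError):
    """Raised when an improper exponential-weighted integral does not converge."""


@dataclass(frozen=True)
class WeightKernel:
    """Offset difference-of-exponentials connectivity.

    Parameters
    ----------
    a_e, a_i:
        Excitatory and inhibitory amplitudes, ``a_e > a_i > 0``.
    sigma_e, sigma_i:
        Excitatory and inhibitory decay rates (1/length), ``sigma_e > sigma_i > 0``.
    x0:
        Offset of the kernel peak (length).  Positive offsets produce
        rightward-moving pulses.
    """

    a_e: float
    a_i: float
    sigma_e: float
    sigma_i: float
    x0: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a_e > self.a_i > 0.0):
            raise ValueError(
                f"require a_e > a_i > 0, got a_e={self.a_e}, a_i={self.a_i}"
            )
        if not (self.sigma_e > self.sigma_i > 0.0):
            raise ValueError(
                "require sigma_e > sigma_i > 0, got "
                f"sigma_e={self.sigma_e}, sigma_i={self.sigma_i}"
            )

    @property
    def terms(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """(amplitude, rate) pairs of the two exponential components."""
        return ((self.a_e, self.sigma_e), (-self.a_i, self.sigma_i))

    def __call__(self, x):
        return weight(x, self)


def weight(x, k: WeightKernel):
    """Synaptic weight w(x)."""
    r = np.abs(np.asarray(x, dtype=float) - k.x0)
    return k.a_e * np.exp(-k.sigma_e * r) - k.a_i * np.exp(-k.sigma_i * r)


def cumulative_weight(x, k: WeightKernel):
    """int_{x0}^{x} w(s) ds, the odd-about-x0 antiderivative of the kernel."""
    x = np.asarray(x, dtype=float)
    r = x - k.x0
    out = np.zeros_like(r)
    for a, s in k.terms:
        out = out + np.sign(r) * (a / s) * (1.0 - np.exp(-s * np.abs(r)))
    return out


def total_mass(k: WeightKernel) -> float:
    """int_{-inf}^{inf} w(x) dx = 2 (a_e/sigma_e - a_i/sigma_i)."""
    return 2.0 * (k.a_e / k.sigma_e - k.a_i / k.sigma_i)


def window_integral(xi, lower_shift, upper_shift, k: WeightKernel):
    """W(xi) = int_{xi - upper_shift}^{xi - lower_shift} w(x) dx.

    Covers both the free-pulse window (0, d) and the stimulus-locked window
    (d1, d2).  Branch selection across the kernel peak is implicit in the
    piecewise antiderivative.
    """
    if not np.all(np.asarray(lower_shift) <= np.asarray(upper_shift)):
        raise ValueError("window requires lower_shift <= upper_shift")
    xi = np.asarray(xi, dtype=float)
    return cumulative_weight(xi - lower_shift, k) - cumulative_weight(xi - upper_shift, k)


def _check_decay(decay) -> complex:
    decay = complex(decay)
    if decay.real <= 0.0:
        raise DivergentIntegralError(
            f"half-line transform requires Re(decay) > 0, got decay={decay}"
        )
    return decay


def _g_term(r, a: float, s: float, g: complex):
    """Half-line transform of a single exponential term, argument r = z - x0."""
    r = np.asarray(r, dtype=float)
    rp = np.maximum(r, 0.0)
    rn = np.minimum(r, 0.0)
    pos = a * np.exp(-s * rp) / (g + s)
    if abs(s - g) < _DEGENERATE_TOL:
        neg = a * np.exp(g * rn) * (-rn + 1.0 / (2.0 * g))
    else:
        neg = a * (
            (np.exp(g * rn) - np.exp(s * rn)) / (s - g) + np.exp(g * rn) / (g + s)
        )
    return np.where(r >= 0.0, pos, neg)


def _ag_term(r, a: float, s: float, g: complex):
    """Antiderivative (in z) of ``_g_term``, continuous at the kernel peak."""
    r = np.asarray(r, dtype=float)
    rp = np.maximum(r, 0.0)
    rn = np.minimum(r, 0.0)
    if abs(s - g) < _DEGENERATE_TOL:
        neg = a * np.exp(g * rn) * (1.5 - rn * g) / g**2
    else:
        neg = a * (
            2.0 * s * np.exp(g * rn) / (g * (s * s - g * g))
            - np.exp(s * rn) / (s * (s - g))
        )
    pos = 2.0 * a / (g * s) - a * np.exp(-s * rp) / (s * (g + s))
    return np.where(r <= 0.0, neg, pos)


def half_line_transform(z, decay, k: WeightKernel, side: int = 1):
    """Exponentially weighted half-line integral of the kernel.

    ``side=+1`` gives ``G(z) = int_z^inf exp(-decay (y-z)) w(y) dy``;
    ``side=-1`` gives the mirrored ``int_{-inf}^z exp(-decay (z-y)) w(y) dy``,
    evaluated via the kernel's mirror symmetry about ``x0``.
    Supports complex ``decay`` with positive real part.
    """
    g = _check_decay(decay)
    z = np.asarray(z, dtype=float)
    if side == -1:
        z = 2.0 * k.x0 - z
    out = _g_term(z - k.x0, k.a_e, k.sigma_e, g) + _g_term(z - k.x0, -k.a_i, k.sigma_i, g)
    if g.imag == 0.0:
        out = out.real
    return out if out.ndim else out[()]


def half_line_transform_antiderivative(z, decay, k: WeightKernel):
    """Antiderivative in ``z`` of ``half_line_transform(z, decay, k, side=+1)``."""
    g = _check_decay(decay)
    z = np.asarray(z, dtype=float)
    out = _ag_term(z - k.x0, k.a_e, k.sigma_e, g) + _ag_term(z - k.x0, -k.a_i, k.sigma_i, g)
    if g.imag == 0.0:
        out = out.real
    return out if out.ndim else out[()]


def window_transform(xi, lower_shift, upper_shift, decay, k: WeightKernel, side: int = 1):
    """int over the window of half-line transforms of the kernel.

    ``side=+1`` evaluates ``int_{lower}^{upper} G(xi - s; decay) ds``
    (rightward-moving waves); ``side=-1`` the mirrored version for leftward
    motion.  Dividing by the wave speed turns this directly into the
    traveling-pulse profile.
    """
    xi = np.asarray(xi, dtype=float)
    if side == 1:
        return half_line_transform_antiderivative(
            xi - lower_shift, decay, k
        ) - half_line_transform_antiderivative(xi - upper_shift, decay, k)
    # mirror: int G_minus(u) du over [xi-upper, xi-lower]
    return half_line_transform_antiderivative(
        2.0 * k.x0 - xi + upper_shift, decay, k
    ) - half_line_transform_antiderivative(2.0 * k.x0 - xi + lower_shift, decay, k)


def convolve_wP(xi, lam, speed, k: WeightKernel):
    """Convolution of the kernel with the one-sided exponential P_lambda.

    For speed ``v > 0`` this is ``int_xi^inf w(y) exp((lam+1)(xi-y)/v) dy``;
    for ``v < 0`` the mirrored half-line applies.  Requires ``Re(lam) > -1``
    (strictly right of the essential spectrum).
    """
    if speed == 0.0:
        raise ValueError("convolve_wP requires a nonzero speed")
    lam = complex(lam)
    if lam.real <= -1.0:
        raise DivergentIntegralError(
            f"convolve_wP requires Re(lam) > -1, got lam={lam}"
        )
    decay = (lam + 1.0) / speed
    if speed > 0:
        return half_line_transform(xi, decay, k, side=1)
    return half_line_transform(xi, -decay, k, side=-1)


def _branch_terms(branch: int, window, k: WeightKernel):
    """Exponential-term representation (coef, rate) of W_n on its branch."""
    d1, d2 = window
    terms = []
    for a, s in k.terms:
        if branch == 1:  # xi >= x0 + d2: both window endpoints right of the peak
            coef = (a / s) * (np.exp(s * (k.x0 + d2)) - np.exp(s * (k.x0 + d1)))
            terms.append((coef, -s))
        elif branch == 3:  # xi <= x0 + d1: both endpoints left of the peak
            coef = (a / s) * (np.exp(-s * (k.x0 + d1)) - np.exp(-s * (k.x0 + d2)))
            terms.append((coef, s))
        elif branch == 2:  # window straddles the peak
            terms.append((2.0 * a / s, 0.0))
            terms.append((-(a / s) * np.exp(s * (k.x0 + d1)), -s))
            terms.append((-(a / s) * np.exp(-s * (k.x0 + d2)), s))
        else:
            raise ValueError(f"branch must be 1, 2 or 3, got {branch}")
    return terms


def _exp_integral(coef, rate, decay, lo, hi):
    """int_lo^hi coef * exp((rate - decay) s) ds with +-inf limits allowed."""
    mu = rate - decay
    if hi == np.inf:
        if np.real(mu) >= 0:
            raise DivergentIntegralError(
                "improper integral toward +inf requires Re(rate - decay) < 0"
            )
        return -coef * np.exp(mu * lo) / mu
    if lo == -np.inf:
        if np.real(mu) <= 0:
            raise DivergentIntegralError(
                "improper integral toward -inf requires Re(rate - decay) > 0"
            )
        return coef * np.exp(mu * hi) / mu
    if abs(mu) < _DEGENERATE_TOL:
        return coef * (hi - lo)
    return coef * (np.exp(mu * hi) - np.exp(mu * lo)) / mu


def exp_weighted_window(xi, decay, branch, window, k: WeightKernel, direction: int = 1):
    """The M_n / N_n building blocks of the piecewise pulse profile.

    ``direction=+1`` returns ``M_n(xi) = int_xi^{xi_n} W_n(s) exp(-decay s) ds``
    with upper limits ``xi_1 = inf``, ``xi_2 = x0 + d2``, ``xi_3 = x0 + d1``
    (rightward waves); ``direction=-1`` returns
    ``N_n(xi) = int_{xi_n} ^ xi W_n(s) exp(-decay s) ds`` with
    ``xi_3 = -inf``, ``xi_2 = x0 + d1``, ``xi_1 = x0 + d2`` (leftward waves).
    ``window = (d1, d2)``; the free pulse uses (0, d).
    """
    d1, d2 = window
    decay = complex(decay)
    terms = _branch_terms(branch, window, k)
    if direction == 1:
        limits = {1: np.inf, 2: k.x0 + d2, 3: k.x0 + d1}
        lo, hi = xi, limits[branch]
    elif direction == -1:
        limits = {1: k.x0 + d2, 2: k.x0 + d1, 3: -np.inf}
        lo, hi = limits[branch], xi
    else:
        raise ValueError("direction must be +1 or -1")
    val = sum(_exp_integral(coef, rate, decay, lo, hi) for coef, rate in terms)
    return val.real if decay.imag == 0.0 else val
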
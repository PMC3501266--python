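"""Perturbative wandering theory: adjoint null vector, diffusivity, OU rate.

Splitting the stochastic field into a rigidly displaced mean profile
U0(xi - Delta(t)) plus O(sqrt(eps)) shape fluctuations, projecting the
fluctuation equation onto the adjoint mode V of the linearized operator
turns the displacement Delta(t) into a scalar SDE:

* free pulse:   pure Brownian motion,  <Delta(t)^2> = 2 D(eps) t;
* locked pulse: Ornstein-Uhlenbeck,    variance -> D(eps)/A as t -> inf,

with  D(eps) = eps * int V^2 g(U0)^2 / [int V U0']^2  and
A = int V I' / int V U0'.

For Heaviside firing and linear gain g(U) = g0 U everything is explicit:
V is a pair of one-sided exponentials launched at the threshold crossings,
with weights set by the kernel transform b(z) = (1/c) int_z^inf
e^{-Gamma (s-z)} w(s) ds.  For a free pulse V is the exact null vector of
the adjoint operator.  A locked pulse has no zero eigenvalue (translation
symmetry is broken), so V is instead the adjoint eigenfunction of the
slowest discrete mode lambda_1; with that choice the restoring rate
satisfies A = -lambda_1 identically, since L U0' = -I' implies
<V, L U0'> = lambda_1 <V, U0'> = -<V, I'>.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .kernels import half_line_transform
from .stochastic_sim import EffectivePulse, NoiseModel
from .stimulus_locked import LockedPulse

__all__ = [
    "AdjointNullVector",
    "DiffusionEstimate",
    "b_function",
    "adjoint_null_vector",
    "diffusivity",
    "ou_rate",
    "variance_curve",
]

RANK_TOL = 1e-8


def _context(ctx):
    """(crossings, base decay 1-eps*C0*g0^2, speed, kernel) of a pulse context."""
    if isinstance(ctx, EffectivePulse):
        return (0.0, ctx.width), ctx.Gamma * ctx.c_eps, ctx.c_eps, ctx.kernel
    if isinstance(ctx, LockedPulse):
        v = ctx.stimulus.v
        if v <= 0:
            raise NotImplementedError(
                "locked adjoint mode is implemented for v > 0 only"
            )
        return (ctx.d1, ctx.d2), ctx.gamma * v, v, ctx.kernel
    raise TypeError(f"unsupported context {type(ctx).__name__}")


def b_function(z, ctx):
    """b(z) = (1/c) int_z^inf exp(-Gamma (s - z)) w(s) ds.

    Building block of the profile derivative (U0'(xi) = b(xi) - b(xi -
    Delta) for the free pulse) and of the adjoint mode amplitudes."""
    _, shift, speed, kernel = _context(ctx)
    gamma = shift / speed
    if gamma <= 0:
        raise ValueError("b_function requires a positive decay rate Gamma")
    return half_line_transform(z, gamma, kernel) / speed


@dataclass(frozen=True)
class AdjointNullVector:
    """Adjoint mode V(xi): one-sided exponentials launched at the crossings.

    ``coeffs`` are the amplitudes of H(xi - z_n) exp(-Gamma (xi - z_n));
    for a free pulse these are exactly (b(Delta), -b(-Delta)) with
    ``eigenvalue`` 0; for a locked pulse ``eigenvalue`` is the slowest
    discrete mode lambda_1 < 0.  ``matrix_residual`` certifies the rank-1
    self-consistency system (relative determinant magnitude).
    """

    crossings: tuple[float, float]
    Gamma: float
    coeffs: tuple[float, float]
    matrix_residual: float
    eigenvalue: float = 0.0

    def __call__(self, xi):
        xi = np.asarray(xi, dtype=float)
        z1, z2 = self.crossings
        a, b = self.coeffs
        t1 = np.where(xi >= z1, a * np.exp(-self.Gamma * np.maximum(xi - z1, 0.0)), 0.0)
        t2 = np.where(xi >= z2, b * np.exp(-self.Gamma * np.maximum(xi - z2, 0.0)), 0.0)
        out = t1 + t2
        return out if out.ndim else out[()]


def _selfconsistency_matrix(lam, width, du1, du2, shift, speed, kernel):
    """2x2 system tying the jump amplitudes of the adjoint mode at the crossings."""
    gamma = (lam + shift) / speed
    b = lambda z: half_line_transform(z, gamma, kernel) / speed  # noqa: E731
    return np.array(
        [
            [b(0.0) / du1 - 1.0, b(width) / du1],
            [b(-width) / du2, b(0.0) / du2 - 1.0],
        ]
    ), b


def _mode_from_matrix(M, b, crossings, gamma):
    det = abs(np.linalg.det(M))
    residual = det / max(np.linalg.norm(M) ** 2, 1e-300)
    if residual > RANK_TOL:
        raise ValueError(
            f"adjoint self-consistency matrix is not rank-1 (residual {residual:.3g}); "
            "invalid pulse context"
        )
    width = crossings[1] - crossings[0]
    _, _, vh = np.linalg.svd(M)
    A, B = vh[-1]
    target = b(width)
    if abs(A) > 1e-12 * (abs(A) + abs(B)) and abs(target) > 0:
        s = target / A
        A, B = A * s, B * s
    return AdjointNullVector(
        crossings=crossings,
        Gamma=gamma,
        coeffs=(float(A), float(B)),
        matrix_residual=residual,
    )


def adjoint_null_vector(ctx) -> AdjointNullVector:
    """Adjoint projection mode V for a free or stimulus-locked pulse context.

    Free (EffectivePulse): the exact null vector, closed form
    V = b(Delta) H(xi) e^{-Gamma xi} - b(-Delta) H(xi-Delta) e^{-Gamma (xi-Delta)}.
    Locked (LockedPulse, v > 0): the adjoint eigenfunction of the slowest
    discrete mode, located as the largest real root of the self-consistency
    determinant (the noise-modified Evans function) below zero.
    """
    (z1, z2), shift, speed, kernel = _context(ctx)
    width = z2 - z1
    if isinstance(ctx, EffectivePulse):
        du1 = abs(float(ctx.profile_deriv(0.0)))
        du2 = abs(float(ctx.profile_deriv(width)))
        M, b = _selfconsistency_matrix(0.0, width, du1, du2, shift, speed, kernel)
        mode = _mode_from_matrix(M, b, (z1, z2), shift / speed)
        return mode
    # locked: find the slowest adjoint eigenvalue lambda_1
    du1 = abs(float(ctx.profile_deriv(z1)))
    du2 = abs(float(ctx.profile_deriv(z2)))

    def det_fn(lam):
        M, _ = _selfconsistency_matrix(lam, width, du1, du2, shift, speed, kernel)
        return np.linalg.det(M)

    lo = -shift + 1e-6  # decay (lam + shift)/v must stay positive
    lams = np.linspace(lo, 2.0, 600)
    vals = np.array([det_fn(x) for x in lams])
    sign_change = np.where(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
    roots = [brentq(det_fn, lams[i], lams[i + 1], xtol=1e-13) for i in sign_change]
    if not roots:
        raise ValueError(
            "no real adjoint eigenvalue found right of the essential spectrum; "
            "cannot build the locked projection mode"
        )
    lam1 = max(roots)
    gamma = (lam1 + shift) / speed
    M, b = _selfconsistency_matrix(lam1, width, du1, du2, shift, speed, kernel)
    mode = _mode_from_matrix(M, b, (z1, z2), gamma)
    return AdjointNullVector(
        crossings=mode.crossings,
        Gamma=mode.Gamma,
        coeffs=mode.coeffs,
        matrix_residual=mode.matrix_residual,
        eigenvalue=float(lam1),
    )


@dataclass(frozen=True)
class DiffusionEstimate:
    """Theoretical wandering parameters: diffusivity and OU relaxation rate."""

    D_theory: float
    A_rate: float
    eps: float

    def variance(self, t):
        return variance_curve(t, self)


def _integrate_piecewise(f, null: AdjointNullVector):
    z1, z2 = null.crossings
    tail = 60.0 / null.Gamma
    pts = [z1, z2, z2 + 0.25 * tail, z2 + tail]
    return sum(quad(f, lo, hi, limit=400)[0] for lo, hi in zip(pts[:-1], pts[1:]))


def _projection_integral(null: AdjointNullVector, ctx) -> float:
    """int V(xi) U0'(xi) dxi over the support of V."""
    return _integrate_piecewise(lambda xi: null(xi) * ctx.profile_deriv(xi), null)


def diffusivity(null: AdjointNullVector, ctx, noise: NoiseModel) -> DiffusionEstimate:
    """Effective diffusivity D(eps) of the wandering displacement.

    Evaluates eps * int V^2 g(U0)^2 / [int V U0']^2 by adaptive quadrature
    split at the profile kinks; exactly linear in eps for linear gain.
    The OU rate is left at 0 -- combine with :func:`ou_rate` for locked
    pulses.
    """
    if noise.eps == 0.0:
        return DiffusionEstimate(D_theory=0.0, A_rate=0.0, eps=0.0)
    num = _integrate_piecewise(
        lambda xi: null(xi) ** 2 * noise.g(ctx.profile(xi)) ** 2, null
    )
    den = _projection_integral(null, ctx)
    if abs(den) < 1e-12:
        raise ZeroDivisionError("int V U0' vanishes; wandering theory inapplicable")
    return DiffusionEstimate(D_theory=noise.eps * num / den**2, A_rate=0.0, eps=noise.eps)


def ou_rate(null: AdjointNullVector, ctx: LockedPulse, s=None) -> float:
    """OU relaxation rate A of a stimulus-locked pulse.

    The rectangular stimulus has I'(xi) = I0 [delta(xi) - delta(xi - d)],
    so A = I0 (V(0) - V(d)) / int V U0'.  With V the slowest adjoint
    eigenfunction this equals -lambda_1 identically; the integral form is
    evaluated anyway as a consistency check of the construction.  A > 0 is
    the restoring force that saturates the wandering variance at D/A.
    """
    s = s if s is not None else ctx.stimulus
    if s.I0 == 0.0:
        return 0.0
    den = _projection_integral(null, ctx)
    if abs(den) < 1e-12:
        raise ZeroDivisionError("int V U0' vanishes; wandering theory inapplicable")
    return float(s.I0 * (null(0.0) - null(s.width_d)) / den)


def variance_curve(t, est: DiffusionEstimate):
    """<Delta(t)^2> - <Delta(t)>^2: 2 D t for A = 0, else (D/A)(1 - e^{-2At})."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    if est.A_rate == 0.0:
        out = 2.0 * est.D_theory * t
    else:
        out = (est.D_theory / est.A_rate) * (1.0 - np.exp(-2.0 * est.A_rate * t))
    return out if out.ndim else out[()]
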
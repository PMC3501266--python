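"""Linear stability of traveling pulses via the Evans function.

Linearizing the field equation about a pulse in the co-moving frame yields a
nonlocal operator whose discrete spectrum is given by the zeros of a 2x2
determinant, the Evans function E(lambda).  The essential spectrum is the
vertical line Re(lambda) = -1 (the field's unit decay rate), so stability is
decided entirely by Evans zeros in Re(lambda) > -1:

* free pulses: stable iff lambda = 0 is a simple zero (translation mode)
  and every other zero has negative real part;
* stimulus-locked pulses: translation symmetry is broken, so stability
  requires every zero to have negative real part.

Roots are located by sampling E on a rectangular grid, seeding complex
Newton iterations wherever the zero contours of Re E and Im E cross in a
cell, plus a dense scan of the real axis.  A finite-difference
discretization of the linearized operator is provided as an independent
numerical cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .kernels import WeightKernel, convolve_wP, weight, window_integral
from .free_pulse import FreePulse

__all__ = [
    "SpectrumReport",
    "EssentialSpectrum",
    "evans_free",
    "evans_locked",
    "find_eigenvalues",
    "essential_spectrum",
    "classify_stability",
    "linearized_operator_matrix",
]

ZERO_TOL = 1e-6  # |lambda| below this counts as the translation eigenvalue


@dataclass(frozen=True)
class SpectrumReport:
    """Discrete spectrum, essential-spectrum abscissa and stability verdict."""

    eigenvalues: tuple
    essential_re: float
    is_stable: bool | None
    verdict: str
    evans_grid: np.ndarray | None = field(default=None, repr=False)


@dataclass(frozen=True)
class EssentialSpectrum:
    """The continuous spectrum: a vertical line lambda = -1 - 2*pi*i*k*c."""

    speed: float
    abscissa: float = -1.0

    def line(self, kvals):
        """Parametrized spectral line over Fourier wavenumbers k."""
        kvals = np.asarray(kvals, dtype=float)
        return -1.0 - 2j * np.pi * kvals * self.speed

    def resolvent_kernel_transform(self, lam, kvals):
        """Fourier transform of the one-sided kernel P_lambda; diverges on the line."""
        kvals = np.asarray(kvals, dtype=float)
        return 1.0 / ((complex(lam) + 1.0) / self.speed + 2j * np.pi * kvals)


def essential_spectrum(speed: float) -> EssentialSpectrum:
    """Essential spectrum of the linearization about a pulse at the given speed."""
    if speed == 0.0:
        raise ValueError("essential spectrum is defined for a nonzero wave speed")
    return EssentialSpectrum(speed=float(speed))


def evans_free(lam, p: FreePulse):
    """Evans function of a freely propagating pulse, Re(lam) > -1."""
    k, kappa, c, d = p.kernel, p.kappa, p.c, p.d
    K0 = 1.0 / abs(kappa - window_integral(0.0, 0.0, d, k))
    Kd = 1.0 / abs(kappa - window_integral(d, 0.0, d, k))
    w0 = convolve_wP(0.0, lam, c, k)
    return (
        (K0 * w0 - 1.0) * (Kd * w0 - 1.0)
        - K0 * Kd * convolve_wP(d, lam, c, k) * convolve_wP(-d, lam, c, k)
    )


def evans_locked(lam, p):
    """Evans function of a stimulus-locked pulse (LockedPulse), Re(lam) > -1."""
    s = p.stimulus
    if s.v == 0.0:
        raise ValueError("locked Evans function requires a nonzero stimulus speed")
    k, kappa, d1, d2 = p.kernel, p.kappa, p.d1, p.d2
    sgn = 1.0 if s.v > 0 else -1.0
    edge_tol = 1e-9
    Ks = []
    for dn in (d1, d2):
        if abs(dn) < edge_tol or abs(dn - s.width_d) < edge_tol:
            raise ValueError(
                "threshold crossing coincides with a stimulus edge; the "
                "linearization coefficient is discontinuous there (degenerate case)"
            )
        Idn = s.I0 if 0.0 <= dn <= s.width_d else 0.0
        Ks.append(sgn / abs(kappa - window_integral(dn, d1, d2, k) - Idn))
    K1, K2 = Ks
    w0 = convolve_wP(0.0, lam, s.v, k)
    return (
        (K1 * w0 - 1.0) * (K2 * w0 - 1.0)
        - K1 * K2 * convolve_wP(d2 - d1, lam, s.v, k) * convolve_wP(d1 - d2, lam, s.v, k)
    )


def _newton_polish(f, z0: complex, tol: float = 1e-12, maxit: int = 60):
    z = complex(z0)
    for _ in range(maxit):
        fz = f(z)
        h = 1e-7 * (1.0 + abs(z))
        df = (f(z + h) - f(z - h)) / (2.0 * h)
        if df == 0:
            return None
        step = fz / df
        z = z - step
        if z.real <= -1.0 + 1e-9:
            return None
        if abs(step) < tol:
            return z
    return z if abs(f(z)) < 1e-8 else None


def find_eigenvalues(
    evans,
    box: tuple[float, float, float, float] = (-0.95, 1.0, -2.0, 2.0),
    grid: tuple[int, int] = (90, 61),
    dedupe_tol: float = 1e-6,
):
    """Zeros of an Evans function inside a rectangular box right of Re = -1.

    Samples E on a grid; cells where both Re E and Im E change sign seed a
    complex Newton polish, augmented by a bracketed scan of the real axis
    (real roots dominate in practice and conjugate symmetry pairs any
    complex ones).  Roots near the box boundary trigger a warning since
    eigenvalues just outside would be missed.
    """
    re_min, re_max, im_min, im_max = box
    if re_min <= -1.0:
        raise ValueError("search box must lie strictly right of Re(lambda) = -1")
    res = np.linspace(re_min, re_max, grid[0])
    ims = np.linspace(im_min, im_max, grid[1])
    E = np.empty((grid[1], grid[0]), dtype=complex)
    for i, b in enumerate(ims):
        for j, a in enumerate(res):
            E[i, j] = evans(complex(a, b))
    seeds: list[complex] = []
    reE, imE = E.real, E.imag
    for i in range(grid[1] - 1):
        for j in range(grid[0] - 1):
            cr = reE[i : i + 2, j : j + 2]
            ci = imE[i : i + 2, j : j + 2]
            if cr.min() < 0 < cr.max() and ci.min() < 0 < ci.max():
                seeds.append(complex((res[j] + res[j + 1]) / 2, (ims[i] + ims[i + 1]) / 2))
    # dense real-axis bracketing (E is real there by conjugate symmetry)
    if im_min <= 0.0 <= im_max:
        xs = np.linspace(re_min, re_max, 8 * grid[0])
        vals = np.array([evans(complex(x, 0.0)).real for x in xs])
        sign_change = np.where(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
        seeds.extend(complex((xs[i] + xs[i + 1]) / 2, 0.0) for i in sign_change)
    roots: list[complex] = []
    for z0 in seeds:
        z = _newton_polish(evans, z0)
        if z is None:
            continue
        if abs(z.imag) < 1e-10:
            z = complex(z.real, 0.0)
        if not (re_min - 1e-6 <= z.real <= re_max + 1e-6 and im_min - 1e-6 <= z.imag <= im_max + 1e-6):
            continue
        if abs(evans(z)) > 1e-7:
            continue
        if any(abs(z - r) < dedupe_tol * (1.0 + abs(r)) for r in roots):
            continue
        roots.append(z)
    # warn only near the right/imaginary edges: roots drifting toward the
    # left edge approach the essential spectrum and are strongly stable
    margin = 0.02 * max(re_max - re_min, im_max - im_min)
    for z in roots:
        if (
            abs(z.real - re_max) < margin
            or min(abs(z.imag - im_min), abs(z.imag - im_max)) < margin
        ):
            warnings.warn(
                f"Evans root {z:.6g} lies near the search-box boundary; "
                "eigenvalues outside the box may have been missed",
                stacklevel=2,
            )
    return sorted(roots, key=lambda z: (z.real, z.imag))


def _default_box(speed: float, width: float) -> tuple[float, float, float, float]:
    # right edge generous: unstable real eigenvalues of fast branches can
    # exceed 1 (E -> 1 as Re lambda -> inf, so roots are confined in practice)
    b = max(2.0 * np.pi * abs(speed) / width, 2.0)
    return (-0.95, 3.0, -b, b)


def classify_stability(p, box=None, grid=(90, 61)) -> SpectrumReport:
    """Run the Evans root search and apply the stability criterion.

    Free pulses must have a (simple) zero eigenvalue from translation
    invariance plus strictly stable remaining spectrum; locked pulses must
    have strictly stable spectrum outright.  Roots within ``ZERO_TOL`` of
    the imaginary axis (other than the translation mode) yield an
    ``unknown`` verdict.
    """
    locked = hasattr(p, "stimulus")
    if locked:
        speed, width = p.stimulus.v, p.d2 - p.d1
        ev = lambda lam: evans_locked(lam, p)  # noqa: E731
    else:
        speed, width = p.c, p.d
        ev = lambda lam: evans_free(lam, p)  # noqa: E731
    if box is None:
        box = _default_box(speed, width)
    roots = find_eigenvalues(ev, box=box, grid=grid)
    # extended real-axis sweep: real eigenvalues can sit far right of any
    # fixed box when a linearization coefficient is large (narrow pulses
    # with a crossing near the stimulus plateau); E -> 1 as lambda -> +inf
    xs = np.linspace(box[1], 200.0, 4000)
    vals = np.array([ev(complex(x, 0.0)).real for x in xs])
    for i in np.where(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]:
        from scipy.optimize import brentq

        r = complex(brentq(lambda x: ev(complex(x, 0.0)).real, xs[i], xs[i + 1]), 0.0)
        if not any(abs(r - z) < 1e-6 * (1 + abs(z)) for z in roots):
            roots.append(r)
    roots = sorted(roots, key=lambda z: (z.real, z.imag))
    zero = [z for z in roots if abs(z) < ZERO_TOL]
    rest = [z for z in roots if abs(z) >= ZERO_TOL]
    marginal = [z for z in rest if abs(z.real) <= ZERO_TOL]
    if marginal:
        verdict = "unknown"
        stable = None
    elif locked:
        stable = all(z.real < -ZERO_TOL for z in roots)
        verdict = "stable" if stable else "unstable"
    else:
        if not zero:
            # translation mode must exist; failing to find it means the
            # numerics cannot certify anything
            verdict, stable = "unknown", None
        else:
            stable = all(z.real < -ZERO_TOL for z in rest)
            verdict = "stable" if stable else "unstable"
    return SpectrumReport(
        eigenvalues=tuple(roots),
        essential_re=-1.0,
        is_stable=stable,
        verdict=verdict,
    )


def linearized_operator_matrix(p, x_min: float, x_max: float, dx: float) -> np.ndarray:
    """Dense finite-difference discretization of the linearized operator.

    Independent cross-check for the Evans construction: eigenvalues of this
    matrix (away from the essential spectrum) approximate the Evans zeros.
    Central differences for the advection term; the point evaluations at the
    threshold crossings use the nearest grid node.
    """
    locked = hasattr(p, "stimulus")
    x = np.arange(x_min, x_max + dx / 2, dx)
    n = x.size
    k = p.kernel
    if locked:
        speed = p.stimulus.v
        crossings = (p.d1, p.d2)
        shift = p.gamma * speed  # 1 for noiseless, 1 - eps C0 g0^2 with noise
    else:
        speed = p.c
        crossings = (0.0, p.d)
        gamma = getattr(p, "Gamma", None) or p.gamma
        shift = gamma * speed
    # F'(U0) concentrates on the crossings with weight 1/|U0'(z_n)|
    coefs = [1.0 / abs(float(p.profile_deriv(z))) for z in crossings]
    D = np.zeros((n, n))
    idx = np.arange(n - 1)
    D[idx, idx + 1] += 1.0 / (2 * dx)
    D[idx + 1, idx] -= 1.0 / (2 * dx)
    D[0, 0], D[0, 1] = -1.0 / dx, 1.0 / dx
    D[-1, -1], D[-1, -2] = 1.0 / dx, -1.0 / dx
    L = speed * D - shift * np.eye(n)
    for dn, coef in zip(crossings, coefs):
        # linear interpolation of the point evaluation across the two
        # neighboring nodes keeps the discretization second-order
        pos = (dn - x_min) / dx
        j = int(np.floor(pos))
        frac = pos - j
        col = coef * weight(x - dn, k)
        L[:, j] += (1.0 - frac) * col
        if j + 1 < n:
            L[:, j + 1] += frac * col
    return L
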
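"""Level-set tracking of stochastic waves and ensemble statistics.

The wave position in a given trial is measured as the interpolated location
X_a(t) where the field crosses a level a; sampling several levels per edge
and averaging first over levels, then over trials, gives the mean path
X̄(t) and the wandering variance sigma_X^2(t).  For free pulses the
variance grows linearly (Brownian wandering, slope 2 D); for
stimulus-locked pulses it saturates at D/A (Ornstein-Uhlenbeck wandering).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "WaveTrackEnsemble",
    "EdgeStats",
    "level_crossings",
    "track_ensemble",
    "ensemble_stats",
    "width_stats",
    "fit_linear",
    "fit_ou_variance",
    "fit_ou_acf",
    "default_levels",
    "brownian_tracks",
    "ou_tracks",
]


def default_levels(kappa: float) -> tuple[float, ...]:
    """Default level values per edge: fractions of the firing threshold."""
    return (0.6 * kappa, 0.8 * kappa, kappa)


def level_crossings(x, u, level, prev=None):
    """(trailing, leading) crossing positions of ``u`` through ``level``.

    Sub-grid positions by linear interpolation.  With multiple crossings
    (noisy frames) the crossing nearest the previous frame's position is
    chosen per edge; on the first frame the up/down crossings bounding the
    widest superthreshold component are used.  Returns (nan, nan) when the
    field never reaches the level.
    """
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    above = u > level
    if not above.any() or above.all():
        return (np.nan, np.nan)
    flips = np.where(above[:-1] != above[1:])[0]
    frac = (level - u[flips]) / (u[flips + 1] - u[flips])
    pos = x[flips] + frac * (x[flips + 1] - x[flips])
    ups = pos[~above[flips]]  # crossing upward (entering superthreshold)
    downs = pos[above[flips]]
    if ups.size == 0 or downs.size == 0:
        return (np.nan, np.nan)
    if prev is not None and np.isfinite(prev[0]) and np.isfinite(prev[1]):
        trailing = ups[np.argmin(np.abs(ups - prev[0]))]
        leading = downs[np.argmin(np.abs(downs - prev[1]))]
        return (trailing, leading)
    # first frame: bound the widest superthreshold run
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(int))
    starts = np.where(d == 1)[0]
    ends = np.where(d == -1)[0]
    widths = ends - starts
    imax = int(np.argmax(widths))
    lo, hi = x[starts[imax]], x[min(ends[imax], x.size - 1)]
    trailing = ups[np.argmin(np.abs(ups - lo))]
    leading = downs[np.argmin(np.abs(downs - hi))]
    return (trailing, leading)


@dataclass
class WaveTrackEnsemble:
    """Per-trial, per-level, per-edge crossing positions X_a(t)."""

    times: np.ndarray  # (n_times,)
    levels: np.ndarray  # (n_levels,)
    positions: np.ndarray  # (n_trials, n_levels, n_times, 2): [:, :, :, 0]=trailing
    n_trials: int

    def edge(self, which: str) -> np.ndarray:
        return self.positions[..., 0 if which == "trailing" else 1]


def track_ensemble(rec, levels) -> WaveTrackEnsemble:
    """Track level crossings through an ensemble recording.

    ``rec`` is a ``SimRecording``; temporal continuity (nearest crossing to
    the previous frame) disambiguates spurious threshold touches in noisy
    frames.
    """
    levels = np.atleast_1d(np.asarray(levels, dtype=float))
    n_trials, n_times, _ = rec.fields.shape
    out = np.full((n_trials, levels.size, n_times, 2), np.nan)
    for i in range(n_trials):
        for j, a in enumerate(levels):
            prev = None
            for m in range(n_times):
                tr, le = level_crossings(rec.x, rec.fields[i, m], a, prev=prev)
                out[i, j, m] = (tr, le)
                if np.isfinite(tr) and np.isfinite(le):
                    prev = (tr, le)
    return WaveTrackEnsemble(
        times=np.asarray(rec.times), levels=levels, positions=out, n_trials=n_trials
    )


@dataclass
class EdgeStats:
    """Mean path and wandering variance of one edge, with fitted parameters."""

    times: np.ndarray
    mean: np.ndarray
    variance: np.ndarray
    speed: float
    intercept: float
    speed_r2: float
    D: float | None = None
    var_r2: float | None = None
    A: float | None = None

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "mean": self.mean, "var": self.variance})


def fit_linear(t, y, window: tuple[float, float] | None = None):
    """Least-squares line fit of y(t) over an optional time window.

    Returns (slope, intercept, r_squared)."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, y = t[m], y[m]
    if t.size < 3:
        raise ValueError("fit window must contain at least 3 recording instants")
    A = np.vstack([t, np.ones_like(t)]).T
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - (slope * t + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(r2)


def fit_ou_variance(t, var, window: tuple[float, float] | None = None):
    """Fit the saturating variance curve (D/A)(1 - exp(-2 A t)).

    Returns (D, A, r_squared)."""
    t = np.asarray(t, dtype=float)
    var = np.asarray(var, dtype=float)
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, var = t[m], var[m]
    if t.size < 3:
        raise ValueError("fit window must contain at least 3 recording instants")
    sat = max(var[-1], 1e-12)
    slope0 = max((var[min(2, t.size - 1)] - var[0]) / max(t[min(2, t.size - 1)] - t[0], 1e-9), 1e-12)
    A0 = max(slope0 / (2 * sat), 1e-3)
    D0 = sat * A0

    def model(tt, D, A):
        return (D / A) * (1.0 - np.exp(-2.0 * A * tt))

    popt, _ = curve_fit(
        model, t, var, p0=(D0, A0), bounds=([0.0, 1e-6], [np.inf, np.inf]), maxfev=20000
    )
    resid = var - model(t, *popt)
    ss_tot = np.sum((var - var.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return float(popt[0]), float(popt[1]), float(r2)


def fit_ou_acf(
    tracks: WaveTrackEnsemble,
    edge: str = "leading",
    t_min: float = 25.0,
    max_lag: float = 12.0,
    lag_step: float = 0.5,
):
    """(D, A) of OU wandering from the stationary autocorrelation.

    In the saturated regime the displacement autocovariance is
    (D/A) exp(-A tau); fitting its log over lags tau <= ``max_lag`` and
    multiplying the decay rate into the stationary variance uses every
    time pair, which is substantially more efficient than fitting the
    transient variance curve.  Requires the record to extend several
    relaxation times past ``t_min``.
    """
    X = tracks.edge(edge)
    t = tracks.times
    sel = t >= t_min
    if sel.sum() < 8:
        raise ValueError("too few stationary recording instants past t_min")
    dev = X[:, :, sel] - np.nanmean(X[:, :, sel], axis=0, keepdims=True)
    dev = dev.reshape(-1, int(sel.sum()))
    var = float(np.nanvar(dev, axis=0, ddof=1).mean())
    dt = t[1] - t[0]
    step = max(1, int(round(lag_step / dt)))
    lags = range(0, int(round(max_lag / dt)) + 1, step)
    acf = np.array(
        [(lag * dt, np.nanmean(dev[:, : dev.shape[1] - lag] * dev[:, lag:])) for lag in lags]
    )
    good = acf[:, 1] > 0.05 * acf[0, 1]
    A = -np.polyfit(acf[good, 0], np.log(acf[good, 1]), 1)[0]
    return float(var * A), float(A)


def ensemble_stats(
    tracks: WaveTrackEnsemble,
    edge: str = "leading",
    fit_window: tuple[float, float] | None = None,
    transient_frac: float = 0.25,
    model: str = "brownian",
) -> EdgeStats:
    """Two-stage mean/variance curves of one edge, with parameter fits.

    Mean: average over levels then trials.  Variance: each level's track is
    demeaned by its own across-trial mean, so constant level offsets do not
    inflate it; the demeaned second moment estimates <Delta(t)^2>.  The fit
    window defaults to discarding the first ``transient_frac`` of the run.
    ``model='brownian'`` fits var ~ 2 D t; ``'ou'`` fits the saturating
    curve for (D, A).
    """
    if tracks.n_trials < 2:
        raise ValueError("ensemble statistics require at least 2 trials")
    X = tracks.edge(edge)  # (n_trials, n_levels, n_times)
    t = tracks.times
    mean_path = np.nanmean(X, axis=(0, 1))
    per_level_mean = np.nanmean(X, axis=0, keepdims=True)
    dev = X - per_level_mean
    variance = np.nanmean(np.nanvar(X, axis=0, ddof=1), axis=0)
    if fit_window is None:
        fit_window = (transient_frac * t[-1], t[-1])
    speed, intercept, r2 = fit_linear(t, mean_path, fit_window)
    stats = EdgeStats(
        times=t, mean=mean_path, variance=variance,
        speed=speed, intercept=intercept, speed_r2=r2,
    )
    if model == "brownian":
        vslope, _, vr2 = fit_linear(t, variance, fit_window)
        stats.D = vslope / 2.0
        stats.var_r2 = vr2
    elif model == "ou":
        D, A, vr2 = fit_ou_variance(t, variance)
        stats.D, stats.A, stats.var_r2 = D, A, vr2
    return stats


def width_stats(tracks: WaveTrackEnsemble, level: float) -> pd.DataFrame:
    """Mean and variance over trials of the pulse width at one level.

    Width is leading minus trailing crossing, D(t) = X_d(t) - Y_d(t).
    Missing crossings propagate as NaN."""
    j = int(np.argmin(np.abs(tracks.levels - level)))
    if abs(tracks.levels[j] - level) > 1e-9 * (1 + abs(level)):
        raise ValueError(f"level {level} was not tracked (have {tracks.levels})")
    w = tracks.positions[:, j, :, 1] - tracks.positions[:, j, :, 0]
    return pd.DataFrame(
        {
            "t": tracks.times,
            "mean_width": np.nanmean(w, axis=0),
            "var_width": np.nanvar(w, axis=0, ddof=1),
        }
    )


def _tracks_from_displacement(times, delta, speed, offsets, width, obs_noise=0.0, rng=None):
    """Assemble a rigid-pulse WaveTrackEnsemble from per-trial displacements.

    ``obs_noise`` adds independent per-level measurement jitter, emulating
    the interpolation error of real level-set reads."""
    n_trials, _ = delta.shape
    offsets = np.asarray(offsets, dtype=float)
    base = speed * np.asarray(times)[None, None, :] + delta[:, None, :]
    trailing = base + offsets[None, :, None]
    leading = trailing + width
    pos = np.stack([trailing, leading], axis=-1)
    if obs_noise > 0.0:
        rng = np.random.default_rng(rng)
        pos = pos + obs_noise * rng.standard_normal(pos.shape)
    return WaveTrackEnsemble(
        times=np.asarray(times, dtype=float),
        levels=np.arange(offsets.size, dtype=float),
        positions=pos,
        n_trials=n_trials,
    )


def brownian_tracks(c, D, times, n_trials, rng=None, offsets=(0.0, 0.3, 0.6),
                    width=10.0, obs_noise=0.0):
    """Synthetic rigid-pulse tracks with exact Brownian wandering (oracle)."""
    rng = np.random.default_rng(rng)
    times = np.asarray(times, dtype=float)
    dt = np.diff(times)
    steps = rng.standard_normal((n_trials, dt.size)) * np.sqrt(2.0 * D * dt)
    delta = np.concatenate([np.zeros((n_trials, 1)), np.cumsum(steps, axis=1)], axis=1)
    return _tracks_from_displacement(times, delta, c, offsets, width,
                                     obs_noise=obs_noise, rng=rng)


def ou_tracks(v, D, A, times, n_trials, rng=None, offsets=(0.0, 0.3, 0.6),
              width=10.0, delta0=0.0, obs_noise=0.0):
    """Synthetic rigid-pulse tracks with exact Ornstein-Uhlenbeck wandering.

    Uses the exact OU transition density for d Delta = -A Delta dt + dW,
    <dW^2> = 2 D dt, so the discrete tracks are samples of the continuous
    process with no time-stepping bias."""
    rng = np.random.default_rng(rng)
    times = np.asarray(times, dtype=float)
    n = times.size
    delta = np.empty((n_trials, n))
    delta[:, 0] = delta0
    for m in range(1, n):
        dt = times[m] - times[m - 1]
        decay = np.exp(-A * dt)
        sd = np.sqrt((D / A) * (1.0 - decay**2))
        delta[:, m] = delta[:, m - 1] * decay + sd * rng.standard_normal(n_trials)
    return _tracks_from_displacement(times, delta, v, offsets, width,
                                     obs_noise=obs_noise, rng=rng)
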
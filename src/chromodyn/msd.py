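"""Mean squared displacement analysis and anomalous-diffusion fitting.

The time-averaged MSD of a 2-D trajectory with N points at interval Δt is

    MSD(n·Δt) = 1/(N-n) Σ_{i=1}^{N-n} [(x_{i+n} - x_i)² + (y_{i+n} - y_i)²]

using all N - n overlapping displacement pairs at lag n. Ensemble curves
average the per-track time-averaged values lag by lag with equal track
weights. Curves are fitted with the anomalous diffusion model

    MSD(t) = A t^alpha + sigma²

where alpha is the anomalous exponent (alpha < 1 subdiffusive, alpha > 1
with a directed component), A the anomalous coefficient (μm²/s^alpha) and
sigma the positioning accuracy entering as a constant offset. Two effective
diffusion coefficients summarize a curve: D = p/4 with p the least-squares
slope of the first four MSD points, and a denoised variant averaging the
tangent of the fitted power law between 0.1 s and 1.0 s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .tracks import Trajectory

logger = logging.getLogger(__name__)


@dataclass
class MSDCurve:
    lags: np.ndarray          # seconds, n·Δt
    values: np.ndarray        # μm²
    n_pairs: np.ndarray       # displacement pairs contributing per lag
    n_tracks_averaged: int = 1

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs)
        if np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be positive and increasing")


@dataclass
class AnomalousFit:
    A: float
    alpha: float
    sigma: float
    r_squared: float
    fit_range: tuple
    converged: bool = True

    def predict(self, t):
        return self.A * np.asarray(t, dtype=float) ** self.alpha + self.sigma ** 2


@dataclass
class EffectiveDiffusion:
    D_first4: float | None    # μm²/s, slope of first 4 MSD points / 4
    D_tangent: float | None   # μm²/s, mean tangent of fitted curve on [0.1, 1] s


def compute_tamsd(traj: Trajectory, max_lag: int | None = None) -> MSDCurve:
    """Time-averaged MSD of a single trajectory over lags 1..max_lag frames.

    Frames are assumed consecutive (the generator and SPT linking emit
    gap-free tracks); the lag axis is in seconds.
    """
    n = traj.n_points
    if n < 2:
        raise ValueError("need at least 2 points")
    if max_lag is None:
        max_lag = n - 1
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if max_lag > n - 1:
        logger.warning("max_lag %d truncated to %d", max_lag, n - 1)
        max_lag = n - 1
    lags = np.arange(1, max_lag + 1)
    values = np.empty(max_lag)
    for k, lag in enumerate(lags):
        dx = traj.x[lag:] - traj.x[:-lag]
        dy = traj.y[lag:] - traj.y[:-lag]
        values[k] = np.mean(dx * dx + dy * dy)
    return MSDCurve(lags * traj.frame_interval, values, n - lags)


def ensemble_msd(tracks, max_lag: int, min_tracks_per_lag: int = 1) -> MSDCurve:
    """Time-ensemble-averaged MSD: per-lag mean of per-track TA-MSDs.

    Tracks are weighted equally; lags contributed by fewer than
    ``min_tracks_per_lag`` tracks are dropped.
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("empty track collection")
    dt = tracks[0].frame_interval
    acc = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    pair_counts = np.zeros(max_lag, dtype=int)
    for traj in tracks:
        if traj.n_points < 2:
            continue
        curve = compute_tamsd(traj, min(max_lag, traj.n_points - 1))
        m = len(curve.values)
        acc[:m] += curve.values
        counts[:m] += 1
        pair_counts[:m] += curve.n_pairs
    keep = counts >= max(1, min_tracks_per_lag)
    if not np.any(keep):
        raise ValueError("no lag has enough contributing tracks")
    lags = np.arange(1, max_lag + 1)[keep] * dt
    return MSDCurve(lags, acc[keep] / counts[keep], pair_counts[keep],
                    n_tracks_averaged=len(tracks))


def fit_anomalous(msd: MSDCurve, fit_range: tuple | None = None,
                  min_pairs: int = 5, constrain_sigma: bool = True) -> AnomalousFit:
    """Weighted least-squares fit of MSD(t) = A t^alpha + sigma².

    Weights are the per-lag pair counts; the non-linear fit is initialized
    from a log-log regression of the raw curve. ``sigma²`` is fitted as a
    free non-negative offset (set ``constrain_sigma=False`` to allow a
    negative offset). Non-convergence returns a flagged fit, never silent
    defaults.
    """
    mask = np.asarray(msd.n_pairs) >= min_pairs
    if fit_range is not None:
        lo, hi = fit_range
        mask &= (msd.lags > lo) & (msd.lags <= hi)
    t = msd.lags[mask]
    y = msd.values[mask]
    w = np.asarray(msd.n_pairs, dtype=float)[mask]
    if len(t) < 4:
        raise ValueError("need at least 4 lags in the fit range")
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(np.log(t[pos]), np.log(y[pos]), 1)
        a0 = float(np.clip(slope, 0.05, 2.0))
        A0 = float(np.exp(intercept))
    else:
        a0, A0 = 1.0, max(y.max(), 1e-9)

    def model(tt, A, alpha, sig2):
        return A * tt ** alpha + sig2

    lower = [0.0, 1e-3, 0.0 if constrain_sigma else -np.inf]
    upper = [np.inf, 2.0, np.inf]
    try:
        popt, _ = curve_fit(
            model, t, y, p0=[A0, a0, 0.0 if constrain_sigma else min(y.min(), 0.0)],
            sigma=1.0 / np.sqrt(w), bounds=(lower, upper), maxfev=20_000,
        )
        converged = True
    except RuntimeError:
        logger.warning("anomalous fit failed to converge; returning initialization")
        popt, converged = [A0, a0, 0.0], False
    resid = y - model(t, *popt)
    ss_res = float(np.sum(w * resid ** 2))
    ss_tot = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    sig2 = popt[2]
    sigma = float(np.sqrt(sig2)) if sig2 >= 0 else -float(np.sqrt(-sig2))
    used_range = (float(t[0]), float(t[-1])) if fit_range is None else tuple(fit_range)
    return AnomalousFit(float(popt[0]), float(popt[1]), sigma, r2,
                        used_range, converged)


def effective_diffusion(msd: MSDCurve, fit: AnomalousFit | None = None,
                        tangent_window: tuple = (0.1, 1.0)) -> EffectiveDiffusion:
    """Two effective-D summaries of an MSD curve.

    ``D_first4`` is the least-squares slope over the first four lag points
    divided by 4 (reported as missing when fewer than 4 lags exist);
    ``D_tangent`` averages the tangent of the fitted power law over the
    window, in closed form A (t1^a - t0^a) / (4 (t1 - t0)).
    """
    d4 = None
    if len(msd.lags) >= 4:
        p = np.polyfit(msd.lags[:4], msd.values[:4], 1)[0]
        d4 = float(p / 4.0)
    dtan = None
    if fit is not None and fit.converged:
        t0, t1 = tangent_window
        dtan = float(fit.A * (t1 ** fit.alpha - t0 ** fit.alpha) / (4.0 * (t1 - t0)))
    return EffectiveDiffusion(d4, dtan)
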
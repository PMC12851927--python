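"""Behavioral statistics: lick-time summaries and hazard-rate analysis.

The hazard rate ``h(t) = f(t) / (1 - F(t))`` is the instantaneous probability
of the first lick occurring at ``t`` given that it has not occurred yet — the
moment-by-moment drive to lick.  A "pause" of the underlying timer shifts the
hazard curve in time; a "rewind" drives it to zero at the manipulation offset.
Curves are binned at 20 ms and smoothed with a centered 5-bin boxcar; temporal
shifts between two curves are measured as the difference of the 50%-rise
points of sigmoid fits restricted to times before the CDF reaches 80% (beyond
that the at-risk denominator is small and the hazard is noisy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .core import Trial

__all__ = [
    "HazardCurve",
    "LickStats",
    "hazard_rate",
    "hazard_shift",
    "lick_stats",
    "trials_licking_after",
]


@dataclass
class HazardCurve:
    """Hazard of a first-lick-time distribution on a fixed 20-ms lattice.

    ``h`` is the boxcar-smoothed hazard (probability per bin), ``h_raw`` the
    unsmoothed one; ``f`` and ``F`` are the per-bin event probability and the
    CDF at bin ends.  ``at_risk`` counts trials surviving (and uncensored) at
    each bin start.
    """

    t: np.ndarray          # bin centers, s
    h: np.ndarray          # smoothed hazard, probability / bin
    h_raw: np.ndarray
    f: np.ndarray
    F: np.ndarray
    at_risk: np.ndarray
    bin_size: float
    smooth_bins: int
    n_trials: int

    def t80(self) -> float:
        """Time at which the CDF reaches 80% of its final value, capped at 0.8."""
        target = min(0.8, 0.8 * self.F[-1]) if self.F[-1] < 0.8 else 0.8
        idx = np.searchsorted(self.F, target)
        idx = min(idx, self.t.size - 1)
        return self.t[idx]

    def value_at(self, time: float) -> float:
        """Smoothed hazard in the bin containing ``time``."""
        idx = int(np.clip(np.floor((time - (self.t[0] - self.bin_size / 2)) / self.bin_size),
                          0, self.t.size - 1))
        return float(self.h[idx])


def _centered_boxcar(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    # shrinking window at the edges keeps constants unchanged
    half = width // 2
    out = np.empty_like(x, dtype=float)
    for i in range(x.size):
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def hazard_rate(
    lick_times: np.ndarray | Sequence[float],
    t_max: float = 5.0,
    bin_size: float = 0.02,
    smooth_bins: int = 5,
) -> HazardCurve:
    """Empirical hazard of first-lick times, 20-ms bins, 5-bin boxcar.

    ``lick_times`` may contain NaN for no-lick trials; these enter as
    right-censored at ``t_max`` (they survive the whole observation window),
    so they deflate the hazard without ever contributing an event.  Raises
    ``ValueError`` if every trial is censored.
    """
    lt = np.asarray(lick_times, dtype=float)
    n = lt.size
    licked = np.isfinite(lt)
    if not licked.any():
        raise ValueError("hazard undefined: all trials are no-lick")
    n_bins = int(round(t_max / bin_size))
    edges = bin_size * np.arange(n_bins + 1)
    events, _ = np.histogram(lt[licked], bins=edges)
    late = int(np.sum(lt[licked] >= t_max))  # events beyond the horizon stay at risk, never fire
    cum_events = np.cumsum(events)
    at_risk = n - np.concatenate(([0], cum_events[:-1]))
    with np.errstate(invalid="ignore", divide="ignore"):
        h_raw = np.where(at_risk > 0, events / np.maximum(at_risk, 1), 0.0)
    f = events / n
    F = cum_events / n
    h = _centered_boxcar(h_raw, smooth_bins)
    del late
    return HazardCurve(
        t=0.5 * (edges[:-1] + edges[1:]),
        h=h,
        h_raw=h_raw,
        f=f,
        F=F,
        at_risk=at_risk,
        bin_size=bin_size,
        smooth_bins=smooth_bins,
        n_trials=n,
    )


def _sigmoid(t, base, amp, midpoint, scale):
    return base + amp / (1.0 + np.exp(-(t - midpoint) / scale))


@dataclass
class SigmoidFit:
    midpoint: float
    params: np.ndarray | None
    converged: bool


def fit_hazard_sigmoid(curve: HazardCurve) -> SigmoidFit:
    """Fit a 4-parameter logistic to the smoothed hazard up to ``t80``.

    Falls back to the half-maximum crossing (linear interpolation) when the
    fit does not converge; the fallback is flagged via ``converged=False``.
    """
    t80 = curve.t80()
    mask = curve.t <= t80
    t, h = curve.t[mask], curve.h[mask]
    if t.size < 5:
        mask = np.ones_like(curve.t, dtype=bool)
        t, h = curve.t, curve.h
    amp0 = max(h.max() - h.min(), 1e-6)
    mid0 = t[np.searchsorted(h, h.min() + amp0 / 2, sorter=np.argsort(h))] if h.size else 0.5
    p0 = [max(h.min(), 1e-9), amp0, float(np.clip(mid0, t[0], t[-1])), 0.1]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _sigmoid, t, h, p0=p0,
                bounds=([0, 0, t[0] - 1.0, 1e-3], [np.inf, np.inf, t[-1] + 1.0, 2.0]),
                maxfev=20000,
            )
        return SigmoidFit(midpoint=float(popt[2]), params=popt, converged=True)
    except RuntimeError:
        half = h.min() + 0.5 * (h.max() - h.min())
        above = np.nonzero(h >= half)[0]
        if above.size == 0 or above[0] == 0:
            return SigmoidFit(midpoint=float(t[0]), params=None, converged=False)
        i = above[0]
        frac = (half - h[i - 1]) / max(h[i] - h[i - 1], 1e-12)
        return SigmoidFit(midpoint=float(t[i - 1] + frac * (t[i] - t[i - 1])), params=None,
                          converged=False)


def half_max_crossing(curve: HazardCurve, level: float | None = None) -> float:
    """First upward crossing of half the curve's maximum smoothed hazard.

    This is the 50%-rise point read directly off the curve (the sigmoid fit's
    midpoint when the fit is exact) and is robust to transient dips carved
    into the hazard by a manipulation, which pull a global sigmoid fit around.
    Like the sigmoid fit, the search is limited to times before the CDF
    reaches 80% of its final value, beyond which the small at-risk
    denominator makes the hazard noisy.
    """
    mask = curve.t <= curve.t80()
    t, h = curve.t[mask], curve.h[mask]
    half = 0.5 * h.max() if level is None else level
    above = np.nonzero(h >= half)[0]
    if above.size == 0:
        return float(t[-1])
    i = above[0]
    if i == 0:
        return float(t[0])
    frac = (half - h[i - 1]) / max(h[i] - h[i - 1], 1e-12)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def hazard_shift(
    curve_a: HazardCurve, curve_b: HazardCurve, method: str = "sigmoid"
) -> float:
    """Temporal shift (s) of ``curve_b`` relative to ``curve_a``.

    Positive values mean the hazard of ``b`` rises later.  With
    ``method="sigmoid"`` both curves are fitted with a 4-parameter sigmoid
    below their own ``t80`` and the 50%-rise midpoints are differenced; with
    ``method="crossing"`` the 50% points are read as half-maximum crossings.
    """
    if method == "sigmoid":
        fa, fb = fit_hazard_sigmoid(curve_a), fit_hazard_sigmoid(curve_b)
        return fb.midpoint - fa.midpoint
    if method == "crossing":
        # Horizontal displacement at matched hazard levels, averaged over the
        # upper portion of the reference curve's rise (its 50-75%-mass
        # points).  For a transient manipulation the post-offset hazard is an
        # exact time translation of the reference, so this reads the
        # translation off directly; levels lower down the rise can fall
        # inside the manipulation window, where the hazard reflects the
        # manipulation itself rather than the shifted timer state.
        f_norm = curve_a.F / curve_a.F[-1]
        deltas = []
        for mass in np.arange(0.50, 0.76, 0.05):
            level = curve_a.h[min(np.searchsorted(f_norm, mass), curve_a.h.size - 1)]
            deltas.append(half_max_crossing(curve_b, level) - half_max_crossing(curve_a, level))
        return float(np.mean(deltas))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class LickStats:
    median_lick_time: float | None
    no_lick_rate: float
    lick_times: np.ndarray
    n_trials: int
    post_stim_lick_rate: float | None = None

    def cdf(self, t: np.ndarray) -> np.ndarray:
        """Empirical cumulative lick-time distribution over all trials."""
        lt = self.lick_times[np.isfinite(self.lick_times)]
        return np.searchsorted(np.sort(lt), t, side="right") / max(self.n_trials, 1)


def trials_licking_after(trials: Sequence[Trial], onset: float) -> list[Trial]:
    """Trials whose first lick falls after ``onset`` (plus no-lick trials).

    Perturbation comparisons condition on the first lick occurring after the
    photostimulation onset in stimulated and control trials alike, so that
    trials already resolved before the manipulation cannot dilute the effect.
    """
    return [t for t in trials if t.first_lick_time is None or t.first_lick_time > onset]


def lick_stats(
    trials: Sequence[Trial],
    no_lick_horizon: float = 5.0,
    min_lick_time: float | None = None,
) -> LickStats:
    """Summary statistics of first-lick times for a set of cue trials.

    ``no_lick_rate`` is the fraction of cue trials without a lick within
    ``no_lick_horizon`` seconds of the cue.  ``min_lick_time`` applies the
    perturbation-comparison restriction (licks must occur after that time).
    The post-stimulation lick rate — the probability of licking within 0.6 s
    of the photostimulation offset in no-cue trials — is reported when
    perturbed no-cue trials are present.
    """
    if min_lick_time is not None:
        trials = trials_licking_after(trials, min_lick_time)
    cue = [t for t in trials if t.cue_present]
    lt = np.array([np.nan if t.first_lick_time is None else t.first_lick_time for t in cue])
    if lt.size == 0:
        return LickStats(None, 0.0, lt, 0)
    responded = np.isfinite(lt) & (lt <= no_lick_horizon)
    no_lick_rate = 1.0 - responded.mean()
    median = float(np.median(lt[np.isfinite(lt)])) if np.isfinite(lt).any() else None

    nocue_stim = [
        t for t in trials if not t.cue_present and t.perturbation is not None
    ]
    post_rate = None
    if nocue_stim:
        hits = [
            t.first_lick_time is not None
            and t.perturbation.offset < t.first_lick_time <= t.perturbation.offset + 0.6
            for t in nocue_stim
        ]
        post_rate = float(np.mean(hits))
    return LickStats(median, float(no_lick_rate), lt, len(cue), post_rate)
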
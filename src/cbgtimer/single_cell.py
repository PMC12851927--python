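"""Per-neuron analyses: warping, ramping characterization, modulation tests.

Temporal warping linearly rescales post-cue spike times by each trial's lick
time (``t_warped = t * LT_target / LT``, ``LT_target`` = 1 s); a neuron
whose activity pattern stretches with trial duration ("temporal scaling")
shows reduced across-trial rate variance after warping, whereas a neuron
firing in absolute time does not.  Ramping is characterized by
cross-validated polynomial fits of the cue-to-lick PSTH; modulation tests
compare pre-lick firing with the pre-cue baseline (signed-rank) and
photostimulation windows against control trials (rank-sum).  The partial
rank correlation isolates trial-history coding from the correlated upcoming
lick time.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import Session, causal_boxcar

__all__ = [
    "RampFit",
    "warp_spike_times",
    "across_trial_variance",
    "characterize_ramp",
    "prelick_modulation",
    "photostim_modulation",
    "partial_rank_correlation",
]


def warp_spike_times(
    spikes_after_cue: np.ndarray, lick_time: float, target: float = 1.0
) -> np.ndarray:
    """Linearly rescale post-cue spike times to a common trial duration.

    ``t_warped = t * target / LT``; a spike exactly at the lick maps exactly
    to ``target``.  Spike counts are preserved (pure rescaling).
    """
    if not lick_time > 0:
        raise ValueError("lick time must be > 0")
    return np.asarray(spikes_after_cue, dtype=float) * (target / lick_time)


def _window_rates(
    session: Session,
    unit_index: int,
    trial_indices: np.ndarray,
    windows: list[tuple[float, float]],
    warp: bool,
    target: float = 1.0,
) -> np.ndarray:
    """Per-trial firing rate in each window (trials x windows), optionally warped."""
    unit = session.units[unit_index]
    out = np.zeros((len(trial_indices), len(windows)))
    for r, i in enumerate(trial_indices):
        onset = session.cue_onsets[i]
        lick = session.trials[i].first_lick_time
        rel = unit.spike_times - onset
        rel = rel[(rel >= 0) & (rel <= (lick if lick is not None else np.inf))]
        if warp:
            # phase-locked windows: centered at fixed fractions of the trial
            # (warped time) but of fixed 200-ms original duration, so the
            # Poisson sampling noise matches the time-locked comparison and
            # only the alignment of the rate profile differs
            scale = lick / target
            for c, (lo, hi) in enumerate(windows):
                center = 0.5 * (lo + hi) * scale
                half = 0.5 * (hi - lo)
                a, b = max(center - half, 0.0), min(center + half, lick)
                out[r, c] = np.sum((rel >= a) & (rel < b)) / max(b - a, 1e-9)
        else:
            for c, (lo, hi) in enumerate(windows):
                out[r, c] = np.sum((rel >= lo) & (rel < hi)) / (hi - lo)
    return out


@dataclass
class VarianceResult:
    var_orig: float
    var_warped: float
    signal_diff: float                 # Poisson-corrected var_orig - var_warped
    significant_reduction: bool
    ci: tuple[float, float]


def across_trial_variance(
    session: Session,
    unit_index: int,
    trial_indices: np.ndarray | None = None,
    n_windows: int = 5,
    window_size: float = 0.2,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> VarianceResult:
    """Across-trial rate variance before vs after warping.

    Variance is computed per post-cue 200-ms window (five windows) and
    averaged.  Significance of the reduction is assessed by bootstrapping
    trials (1000 draws) of ``var_orig - var_warped``; the reduction is
    significant when the 95% CI excludes zero from above.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if trial_indices is None:
        # licks must cover the analysis windows, otherwise truncation at the
        # lick dominates the unwarped variance
        span = n_windows * window_size
        trial_indices = np.array(
            [
                i
                for i, t in enumerate(session.trials)
                if t.licked and t.cue_present and t.first_lick_time >= span
            ]
        )
    if trial_indices.size < 2:
        raise ValueError("need at least 2 trials")
    windows = [(k * window_size, (k + 1) * window_size) for k in range(n_windows)]
    orig = _window_rates(session, unit_index, trial_indices, windows, warp=False)
    warped = _window_rates(session, unit_index, trial_indices, windows, warp=True)

    def signal_var(x: np.ndarray) -> float:
        # across-trial variance minus the Poisson sampling contribution
        # (mean rate / window duration), so windows sampling different
        # portions of the ramp compare on signal alone
        return float(
            (x.var(axis=0, ddof=1) - x.mean(axis=0) / window_size).mean()
        )

    def stat(rows: np.ndarray) -> float:
        return signal_var(orig[rows]) - signal_var(warped[rows])

    n = trial_indices.size
    diffs = np.array([stat(rng.integers(0, n, n)) for _ in range(n_boot)])
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return VarianceResult(
        var_orig=float(orig.var(axis=0, ddof=1).mean()),
        var_warped=float(warped.var(axis=0, ddof=1).mean()),
        signal_diff=stat(np.arange(n)),
        significant_reduction=bool(lo > 0),
        ci=(float(lo), float(hi)),
    )


@dataclass
class RampFit:
    order: int
    coeffs: np.ndarray
    grid: np.ndarray
    fitted: np.ndarray
    monotonic: bool
    peak_time: float
    n_trials: int


def _trial_psth(
    session: Session,
    unit_index: int,
    trial_indices: np.ndarray,
    grid: np.ndarray,
    bin_size: float = 0.001,
    boxcar: float = 0.2,
) -> np.ndarray:
    """Mean rate on ``grid`` from 1-ms binned, 200-ms causal-boxcar PSTHs."""
    unit = session.units[unit_index]
    t_max = grid[-1] + bin_size
    n_bins = int(round(t_max / bin_size))
    edges = bin_size * np.arange(n_bins + 1)
    acc = np.zeros(n_bins)
    for i in trial_indices:
        onset = session.cue_onsets[i]
        rel = unit.spike_times - onset
        rel = rel[(rel >= 0) & (rel < t_max)]
        counts, _ = np.histogram(rel, bins=edges)
        acc += counts
    rate = acc / (trial_indices.size * bin_size)
    rate = causal_boxcar(rate[None, None, :], int(round(boxcar / bin_size)))[0, 0]
    centers = edges[:-1] + bin_size / 2
    return np.interp(grid, centers, rate)


def characterize_ramp(
    session: Session,
    unit_index: int,
    lick_range: tuple[float, float] = (1.25, 1.5),
    orders: range = range(1, 9),
    n_repeats: int = 10,
    min_trials: int = 50,
    seed: int | np.random.Generator | None = None,
) -> RampFit | None:
    """Polynomial characterization of the cue-to-lick firing profile.

    Uses trials with lick times inside ``lick_range`` (at least 50).  Ten
    times: trials are split into random halves, orders 1-8 are fit to the
    train PSTH (10-ms grid from cue to the group's minimum lick time) and
    scored by MSE on the test PSTH; the winning order is the mode over
    repeats (ties broken toward the smallest order).  The final fit on all
    trials yields monotonicity (derivative keeps one sign) and peak time.
    Returns ``None`` (unit skipped) with fewer than ``min_trials`` trials.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = np.array(
        [
            i
            for i, t in enumerate(session.trials)
            if t.licked and lick_range[0] <= t.first_lick_time < lick_range[1]
        ]
    )
    if idx.size < min_trials:
        return None
    t_end = min(session.trials[i].first_lick_time for i in idx)
    grid = np.arange(0.0, t_end, 0.01)

    winners = []
    for _ in range(n_repeats):
        perm = rng.permutation(idx)
        half = idx.size // 2
        train, test = perm[:half], perm[half:]
        y_train = _trial_psth(session, unit_index, train, grid)
        y_test = _trial_psth(session, unit_index, test, grid)
        errs = []
        for order in orders:
            coef = np.polyfit(grid, y_train, order)
            errs.append(np.mean((np.polyval(coef, grid) - y_test) ** 2))
        winners.append(list(orders)[int(np.argmin(errs))])
    counts = Counter(winners)
    top = max(counts.values())
    best_order = min(o for o, c in counts.items() if c == top)

    y_all = _trial_psth(session, unit_index, idx, grid)
    coef = np.polyfit(grid, y_all, best_order)
    fitted = np.polyval(coef, grid)
    deriv = np.polyval(np.polyder(coef), grid)
    monotonic = bool(np.all(deriv >= 0) or np.all(deriv <= 0))
    return RampFit(
        order=best_order, coeffs=coef, grid=grid, fitted=fitted,
        monotonic=monotonic, peak_time=float(grid[int(np.argmax(fitted))]),
        n_trials=int(idx.size),
    )


@dataclass
class ModulationResult:
    p_value: float
    direction: str                     # "excited" / "inhibited" / "none"
    excluded_reason: str | None = None


def prelick_modulation(
    session: Session,
    unit_index: int,
    prelick_window: tuple[float, float] = (-0.5, -0.2),
    baseline_window: tuple[float, float] = (-1.0, 0.0),
) -> ModulationResult:
    """Two-sided paired signed-rank: pre-lick rate vs pre-cue baseline.

    Pre-lick is 0.2-0.5 s before the lick; baseline is 0-1 s before the cue,
    paired per trial.
    """
    unit = session.units[unit_index]
    pre, base = [], []
    for i, t in enumerate(session.trials):
        if not (t.licked and t.cue_present):
            continue
        onset = session.cue_onsets[i]
        lick_abs = onset + t.first_lick_time
        rel_lick = unit.spike_times - lick_abs
        pre.append(
            np.sum((rel_lick >= prelick_window[0]) & (rel_lick < prelick_window[1]))
            / (prelick_window[1] - prelick_window[0])
        )
        rel_cue = unit.spike_times - onset
        base.append(
            np.sum((rel_cue >= baseline_window[0]) & (rel_cue < baseline_window[1]))
            / (baseline_window[1] - baseline_window[0])
        )
    pre, base = np.asarray(pre), np.asarray(base)
    if pre.size < 5 or np.all(pre == base):
        return ModulationResult(1.0, "none", "insufficient or constant data")
    res = stats.wilcoxon(pre, base, zero_method="wilcox")
    direction = "excited" if np.mean(pre - base) > 0 else "inhibited"
    return ModulationResult(float(res.pvalue), direction if res.pvalue < 0.05 else "none")


def photostim_modulation(
    session: Session,
    unit_index: int,
    window: tuple[float, float] = (0.05, 0.25),
    min_rate: float = 1.0,
    min_trials: int = 10,
    alpha: float = 0.05,
) -> ModulationResult:
    """Two-sided rank-sum of rates in the post-stimulation-onset window.

    Spikes within 50-250 ms of the photostimulation onset are compared
    between control and stimulated trials.  Trials licking before the
    stimulation onset are excluded; units need > ``min_rate`` spikes/s in
    the window (control trials) and at least ``min_trials`` trials per
    condition.
    """
    unit = session.units[unit_index]
    stim_rates, ctrl_rates = [], []
    onsets = [
        t.perturbation.onset for t in session.trials if t.perturbation is not None
    ]
    if not onsets:
        return ModulationResult(1.0, "none", "no perturbed trials")
    stim_onset = float(np.median(onsets))
    for i, t in enumerate(session.trials):
        if t.licked and t.first_lick_time <= stim_onset:
            continue
        rel = unit.spike_times - (session.cue_onsets[i] + stim_onset)
        rate = np.sum((rel >= window[0]) & (rel < window[1])) / (window[1] - window[0])
        (stim_rates if t.perturbation is not None else ctrl_rates).append(rate)
    stim_rates, ctrl_rates = np.asarray(stim_rates), np.asarray(ctrl_rates)
    if stim_rates.size < min_trials or ctrl_rates.size < min_trials:
        return ModulationResult(1.0, "none", "too few trials per condition")
    if ctrl_rates.mean() <= min_rate:
        return ModulationResult(1.0, "none", "control rate below threshold")
    res = stats.ranksums(stim_rates, ctrl_rates)
    if res.pvalue < alpha:
        direction = "inhibited" if stim_rates.mean() < ctrl_rates.mean() else "excited"
    else:
        direction = "none"
    return ModulationResult(float(res.pvalue), direction)


@dataclass
class PartialCorrelation:
    rho: float
    null_shuffle: np.ndarray
    null_session: np.ndarray | None
    significant: bool


def _partial_spearman(r: np.ndarray, p: np.ndarray, u: np.ndarray) -> float:
    """rho_RP.U = (rho_RP - rho_RU rho_PU) / sqrt((1-rho_RU^2)(1-rho_PU^2))."""
    rho_rp = stats.spearmanr(r, p).statistic
    rho_ru = stats.spearmanr(r, u).statistic
    rho_pu = stats.spearmanr(p, u).statistic
    denom = np.sqrt((1 - rho_ru**2) * (1 - rho_pu**2))
    if denom < 1e-12:
        raise ValueError("degenerate partial correlation (|rho| = 1 with conditioner)")
    return float((rho_rp - rho_ru * rho_pu) / denom)


def partial_rank_correlation(
    rate: np.ndarray,
    prev_lick: np.ndarray,
    upcoming_lick: np.ndarray,
    n_shuffles: int = 1000,
    other_sessions: list[np.ndarray] | None = None,
    seed: int | np.random.Generator | None = None,
) -> PartialCorrelation:
    """Spearman partial correlation of firing with previous lick time.

    Removes the effect of the upcoming lick time via the standard partial-
    correlation formula on rank correlations.  Nulls: (a) shuffling the
    trial order of the history variable (1000 iterations) and (b), when
    other sessions' previous-lick vectors are supplied, a session
    permutation pairing the rates with history from a different session.
    The observed value is significant when outside the 95% band of the
    shuffle null.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate = np.asarray(rate, float)
    prev_lick = np.asarray(prev_lick, float)
    upcoming_lick = np.asarray(upcoming_lick, float)
    if rate.size < 20:
        raise ValueError("need at least 20 trials")
    for name, v in (("rate", rate), ("prev_lick", prev_lick), ("upcoming", upcoming_lick)):
        if np.all(v == v[0]):
            raise ValueError(f"constant input vector: {name}")
    rho = _partial_spearman(rate, prev_lick, upcoming_lick)

    null_shuffle = np.array(
        [
            _partial_spearman(rate, rng.permutation(prev_lick), upcoming_lick)
            for _ in range(n_shuffles)
        ]
    )
    null_session = None
    if other_sessions:
        vals = []
        for _ in range(n_shuffles):
            other = other_sessions[rng.integers(0, len(other_sessions))]
            k = min(other.size, rate.size)
            vals.append(_partial_spearman(rate[:k], other[:k], upcoming_lick[:k]))
        null_session = np.array(vals)
    lo, hi = np.percentile(null_shuffle, [2.5, 97.5])
    return PartialCorrelation(
        rho=rho, null_shuffle=null_shuffle, null_session=null_session,
        significant=bool(rho < lo or rho > hi),
    )
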
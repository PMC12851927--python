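"""Targeted dimensionality reduction and population-level analyses.

Task-related directions ("modes") in population activity space are defined
from window differences of trial-mean activity: each mode is the unit-norm
difference between the mean activity in a defining window and the pre-cue
baseline (0-1 s before cue).  The defining windows are 0-0.3 s after the cue
(cue mode), 0.5-0.8 s before the lick (middle mode), 0.2-0.5 s before the
lick (ramp mode, ``w = r_before_lick - r_before_cue``), and 0-0.3 s after
the lick (execution mode).  Gram-Schmidt orthogonalization is applied in a
fixed order: middle is orthogonalized to ramp, cue to both, execution to
ramp.  The trial-history mode — each neuron's Spearman correlation between
inter-trial-interval firing and the regression-predicted lick time — is not
orthogonalized to anything.

Also here: projections and variance explained, mode angles with shuffle
nulls, population correlation matrices with peak-correlation traces,
pseudo-session assembly, and the 2-D (ramp x middle) vector-field analysis
used to distinguish rewinding from collapse toward zero activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import LICK_TIME_RANGES, Session

__all__ = [
    "ModeSet",
    "MODE_WINDOWS",
    "define_modes",
    "define_trial_history_mode",
    "project",
    "variance_explained",
    "mode_angle",
    "population_correlation_analysis",
    "group_mean_activity",
    "vector_field_2d",
    "assemble_pseudo_session",
]

#: Defining windows (seconds; negative = before the alignment event).
MODE_WINDOWS = {
    "cue": ("cue", 0.0, 0.3),
    "middle": ("lick", -0.8, -0.5),
    "ramp": ("lick", -0.5, -0.2),
    "execution": ("lick", 0.0, 0.3),
    "baseline": ("cue", -1.0, 0.0),
}

#: Orthogonalization order: mode -> modes it is made orthogonal to.
ORTHOGONALIZATION = {
    "middle": ("ramp",),
    "cue": ("middle", "ramp"),
    "execution": ("ramp",),
}


@dataclass
class ModeSet:
    """Unit-norm population directions with their orthogonalization record."""

    modes: dict[str, np.ndarray]
    orthogonalized: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.modes[name]

    def check(self, tol: float = 1e-10) -> None:
        for name, vec in self.modes.items():
            if abs(np.linalg.norm(vec) - 1.0) > 1e-9:
                raise AssertionError(f"mode {name} not unit norm")
        for name, others in self.orthogonalized.items():
            for other in others:
                if abs(self.modes[name] @ self.modes[other]) > tol:
                    raise AssertionError(f"modes {name} and {other} not orthogonal")


def _window_mean_rates(
    session: Session, trial_indices: np.ndarray, anchor: str, lo: float, hi: float
) -> np.ndarray:
    """Per-unit mean rate in [lo, hi) relative to cue or lick, over trials."""
    rates = np.zeros(session.n_units)
    for u, unit in enumerate(session.units):
        total, used = 0.0, 0
        for i in trial_indices:
            trial = session.trials[i]
            if anchor == "lick":
                if trial.first_lick_time is None:
                    continue
                t0 = session.cue_onsets[i] + trial.first_lick_time
            else:
                t0 = session.cue_onsets[i]
            st = unit.spike_times
            total += np.sum((st >= t0 + lo) & (st < t0 + hi)) / (hi - lo)
            used += 1
        rates[u] = total / max(used, 1)
    return rates


def define_modes(
    session: Session,
    trial_indices: np.ndarray | None = None,
    names: tuple[str, ...] = ("cue", "middle", "ramp", "execution"),
) -> ModeSet:
    """Window-difference modes with Gram-Schmidt orthogonalization.

    Each mode is (mean activity in its window - mean activity in the pre-cue
    baseline window), normalized to unit length; orthogonalization follows
    the fixed order recorded in ``ORTHOGONALIZATION`` (ramp first, untouched).
    """
    if session.n_units < 1:
        raise ValueError("need at least one unit")
    if trial_indices is None:
        trial_indices = np.array(
            [i for i, t in enumerate(session.trials) if t.licked and t.cue_present]
        )
    anchor, lo, hi = MODE_WINDOWS["baseline"]
    base = _window_mean_rates(session, trial_indices, anchor, lo, hi)
    raw: dict[str, np.ndarray] = {}
    for name in names:
        anchor, lo, hi = MODE_WINDOWS[name]
        diff = _window_mean_rates(session, trial_indices, anchor, lo, hi) - base
        norm = np.linalg.norm(diff)
        if norm < 1e-12:
            raise ValueError(f"zero difference vector for mode {name!r}")
        raw[name] = diff / norm

    modes: dict[str, np.ndarray] = {"ramp": raw["ramp"]} if "ramp" in raw else {}
    ortho_rec: dict[str, tuple[str, ...]] = {}
    # fixed dependency order: ramp stays raw; middle and execution are made
    # orthogonal to ramp; cue to both middle and ramp
    order = [n for n in ("middle", "execution", "cue") if n in names]
    order += [n for n in names if n not in order and n != "ramp"]
    for name in order:
        vec = raw[name].copy()
        against = tuple(m for m in ORTHOGONALIZATION.get(name, ()) if m in modes)
        for other in against:
            vec = vec - (vec @ modes[other]) * modes[other]
        norm = np.linalg.norm(vec)
        if norm < 1e-12:
            raise ValueError(f"mode {name!r} degenerate after orthogonalization")
        modes[name] = vec / norm
        if against:
            ortho_rec[name] = against
    return ModeSet(modes=modes, orthogonalized=ortho_rec)


def define_trial_history_mode(
    iti_rates: np.ndarray, predicted_lick: np.ndarray
) -> np.ndarray:
    """Trial-history mode from ITI firing vs regression-predicted lick time.

    ``iti_rates`` is trials x units (rates 0-1 s before the cue);
    ``predicted_lick`` is the per-trial prediction of the trial-history
    regression (lags 1-2 of previous lick time and its reward interaction).
    Each neuron's loading is its Spearman rank correlation; constant-rate
    units get 0 with a warning; the vector is normalized to unit length.
    """
    iti_rates = np.asarray(iti_rates, float)
    predicted_lick = np.asarray(predicted_lick, float)
    n_units = iti_rates.shape[1]
    loadings = np.zeros(n_units)
    for u in range(n_units):
        col = iti_rates[:, u]
        if np.all(col == col[0]):
            warnings.warn(f"unit {u}: constant ITI activity; loading set to 0")
            continue
        loadings[u] = stats.spearmanr(col, predicted_lick).statistic
    norm = np.linalg.norm(loadings)
    if norm < 1e-12:
        raise ValueError("trial-history mode degenerate (all loadings zero)")
    return loadings / norm


def project(
    activity: np.ndarray,
    mode: np.ndarray,
    normalization: str = "raw",
    control_sd: float | None = None,
) -> np.ndarray:
    """Project activity (... x units x bins) onto a mode vector.

    ``normalization="control_sd"`` divides by the standard deviation of the
    projection among control trials *without* subtracting the mean, so 0
    keeps meaning zero spiking activity (the convention of the 2-D state-
    space analyses).
    """
    activity = np.asarray(activity, float)
    mode = np.asarray(mode, float)
    if activity.shape[-2] != mode.size:
        raise ValueError("unit-dimension mismatch between activity and mode")
    proj = np.einsum("...ub,u->...b", activity, mode)
    if normalization == "raw":
        return proj
    if normalization == "control_sd":
        sd = float(np.std(proj)) if control_sd is None else control_sd
        if sd < 1e-12:
            raise ValueError("zero control SD")
        return proj / sd
    raise ValueError(f"unknown normalization {normalization!r}")


def variance_explained(
    mean_activity: np.ndarray,
    modes: dict[str, np.ndarray],
    baseline: np.ndarray | None = None,
    skip_baseline_subtraction: tuple[str, ...] = ("trial_history",),
) -> dict[str, float]:
    """Proportion of squared activity captured by each mode.

    ``mean_activity`` is units x bins (trial-group mean, 200-ms causal
    boxcar applied upstream); ``baseline`` is the per-unit mean 0-0.2 s
    before the cue, subtracted before computing power (except for modes
    listed in ``skip_baseline_subtraction``, per the trial-history-mode
    convention).  For mutually orthogonal modes the proportions sum to <= 1
    (Bessel).
    """
    A = np.asarray(mean_activity, float)
    base = np.zeros(A.shape[0]) if baseline is None else np.asarray(baseline, float)
    centered = A - base[:, None]
    total = float(np.sum(centered**2))
    if total < 1e-12:
        raise ValueError("zero total activity power")
    out = {}
    for name, w in modes.items():
        source = A if name in skip_baseline_subtraction else centered
        out[name] = float(np.sum((w @ source) ** 2)) / total
    return out


def mode_angle(
    mode_a: np.ndarray,
    mode_b: np.ndarray,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> dict:
    """Cosine similarity with an entry-shuffle null.

    Cosine similarity shrinks toward orthogonality as dimensionality grows,
    so significance is assessed against shuffles of one vector's entries:
    the observed cosine is significant when outside the null's 95% band.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = np.asarray(mode_a, float)
    b = np.asarray(mode_b, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("zero vector")
    cos = float(a @ b / (na * nb))
    null = np.array([a @ rng.permutation(b) / (na * nb) for _ in range(n_shuffles)])
    lo, hi = np.percentile(null, [2.5, 97.5])
    return {"cosine": cos, "null": null, "significant": bool(cos < lo or cos > hi)}


def group_mean_activity(
    session: Session,
    trial_indices: np.ndarray,
    bin_size: float = 0.2,
    window: tuple[float, float] = (0.0, 2.0),
    smoothing: float = 0.0,
) -> np.ndarray:
    """Units x bins mean firing rate over a trial group, cue-aligned."""
    from .core import bin_spikes

    tensor = bin_spikes(
        session, bin_size, alignment="cue", window=window,
        smoothing=smoothing, trial_indices=trial_indices,
    )
    return tensor.values.mean(axis=0)


def population_correlation_analysis(
    reference: np.ndarray,
    comparison: np.ndarray,
    threshold: float = 0.8,
) -> dict:
    """Pearson correlation between population vectors at all time-bin pairs.

    ``reference`` and ``comparison`` are units x bins mean-activity matrices
    (200-ms bins).  Entry [i, j] of the matrix correlates comparison bin i
    with reference bin j.  The peak trace gives, per reference bin, the
    comparison time with maximal correlation, emitted as NaN when the
    maximum does not exceed ``threshold`` or the column is degenerate.
    """
    ref = np.asarray(reference, float)
    comp = np.asarray(comparison, float)
    if ref.shape[0] < 2 or comp.shape[0] < 2:
        raise ValueError("need at least 2 units")
    nr, nc = ref.shape[1], comp.shape[1]
    corr = np.full((nc, nr), np.nan)
    ref_c = ref - ref.mean(axis=0)
    comp_c = comp - comp.mean(axis=0)
    ref_sd = np.linalg.norm(ref_c, axis=0)
    comp_sd = np.linalg.norm(comp_c, axis=0)
    for i in range(nc):
        if comp_sd[i] < 1e-12:
            continue  # undefined correlation stays missing, never 0
        for j in range(nr):
            if ref_sd[j] < 1e-12:
                continue
            corr[i, j] = float(comp_c[:, i] @ ref_c[:, j] / (comp_sd[i] * ref_sd[j]))
    peak = np.full(nr, np.nan)
    for j in range(nr):
        col = corr[:, j]
        if np.all(np.isnan(col)):
            continue
        i = int(np.nanargmax(col))
        if col[i] > threshold:
            peak[j] = i
    return {"corr": corr, "peak_index": peak}


def vector_field_2d(
    middle_proj: np.ndarray,
    ramp_proj: np.ndarray,
    lick_bin: np.ndarray,
    stim_trials: np.ndarray,
    stim_bins: tuple[int, int],
    bin_width: float = 0.5,
    min_points: int = 30,
    radial_exclusion: float = np.pi / 6,
) -> dict:
    """Mean flow fields in the (middle, ramp) plane, control vs stimulation.

    ``middle_proj`` / ``ramp_proj`` are trials x bins control-SD-normalized
    projections (50-ms bins, cue to lick; ``lick_bin`` gives each trial's
    last valid bin).  Displacement vectors to the next time bin are pooled:
    control trials contribute all cue-to-lick time points, stimulated trials
    only the bins inside ``stim_bins`` (100-400 ms from the inhibition
    onset).  Vectors are averaged per 0.5-wide spatial bin when more than
    ``min_points`` fall inside.  Bins whose control vector lies within pi/6
    of the through-origin radial line at that location are excluded from the
    angle comparison (flow along the origin line cannot distinguish rewind
    from collapse to zero).
    """
    X, Y = np.asarray(middle_proj, float), np.asarray(ramp_proj, float)
    n_trials, n_bins = X.shape

    def collect(trials: np.ndarray, bin_range: tuple[int, int] | None):
        pts, vecs = [], []
        for tr in trials:
            last = int(lick_bin[tr])
            lo = 0 if bin_range is None else bin_range[0]
            hi = last - 1 if bin_range is None else min(bin_range[1], last - 1)
            for b in range(lo, hi):
                pts.append((X[tr, b], Y[tr, b]))
                vecs.append((X[tr, b + 1] - X[tr, b], Y[tr, b + 1] - Y[tr, b]))
        return np.asarray(pts).reshape(-1, 2), np.asarray(vecs).reshape(-1, 2)

    ctrl_mask = ~np.asarray(stim_trials, bool)
    pts_c, vec_c = collect(np.nonzero(ctrl_mask)[0], None)
    pts_s, vec_s = collect(np.nonzero(~ctrl_mask)[0], stim_bins)

    def binned_field(pts, vecs):
        field: dict[tuple[int, int], np.ndarray] = {}
        if pts.size == 0:
            return field
        keys = np.floor(pts / bin_width).astype(int)
        for key in {tuple(k) for k in keys}:
            mask = np.all(keys == key, axis=1)
            if mask.sum() > min_points:
                field[key] = vecs[mask].mean(axis=0)
        return field

    f_ctrl = binned_field(pts_c, vec_c)
    f_stim = binned_field(pts_s, vec_s)

    angles = {}
    excluded = []
    for key in sorted(set(f_ctrl) & set(f_stim)):
        vc, vs = f_ctrl[key], f_stim[key]
        center = (np.asarray(key) + 0.5) * bin_width
        radial = np.arctan2(center[1], center[0])
        ang_c = np.arctan2(vc[1], vc[0])
        # distance to the through-origin line (mod pi)
        d = abs((ang_c - radial + np.pi / 2) % np.pi - np.pi / 2)
        if d <= radial_exclusion:
            excluded.append(key)
            continue
        ang_s = np.arctan2(vs[1], vs[0])
        diff = (ang_s - ang_c + np.pi) % (2 * np.pi) - np.pi
        angles[key] = float(diff)
    return {
        "control_field": f_ctrl,
        "stim_field": f_stim,
        "angle_diff": angles,
        "excluded_bins": excluded,
    }


def assemble_pseudo_session(
    sessions: list[Session],
    n_define: int = 50,
    min_per_range: int = 10,
    ranges: tuple[tuple[float, float], ...] = LICK_TIME_RANGES,
    bin_size: float = 0.2,
    window: tuple[float, float] = (0.0, 2.0),
    seed: int | np.random.Generator | None = None,
) -> dict:
    """Pool units across sessions into a pseudo-population.

    Per unit: requires more than ``min_per_range`` trials in every lick-time
    range; ``n_define`` randomly chosen unperturbed control trials (first
    lick 1-3 s after the cue) define the modes, and a disjoint set of trials
    provides the per-range projection activity.  Returns the definition-
    trial window means needed for mode construction, the per-range mean
    activity (units x ranges x bins), and exclusion reasons.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    define_rates_lick: list[np.ndarray] = []   # per unit: windows for modes
    define_rates_base: list[np.ndarray] = []
    group_means: list[np.ndarray] = []
    included: list[str] = []
    excluded: dict[str, str] = {}
    n_bins = int(round((window[1] - window[0]) / bin_size))

    for session in sessions:
        lt = session.lick_times()
        eligible = np.array(
            [
                i
                for i, t in enumerate(session.trials)
                if t.licked and t.cue_present and t.perturbation is None
                and 1.0 <= t.first_lick_time <= 3.0
            ]
        )
        from .core import group_trials_by_lick_time

        groups = group_trials_by_lick_time(session.trials, ranges)
        per_range_ok = all(len(v) > min_per_range for v in groups.values())
        for u, unit in enumerate(session.units):
            uid = f"{session.session_id}:{unit.unit_id}"
            if not per_range_ok:
                excluded[uid] = "fewer than the required trials in some lick-time range"
                continue
            if eligible.size <= n_define:
                excluded[uid] = "too few eligible mode-definition trials"
                continue
            chosen = rng.choice(eligible, size=n_define, replace=False)
            chosen_set = set(int(c) for c in chosen)
            # strict disjointness: projection trials exclude definition trials
            proj_groups = {
                k: [i for i in v if i not in chosen_set] for k, v in groups.items()
            }
            assert not any(set(v) & chosen_set for v in proj_groups.values())
            base = _window_mean_rates(session, chosen, "cue", -1.0, 0.0)[u]
            ramp_w = _window_mean_rates(session, chosen, "lick", -0.5, -0.2)[u]
            define_rates_base.append(np.array([base]))
            define_rates_lick.append(np.array([ramp_w]))
            means = np.zeros((len(ranges), n_bins))
            for g, (rkey, tr) in enumerate(sorted(proj_groups.items())):
                sub = group_mean_activity(session, np.array(tr), bin_size, window)
                means[g] = sub[u]
            group_means.append(means)
            included.append(uid)
        del lt
    if not included:
        raise ValueError("no units passed pseudo-session inclusion")
    return {
        "unit_ids": included,
        "excluded": excluded,
        "baseline_rate": np.concatenate(define_rates_base),
        "prelick_rate": np.concatenate(define_rates_lick),
        "group_activity": np.stack(group_means),   # units x ranges x bins
        "ranges": ranges,
    }
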
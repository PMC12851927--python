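"""Synthetic session generator with known ground truth.

Generates behavior and spikes with the statistical structure the analysis
stages assume, so that every stage (trial-history regression, warping,
mode decomposition, decoding, matched-pair perturbation comparisons) can be
validated against planted parameters without recorded data.

Behavior
--------
Lick times follow a trial-history process: the predicted lick time of trial
``n`` is ``mu_n = beta0 + sum_k betaT_k * LT_{n-k} + sum_k betaTR_k *
LT_{n-k} * R_{n-k}`` over the most recent licked trials, and the realized
lick time is drawn from an inverse Gaussian with mean ``mu_n`` and shape
``lambda_gen`` (the same distributional family the accumulator timer
assumes), clipped below at 0.2 s.  Reward requires licking at or after the
current delay, delays switch in blocks of 30-70 trials, inter-trial
intervals are 1 s plus an exponential with mean 3 s truncated at 7 s, and
roughly 10% of trials omit the cue (and are never rewarded).

Spikes
------
Each unit is a Poisson process at 1-ms resolution whose rate combines a
baseline, a cue-to-lick ramp — temporally *scalable* (a fixed smoothstep
profile stretched to each trial's lick time) or in absolute time — and a
tonic trial-history component proportional to the standardized predicted
lick time, present throughout the inter-trial interval and the trial.

Perturbations are modeled at the rate level through a shared internal clock
``u(t)``: ALM-silencing-like trials pause the clock (and multiplicatively
suppress rates during the stimulus); D1-inhibition-like trials rewind it at
a configurable rate.  Ramps read the clock, so lick times and population
trajectories shift consistently, and the planted shift is recorded per
trial in the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import PerturbationSpec, Session, Trial, Unit

__all__ = [
    "BehaviorGenConfig",
    "NeuralGenConfig",
    "GroundTruth",
    "make_behavior",
    "make_spikes",
    "make_session",
    "internal_clock",
]


@dataclass(frozen=True)
class BehaviorGenConfig:
    n_trials: int = 600
    delay_levels: tuple[float, ...] = (1.0, 3.0)
    block_length_range: tuple[int, int] = (30, 70)
    beta0: float = 1.2
    beta_T: tuple[float, ...] = (0.3, 0.0)       # lags 1, 2
    beta_TR: tuple[float, ...] = (-0.2, 0.0)
    dispersion: float = 12.0                      # IG shape lambda_gen
    min_lick: float = 0.2
    iti_mean: float = 3.0
    iti_offset: float = 1.0
    iti_max: float = 7.0
    p_no_cue: float = 0.10
    no_lick_horizon: float = 5.0
    # optional perturbation block
    perturb_fraction: float = 0.0
    perturb_kind: str = "pause"                   # "pause" (silencing) or "rewind"
    perturb_target: str = "ALM"
    perturb_onset: float = 0.6
    perturb_duration: float = 0.6
    perturb_ramp_down: float = 0.3
    rewind_rate: float = 2.0                      # clock units/s drained during rewind

    def __post_init__(self) -> None:
        if not self.dispersion > 0:
            raise ValueError("dispersion must be > 0")
        if not 0 <= self.p_no_cue < 1:
            raise ValueError("p_no_cue must be in [0, 1)")


@dataclass(frozen=True)
class NeuralGenConfig:
    n_units: int = 30
    area: str = "ALM"
    baseline_rate: float = 5.0
    ramp_gain: float = 15.0                       # peak ramp amplitude, spikes/s
    scalable_fraction: float = 0.7
    history_fraction: float = 0.4
    history_gain: float = 2.0                     # spikes/s per SD of predicted lick time
    speed_fraction: float = 0.25                  # units carrying the trial's drive 1/LT
    speed_gain: float = 4.0                       # spikes/s per SD of 1/LT, cue-gated
    dt: float = 0.001
    common_gain_sd: float = 0.10                  # shared per-trial multiplicative gain
    monotone_fraction: float = 0.4                # ramp-to-lick units; rest peak mid-trial
    silencing_floor: float = 0.02                 # rate multiplier during silencing
    seed_offset: int = 7919                       # decorrelates spike stream from behavior


@dataclass
class GroundTruth:
    """Planted parameters stored alongside every synthetic session."""

    mu: np.ndarray                                # predicted lick time per trial
    z: np.ndarray                                 # standardized mu
    intended_lick: np.ndarray                     # pre-perturbation draw (NaN no-lick)
    applied_shift: np.ndarray                     # realized - intended lick time
    coefficients: dict
    unit_baseline: np.ndarray | None = None
    unit_gain: np.ndarray | None = None
    unit_history_coef: np.ndarray | None = None
    unit_scalable: np.ndarray | None = None
    unit_peak_phase: np.ndarray | None = None
    unit_speed_coef: np.ndarray | None = None


def internal_clock(
    spec: PerturbationSpec | None,
    kind: str,
    rewind_rate: float,
    t_max: float = 10.0,
    dt: float = 0.001,
) -> tuple[np.ndarray, np.ndarray]:
    """Shared internal time course ``u(t)`` under a perturbation.

    ``u`` advances at unit speed, pauses (silencing) or runs backwards at
    ``rewind_rate`` (D1 inhibition) while the stimulus is on, with linear
    ramp-down of the manipulation strength, and is clamped at zero.
    """
    t = dt * np.arange(int(round(t_max / dt)) + 1)
    if spec is None:
        return t, t.copy()
    full_end = spec.offset - spec.ramp_down
    strength = np.zeros_like(t)
    strength[(t >= spec.onset) & (t < full_end)] = 1.0
    if spec.ramp_down > 0:
        ramp = (t >= full_end) & (t < spec.offset)
        strength[ramp] = (spec.offset - t[ramp]) / spec.ramp_down
    if kind == "pause":
        speed = 1.0 - strength
    elif kind == "rewind":
        speed = (1.0 - strength) * 1.0 + strength * (-rewind_rate)
    else:
        raise ValueError(f"unknown perturbation kind {kind!r}")
    u = np.concatenate(([0.0], np.cumsum(speed[:-1] * dt)))
    if np.any(u < 0):
        # clamp at zero (the representation cannot rewind below trial start):
        # once clamped, resume accumulating from zero
        u = np.zeros_like(t)
        acc = 0.0
        for i in range(1, t.size):
            acc = max(acc + speed[i - 1] * dt, 0.0)
            u[i] = acc
    return t, u


def _lick_from_clock(t: np.ndarray, u: np.ndarray, intended: float) -> float:
    idx = np.searchsorted(u, intended)
    if idx >= t.size:
        return np.nan
    return float(t[idx])


def make_behavior(
    config: BehaviorGenConfig | None = None,
    seed: int | np.random.Generator | None = None,
    animal_id: str = "synthA",
    session_id: str = "s01",
) -> tuple[Session, GroundTruth]:
    """Generate a behavioral session (no units) plus its ground truth."""
    config = config or BehaviorGenConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = config.n_trials

    # block-switched delay schedule
    delays = np.empty(n)
    pos, level = 0, 0
    while pos < n:
        length = int(rng.integers(config.block_length_range[0], config.block_length_range[1] + 1))
        delays[pos : pos + length] = config.delay_levels[level % len(config.delay_levels)]
        level += 1
        pos += length

    cue_present = rng.random(n) >= config.p_no_cue
    perturbed = np.zeros(n, dtype=bool)
    if config.perturb_fraction > 0:
        perturbed = cue_present & (rng.random(n) < config.perturb_fraction)
    target = config.perturb_target
    if config.perturb_kind == "rewind" and target == "ALM":
        target = "VLS-D1"   # rewind-type manipulations hit striatal D1-SPNs
    spec = PerturbationSpec(
        target=target,
        onset=config.perturb_onset,
        duration=config.perturb_duration,
        ramp_down=config.perturb_ramp_down,
        power=1.5 if config.perturb_kind == "pause" else 0.25,
    )
    t_grid, u_pert = internal_clock(spec, config.perturb_kind, config.rewind_rate)

    n_lags = len(config.beta_T)
    mu_arr = np.empty(n)
    intended = np.full(n, np.nan)
    shift = np.zeros(n)
    trials: list[Trial] = []
    onsets: list[float] = []
    history: list[tuple[float, bool]] = []        # (lick time, rewarded) of licked trials
    clipped = 0
    clock_t = 0.0
    steady = config.beta0 / max(1.0 - sum(config.beta_T) - 0.5 * sum(config.beta_TR), 0.1)

    for i in range(n):
        mu = config.beta0
        for k in range(1, n_lags + 1):
            if len(history) >= k:
                lt_k, r_k = history[-k]
            else:
                lt_k, r_k = steady, True
            mu += config.beta_T[k - 1] * lt_k
            mu += config.beta_TR[k - 1] * lt_k * float(r_k)
        if mu <= config.min_lick:
            mu = config.min_lick + 0.1
            clipped += 1
        mu_arr[i] = mu

        first_lick: float | None = None
        rewarded = False
        if cue_present[i]:
            lt = float(
                stats.invgauss.rvs(
                    mu / config.dispersion, scale=config.dispersion, random_state=rng
                )
            )
            lt = max(lt, config.min_lick)
            intended[i] = lt
            if perturbed[i]:
                realized = _lick_from_clock(t_grid, u_pert, lt)
                shift[i] = (realized - lt) if np.isfinite(realized) else np.nan
            else:
                realized = lt
            if np.isfinite(realized) and realized <= config.no_lick_horizon:
                first_lick = realized
                rewarded = realized >= delays[i]
                history.append((realized, rewarded))

        iti = config.iti_offset + min(rng.exponential(config.iti_mean), config.iti_max
                                      - config.iti_offset)
        trials.append(
            Trial(
                index=i,
                delay_duration=float(delays[i]),
                first_lick_time=first_lick,
                rewarded=rewarded,
                cue_present=bool(cue_present[i]),
                perturbation=spec if perturbed[i] else None,
                iti_duration=float(iti),
            )
        )
        onsets.append(clock_t)
        span = (first_lick if first_lick is not None else config.no_lick_horizon) + 1.5
        clock_t += span + iti

    session = Session(
        animal_id=animal_id, session_id=session_id,
        trials=trials, cue_onsets=np.asarray(onsets),
    )
    z = (mu_arr - mu_arr.mean()) / max(mu_arr.std(), 1e-12)
    truth = GroundTruth(
        mu=mu_arr, z=z, intended_lick=intended, applied_shift=shift,
        coefficients={
            "beta0": config.beta0,
            "beta_T": list(config.beta_T),
            "beta_TR": list(config.beta_TR),
            "dispersion": config.dispersion,
            "clipped_mu": clipped,
            "perturb_kind": config.perturb_kind,
            "rewind_rate": config.rewind_rate,
        },
    )
    return session, truth


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def make_spikes(
    session: Session,
    truth: GroundTruth,
    config: NeuralGenConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> Session:
    """Attach Poisson-spiking units to a behavioral session (in place).

    Unit rates between cue and lick follow ``b + g * ramp(u(t) / LT)`` for
    scalable units (``u`` the internal clock, warped by any perturbation)
    or ``b + g * ramp(t / T_ref)`` for absolute-time units; tonic history
    units add ``h_i * z_n`` everywhere.  Silencing-type perturbations
    multiply rates by ``silencing_floor`` while the stimulus is on.
    """
    config = config or NeuralGenConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nu = config.n_units
    dt = config.dt

    scalable = rng.random(nu) < config.scalable_fraction
    baseline = rng.uniform(0.6, 1.4, nu) * config.baseline_rate
    gain = rng.uniform(0.4, 1.2, nu) * config.ramp_gain
    has_hist = rng.random(nu) < config.history_fraction
    hist_coef = np.where(has_hist, rng.normal(0.0, config.history_gain, nu), 0.0)
    # temporal profiles: a monotone ramp peaking at the lick, or a bump
    # peaking part-way through the trial (populations unfold as sequences,
    # with neurons tiling peak times between cue and lick)
    monotone = rng.random(nu) < config.monotone_fraction
    peak_phase = np.where(monotone, 1.0, rng.uniform(0.15, 1.0, nu))
    bump_width = rng.uniform(0.15, 0.3, nu)
    # cue-gated speed input: in the integrator picture the trial's ramp slope
    # is set by a tonic input current proportional to 1/LT, present from the
    # cue onward; a subset of units carries it
    has_speed = rng.random(nu) < config.speed_fraction
    speed_coef = np.where(has_speed, rng.uniform(0.5, 1.5, nu) * config.speed_gain, 0.0)
    # the drive is set by the *intended* lick time: a perturbed trial licks
    # late because its clock was paused or rewound, not because its input
    # was weaker
    with np.errstate(invalid="ignore"):
        inv_lt = 1.0 / truth.intended_lick
    finite = np.isfinite(inv_lt)
    z_speed = np.zeros_like(inv_lt)
    if finite.sum() > 1:
        z_speed[finite] = (inv_lt[finite] - inv_lt[finite].mean()) / max(
            inv_lt[finite].std(), 1e-12)

    t_ref = float(np.nanmedian(truth.intended_lick)) if np.isfinite(
        truth.intended_lick
    ).any() else 1.3

    spikes: list[list[np.ndarray]] = [[] for _ in range(nu)]
    pre = 1.5  # covers the 0-1 s pre-cue ITI window
    for i, trial in enumerate(session.trials):
        onset = session.cue_onsets[i]
        lick = trial.first_lick_time
        span = (lick if lick is not None else 5.0) + 0.5
        n_bins = int(round((pre + span) / dt))
        t_rel = -pre + dt * (np.arange(n_bins) + 0.5)   # relative to cue

        # internal clock for this trial
        if trial.perturbation is not None:
            kind = truth.coefficients.get("perturb_kind", "pause")
            tg, u = internal_clock(trial.perturbation, kind, truth.coefficients.get(
                "rewind_rate", 2.0) if kind == "rewind" else 0.0, t_max=pre + span + 1.0, dt=dt)
            u_rel = np.interp(np.maximum(t_rel, 0.0), tg, u)
            sil = kind == "pause"
            strength = _stim_strength(t_rel, trial.perturbation)
        else:
            u_rel = np.maximum(t_rel, 0.0)
            sil = False
            strength = None

        in_trial = (t_rel >= 0.0) & (t_rel <= (lick if lick is not None else 5.0))
        rates = np.tile(baseline[:, None], (1, n_bins)).astype(float)
        if lick is not None:
            denom = max(truth.intended_lick[i], 0.2) if np.isfinite(
                truth.intended_lick[i]) else lick
            phase_scaled = u_rel / denom
            phase_abs = np.maximum(t_rel, 0.0) / t_ref
            for j in range(nu):
                x = phase_scaled if scalable[j] else phase_abs
                if monotone[j]:
                    prof = _smoothstep(x / peak_phase[j])
                else:
                    prof = np.exp(-0.5 * ((x - peak_phase[j]) / bump_width[j]) ** 2)
                rates[j, in_trial] += gain[j] * prof[in_trial]
        rates += hist_coef[:, None] * truth.z[i]
        if speed_coef.any():
            rates[:, in_trial] += np.outer(speed_coef * z_speed[i],
                                           np.ones(int(in_trial.sum())))
        if config.common_gain_sd > 0:
            # shared slow variability: one multiplicative gain per trial,
            # common to all units (concentrates population covariance in a
            # low-dimensional common mode, as in cortical recordings)
            rates *= np.exp(rng.normal(0.0, config.common_gain_sd))
        if sil and strength is not None:
            mult = config.silencing_floor + (1.0 - config.silencing_floor) * (1.0 - strength)
            rates *= mult[None, :]
        np.maximum(rates, 0.0, out=rates)

        counts = rng.poisson(rates * dt)
        for j in range(nu):
            nz = np.nonzero(counts[j])[0]
            if nz.size:
                reps = np.repeat(t_rel[nz], counts[j][nz])
                spikes[j].append(onset + reps)

    units = []
    total_time = session.cue_onsets[-1] + 10.0
    for j in range(nu):
        st = np.sort(np.concatenate(spikes[j])) if spikes[j] else np.empty(0)
        if config.area.upper() == "ALM":
            width = rng.uniform(0.55, 0.8)
            supp = rng.uniform(10, 30)
            isi_frac = rng.uniform(0.0, 0.05)
        else:
            width = rng.uniform(0.45, 0.7)
            supp = rng.uniform(10, 35)
            isi_frac = rng.uniform(0.0, 0.05)
        units.append(
            Unit(
                unit_id=f"{config.area}_{j:03d}",
                area=config.area,
                spike_times=st,
                mean_rate=st.size / total_time,
                spike_width=width,
                post_spike_suppression=supp,
                long_isi_fraction=isi_frac,
            )
        )
    session.units = units
    truth.unit_baseline = baseline
    truth.unit_gain = gain
    truth.unit_history_coef = hist_coef
    truth.unit_scalable = scalable
    truth.unit_peak_phase = peak_phase
    truth.unit_speed_coef = speed_coef
    return session


def _stim_strength(t_rel: np.ndarray, spec: PerturbationSpec) -> np.ndarray:
    full_end = spec.offset - spec.ramp_down
    s = np.zeros_like(t_rel)
    s[(t_rel >= spec.onset) & (t_rel < full_end)] = 1.0
    if spec.ramp_down > 0:
        ramp = (t_rel >= full_end) & (t_rel < spec.offset)
        s[ramp] = (spec.offset - t_rel[ramp]) / spec.ramp_down
    return s


def make_session(
    behavior: BehaviorGenConfig | None = None,
    neural: NeuralGenConfig | None = None,
    seed: int = 0,
    animal_id: str = "synthA",
    session_id: str = "s01",
) -> tuple[Session, GroundTruth]:
    """Behavior plus spikes in one call, fully determined by ``seed``."""
    rng = np.random.default_rng(seed)
    session, truth = make_behavior(behavior, rng, animal_id=animal_id, session_id=session_id)
    neural = neural or NeuralGenConfig()
    spike_rng = np.random.default_rng(seed + neural.seed_offset)
    make_spikes(session, truth, neural, spike_rng)
    return session, truth
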
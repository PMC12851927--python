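"""Accumulator "timer" simulator with pause/slowdown and rewind perturbations.

The internal representation of elapsed time is a scalar accumulator

    T(t) = integral_0^t r,

with a lick triggered when ``T`` reaches a fixed threshold ``theta = 1``.
The inflow rate ``r`` is constant within a trial but varies across trials so
that the unmanipulated lick time matches an inverse-Gaussian distribution
IG(mu = 1.3 s, lambda = 12): a target time ``t*`` is drawn and ``r = theta /
t*``, making the unmanipulated first-passage time exactly ``t*``.

Two transient manipulations mimic the optogenetic perturbations:

* pause/slowdown — the inflow is scaled by a speed coefficient ``c`` (0 =
  full pause, 0 < c < 1 = slowdown) for the manipulation duration; the
  accumulated deficit shifts the lick time by the same amount at every
  manipulation onset (state-independent).
* rewind — the inflow is replaced by a negative decay rate, actively
  draining the accumulator; ``T`` is clamped at zero, and if it dwells at
  zero continuously for more than 320 ms the trial ends without a lick
  (floor effect), so the shift grows with how much had been accumulated
  (state-dependent) and the hazard rate collapses to zero at the offset.

Manipulation strength decays linearly over the final ``ramp_down`` seconds,
matching the photostimulation ramp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .behavior import HazardCurve, hazard_rate, hazard_shift

__all__ = [
    "TimerConfig",
    "ManipulationSpec",
    "TimerExperiment",
    "draw_rates",
    "simulate_trial",
    "simulate_trials",
    "simulate_experiment",
]


@dataclass(frozen=True)
class TimerConfig:
    """Accumulator parameters; defaults reproduce the reference simulation."""

    theta: float = 1.0
    mu: float = 1.3          # IG mean of target lick times, s
    lam: float = 12.0        # IG shape
    n_trials: int = 10_000
    dt: float = 0.001        # s
    t_max: float = 8.0       # simulation horizon, s

    def __post_init__(self) -> None:
        if not self.theta > 0:
            raise ValueError("theta must be > 0")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.dt > 0.01:
            raise ValueError("dt coarser than 10 ms is too inaccurate")


@dataclass(frozen=True)
class ManipulationSpec:
    """Transient timer manipulation.

    ``kind`` is ``"pause_slowdown"``, ``"rewind"`` or ``"none"``.  ``c`` is
    the speed coefficient for pause/slowdown.  ``r_decay`` is the negative
    drain rate for rewind, in threshold units per second; when
    ``decay_per_trial`` is true it is instead a multiple of each trial's own
    rate ``r``.  ``zero_dwell_nolick`` is the continuous time at zero after
    which the trial is fixed at zero (no lick).
    """

    kind: str = "none"
    onset: float = 0.6
    duration: float = 0.6
    ramp_down: float = 0.3
    c: float = 0.0
    r_decay: float = -2.0
    decay_per_trial: bool = False
    zero_dwell_nolick: float = 0.32

    def __post_init__(self) -> None:
        if self.kind not in ("pause_slowdown", "rewind", "none"):
            raise ValueError(f"unknown manipulation kind {self.kind!r}")
        if self.c < 0:
            raise ValueError("speed coefficient c must be >= 0")
        if self.kind == "rewind" and self.r_decay > 0:
            raise ValueError("r_decay must be <= 0 for rewind")

    @property
    def offset(self) -> float:
        return self.onset + self.duration

    def strength(self, t: np.ndarray | float) -> np.ndarray:
        """Manipulation strength in [0, 1]: 1 full, linear ramp to 0."""
        t = np.asarray(t, dtype=float)
        full_end = self.offset - self.ramp_down
        s = np.zeros_like(t)
        s = np.where((t >= self.onset) & (t < full_end), 1.0, s)
        if self.ramp_down > 0:
            in_ramp = (t >= full_end) & (t < self.offset)
            s = np.where(in_ramp, (self.offset - t) / self.ramp_down, s)
        return s


def draw_rates(
    config: TimerConfig, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Per-trial inflow rates matched to the target lick-time distribution.

    Draws ``t* ~ IG(mu, lambda)`` and returns ``r = theta / t*`` so that the
    unmanipulated first-passage time equals ``t*`` exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_star = stats.invgauss.rvs(
        config.mu / config.lam, scale=config.lam, size=config.n_trials, random_state=rng
    )
    return config.theta / t_star


def simulate_trials(
    rates: np.ndarray,
    manipulation: ManipulationSpec | None = None,
    config: TimerConfig | None = None,
) -> np.ndarray:
    """Integrate the accumulator for every trial; returns lick times (NaN = no lick).

    Forward Euler at ``config.dt`` with within-step linear interpolation of
    the threshold crossing, so an unmanipulated trial licks at ``theta / r``
    to within floating precision.
    """
    config = config or TimerConfig()
    manip = manipulation or ManipulationSpec(kind="none")
    r = np.asarray(rates, dtype=float)
    n = r.size
    dt = config.dt
    steps = int(round(config.t_max / dt))

    T = np.zeros(n)
    lick = np.full(n, np.nan)
    active = np.ones(n, dtype=bool)
    dwell = np.zeros(n)

    times = dt * np.arange(steps)
    strengths = manip.strength(times) if manip.kind != "none" else np.zeros(steps)

    for k in range(steps):
        if not active.any():
            break
        s = strengths[k]
        if manip.kind == "pause_slowdown" and s > 0:
            r_eff = r * (1.0 - s * (1.0 - manip.c))
        elif manip.kind == "rewind" and s > 0:
            decay = manip.r_decay * r if manip.decay_per_trial else manip.r_decay
            r_eff = (1.0 - s) * r + s * decay
        else:
            r_eff = r
        T_new = np.where(active, T + r_eff * dt, T)
        T_new = np.maximum(T_new, 0.0)

        # continuous zero dwell -> no-lick rule
        at_zero = active & (T_new <= 0.0)
        dwell = np.where(at_zero, dwell + dt, 0.0)
        dead = active & (dwell > manip.zero_dwell_nolick)
        active &= ~dead

        crossed = active & (T_new >= config.theta)
        if crossed.any():
            r_step = (T_new - T) / dt  # effective rate inside this step
            t_in = np.where(r_step > 0, (config.theta - T) / np.maximum(r_step, 1e-300), dt)
            lick[crossed] = times[k] + np.clip(t_in[crossed], 0.0, dt)
            active &= ~crossed
        T = T_new
    return lick


def simulate_trial(
    r: float,
    manipulation: ManipulationSpec | None = None,
    config: TimerConfig | None = None,
) -> float:
    """Single-trial convenience wrapper; returns the lick time or NaN."""
    if not r > 0:
        raise ValueError("rate must be > 0")
    return float(simulate_trials(np.array([r]), manipulation, config)[0])


@dataclass
class TimerExperiment:
    """Results of a simulated manipulation experiment."""

    config: TimerConfig
    rates: np.ndarray
    lick_times: dict[str, np.ndarray]
    hazards: dict[str, HazardCurve]
    shifts: dict[str, float]            # hazard 50%-point shift vs control
    no_lick_rate: dict[str, float]
    trajectories: dict[str, np.ndarray] = field(default_factory=dict)

    def cdf(self, condition: str, t: np.ndarray) -> np.ndarray:
        lt = self.lick_times[condition]
        licked = np.sort(lt[np.isfinite(lt)])
        return np.searchsorted(licked, t, side="right") / lt.size


def example_trajectory(
    r: float, manipulation: ManipulationSpec | None, config: TimerConfig
) -> np.ndarray:
    """Internal accumulator time course (columns: t, T) for one trial."""
    manip = manipulation or ManipulationSpec(kind="none")
    dt = config.dt
    steps = int(round(config.t_max / dt))
    times = dt * np.arange(steps)
    T = np.zeros(steps)
    dwell = 0.0
    frozen = False
    for k in range(1, steps):
        t = times[k - 1]
        s = float(manip.strength(t)) if manip.kind != "none" else 0.0
        if manip.kind == "pause_slowdown" and s > 0:
            r_eff = r * (1.0 - s * (1.0 - manip.c))
        elif manip.kind == "rewind" and s > 0:
            decay = manip.r_decay * r if manip.decay_per_trial else manip.r_decay
            r_eff = (1.0 - s) * r + s * decay
        else:
            r_eff = r
        val = 0.0 if frozen else max(T[k - 1] + r_eff * dt, 0.0)
        dwell = dwell + dt if val <= 0 else 0.0
        if dwell > manip.zero_dwell_nolick:
            frozen = True
        T[k] = val
        if val >= config.theta:
            return np.column_stack([times[: k + 1], T[: k + 1]])
    return np.column_stack([times, T])


def _licks_after(lick_times: np.ndarray, onset: float) -> np.ndarray:
    """Drop trials resolved at or before ``onset``; keep no-lick (NaN) trials."""
    keep = ~(np.isfinite(lick_times) & (lick_times <= onset))
    return lick_times[keep]


def simulate_experiment(
    config: TimerConfig | None = None,
    manipulations: dict[str, ManipulationSpec] | None = None,
    onsets: Sequence[float] = (0.6, 0.9),
    seed: int | np.random.Generator | None = None,
    hazard_t_max: float = 5.0,
    shift_method: str = "crossing",
) -> TimerExperiment:
    """Simulate control plus manipulated conditions over a shared rate draw.

    ``manipulations`` maps condition names to specs; each spec is replayed at
    every onset in ``onsets`` (conditions named ``"<name>@<onset>"``), using
    the *same* per-trial rates as the control so differences are purely the
    manipulation.  Hazard curves, sigmoid 50%-point shifts versus control and
    no-lick rates are computed per condition.
    """
    config = config or TimerConfig()
    if manipulations is None:
        manipulations = {
            "pause": ManipulationSpec(kind="pause_slowdown", c=0.5),
            "rewind": ManipulationSpec(kind="rewind", r_decay=-2.0),
        }
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rates = draw_rates(config, rng)

    lick_times = {"control": simulate_trials(rates, None, config)}
    trajectories = {}
    for name, spec in manipulations.items():
        for onset in onsets:
            cond = f"{name}@{onset:g}"
            spec_on = ManipulationSpec(
                kind=spec.kind, onset=onset, duration=spec.duration,
                ramp_down=spec.ramp_down, c=spec.c, r_decay=spec.r_decay,
                decay_per_trial=spec.decay_per_trial,
                zero_dwell_nolick=spec.zero_dwell_nolick,
            )
            lick_times[cond] = simulate_trials(rates, spec_on, config)
            trajectories[cond] = example_trajectory(
                config.theta / config.mu, spec_on, config
            )

    hazards = {k: hazard_rate(v, t_max=hazard_t_max) for k, v in lick_times.items()}
    # Shifts condition on the first lick falling after the manipulation onset
    # in control and manipulated trials alike (trials already resolved before
    # the manipulation carry no information about it).
    shifts = {}
    for name, spec in manipulations.items():
        for onset in onsets:
            cond = f"{name}@{onset:g}"
            keep_c = _licks_after(lick_times["control"], onset)
            keep_m = _licks_after(lick_times[cond], onset)
            shifts[cond] = hazard_shift(
                hazard_rate(keep_c, t_max=hazard_t_max),
                hazard_rate(keep_m, t_max=hazard_t_max),
                method=shift_method,
            )
    no_lick = {
        k: float(np.mean(~np.isfinite(v) | (v > hazard_t_max))) for k, v in lick_times.items()
    }
    return TimerExperiment(
        config=config, rates=rates, lick_times=lick_times, hazards=hazards,
        shifts=shifts, no_lick_rate=no_lick, trajectories=trajectories,
    )
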
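"""Threshold-linear rate networks: the cortico-striatal integrator model zoo.

Each model is a small network of neuronal populations in two areas (ALM =
premotor cortex, STR = striatum, with "STR" standing in for the whole
subcortical loop through the substantia nigra reticulata and thalamus, which
is why excitatory effective weights are allowed).  Membrane currents evolve
as

    tau dh_i/dt = -h_i + sum_j W_ij r_j + I_base_i + I_ext_i(t) + I_stim_i(t)
    r_i = max(h_i, 0)

with membrane time constant ``tau = 10 ms`` and threshold-linear activation.
Temporal integration is implemented either by a continuous attractor (a unit
eigenvalue in ``W``), by a leaky approximation (leading eigenvalue < 1), or
by feedforward amplification across weakly recurrent modules.  Baseline
currents are calibrated so that, without a cue, the system rests at a stable
low-rate fixed point with the target neuron at 5 spikes/s; stability at
baseline is obtained by keeping one partner of each integrating loop just
below threshold, so the marginal direction only engages once the cue-gated
step input arrives.

The zoo (`externally_driven`, `distributed`, `redundant`, `specialized_ALM`,
`ALM_leaky`, `specialized_STR`, plus feedforward chains) differs in *where*
integration lives; optogenetic-style perturbation currents (ALM silencing =
-10 to all ALM units; D1-SPN inhibition = a small negative current to the
striatal target, with per-variant amplitude -0.3, -0.1, -0.1, -0.2, -0.02,
-0.03 chosen to give comparable striatal ramp deflections) discriminate the
variants: only a striatal integrator jointly produces the pause-and-resume
signature under ALM silencing and the gradual-decay/no-jump signature under
D1 inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "NetworkConfig",
    "StimProtocol",
    "ModelVariant",
    "TrajectoryResult",
    "POSITIVE_FEEDBACK_VARIANTS",
    "D1_AMPLITUDES",
    "integrate_dynamics",
    "calibrate_baseline",
    "build_variant",
    "run_perturbation_experiment",
    "classify_parallel_resume",
    "classify_gradual_decay",
    "discriminate_variants",
]

TAU = 0.010  # s

POSITIVE_FEEDBACK_VARIANTS = (
    "externally_driven",
    "distributed",
    "redundant",
    "specialized_ALM",
    "ALM_leaky",
    "specialized_STR",
)

#: D1-SPN inhibition current per positive-feedback variant.
D1_AMPLITUDES = {
    "externally_driven": -0.3,
    "distributed": -0.1,
    "redundant": -0.1,
    "specialized_ALM": -0.2,
    "ALM_leaky": -0.02,
    "specialized_STR": -0.03,
    "feedforward_STR": -0.1,
    "feedforward_ALM": -0.1,
}


@dataclass
class NetworkConfig:
    """Connectivity, baseline currents and integration step of one network."""

    W: np.ndarray
    I_base: np.ndarray
    labels: list[str]
    areas: list[str]
    tau: float = TAU
    dt: float = 1e-4

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = self.W.shape[0]
        if self.W.shape != (n, n):
            raise ValueError("W must be square")
        if not self.tau > 0:
            raise ValueError("tau must be > 0")
        if self.dt > self.tau / 10:
            raise ValueError("dt must be <= tau/10 for a stable Euler step")
        self.I_base = np.asarray(self.I_base, dtype=float)

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def area_indices(self, area: str) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.areas) if a == area])


@dataclass(frozen=True)
class StimProtocol:
    """Perturbation current: targets, amplitude and time course.

    The transient protocol starts 0.6 s after the cue and lasts 0.6 s
    including a 0.3-s linear ramp down; the prolonged variant covers the
    whole trial with no ramp.
    """

    targets: tuple[str, ...]
    amplitude: float
    onset: float = 0.6
    duration: float = 0.6
    ramp_down: float = 0.3
    prolonged: bool = False

    @property
    def offset(self) -> float:
        return self.onset + self.duration

    def current(self, t: float, config: NetworkConfig) -> np.ndarray:
        I = np.zeros(config.n)
        if self.prolonged:
            s = 1.0 if t >= self.onset else 0.0
        else:
            full_end = self.offset - self.ramp_down
            if self.onset <= t < full_end:
                s = 1.0
            elif full_end <= t < self.offset and self.ramp_down > 0:
                s = (self.offset - t) / self.ramp_down
            else:
                s = 0.0
        if s:
            for lab in self.targets:
                I[config.index(lab)] = self.amplitude * s
        return I


@dataclass
class TrajectoryResult:
    """Simulated rate trajectories; ``t=0`` is the cue."""

    t: np.ndarray
    rates: np.ndarray      # time x units
    h: np.ndarray
    config: NetworkConfig

    def rate_of(self, label: str) -> np.ndarray:
        return self.rates[:, self.config.index(label)]

    def at(self, time: float) -> np.ndarray:
        k = int(np.clip(np.searchsorted(self.t, time), 0, self.t.size - 1))
        return self.rates[k]


def integrate_dynamics(
    config: NetworkConfig,
    duration: float,
    I_ext: Callable[[float], np.ndarray] | None = None,
    I_stim: Callable[[float], np.ndarray] | None = None,
    h0: np.ndarray | None = None,
    t_start: float = 0.0,
) -> TrajectoryResult:
    """Forward-Euler integration of the threshold-linear dynamics.

    Raises ``RuntimeError`` naming the first diverging unit if any |h|
    exceeds 1e6.
    """
    n = config.n
    dt, tau = config.dt, config.tau
    steps = int(round(duration / dt))
    h = np.array(config.I_base, dtype=float) if h0 is None else np.array(h0, dtype=float)
    t_axis = t_start + dt * np.arange(steps + 1)
    H = np.empty((steps + 1, n))
    H[0] = h
    for k in range(steps):
        t = t_axis[k]
        r = np.maximum(h, 0.0)
        drive = config.W @ r + config.I_base
        if I_ext is not None:
            drive = drive + I_ext(t)
        if I_stim is not None:
            drive = drive + I_stim(t)
        h = h + (dt / tau) * (-h + drive)
        H[k + 1] = h
        if k % 2000 == 0 and np.any(np.abs(h) > 1e6):
            bad = int(np.argmax(np.abs(h) > 1e6))
            raise RuntimeError(f"dynamics diverged at unit {config.labels[bad]}")
    if np.any(np.abs(H) > 1e6):
        bad = int(np.argmax(np.any(np.abs(H) > 1e6, axis=0)))
        raise RuntimeError(f"dynamics diverged at unit {config.labels[bad]}")
    return TrajectoryResult(t=t_axis, rates=np.maximum(H, 0.0), h=H, config=config)


def calibrate_baseline(
    W: np.ndarray,
    target_h: np.ndarray,
    tau: float = TAU,
    check_stability: bool = True,
) -> np.ndarray:
    """Baseline currents placing the no-cue fixed point at ``target_h``.

    ``target_h`` holds the desired baseline membrane currents (equal to the
    rates for active units, negative for units resting below threshold).
    Solves ``I_base = h* - W f(h*)`` and, when requested, verifies that the
    linearization on the active subset is asymptotically stable (all
    eigenvalues of ``W_active`` strictly inside the unit circle).
    """
    W = np.asarray(W, dtype=float)
    target_h = np.asarray(target_h, dtype=float)
    I_base = target_h - W @ np.maximum(target_h, 0.0)
    if check_stability:
        active = np.nonzero(target_h > 0)[0]
        if active.size:
            sub = W[np.ix_(active, active)]
            lead = np.max(np.abs(np.linalg.eigvals(sub)))
            if lead >= 1.0 - 1e-9:
                raise RuntimeError(
                    f"no stable baseline: active-subsystem leading eigenvalue {lead:.6f} >= 1"
                )
    return I_base


@dataclass
class ModelVariant:
    """A built network variant plus everything needed to run experiments."""

    id: str
    config: NetworkConfig
    target_unit: str                    # defines lick readout (5 Hz -> 0, 10 Hz -> 1)
    step_targets: dict[str, float]      # I_ext weight per unit label
    d1_targets: tuple[str, ...]
    d1_amplitude: float
    integration: str
    expected_unit_eigenvalues: int
    step_amplitude: float = 1.0         # calibrated for a ~1.3-s model lick
    external_ramp: bool = False         # externally driven: ramping input
    cue_transient_targets: dict[str, float] = field(default_factory=dict)
    notes: str = ""

    @property
    def alm_targets(self) -> tuple[str, ...]:
        return tuple(
            lab for lab, a in zip(self.config.labels, self.config.areas) if a == "ALM"
        )

    def external_input(self, amplitude: float | None = None) -> Callable[[float], np.ndarray]:
        """Cue-gated external input: sustained step (or ramp) from t=0."""
        amp = self.step_amplitude if amplitude is None else amplitude
        cfg = self.config
        idx_amp = [(cfg.index(lab), w) for lab, w in self.step_targets.items()]
        cue_idx = [(cfg.index(lab), w) for lab, w in self.cue_transient_targets.items()]

        def I_ext(t: float) -> np.ndarray:
            I = np.zeros(cfg.n)
            if t >= 0:
                scale = amp * t if self.external_ramp else amp
                for i, w in idx_amp:
                    I[i] = w * scale
                # cue-like transient: 600 ms with a 450-ms linear ramp down,
                # injected along an axis orthogonal to the amplified direction
                if cue_idx:
                    if t < 0.15:
                        s = 1.0
                    elif t < 0.6:
                        s = (0.6 - t) / 0.45
                    else:
                        s = 0.0
                    for i, w in cue_idx:
                        I[i] += w * s
            return I

        return I_ext


def _four_unit_config(W: np.ndarray, target_h: np.ndarray) -> NetworkConfig:
    labels = ["a1", "a2", "s1", "s2"]
    areas = ["ALM", "ALM", "STR", "STR"]
    I_base = calibrate_baseline(W, target_h)
    return NetworkConfig(W=W, I_base=I_base, labels=labels, areas=areas)


def _build_positive_feedback(variant: str) -> ModelVariant:
    """The six two-units-per-area positive-feedback architectures."""
    if variant == "specialized_STR":
        # striatal loop s1<->s2 carries the unit eigenvalue; a1 provides the
        # on-manifold step, a2 follows s1 and supplies off-manifold drive
        W = np.array(
            [
                [0.0, 0.0, 0.0, 0.0],     # a1: input unit
                [0.0, 0.0, 0.5, 0.0],     # a2 follows s1
                [0.05, 0.3, 0.0, 1.0],    # s1
                [0.05, -0.3, 1.0, 0.0],   # s2
            ]
        )
        target_h = np.array([-0.5, 5.0, 5.0, -0.02])
        cfg = _four_unit_config(W, target_h)
        return ModelVariant(
            id=variant, config=cfg, target_unit="s1",
            step_targets={"a1": 1.0}, d1_targets=("s1",),
            d1_amplitude=D1_AMPLITUDES[variant],
            integration="continuous_attractor", expected_unit_eigenvalues=2,
            notes="STR integrates ALM input; ALM is input and follower",
        )
    if variant == "specialized_ALM":
        W = np.array(
            [
                [0.0, 1.0, 0.0, 0.0],
                [1.0, 0.0, 0.0, 0.0],
                [0.4, 0.4, 0.0, 0.0],     # striatum follows ALM
                [0.2, 0.2, 0.0, 0.0],
            ]
        )
        target_h = np.array([5.0, -0.02, 5.0, 5.0])
        cfg = _four_unit_config(W, target_h)
        return ModelVariant(
            id=variant, config=cfg, target_unit="s1",
            step_targets={"a1": 1.0}, d1_targets=("s1",),
            d1_amplitude=D1_AMPLITUDES[variant],
            integration="continuous_attractor", expected_unit_eigenvalues=2,
            notes="ALM integrates; STR follows",
        )
    if variant == "ALM_leaky":
        W = np.array(
            [
                [0.0, 0.9, 0.0, 0.0],
                [0.9, 0.0, 0.0, 0.0],
                [0.4, 0.4, 0.0, 0.0],
                [0.2, 0.2, 0.0, 0.0],
            ]
        )
        target_h = np.array([5.0, -0.02, 5.0, 5.0])
        cfg = _four_unit_config(W, target_h)
        return ModelVariant(
            id=variant, config=cfg, target_unit="s1",
            step_targets={"a1": 1.0}, d1_targets=("s1",),
            d1_amplitude=D1_AMPLITUDES[variant],
            integration="leaky", expected_unit_eigenvalues=0,
            notes="ALM integrates with substantial leak (leading eigenvalue 0.9)",
        )
    if variant == "redundant":
        # identical integrators in each area, weak feedforward STR->ALM
        # coupling (block-triangular, so both unit eigenvalues stay exact)
        W = np.array(
            [
                [0.5, 0.5, 0.05, 0.0],
                [0.5, 0.5, 0.0, 0.0],
                [0.0, 0.0, 0.5, 0.5],
                [0.0, 0.0, 0.5, 0.5],
            ]
        )
        target_h = np.array([5.0, -0.02, 5.0, -0.02])
        cfg = _four_unit_config(W, target_h)
        return ModelVariant(
            id=variant, config=cfg, target_unit="s1",
            step_targets={"a1": 1.0, "s1": 1.0}, d1_targets=("s1",),
            d1_amplitude=D1_AMPLITUDES[variant],
            integration="continuous_attractor", expected_unit_eigenvalues=2,
            notes="independent eigenvalue-1 integrators in ALM and STR",
        )
    if variant == "distributed":
        # the unit eigenvalue exists only through the interareal a2<->s2 loop
        W = np.array(
            [
                [0.0, 0.0, 0.0, 0.0],
                [0.0, 0.0, 0.0, 1.0],
                [0.0, 0.5, 0.0, 0.0],     # s1 follows a2
                [0.05, 1.0, 0.0, 0.0],    # s2 closes the loop, reads the a1 step
            ]
        )
        target_h = np.array([-0.5, 5.0, 5.0, -0.02])
        cfg = _four_unit_config(W, target_h)
        return ModelVariant(
            id=variant, config=cfg, target_unit="s1",
            step_targets={"a1": 1.0}, d1_targets=("s1",),
            d1_amplitude=D1_AMPLITUDES[variant],
            integration="continuous_attractor", expected_unit_eigenvalues=2,
            notes="integration requires the long-range loop",
        )
    if variant == "externally_driven":
        W = np.array(
            [
                [0.0, 0.0, 0.0, 0.0],
                [1.0, 0.0, 0.0, 0.0],
                [0.4, 0.4, 0.0, 0.0],
                [0.2, 0.2, 0.0, 0.0],
            ]
        )
        target_h = np.array([5.0, 5.0, 5.0, 5.0])
        cfg = _four_unit_config(W, target_h)
        return ModelVariant(
            id=variant, config=cfg, target_unit="s1",
            step_targets={"a1": 1.0}, d1_targets=("s1",),
            d1_amplitude=D1_AMPLITUDES[variant],
            integration="external", expected_unit_eigenvalues=0,
            external_ramp=True,
            notes="ALM tracks an externally supplied ramping input",
        )
    raise ValueError(f"unknown positive-feedback variant {variant!r}")


def _build_feedforward(variant: str, n_modules: int = 4) -> ModelVariant:
    """Feedforward chain of weakly recurrent 2-cell modules.

    Each module has internal weights giving a leading eigenvalue of 0.9
    (< 1, so no module integrates on its own); feedforward links between
    consecutive modules amplify the input along the uniform direction; a
    global negative baseline gates propagation so that the step-input
    strength controls the speed of the travelling ramp.  The chain lives in
    the striatum (``feedforward_STR``) or in the ALM (``feedforward_ALM``);
    the other area supplies the step input (first module) and reads out the
    last module.  A cue-like transient (600 ms, 450-ms linear ramp down)
    enters the input area orthogonally to the amplified direction.
    """
    chain_area = "STR" if variant == "feedforward_STR" else "ALM"
    io_area = "ALM" if chain_area == "STR" else "STR"
    chain_prefix = "s" if chain_area == "STR" else "a"

    labels = ["in1", "out1"] + [f"{chain_prefix}{k}" for k in range(1, 2 * n_modules + 1)]
    areas = [io_area, io_area] + [chain_area] * (2 * n_modules)
    n = len(labels)
    W = np.zeros((n, n))
    w_rec, w_ff = 0.45, 0.35
    for m in range(n_modules):
        i0 = 2 + 2 * m
        W[i0 : i0 + 2, i0 : i0 + 2] = w_rec          # module recurrence, eig 0.9
        if m + 1 < n_modules:
            W[i0 + 2 : i0 + 4, i0 : i0 + 2] = w_ff   # feedforward link
    # input unit drives module 1; readout follows the last module
    W[2, 0] = W[3, 0] = 0.5
    last = 2 + 2 * (n_modules - 1)
    W[1, last] = W[1, last + 1] = 0.3

    target_h = np.full(n, -0.5)                      # global inhibition on the chain
    target_h[0] = -0.5                               # input unit silent until the step
    target_h[1] = 5.0                                # readout at baseline 5 Hz
    I_base = calibrate_baseline(W, target_h)
    cfg = NetworkConfig(W=W, I_base=I_base, labels=labels, areas=areas)
    mid = 2 + 2 * (n_modules // 2 - 1)
    return ModelVariant(
        id=variant, config=cfg, target_unit="out1",
        step_targets={"in1": 1.0},
        d1_targets=(labels[mid], labels[mid + 2]) if chain_area == "STR" else ("in1",),
        d1_amplitude=D1_AMPLITUDES[variant],
        integration="feedforward_amplification",
        expected_unit_eigenvalues=0,
        cue_transient_targets={"out1": 1.0},
        notes=f"feedforward amplification chain in {chain_area}",
    )


def _verify_eigenstructure(variant: ModelVariant) -> None:
    eig = np.linalg.eigvals(variant.config.W)
    n_unit = int(np.sum(np.abs(np.abs(eig) - 1.0) < 1e-9))
    if variant.integration == "continuous_attractor":
        n_one = int(np.sum(np.abs(eig - 1.0) < 1e-9))
        if n_one < 1:
            raise RuntimeError(f"{variant.id}: no exact unit eigenvalue (got {eig})")
    else:
        lead = np.max(np.abs(eig))
        if lead >= 1.0 - 1e-9:
            raise RuntimeError(f"{variant.id}: leading eigenvalue {lead:.4f} not < 1")
    del n_unit


def build_variant(
    variant: str,
    calibrate_input: bool = True,
    lick_target: float = 1.3,
) -> ModelVariant:
    """Construct, eigen-check and input-calibrate a model variant.

    With ``calibrate_input`` the cue-gated step (or ramp) amplitude is tuned
    by bisection so the unperturbed model lick (ramp-mode activity reaching
    1, i.e. the target neuron reaching 10 spikes/s) occurs near
    ``lick_target`` seconds after the cue.
    """
    if variant in POSITIVE_FEEDBACK_VARIANTS:
        mv = _build_positive_feedback(variant)
    elif variant in ("feedforward_STR", "feedforward_ALM"):
        mv = _build_feedforward(variant)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    _verify_eigenstructure(mv)
    if calibrate_input:
        mv.step_amplitude = _calibrate_step(mv, lick_target)
    return mv


def simulate_variant(
    variant: ModelVariant,
    stim: StimProtocol | None = None,
    amplitude: float | None = None,
    t_pre: float = 1.0,
    t_post: float = 3.0,
) -> TrajectoryResult:
    """Simulate one trial: baseline from ``-t_pre``, cue at 0."""
    cfg = variant.config
    I_ext = variant.external_input(amplitude)
    I_stim = (lambda t: stim.current(t, cfg)) if stim is not None else None
    return integrate_dynamics(
        cfg, t_pre + t_post, I_ext=I_ext, I_stim=I_stim,
        h0=cfg.I_base + cfg.W @ np.maximum(cfg.I_base, 0.0) * 0.0 + 0.0,
        t_start=-t_pre,
    )


def _fixed_point(cfg: NetworkConfig, t_relax: float = 2.0) -> np.ndarray:
    """Baseline h after relaxing the unforced dynamics."""
    run = integrate_dynamics(cfg, t_relax)
    return run.h[-1]


def model_lick_time(variant: ModelVariant, run: TrajectoryResult) -> float:
    """Time (s after cue) when the target neuron's rate reaches 10 spikes/s."""
    r = run.rate_of(variant.target_unit)
    post = run.t >= 0
    above = np.nonzero(post & (r >= 10.0))[0]
    return float(run.t[above[0]]) if above.size else np.nan


def _calibrate_step(variant: ModelVariant, lick_target: float) -> float:
    lo, hi = 1e-3, 1.0
    # grow hi until the lick happens early enough
    for _ in range(20):
        run = simulate_variant(variant, amplitude=hi, t_pre=0.3, t_post=lick_target + 2.0)
        lt = model_lick_time(variant, run)
        if np.isfinite(lt) and lt < lick_target:
            break
        lo, hi = hi, hi * 2.0
    else:
        raise RuntimeError(f"{variant.id}: could not find a licking input amplitude")
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        run = simulate_variant(variant, amplitude=mid, t_pre=0.3, t_post=lick_target + 2.0)
        lt = model_lick_time(variant, run)
        if not np.isfinite(lt) or lt > lick_target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-4:
            break
    # return the licking bound: with a leaky integrator the lick time
    # diverges as the input approaches the saturation threshold, so the
    # midpoint can land on the non-licking side
    return hi


# ---------------------------------------------------------------------------
# ramp modes and perturbation experiments


def ramp_mode_from_run(
    variant: ModelVariant, run: TrajectoryResult, area: str
) -> tuple[np.ndarray, float, float]:
    """Area ramp mode and its affine normalization from a control run.

    The mode is the unit-norm difference between mean activity 0.2-0.5 s
    before the model lick and mean activity 0-1 s before the cue, exactly as
    for recorded populations.  The returned (lo, hi) normalization maps the
    baseline projection to 0 and the projection at the moment the target
    neuron reaches 10 spikes/s to 1.
    """
    lick = model_lick_time(variant, run)
    if not np.isfinite(lick):
        raise RuntimeError(f"{variant.id}: control run never licks")
    idx = run.config.area_indices(area)
    pre_lick = (run.t >= lick - 0.5) & (run.t <= lick - 0.2)
    pre_cue = (run.t >= -1.0) & (run.t <= 0.0)
    w = run.rates[pre_lick][:, idx].mean(0) - run.rates[pre_cue][:, idx].mean(0)
    norm = np.linalg.norm(w)
    if norm < 1e-12:
        raise RuntimeError(f"{variant.id}: degenerate ramp mode in {area}")
    w = w / norm
    proj = run.rates[:, idx] @ w
    lo = proj[pre_cue].mean()
    k10 = int(np.searchsorted(run.t, lick))
    hi = proj[k10]
    if abs(hi - lo) < 1e-12:
        raise RuntimeError(f"{variant.id}: ramp-mode normalization degenerate in {area}")
    return w, float(lo), float(hi)


@dataclass
class PerturbationExperiment:
    """Control and perturbed ramp-mode trajectories for one variant."""

    variant: ModelVariant
    t: np.ndarray
    ramp: dict[str, dict[str, np.ndarray]]   # condition -> area -> normalized ramp
    lick_times: dict[str, float]
    protocols: dict[str, StimProtocol]


def run_perturbation_experiment(
    variant: ModelVariant,
    protocols: dict[str, StimProtocol] | None = None,
    t_post: float = 3.0,
) -> PerturbationExperiment:
    """Simulate control plus perturbation conditions and project on ramp modes.

    Default protocols: transient ALM silencing (-10 to all ALM units, onset
    0.6 s, 0.6-s duration with 0.3-s ramp down) and transient D1 inhibition
    (variant-specific amplitude to the striatal target units).  The model
    lick is the ramp-mode activity of the target area reaching 1.
    """
    if protocols is None:
        protocols = {
            "alm_silencing": StimProtocol(targets=variant.alm_targets, amplitude=-10.0),
            "d1_inhibition": StimProtocol(
                targets=variant.d1_targets, amplitude=variant.d1_amplitude
            ),
        }
    control = simulate_variant(variant, None, t_post=t_post)
    modes = {
        area: ramp_mode_from_run(variant, control, area) for area in ("ALM", "STR")
    }

    def project(run: TrajectoryResult) -> dict[str, np.ndarray]:
        out = {}
        for area, (w, lo, hi) in modes.items():
            idx = run.config.area_indices(area)
            proj = run.rates[:, idx] @ w
            out[area] = (proj - lo) / (hi - lo)
        return out

    ramp = {"control": project(control)}
    licks = {"control": model_lick_time(variant, control)}
    target_area = dict(zip(variant.config.labels, variant.config.areas))[variant.target_unit]
    for name, proto in protocols.items():
        run = simulate_variant(variant, proto, t_post=t_post)
        ramp[name] = project(run)
        # model lick read from the normalized ramp of the target area
        traj = ramp[name][target_area]
        above = np.nonzero((run.t >= 0) & (traj >= 1.0))[0]
        licks[name] = float(run.t[above[0]]) if above.size else np.nan
    return PerturbationExperiment(
        variant=variant, t=control.t, ramp=ramp, lick_times=licks, protocols=protocols,
    )


# ---------------------------------------------------------------------------
# signature classifiers


def _value_at(t: np.ndarray, y: np.ndarray, time: float) -> float:
    return float(np.interp(time, t, y))


def _crossing_after(t: np.ndarray, y: np.ndarray, level: float, t_min: float) -> float:
    mask = t >= t_min
    tt, yy = t[mask], y[mask]
    above = np.nonzero(yy >= level)[0]
    if above.size == 0:
        return np.nan
    i = above[0]
    if i == 0:
        return float(tt[0])
    frac = (level - yy[i - 1]) / max(yy[i] - yy[i - 1], 1e-12)
    return float(tt[i - 1] + frac * (tt[i] - tt[i - 1]))


def classify_parallel_resume(
    t: np.ndarray,
    ctrl: np.ndarray,
    stim: np.ndarray,
    protocol: StimProtocol,
    shift_window: tuple[float, float] = (0.3, 0.9),
) -> dict:
    """Does the perturbed ramp pause and resume in parallel with control?

    Three checks on the (normalized) ramp-mode trajectories: (1) recovery —
    shortly after the stimulation offset the perturbed ramp is back to at
    least half its pre-onset level (it resumes near where it was paused,
    rather than restarting from zero); (2) parallel — the post-offset slope
    matches the control slope over the same ramp range within 30%; (3) the
    time shift between the trajectories, measured at matched ramp levels,
    is on the order of the stimulation duration (within ``shift_window``).
    """
    onset, offset = protocol.onset, protocol.offset
    pre_level = _value_at(t, stim, onset - 0.05)
    post_level = _value_at(t, stim, offset + 0.1)
    recovery_ok = post_level >= 0.5 * pre_level

    # time shift at matched levels on the rising portion after the offset
    levels = np.linspace(max(post_level + 0.05, 0.3), 0.95, 8)
    shifts = []
    for lev in levels:
        tc = _crossing_after(t, ctrl, lev, 0.0)
        ts = _crossing_after(t, stim, lev, offset)
        if np.isfinite(tc) and np.isfinite(ts):
            shifts.append(ts - tc)
    shift = float(np.mean(shifts)) if shifts else np.nan
    shift_ok = bool(shifts) and shift_window[0] <= shift <= shift_window[1]

    def slope(y, lo, hi, t_min):
        t1 = _crossing_after(t, y, lo, t_min)
        t2 = _crossing_after(t, y, hi, t_min)
        if not (np.isfinite(t1) and np.isfinite(t2)) or t2 <= t1:
            return np.nan
        return (hi - lo) / (t2 - t1)
    lo, hi_ = max(post_level + 0.05, 0.4), 0.9
    sc, ss = slope(ctrl, lo, hi_, 0.0), slope(stim, lo, hi_, offset)
    parallel_ok = np.isfinite(sc) and np.isfinite(ss) and abs(ss / sc - 1.0) < 0.3

    return {
        "passes": bool(recovery_ok and shift_ok and parallel_ok),
        "recovery_ok": bool(recovery_ok),
        "shift_ok": bool(shift_ok),
        "parallel_ok": bool(parallel_ok),
        "shift": shift,
        "pre_level": pre_level,
        "post_level": post_level,
    }


def classify_gradual_decay(
    t: np.ndarray,
    ctrl: np.ndarray,
    stim: np.ndarray,
    protocol: StimProtocol,
    min_decay: float = 0.05,
) -> dict:
    """Does the ramp rewind gradually and resume from the decayed level?

    The signature is read from the deficit trace ``d(t) = ctrl(t) - stim(t)``
    (the perturbed trajectory's lag behind its matched control, the same
    quantity the decoded-time comparisons use).  Checks: (1) a meaningful
    total deficit accrues by the stimulation offset (> ``min_decay``
    normalized units); (2) gradual — no more than half of it accrues within
    the first 100 ms (a follower being clamped acquires its full deficit
    within the 10-ms membrane time constant); (3) no jump recovery — at
    150 ms after the offset at least half the deficit persists (the ramp
    resumes from the decayed level instead of snapping back to control).
    """
    onset, offset = protocol.onset, protocol.offset
    deficit = ctrl - stim
    total = _value_at(t, deficit, offset)
    decay_ok = total > min_decay

    early = _value_at(t, deficit, onset + 0.1)
    gradual_ok = decay_ok and early <= 0.5 * total

    persist = _value_at(t, deficit, offset + 0.15)
    nojump_ok = decay_ok and persist >= 0.5 * total

    return {
        "passes": bool(decay_ok and gradual_ok and nojump_ok),
        "decay_ok": bool(decay_ok),
        "gradual_ok": bool(gradual_ok),
        "nojump_ok": bool(nojump_ok),
        "decay": float(total),
        "early_drop": float(early),
        "persisting": float(persist),
    }


def discriminate_variants(
    variants: Sequence[str] = POSITIVE_FEEDBACK_VARIANTS,
) -> dict[str, dict]:
    """Run both perturbation experiments on each variant and classify.

    Returns per variant the parallel-resume verdict (ALM ramp under ALM
    silencing) and the gradual-decay verdict (STR ramp under D1 inhibition),
    plus their conjunction.  Among the positive-feedback zoo only the
    specialized striatal integrator passes both.
    """
    results: dict[str, dict] = {}
    for vid in variants:
        variant = build_variant(vid)
        exp = run_perturbation_experiment(variant)
        pr = classify_parallel_resume(
            exp.t, exp.ramp["control"]["ALM"], exp.ramp["alm_silencing"]["ALM"],
            exp.protocols["alm_silencing"],
        )
        gd = classify_gradual_decay(
            exp.t, exp.ramp["control"]["STR"], exp.ramp["d1_inhibition"]["STR"],
            exp.protocols["d1_inhibition"],
        )
        results[vid] = {
            "parallel_resume": pr,
            "gradual_decay": gd,
            "both": pr["passes"] and gd["passes"],
            "lick_times": exp.lick_times,
        }
    return results
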
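"""Domain types and elementary operations on recorded sessions.

A *session* bundles the behavioral trial table (cue onsets, delay durations,
first-lick times, reward outcomes, optional optogenetic perturbation
descriptors) with the spike trains and waveform metadata of the units recorded
simultaneously.  All downstream analyses — binning, trial-history regression,
mode decomposition, decoding — operate on these containers.

Time conventions
----------------
Within-trial times are seconds relative to cue onset; spike times in
:class:`Unit` are on the session clock.  Bins are half-open ``[t, t + dt)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "PerturbationSpec",
    "Trial",
    "Unit",
    "Session",
    "BinnedTensor",
    "LICK_TIME_RANGES",
    "bin_spikes",
    "select_engaged_trials",
    "classify_unit",
    "group_trials_by_lick_time",
]

#: The six canonical lick-time ranges (seconds, half-open) used to group
#: trials for population analyses.
LICK_TIME_RANGES: tuple[tuple[float, float], ...] = (
    (0.80, 1.10),
    (1.10, 1.25),
    (1.25, 1.40),
    (1.40, 1.55),
    (1.55, 1.70),
    (1.70, 2.00),
)


@dataclass(frozen=True)
class PerturbationSpec:
    """Optogenetic perturbation descriptor attached to a trial.

    Parameters
    ----------
    target
        Manipulated population, e.g. ``"ALM"``, ``"VLS-D1"``, ``"DMS-D1"``.
    laterality
        ``"unilateral"`` or ``"bilateral"``.
    onset
        Photostimulation onset in seconds relative to cue (negative = precue).
    duration
        Total photostimulation duration in seconds (> 0).
    ramp_down
        Final portion of ``duration`` over which the light power decays
        linearly to zero; ``0 <= ramp_down <= duration``.
    power
        Time-averaged laser power in milliwatts.
    """

    target: str
    laterality: str = "bilateral"
    onset: float = 0.6
    duration: float = 0.6
    ramp_down: float = 0.3
    power: float = 1.5

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("perturbation duration must be > 0")
        if not 0 <= self.ramp_down <= self.duration:
            raise ValueError("ramp_down must lie in [0, duration]")

    @property
    def offset(self) -> float:
        """Photostimulation offset in seconds relative to cue."""
        return self.onset + self.duration


@dataclass(frozen=True)
class Trial:
    """One behavioral trial.

    ``first_lick_time`` is seconds from cue onset, ``None`` for no-lick
    trials.  ``rewarded`` implies a lick at or after ``delay_duration``.
    """

    index: int
    delay_duration: float
    first_lick_time: float | None = None
    rewarded: bool = False
    cue_present: bool = True
    cue_intensity: float = 0.0
    perturbation: PerturbationSpec | None = None
    iti_duration: float = 3.0

    def __post_init__(self) -> None:
        if self.first_lick_time is not None and not self.first_lick_time > 0:
            raise ValueError("first_lick_time must be > 0 when present")
        if self.rewarded:
            if self.first_lick_time is None:
                raise ValueError("rewarded trial must have a lick")
            if self.first_lick_time < self.delay_duration:
                raise ValueError("rewarded lick cannot precede the delay end")

    @property
    def licked(self) -> bool:
        return self.first_lick_time is not None


@dataclass(frozen=True)
class Unit:
    """A sorted unit: spike train on the session clock plus waveform features.

    ``spike_width`` and ``post_spike_suppression`` are in milliseconds;
    ``long_isi_fraction`` is the proportion of inter-spike intervals longer
    than the configured "long" threshold (used for FSI classification).
    Feature fields may be ``None`` when unavailable.
    """

    unit_id: str
    area: str
    spike_times: np.ndarray
    mean_rate: float | None = None
    spike_width: float | None = None
    post_spike_suppression: float | None = None
    long_isi_fraction: float | None = None

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times, dtype=float)
        if st.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if st.size > 1 and np.any(np.diff(st) < 0):
            raise ValueError("spike_times must be nondecreasing")
        object.__setattr__(self, "spike_times", st)
        if self.mean_rate is not None and self.mean_rate < 0:
            raise ValueError("mean_rate must be >= 0")


@dataclass
class Session:
    """A recording session: ordered trials, their cue onsets, and units."""

    animal_id: str
    session_id: str
    trials: list[Trial]
    cue_onsets: np.ndarray
    units: list[Unit] = field(default_factory=list)
    condition: str = "switching"

    def __post_init__(self) -> None:
        self.cue_onsets = np.asarray(self.cue_onsets, dtype=float)
        if len(self.trials) != self.cue_onsets.size:
            raise ValueError("trial count must equal cue_onsets count")
        if self.cue_onsets.size > 1 and np.any(np.diff(self.cue_onsets) <= 0):
            raise ValueError("trials must be ordered by cue onset")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_units(self) -> int:
        return len(self.units)

    def lick_times(self) -> np.ndarray:
        """First-lick times relative to cue, NaN for no-lick trials."""
        return np.array(
            [np.nan if t.first_lick_time is None else t.first_lick_time for t in self.trials]
        )

    def subset_trials(self, indices: Sequence[int]) -> "Session":
        idx = list(indices)
        return Session(
            animal_id=self.animal_id,
            session_id=self.session_id,
            trials=[replace(self.trials[i], index=k) for k, i in enumerate(idx)],
            cue_onsets=self.cue_onsets[idx],
            units=self.units,
            condition=self.condition,
        )


@dataclass
class BinnedTensor:
    """Trials x units x bins firing-rate tensor with alignment provenance.

    ``values`` holds rates in spikes/s.  ``alignment`` is ``"cue"`` or
    ``"lick"``; ``window`` is (start, end) seconds relative to the alignment
    event.  ``smoothing`` records the causal boxcar width in seconds (0 for
    none).  ``trial_indices`` maps rows back to session trial indices (lick
    alignment drops no-lick trials).
    """

    values: np.ndarray
    bin_size: float
    alignment: Literal["cue", "lick"]
    window: tuple[float, float]
    smoothing: float = 0.0
    trial_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be trials x units x bins")

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]

    @property
    def bin_edges(self) -> np.ndarray:
        start, end = self.window
        return start + self.bin_size * np.arange(self.n_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        edges = self.bin_edges
        return 0.5 * (edges[:-1] + edges[1:])


def causal_boxcar(values: np.ndarray, width_bins: int) -> np.ndarray:
    """Causal boxcar filter along the last axis.

    Each output bin is the mean of the current bin and the ``width_bins - 1``
    preceding bins; at the start of the window only the available partial
    history is averaged (shrinking window), so a constant input is unchanged
    everywhere and no future bins leak in.
    """
    if width_bins <= 1:
        return values
    csum = np.cumsum(values, axis=-1)
    out = np.empty_like(values, dtype=float)
    n = values.shape[-1]
    for b in range(n):
        lo = max(0, b - width_bins + 1)
        total = csum[..., b] - (csum[..., lo - 1] if lo > 0 else 0.0)
        out[..., b] = total / (b - lo + 1)
    return out


def bin_spikes(
    session: Session,
    bin_size: float,
    alignment: Literal["cue", "lick"] = "cue",
    window: tuple[float, float] = (-1.0, 2.0),
    smoothing: float = 0.0,
    trial_indices: Sequence[int] | None = None,
) -> BinnedTensor:
    """Bin session spike trains into a trials x units x bins rate tensor.

    Each entry is the spike count in the half-open bin divided by
    ``bin_size`` (spikes/s), optionally smoothed with a causal boxcar of
    width ``smoothing`` seconds.  For ``alignment="lick"`` only trials with a
    first lick are included.  The unsmoothed tensor conserves spike counts:
    ``values.sum(axis=2) * bin_size`` equals the number of spikes inside the
    window exactly.
    """
    if not session.units:
        raise ValueError("session has no units")
    start, end = window
    if not end > start:
        raise ValueError("window end must exceed start")
    n_bins = int(round((end - start) / bin_size))

    if trial_indices is None:
        trial_indices = range(session.n_trials)
    rows: list[int] = []
    anchors: list[float] = []
    for i in trial_indices:
        t = session.trials[i]
        if alignment == "lick":
            if t.first_lick_time is None:
                continue
            anchors.append(session.cue_onsets[i] + t.first_lick_time)
        else:
            anchors.append(session.cue_onsets[i])
        rows.append(i)

    values = np.zeros((len(rows), session.n_units, n_bins))
    edges = start + bin_size * np.arange(n_bins + 1)
    for u, unit in enumerate(session.units):
        st = unit.spike_times
        for r, anchor in enumerate(anchors):
            rel = st[(st >= anchor + start) & (st < anchor + end)] - anchor
            if rel.size:
                counts, _ = np.histogram(rel, bins=edges)
                values[r, u] = counts / bin_size
    if smoothing > 0:
        width_bins = max(1, int(round(smoothing / bin_size)))
        values = causal_boxcar(values, width_bins)
    return BinnedTensor(
        values=values,
        bin_size=bin_size,
        alignment=alignment,
        window=window,
        smoothing=smoothing,
        trial_indices=np.asarray(rows),
    )


def select_engaged_trials(session: Session) -> tuple[int, int] | None:
    """Return the engaged-trial index range ``(start, stop)``, stop exclusive.

    ``start`` is the index of the trial that completes the first run of five
    consecutive cue trials with licks.  ``stop`` excludes the 20 trials
    preceding the last run of three consecutive no-lick, unperturbed cue
    trials (i.e. ``stop = first index of that run - 20``); with no such run
    all trials through the end are kept.  Returns ``None`` when the criteria
    yield an empty range.  Indices are 0-based.
    """
    trials = session.trials
    n = len(trials)

    start = None
    run = 0
    for i, t in enumerate(trials):
        if t.cue_present and t.licked:
            run += 1
            if run == 5:
                start = i
                break
        else:
            run = 0
    if start is None:
        return None

    stop = n
    run = 0
    last_run_start = None
    for i, t in enumerate(trials):
        if t.cue_present and not t.licked and t.perturbation is None:
            run += 1
            if run >= 3:
                last_run_start = i - run + 1
        else:
            run = 0
    if last_run_start is not None:
        stop = last_run_start - 20
    if stop <= start:
        return None
    return start, stop


def classify_unit(unit: Unit, long_isi_threshold: float = 0.10) -> str:
    """Rule-based cell-type assignment from waveform and rate features.

    ALM units: putative pyramidal iff mean rate > 0.5 spikes/s and spike
    width >= 0.5 ms, otherwise ``ALM_other``.  Striatal units with mean rate
    > 0.1 spikes/s: SPN iff width >= 0.4 ms and post-spike suppression
    <= 40 ms; FSI iff width < 0.4 ms and long-ISI fraction < the threshold
    (default 10%); remaining analyzed units are TAN.  Everything else (low
    rate, missing features) is ``unclassified``.
    """
    area = unit.area.upper()
    if area == "ALM":
        if unit.mean_rate is None or unit.spike_width is None:
            warnings.warn(f"unit {unit.unit_id}: missing features; unclassified")
            return "unclassified"
        if unit.mean_rate > 0.5 and unit.spike_width >= 0.5:
            return "ALM_pyramidal"
        return "ALM_other"
    # striatal subregions (VLS, DMS, STR, ...)
    if unit.mean_rate is None:
        warnings.warn(f"unit {unit.unit_id}: missing mean rate; unclassified")
        return "unclassified"
    if unit.mean_rate <= 0.1:
        return "unclassified"
    if unit.spike_width is None:
        warnings.warn(f"unit {unit.unit_id}: missing spike width; unclassified")
        return "unclassified"
    if unit.spike_width >= 0.4:
        if unit.post_spike_suppression is not None and unit.post_spike_suppression <= 40:
            return "SPN"
        return "TAN"
    if unit.long_isi_fraction is not None and unit.long_isi_fraction < long_isi_threshold:
        return "FSI"
    return "TAN"


def group_trials_by_lick_time(
    trials: Sequence[Trial],
    ranges: Sequence[tuple[float, float]] = LICK_TIME_RANGES,
) -> dict[tuple[float, float], list[int]]:
    """Assign licked trials to half-open lick-time ranges ``[lo, hi)``.

    No-lick trials and licks outside every range are left out; each trial
    lands in at most one group.  Overlapping ranges raise ``ValueError``.
    """
    srt = sorted(ranges)
    for (lo1, hi1), (lo2, _hi2) in zip(srt, srt[1:]):
        if lo2 < hi1:
            raise ValueError(f"overlapping ranges {(lo1, hi1)} and {(lo2, _hi2)}")
    groups: dict[tuple[float, float], list[int]] = {tuple(r): [] for r in ranges}
    for i, t in enumerate(trials):
        if t.first_lick_time is None:
            continue
        for lo, hi in ranges:
            if lo <= t.first_lick_time < hi:
                groups[(lo, hi)].append(i)
                break
    return groups
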
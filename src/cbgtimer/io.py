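"""Session bundle I/O.

A session is stored as a directory of delimited-text tables plus a YAML
manifest::

    <bundle>/
      manifest.yaml   animal/session ids, condition, table inventory
      trials.csv      one row per trial (perturbation columns prefixed perturb_)
      spikes.csv      unit_id, time_s
      units.csv       unit metadata (waveform features)

Absent first licks are encoded as empty fields.  The round trip is lossless
for all :class:`~cbgtimer.core.Session` fields.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import PerturbationSpec, Session, Trial, Unit

__all__ = ["save_session", "load_session", "BundleError"]

_MANIFEST = "manifest.yaml"
_TABLES = ("trials.csv", "spikes.csv", "units.csv")


class BundleError(RuntimeError):
    """Malformed or incomplete session bundle."""


def save_session(session: Session, path: str | Path) -> Path:
    """Write ``session`` as a bundle directory; returns the directory path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rows = []
    for trial, onset in zip(session.trials, session.cue_onsets):
        row = {
            "index": trial.index,
            "cue_onset_s": onset,
            "delay_duration": trial.delay_duration,
            "first_lick_time": "" if trial.first_lick_time is None else trial.first_lick_time,
            "rewarded": int(trial.rewarded),
            "cue_present": int(trial.cue_present),
            "cue_intensity": trial.cue_intensity,
            "iti_duration": trial.iti_duration,
        }
        p = trial.perturbation
        row.update(
            {
                "perturb_target": "" if p is None else p.target,
                "perturb_laterality": "" if p is None else p.laterality,
                "perturb_onset": "" if p is None else p.onset,
                "perturb_duration": "" if p is None else p.duration,
                "perturb_ramp_down": "" if p is None else p.ramp_down,
                "perturb_power": "" if p is None else p.power,
            }
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path / "trials.csv", index=False)

    spike_frames = [
        pd.DataFrame({"unit_id": unit.unit_id, "time_s": unit.spike_times})
        for unit in session.units
    ]
    spikes = (
        pd.concat(spike_frames, ignore_index=True)
        if spike_frames
        else pd.DataFrame(columns=["unit_id", "time_s"])
    )
    spikes.to_csv(path / "spikes.csv", index=False)

    pd.DataFrame(
        [
            {
                "unit_id": u.unit_id,
                "area": u.area,
                "mean_rate": "" if u.mean_rate is None else u.mean_rate,
                "spike_width": "" if u.spike_width is None else u.spike_width,
                "post_spike_suppression": ""
                if u.post_spike_suppression is None
                else u.post_spike_suppression,
                "long_isi_fraction": "" if u.long_isi_fraction is None else u.long_isi_fraction,
            }
            for u in session.units
        ],
        columns=[
            "unit_id",
            "area",
            "mean_rate",
            "spike_width",
            "post_spike_suppression",
            "long_isi_fraction",
        ],
    ).to_csv(path / "units.csv", index=False)

    manifest = {
        "format": "cbgtimer-session-bundle",
        "version": 1,
        "animal_id": session.animal_id,
        "session_id": session.session_id,
        "condition": session.condition,
        "n_trials": session.n_trials,
        "n_units": session.n_units,
        "tables": list(_TABLES),
    }
    (path / _MANIFEST).write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def load_session(path: str | Path) -> Session:
    """Load a session bundle written by :func:`save_session`."""
    path = Path(path)
    manifest_path = path / _MANIFEST
    if not manifest_path.exists():
        raise BundleError(f"manifest not found: {manifest_path}")
    manifest = yaml.safe_load(manifest_path.read_text())
    for table in _TABLES:
        if not (path / table).exists():
            raise BundleError(f"missing table: {path / table}")

    trials_df = pd.read_csv(path / "trials.csv")
    trials: list[Trial] = []
    onsets: list[float] = []
    for pos, row in enumerate(trials_df.to_dict("records")):
        try:
            perturb = None
            target = row.get("perturb_target")
            if isinstance(target, str) and target:
                perturb = PerturbationSpec(
                    target=target,
                    laterality=row["perturb_laterality"],
                    onset=float(row["perturb_onset"]),
                    duration=float(row["perturb_duration"]),
                    ramp_down=float(row["perturb_ramp_down"]),
                    power=float(row["perturb_power"]),
                )
            trials.append(
                Trial(
                    index=int(row["index"]),
                    delay_duration=float(row["delay_duration"]),
                    first_lick_time=_opt_float(row.get("first_lick_time")),
                    rewarded=bool(int(row["rewarded"])),
                    cue_present=bool(int(row["cue_present"])),
                    cue_intensity=float(row["cue_intensity"]),
                    perturbation=perturb,
                    iti_duration=float(row["iti_duration"]),
                )
            )
            onsets.append(float(row["cue_onset_s"]))
        except (KeyError, ValueError, TypeError) as err:
            raise BundleError(f"trials.csv row {pos}: {err}") from err

    units_df = pd.read_csv(path / "units.csv")
    spikes_df = pd.read_csv(path / "spikes.csv")
    spike_groups = (
        {str(k): np.sort(v["time_s"].to_numpy(float)) for k, v in spikes_df.groupby("unit_id")}
        if len(spikes_df)
        else {}
    )
    units: list[Unit] = []
    for pos, row in enumerate(units_df.to_dict("records")):
        try:
            uid = str(row["unit_id"])
            units.append(
                Unit(
                    unit_id=uid,
                    area=str(row["area"]),
                    spike_times=spike_groups.get(uid, np.empty(0)),
                    mean_rate=_opt_float(row.get("mean_rate")),
                    spike_width=_opt_float(row.get("spike_width")),
                    post_spike_suppression=_opt_float(row.get("post_spike_suppression")),
                    long_isi_fraction=_opt_float(row.get("long_isi_fraction")),
                )
            )
        except (KeyError, ValueError, TypeError) as err:
            raise BundleError(f"units.csv row {pos}: {err}") from err

    return Session(
        animal_id=str(manifest["animal_id"]),
        session_id=str(manifest["session_id"]),
        trials=trials,
        cue_onsets=np.asarray(onsets),
        units=units,
        condition=str(manifest.get("condition", "switching")),
    )
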
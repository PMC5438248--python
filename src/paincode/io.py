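"""Reading, writing and validating the plain-CSV interchange tables.

Three long-format tables carry everything the pipeline needs:

``spikes.csv``    session_id, unit_id, trial_id, t_s
    One row per spike; ``t_s`` is the spike time in seconds relative to
    stimulus (laser) onset, within ``[-window, +window)``.
``trials.csv``    session_id, trial_id, stimulus, withdrawal_latency_s, laser_mW
    One row per trial; ``stimulus`` is one of NS/LS/HS; an empty
    ``withdrawal_latency_s`` means no withdrawal occurred within 5 s.
``behavior.csv``  animal_id, group, phase, chamber, seconds, paired_stimulus
    Chamber occupancy per phase (baseline/test) of a two-chamber
    place-aversion test.

No standard electrophysiology container fits trial-aligned sorted spikes plus
behavioral tables, so CSV is the interchange format; validation reports the
offending row numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

STIMULI = ("NS", "LS", "HS")
LASER_MW = {"NS": 50.0, "LS": 150.0, "HS": 250.0}

SPIKE_COLUMNS = ["session_id", "unit_id", "trial_id", "t_s"]
TRIAL_COLUMNS = ["session_id", "trial_id", "stimulus", "withdrawal_latency_s", "laser_mW"]
BEHAVIOR_COLUMNS = ["animal_id", "group", "phase", "chamber", "seconds", "paired_stimulus"]


class FormatError(ValueError):
    """A file is structurally malformed (e.g. a declared column is missing)."""


class ValidationError(ValueError):
    """File contents violate a session invariant (with row numbers)."""


@dataclass
class SpikeSession:
    """Trial-aligned spikes of simultaneously recorded units plus metadata.

    ``spikes`` has columns ``unit_id, trial_id, t_s`` and ``trials`` has
    columns ``trial_id, stimulus, withdrawal_latency_s, laser_mW`` (plus an
    optional ``iti_s``).  Times are seconds relative to stimulus onset.
    """

    session_id: str
    units: list[str]
    spikes: pd.DataFrame
    trials: pd.DataFrame
    window_s: float = 5.0

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def validate(self) -> None:
        errors: list[str] = []
        missing = [c for c in ("unit_id", "trial_id", "t_s") if c not in self.spikes.columns]
        if missing:
            raise FormatError(f"spike table missing columns {missing}")
        missing = [c for c in ("trial_id", "stimulus") if c not in self.trials.columns]
        if missing:
            raise FormatError(f"trial table missing columns {missing}")

        bad = ~self.trials["stimulus"].isin(STIMULI)
        for row in self.trials.index[bad]:
            errors.append(f"trials row {row}: stimulus "
                          f"{self.trials.at[row, 'stimulus']!r} not in {STIMULI}")
        if "withdrawal_latency_s" in self.trials.columns:
            lat = pd.to_numeric(self.trials["withdrawal_latency_s"], errors="coerce")
            bad = lat.notna() & ((lat < 0) | (lat >= 5.0))
            for row in self.trials.index[bad]:
                errors.append(f"trials row {row}: withdrawal latency {lat[row]} "
                              f"outside [0, 5) s")

        known_trials = set(self.trials["trial_id"])
        known_units = set(self.units)
        bad = ~self.spikes["trial_id"].isin(known_trials)
        for row in self.spikes.index[bad]:
            errors.append(f"spikes row {row}: unknown trial_id "
                          f"{self.spikes.at[row, 'trial_id']!r}")
        bad = ~self.spikes["unit_id"].isin(known_units)
        for row in self.spikes.index[bad]:
            errors.append(f"spikes row {row}: unknown unit_id "
                          f"{self.spikes.at[row, 'unit_id']!r}")
        t = self.spikes["t_s"].to_numpy(dtype=float)
        bad = (t < -self.window_s) | (t >= self.window_s)
        for row in self.spikes.index[np.asarray(bad)]:
            errors.append(f"spikes row {row}: t_s={self.spikes.at[row, 't_s']} outside "
                          f"[-{self.window_s}, {self.window_s}) s")
        if errors:
            head = errors[:20]
            more = f" (+{len(errors) - 20} more)" if len(errors) > 20 else ""
            raise ValidationError("; ".join(head) + more)

    def subset_units(self, keep: list[str]) -> "SpikeSession":
        keep_set = set(keep)
        return SpikeSession(
            session_id=self.session_id,
            units=[u for u in self.units if u in keep_set],
            spikes=self.spikes[self.spikes["unit_id"].isin(keep_set)].reset_index(drop=True),
            trials=self.trials.copy(),
            window_s=self.window_s,
        )

    def subset_trials(self, trial_ids) -> "SpikeSession":
        keep = set(trial_ids)
        return SpikeSession(
            session_id=self.session_id,
            units=list(self.units),
            spikes=self.spikes[self.spikes["trial_id"].isin(keep)].reset_index(drop=True),
            trials=self.trials[self.trials["trial_id"].isin(keep)].reset_index(drop=True),
            window_s=self.window_s,
        )

    def trials_for(self, stimulus: str) -> np.ndarray:
        return self.trials.loc[self.trials["stimulus"] == stimulus, "trial_id"].to_numpy()


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")


def read_sessions(spikes_path, trials_path, window_s: float = 5.0) -> list[SpikeSession]:
    """Read and validate every session found in a spike/trial table pair."""
    # round_trip: parse floats to the exact value the writer printed
    spikes = pd.read_csv(spikes_path, float_precision="round_trip")
    trials = pd.read_csv(trials_path, float_precision="round_trip")
    _require_columns(spikes, SPIKE_COLUMNS, spikes_path)
    _require_columns(trials, TRIAL_COLUMNS[:3], trials_path)
    sessions = []
    for sid, strials in trials.groupby("session_id", sort=True):
        sspikes = spikes[spikes["session_id"] == sid]
        units = sorted(sspikes["unit_id"].astype(str).unique())
        sess = SpikeSession(
            session_id=str(sid),
            units=units,
            spikes=sspikes.drop(columns=["session_id"]).reset_index(drop=True),
            trials=strials.drop(columns=["session_id"]).reset_index(drop=True),
            window_s=window_s,
        )
        sess.validate()
        sessions.append(sess)
    orphans = set(spikes["session_id"]) - set(trials["session_id"])
    if orphans:
        raise ValidationError(f"spike rows reference sessions with no trials: {sorted(orphans)}")
    return sessions


def read_spike_table(spikes_path, trials_path, session_id: str | None = None,
                     window_s: float = 5.0) -> SpikeSession:
    """Read a single validated :class:`SpikeSession` from CSV."""
    sessions = read_sessions(spikes_path, trials_path, window_s=window_s)
    if session_id is not None:
        for s in sessions:
            if s.session_id == str(session_id):
                return s
        raise ValidationError(f"session {session_id!r} not found")
    if len(sessions) != 1:
        raise ValidationError(
            f"expected a single session, found {len(sessions)}; pass session_id")
    return sessions[0]


def write_sessions(sessions: list[SpikeSession], spikes_path, trials_path) -> None:
    spike_frames, trial_frames = [], []
    for s in sessions:
        sp = s.spikes.copy()
        sp.insert(0, "session_id", s.session_id)
        spike_frames.append(sp[SPIKE_COLUMNS])
        tr = s.trials.copy()
        tr.insert(0, "session_id", s.session_id)
        trial_frames.append(tr)
    # %.17g prints the shortest digits that reconstruct the exact float64
    pd.concat(spike_frames, ignore_index=True).to_csv(spikes_path, index=False,
                                                      float_format="%.17g")
    pd.concat(trial_frames, ignore_index=True).to_csv(trials_path, index=False,
                                                      float_format="%.17g")


# -- behavioral (place-aversion) records -------------------------------------

@dataclass
class ChamberOccupancy:
    baseline_s: float
    test_s: float
    paired_stimulus: str


@dataclass
class CPARecord:
    """Per-animal two-chamber occupancy at baseline and test phases."""

    animal_id: str
    group: str
    chambers: dict[str, ChamberOccupancy] = field(default_factory=dict)

    def chamber_for(self, stimulus: str) -> str:
        for name, occ in self.chambers.items():
            if occ.paired_stimulus == stimulus:
                return name
        raise KeyError(f"no chamber paired with {stimulus!r} for animal {self.animal_id}")


def read_behavior_table(path) -> list[CPARecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, BEHAVIOR_COLUMNS, path)
    records: list[CPARecord] = []
    for (animal, group), sub in df.groupby(["animal_id", "group"], sort=True):
        rec = CPARecord(animal_id=str(animal), group=str(group))
        for chamber, csub in sub.groupby("chamber"):
            phases = dict(zip(csub["phase"], csub["seconds"]))
            if not {"baseline", "test"} <= set(phases):
                raise ValidationError(
                    f"animal {animal}: chamber {chamber} lacks baseline/test rows")
            rec.chambers[str(chamber)] = ChamberOccupancy(
                baseline_s=float(phases["baseline"]),
                test_s=float(phases["test"]),
                paired_stimulus=str(csub["paired_stimulus"].iloc[0]),
            )
        records.append(rec)
    return records


def write_behavior_table(records: list[CPARecord], path) -> None:
    rows = []
    for rec in records:
        for chamber, occ in rec.chambers.items():
            for phase, seconds in (("baseline", occ.baseline_s), ("test", occ.test_s)):
                rows.append({
                    "animal_id": rec.animal_id, "group": rec.group, "phase": phase,
                    "chamber": chamber, "seconds": seconds,
                    "paired_stimulus": occ.paired_stimulus,
                })
    pd.DataFrame(rows, columns=BEHAVIOR_COLUMNS).to_csv(path, index=False,
                                                        float_format="%.17g")
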
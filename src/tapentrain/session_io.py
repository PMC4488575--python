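"""Data model and file I/O for tapping sessions.

A study is a set of trials -- ordered tap-onset times in milliseconds
from trial start -- organised per stimulus condition, together with the
stimulus-onset tracks the participant heard.  The canonical interchange
format is a long-form CSV (one row per tap) with a JSON sidecar holding
the stimulus tracks; Standard MIDI Files are supported as an import path
only, since tapping hardware typically logs note-on events.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import _midi

__all__ = [
    "CONDITIONS",
    "ISOCHRONOUS_ISI",
    "RANDOM_ISI_SET",
    "TapTrial",
    "StimulusTrack",
    "StudyDataset",
    "SchemaError",
    "DataError",
    "read_trials",
    "write_trials",
    "read_midi_onsets",
]

#: nominal inter-stimulus interval (ms) per isochronous condition
ISOCHRONOUS_ISI = {
    "ISI320": 320.0, "ISI340": 340.0, "ISI360": 360.0, "ISI380": 380.0,
    "ISI400": 400.0, "ISI500": 500.0, "ISI600": 600.0,
}

#: the interval menu of the random condition (ms, equiprobable)
RANDOM_ISI_SET = (300.0, 400.0, 500.0, 600.0, 700.0, 800.0)

CONDITIONS = ("NO_STIM", *ISOCHRONOUS_ISI, "RANDOM")

CSV_COLUMNS = ["participant", "condition", "session", "trial", "role",
               "tap_index", "onset_ms", "key"]

#: taps per complete trial in the study design
TAPS_PER_TRIAL = 30


class SchemaError(ValueError):
    """A file does not conform to the documented columnar schema."""


class DataError(ValueError):
    """File contents violate a trial invariant (names the trial)."""


@dataclass(frozen=True)
class TapTrial:
    """One trial's ordered tap onsets (ms from trial start).

    ``key_labels``, when present, must strictly alternate between the two
    keys (the task is alternate tapping of C4 and C5).  Trials with fewer
    than 30 taps are retained but reported incomplete.
    """

    trial_id: str
    role: str  # "training" | "test"
    onsets_ms: tuple
    key_labels: tuple | None = None

    def __post_init__(self):
        if self.role not in ("training", "test"):
            raise ValueError(f"unknown trial role {self.role!r}")
        onsets = tuple(float(t) for t in self.onsets_ms)
        object.__setattr__(self, "onsets_ms", onsets)
        arr = np.asarray(onsets)
        if arr.size and arr[0] < 0:
            raise DataError(f"trial {self.trial_id}: negative onset time")
        if arr.size > 1 and not np.all(np.diff(arr) > 0):
            raise DataError(
                f"trial {self.trial_id}: onsets not strictly increasing")
        if self.key_labels is not None:
            labels = tuple(self.key_labels)
            if len(labels) != len(onsets):
                raise DataError(
                    f"trial {self.trial_id}: key labels length mismatch")
            if any(a == b for a, b in zip(labels, labels[1:])):
                raise DataError(
                    f"trial {self.trial_id}: key labels do not alternate")
            object.__setattr__(self, "key_labels", labels)

    @property
    def n_taps(self) -> int:
        return len(self.onsets_ms)

    def is_complete(self, min_taps: int = TAPS_PER_TRIAL) -> bool:
        return self.n_taps >= min_taps

    def onsets(self) -> np.ndarray:
        return np.asarray(self.onsets_ms, dtype=float)

    def shifted(self, offset_ms: float) -> "TapTrial":
        """Constant latency shift applied to every onset."""
        return replace(self, onsets_ms=tuple(t + offset_ms
                                             for t in self.onsets_ms))


@dataclass(frozen=True)
class StimulusTrack:
    """Stimulus-onset times for one condition.

    Isochronous tracks have all successive differences equal to the
    nominal ISI; random tracks draw each interval from the six-element
    menu; the no-stimulus condition has an empty onset list.
    """

    condition: str
    onsets_ms: tuple
    nominal_isi_ms: float | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        onsets = tuple(float(t) for t in self.onsets_ms)
        object.__setattr__(self, "onsets_ms", onsets)
        arr = np.asarray(onsets)
        diffs = np.diff(arr)
        if arr.size > 1 and not np.all(diffs > 0):
            raise ValueError(f"{self.condition}: onsets not increasing")
        if self.condition == "NO_STIM":
            if onsets:
                raise ValueError("NO_STIM track must have no onsets")
        elif self.condition == "RANDOM":
            if diffs.size and not np.all(np.isin(diffs, RANDOM_ISI_SET)):
                raise ValueError("RANDOM track interval outside the menu")
        else:
            nominal = ISOCHRONOUS_ISI[self.condition]
            stated = self.nominal_isi_ms
            if stated is not None and stated != nominal:
                raise ValueError(
                    f"{self.condition}: nominal ISI {stated} != {nominal}")
            object.__setattr__(self, "nominal_isi_ms", nominal)
            if diffs.size and not np.allclose(diffs, nominal):
                raise ValueError(
                    f"{self.condition}: intervals deviate from nominal ISI")

    @property
    def n_onsets(self) -> int:
        return len(self.onsets_ms)

    def onsets(self) -> np.ndarray:
        return np.asarray(self.onsets_ms, dtype=float)

    def to_dict(self) -> dict:
        return {"condition": self.condition,
                "nominal_isi_ms": self.nominal_isi_ms,
                "onsets_ms": list(self.onsets_ms),
                "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusTrack":
        return cls(condition=d["condition"],
                   onsets_ms=tuple(d["onsets_ms"]),
                   nominal_isi_ms=d.get("nominal_isi_ms"),
                   seed=d.get("seed"))


@dataclass
class StudyDataset:
    """All trials of one participant, organised per condition.

    ``sessions`` maps a condition label to the ordered list of
    (test trial, stimulus track) pairs; ``training_pool`` holds the
    interleaved no-stimulus training trials used by the Monte Carlo
    re-pairing null.  A complete design has 6 sessions x 3 test trials
    per condition and 30 training trials.
    """

    participant_id: str
    sessions: dict = field(default_factory=dict)
    training_pool: list = field(default_factory=list)
    species_profile: str | None = None

    def conditions(self) -> list:
        return list(self.sessions)

    def test_trials(self, condition: str) -> list:
        return [trial for trial, _ in self.sessions.get(condition, [])]

    def track_for(self, condition: str) -> StimulusTrack | None:
        pairs = self.sessions.get(condition, [])
        for _, track in pairs:
            if track is not None:
                return track
        return None

    def n_test_taps(self, condition: str) -> int:
        return sum(t.n_taps for t in self.test_trials(condition))

    def is_complete(self, n_test_trials: int = 18,
                    n_training: int = TAPS_PER_TRIAL) -> bool:
        return (len(self.training_pool) >= n_training and all(
            len(self.sessions[c]) >= n_test_trials
            and all(t.is_complete() for t, _ in self.sessions[c])
            for c in self.sessions))


def _trial_sort_or_fail(trial_id, onsets, tolerance_ms):
    arr = np.asarray(onsets, dtype=float)
    if arr.size > 1:
        viol = -np.diff(arr)
        worst = float(viol.max(initial=0.0))
        if worst > 0:
            if worst > tolerance_ms:
                raise DataError(
                    f"trial {trial_id}: non-monotone onsets "
                    f"(worst inversion {worst:.3f} ms exceeds tolerance)")
            arr = np.sort(arr)
        if np.any(np.diff(arr) == 0):
            raise DataError(f"trial {trial_id}: duplicated onset time")
    return tuple(arr.tolist())


def _default_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".stimuli.json")


def _read_tracks(path: Path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    tracks = payload["tracks"] if isinstance(payload, dict) and \
        "tracks" in payload else payload
    return {d["condition"]: StimulusTrack.from_dict(d)
            for d in tracks}


def read_trials(path, format: str = "csv", stimuli_path=None,
                jitter_tolerance_ms: float = 0.0,
                latency_shift_ms: float = 0.0) -> StudyDataset:
    """Load a study from CSV (+ stimulus JSON sidecar) or a JSON dump.

    Rows are grouped into trials in file order; onsets are re-sorted only
    when the worst inversion is within ``jitter_tolerance_ms``, otherwise
    a :class:`DataError` names the offending trial.  An optional constant
    ``latency_shift_ms`` is added to every onset (no correction by
    default: recorded onsets are taken at face value).
    """
    path = Path(path)
    if format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        tracks = {c: StimulusTrack.from_dict(d)
                  for c, d in payload.get("tracks", {}).items()}
        dataset = StudyDataset(participant_id=payload["participant_id"],
                               species_profile=payload.get("species_profile"))
        for cond, trials in payload.get("sessions", {}).items():
            dataset.sessions[cond] = [
                (TapTrial(trial_id=t["trial_id"], role=t["role"],
                          onsets_ms=_trial_sort_or_fail(
                              t["trial_id"],
                              [x + latency_shift_ms for x in t["onsets_ms"]],
                              jitter_tolerance_ms),
                          key_labels=tuple(t["key_labels"])
                          if t.get("key_labels") else None),
                 tracks.get(cond))
                for t in trials]
        dataset.training_pool = [
            TapTrial(trial_id=t["trial_id"], role="training",
                     onsets_ms=_trial_sort_or_fail(
                         t["trial_id"],
                         [x + latency_shift_ms for x in t["onsets_ms"]],
                         jitter_tolerance_ms))
            for t in payload.get("training_pool", [])]
        return dataset
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")

    frame = pd.read_csv(path, dtype={"trial": str, "key": str},
                        float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in frame.columns and
               c != "key"]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    participants = frame["participant"].unique()
    if len(participants) > 1:
        raise SchemaError(
            f"one participant per file, found {sorted(map(str, participants))}")

    sidecar = Path(stimuli_path) if stimuli_path else _default_sidecar(path)
    tracks = _read_tracks(sidecar) if sidecar.exists() else {}

    dataset = StudyDataset(
        participant_id=str(participants[0]) if len(participants) else "")
    has_key = "key" in frame.columns
    for (cond, session, trial_id, role), group in frame.groupby(
            ["condition", "session", "trial", "role"], sort=False):
        if cond not in CONDITIONS:
            raise SchemaError(f"unknown condition {cond!r}")
        group = group.sort_values("tap_index")
        onsets = _trial_sort_or_fail(
            trial_id, group["onset_ms"].to_numpy() + latency_shift_ms,
            jitter_tolerance_ms)
        keys = None
        if has_key and group["key"].notna().all() and len(group):
            keys = tuple(group["key"].tolist())
        trial = TapTrial(trial_id=str(trial_id), role=role,
                         onsets_ms=onsets, key_labels=keys)
        if role == "training":
            dataset.training_pool.append(trial)
        else:
            dataset.sessions.setdefault(cond, []).append(
                (trial, tracks.get(cond)))
    return dataset


def write_trials(dataset: StudyDataset, path, format: str = "csv",
                 stimuli_path=None) -> None:
    """Write a dataset so that :func:`read_trials` reproduces it exactly.

    CSV keeps one row per tap; the stimulus tracks go to the JSON
    sidecar.  Onset values round-trip bit-identically (full float repr).
    """
    path = Path(path)
    if format == "json":
        payload = {
            "participant_id": dataset.participant_id,
            "species_profile": dataset.species_profile,
            "tracks": {c: t.to_dict() for c in dataset.sessions
                       if (t := dataset.track_for(c)) is not None},
            "sessions": {
                cond: [{"trial_id": t.trial_id, "role": t.role,
                        "onsets_ms": list(t.onsets_ms),
                        "key_labels": list(t.key_labels)
                        if t.key_labels else None}
                       for t, _ in pairs]
                for cond, pairs in dataset.sessions.items()},
            "training_pool": [{"trial_id": t.trial_id,
                               "onsets_ms": list(t.onsets_ms)}
                              for t in dataset.training_pool],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
        return
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")

    rows = []

    def emit(cond, session, trial):
        for i, onset in enumerate(trial.onsets_ms):
            rows.append({
                "participant": dataset.participant_id,
                "condition": cond,
                "session": session,
                "trial": trial.trial_id,
                "role": trial.role,
                "tap_index": i,
                "onset_ms": onset,
                "key": trial.key_labels[i] if trial.key_labels else "",
            })

    for i, trial in enumerate(dataset.training_pool):
        emit("NO_STIM", i, trial)
    for cond, pairs in dataset.sessions.items():
        for i, (trial, _) in enumerate(pairs):
            emit(cond, i, trial)
    frame = pd.DataFrame(rows, columns=CSV_COLUMNS)
    # 17 significant digits keep onset values bit-identical on re-read
    frame.to_csv(path, index=False, float_format="%.17g")

    tracks = {c: dataset.track_for(c) for c in dataset.sessions}
    tracks = {c: t for c, t in tracks.items() if t is not None}
    sidecar = Path(stimuli_path) if stimuli_path else _default_sidecar(path)
    with open(sidecar, "w") as fh:
        json.dump({"tracks": [t.to_dict() for t in tracks.values()]}, fh)


def read_midi_onsets(path, channel: int = 0,
                     gap_split_ms: float | None = None) -> list:
    """Import note-on onsets from a Standard MIDI File as trials.

    Note-on events (velocity > 0) on ``channel`` are converted to
    milliseconds through the file's tempo map.  By default each MIDI
    track becomes one trial; with ``gap_split_ms`` the pooled onset
    stream is instead split into trials wherever successive onsets are
    more than the threshold apart.  Each trial's clock is rebased to its
    first onset.
    """
    onsets_per_track = _midi.note_on_times_ms(Path(path), channel=channel)
    if gap_split_ms is not None:
        merged = np.sort(np.concatenate(
            [np.asarray(t) for t in onsets_per_track if len(t)] or
            [np.empty(0)]))
        if merged.size == 0:
            return []
        cut = np.flatnonzero(np.diff(merged) > gap_split_ms) + 1
        chunks = np.split(merged, cut)
    else:
        chunks = [np.asarray(t) for t in onsets_per_track if len(t)]
    return [TapTrial(trial_id=f"midi_{i}", role="test",
                     onsets_ms=tuple((c - c[0]).tolist()))
            for i, c in enumerate(chunks)]
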
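"""Stimulus tracks and the mapping of tap onsets to circular phase.

A tap is matched to its nearest stimulus onset and its signed asynchrony
(positive = tap after the onset) is normalised by the local
inter-stimulus interval to give an angle in (-180, 180], with onsets at
0 degrees.  A tap exactly midway between two onsets belongs to the
preceding onset and maps to +180.  Taps outside the track envelope
(half an interval before the first onset or after the last) cannot be
matched and are dropped with a count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circular_stats import wrap_degrees
from .session_io import (ISOCHRONOUS_ISI, RANDOM_ISI_SET, StimulusTrack,
                         TapTrial)

__all__ = [
    "PhaseSample",
    "TrialPhases",
    "generate_stimulus_track",
    "tap_to_phase",
    "angle_to_ms",
    "phases_for_trial",
    "trial_angles",
]


@dataclass(frozen=True)
class PhaseSample:
    """One tap's position relative to the stimulus rhythm."""

    tap_time_ms: float
    matched_onset_ms: float
    local_isi_ms: float
    angle_deg: float
    asynchrony_ms: float


@dataclass(frozen=True)
class TrialPhases:
    """Phases of every matchable tap of one trial, in tap order."""

    samples: tuple
    n_unmatched: int

    @property
    def angles_deg(self) -> np.ndarray:
        return np.asarray([s.angle_deg for s in self.samples], dtype=float)

    @property
    def n(self) -> int:
        return len(self.samples)


def generate_stimulus_track(condition: str, n_onsets: int,
                            seed=None) -> StimulusTrack:
    """Build a stimulus track starting at time 0.

    Isochronous conditions are arithmetic sequences of the nominal ISI.
    The random condition draws each successive interval independently
    and equiprobably from {300, ..., 800} ms and requires a seed (an int
    or a ``numpy.random.Generator``) for reproducibility.
    """
    if condition == "NO_STIM":
        if n_onsets > 0:
            raise ValueError("NO_STIM cannot carry stimulus onsets")
        return StimulusTrack(condition="NO_STIM", onsets_ms=())
    if n_onsets < 1:
        raise ValueError("need at least one onset")
    if condition in ISOCHRONOUS_ISI:
        isi = ISOCHRONOUS_ISI[condition]
        onsets = isi * np.arange(n_onsets)
        return StimulusTrack(condition=condition, onsets_ms=tuple(onsets),
                             nominal_isi_ms=isi)
    if condition == "RANDOM":
        if seed is None:
            raise ValueError("RANDOM track requires a seed")
        rng = np.random.default_rng(seed)
        intervals = rng.choice(RANDOM_ISI_SET, size=n_onsets - 1)
        onsets = np.concatenate([[0.0], np.cumsum(intervals)])
        return StimulusTrack(
            condition="RANDOM", onsets_ms=tuple(onsets),
            seed=seed if isinstance(seed, (int, np.integer)) else None)
    raise ValueError(f"unknown condition {condition!r}")


def angle_to_ms(angle_deg: float, isi_ms: float) -> float:
    """Convert a phase angle back to a signed asynchrony in ms."""
    if not isi_ms > 0:
        raise ValueError("ISI must be positive")
    if not -180.0 < angle_deg <= 180.0:
        raise ValueError("angle must lie in (-180, 180]")
    return angle_deg / 360.0 * isi_ms


def _match_taps(taps: np.ndarray, track: StimulusTrack,
                reference_isi_ms: float | None):
    """Vectorised nearest-onset matching; returns a masked sample table.

    Output arrays are aligned with ``taps``; entries where ``matched`` is
    False fall outside the track envelope.
    """
    onsets = track.onsets()
    if onsets.size == 0:
        raise ValueError("cannot compute phases against an empty track")
    if onsets.size == 1:
        raise ValueError("need at least two stimulus onsets")
    gaps = np.diff(onsets)

    if track.nominal_isi_ms is not None and reference_isi_ms is None:
        # exact arithmetic path for isochronous tracks
        isi = track.nominal_isi_ms
        matched = (taps >= onsets[0] - isi / 2.0) & \
                  (taps <= onsets[-1] + isi / 2.0)
        u = (taps - onsets[0]) / isi
        k = np.ceil(u - 0.5)            # round half down: midpoint ties
        k = np.clip(k, 0, onsets.size - 1).astype(int)
        asyn = taps - onsets[k]
        local = np.full_like(taps, isi)
        return matched, onsets[k], local, asyn

    # general path: explicit neighbour comparison
    j = np.searchsorted(onsets, taps, side="right") - 1
    j = np.clip(j, 0, onsets.size - 2)
    prev_d = taps - onsets[j]
    next_d = onsets[j + 1] - taps
    take_prev = prev_d <= next_d        # midpoint tie -> preceding onset
    k = np.where(take_prev, j, j + 1)
    # taps before the first onset sit left of every interval
    before = taps < onsets[0]
    k = np.where(before, 0, k)
    asyn = taps - onsets[k]
    gap_idx = np.clip(j, 0, gaps.size - 1)
    local = gaps[gap_idx]
    matched = (taps >= onsets[0] - gaps[0] / 2.0) & \
              (taps <= onsets[-1] + gaps[-1] / 2.0)
    if reference_isi_ms is not None:
        local = np.full_like(taps, float(reference_isi_ms))
    return matched, onsets[k], local, asyn


def tap_to_phase(tap_time_ms: float, track: StimulusTrack,
                 reference_isi_ms: float | None = None) -> PhaseSample | None:
    """Phase of a single tap, or None when the tap is unmatchable.

    ``reference_isi_ms`` switches the normalisation from the local
    interval containing the tap to a fixed reference interval (relevant
    only for the random condition, where the choice is not unique).
    """
    taps = np.asarray([float(tap_time_ms)])
    matched, onset, local, asyn = _match_taps(taps, track, reference_isi_ms)
    if not matched[0]:
        return None
    angle = wrap_degrees(360.0 * asyn[0] / local[0])
    return PhaseSample(tap_time_ms=float(taps[0]),
                       matched_onset_ms=float(onset[0]),
                       local_isi_ms=float(local[0]),
                       angle_deg=float(angle),
                       asynchrony_ms=float(asyn[0]))


def phases_for_trial(trial: TapTrial, track: StimulusTrack,
                     reference_isi_ms: float | None = None) -> TrialPhases:
    """Map every tap of a trial to phase; unmatched taps are counted."""
    if track.condition == "NO_STIM":
        raise ValueError(
            "phases require a stimulus track; pair NO_STIM trials with a "
            "reference track first (re-pairing null)")
    taps = trial.onsets()
    matched, onset, local, asyn = _match_taps(taps, track, reference_isi_ms)
    angles = wrap_degrees(360.0 * asyn / local)
    samples = tuple(
        PhaseSample(tap_time_ms=float(t), matched_onset_ms=float(o),
                    local_isi_ms=float(li), angle_deg=float(a),
                    asynchrony_ms=float(s))
        for t, o, li, a, s, ok in zip(taps, onset, local,
                                      np.atleast_1d(angles), asyn, matched)
        if ok)
    return TrialPhases(samples=samples,
                       n_unmatched=int((~matched).sum()))


def trial_angles(trial: TapTrial, track: StimulusTrack,
                 reference_isi_ms: float | None = None) -> np.ndarray:
    """Fast path: matched angles only, skipping per-sample objects."""
    if track.condition == "NO_STIM":
        raise ValueError("phases require a stimulus track")
    taps = trial.onsets()
    matched, _, local, asyn = _match_taps(taps, track, reference_isi_ms)
    return np.atleast_1d(
        wrap_degrees(360.0 * asyn[matched] / local[matched]))
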
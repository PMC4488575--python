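"""Synthetic tapper: self-paced alternate tapping with optional
phase coupling to a distractor rhythm.

The generative model has three ingredients:

* a motor period ``T_m`` (the spontaneous tempo) that performs a
  Gaussian random walk within each trial (``drift_sd_ms`` per tap),
* white Gaussian per-interval noise (``period_noise_sd_ms``), and
* optional proportional phase correction: when a stimulus track is
  present, a fraction ``coupling_gain`` of the provisional tap's
  asynchrony to the nearest stimulus onset is subtracted from the next
  onset, but only while the provisional phase lies within
  ``coupling_window_deg`` of an onset (180 = always).

With zero gain the process is pure self-paced tapping; with the gain
high and the motor tempo near the stimulus tempo the phases contract
toward 0 degrees -- the simulator's stand-in for intermittent
entrainment.  Coupling is a minimal phenomenological mechanism, not a
claim about the underlying biology.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace

import numpy as np
import yaml

from .phase_model import generate_stimulus_track
from .session_io import (ISOCHRONOUS_ISI, StimulusTrack, StudyDataset,
                         TapTrial)

__all__ = [
    "TapperParams",
    "PlantedStudy",
    "load_presets",
    "profile_params",
    "simulate_trial",
    "simulate_study",
    "planted_entrainment_study",
]

#: physiological refractory floor for successive taps (ms)
MIN_INTERVAL_MS = 1.0

_KEYS = ("C4", "C5")


def load_presets() -> dict:
    """Simulator presets shipped with the package (versioned YAML)."""
    text = (importlib.resources.files("tapentrain") / "presets.yaml") \
        .read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class TapperParams:
    """Parameters of the synthetic tapper (times in ms)."""

    base_period_ms: float = 450.0
    period_noise_sd_ms: float = 20.0
    drift_sd_ms: float = 1.5
    coupling_gain: float = 0.0
    coupling_window_deg: float = 180.0
    n_taps_per_trial: int = 30

    def __post_init__(self):
        if not self.base_period_ms > 0:
            raise ValueError("base period must be positive")
        if self.period_noise_sd_ms < 0 or self.drift_sd_ms < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0.0 <= self.coupling_gain < 1.0:
            raise ValueError("coupling gain must lie in [0, 1)")
        if not 0.0 < self.coupling_window_deg <= 180.0:
            raise ValueError("coupling window must lie in (0, 180]")
        if self.n_taps_per_trial < 1:
            raise ValueError("need at least one tap per trial")


def profile_params(profile: str, rng=None, coupling_gain: float = 0.0,
                   base_period_ms: float | None = None) -> TapperParams:
    """TapperParams for a named participant profile.

    The base period is drawn uniformly from the profile's documented
    range unless given explicitly; pass an ``rng`` to make the draw
    reproducible.
    """
    presets = load_presets()["profiles"]
    if profile not in presets:
        raise ValueError(f"unknown profile {profile!r}; "
                         f"choose from {sorted(presets)}")
    spec = presets[profile]
    if base_period_ms is None:
        lo, hi = spec["base_period_range_ms"]
        rng = np.random.default_rng(rng)
        base_period_ms = float(rng.uniform(lo, hi))
    return TapperParams(base_period_ms=base_period_ms,
                        period_noise_sd_ms=spec["period_noise_sd_ms"],
                        drift_sd_ms=spec["drift_sd_ms"],
                        coupling_gain=coupling_gain)


def _nearest_asynchrony(t: float, onsets: np.ndarray,
                        gaps: np.ndarray) -> tuple[float, float]:
    """(asynchrony, local interval) of time t to its nearest onset."""
    j = int(np.searchsorted(onsets, t, side="right")) - 1
    if j < 0:
        return t - onsets[0], float(gaps[0])
    if j >= onsets.size - 1:
        return t - onsets[-1], float(gaps[-1])
    prev_d = t - onsets[j]
    next_d = onsets[j + 1] - t
    asyn = prev_d if prev_d <= next_d else -next_d
    return float(asyn), float(gaps[j])


def simulate_trial(params: TapperParams, track: StimulusTrack | None = None,
                   rng=None, trial_id: str = "t0",
                   role: str = "test") -> TapTrial:
    """Simulate one trial of alternate tapping.

    The first onset is drawn uniformly in [0, base period) so the
    initial phase relative to any stimulus is random.  Deterministic
    under a fixed ``rng`` state.
    """
    rng = np.random.default_rng(rng)
    couple = (track is not None and track.n_onsets >= 2
              and params.coupling_gain > 0.0)
    if couple:
        onsets = track.onsets()
        gaps = np.diff(onsets)

    period = params.base_period_ms
    t = float(rng.uniform(0.0, params.base_period_ms))
    taps = [t]
    for _ in range(params.n_taps_per_trial - 1):
        period += rng.normal(0.0, params.drift_sd_ms)
        t_next = taps[-1] + period + rng.normal(0.0, params.period_noise_sd_ms)
        if couple:
            asyn, local = _nearest_asynchrony(t_next, onsets, gaps)
            if abs(360.0 * asyn / local) <= params.coupling_window_deg:
                t_next -= params.coupling_gain * asyn
        t_next = max(t_next, taps[-1] + MIN_INTERVAL_MS)
        taps.append(t_next)
    labels = tuple(_KEYS[i % 2] for i in range(len(taps)))
    return TapTrial(trial_id=trial_id, role=role, onsets_ms=tuple(taps),
                    key_labels=labels)


def _track_for(condition: str, params: TapperParams, rng) -> StimulusTrack:
    # twice the expected trial duration leaves ample margin for noise
    duration = 2.0 * params.n_taps_per_trial * params.base_period_ms
    if condition in ISOCHRONOUS_ISI:
        n = int(np.ceil(duration / ISOCHRONOUS_ISI[condition])) + 2
        return generate_stimulus_track(condition, n)
    if condition == "RANDOM":
        n = int(np.ceil(duration / 300.0)) + 2
        return generate_stimulus_track(condition, n, seed=rng)
    return generate_stimulus_track("NO_STIM", 0)


def simulate_study(profile: str, coupling_gain: float = 0.0,
                   conditions=None, seed=None,
                   base_period_ms: float | None = None,
                   participant_id: str | None = None) -> StudyDataset:
    """Simulate a complete single-participant study.

    Default design: 6 sessions x 3 test trials per condition (18 test
    trials, 540 taps when complete) plus 30 no-stimulus training trials
    feeding the Monte Carlo re-pairing pool.  One stimulus track per
    condition, shared across its trials.
    """
    presets = load_presets()
    design = presets["study_design"]
    if conditions is None:
        conditions = design["exp1_conditions"]
    rng = np.random.default_rng(seed)
    params = profile_params(profile, rng=rng, coupling_gain=coupling_gain,
                            base_period_ms=base_period_ms)
    dataset = StudyDataset(
        participant_id=participant_id or f"sim_{profile}",
        species_profile=profile)

    dataset.training_pool = [
        simulate_trial(replace(params, coupling_gain=0.0), None, rng,
                       trial_id=f"train_{i:02d}", role="training")
        for i in range(design["n_training_trials"])]

    n_test = design["n_sessions"] * design["trials_per_session"]
    for condition in conditions:
        track = _track_for(condition, params, rng)
        trial_track = None if condition == "NO_STIM" else track
        dataset.sessions[condition] = [
            (simulate_trial(params, trial_track, rng,
                            trial_id=f"{condition}_s{i // 3}_t{i % 3}"),
             trial_track)
            for i in range(n_test)]
    return dataset


@dataclass(frozen=True)
class PlantedStudy:
    """A simulated condition with known ground-truth entrained trials."""

    dataset: StudyDataset
    condition: str
    planted_trial_ids: tuple


def planted_entrainment_study(n_entrained: int, coupling_gain: float = 0.5,
                              mismatch_pct: float = 0.0, seed=None,
                              condition: str = "ISI400",
                              n_trials: int = 18,
                              n_training: int = 30) -> PlantedStudy:
    """Plant phase-locked trials among self-paced ones.

    Exactly ``n_entrained`` of the ``n_trials`` test trials are
    simulated with the coupling on; the remainder tap self-paced.  The
    tapper's motor period is the stimulus ISI scaled by
    ``1 + mismatch_pct/100``, and its variability comes from the
    ``planted`` preset.  Planted positions are chosen at random and
    recorded as ground truth for recovery experiments.
    """
    if condition not in ISOCHRONOUS_ISI:
        raise ValueError("planted studies need an isochronous condition")
    if not 0 <= n_entrained <= n_trials:
        raise ValueError("invalid planted-trial count")
    rng = np.random.default_rng(seed)
    presets = load_presets()
    noise = presets["planted"]
    isi = ISOCHRONOUS_ISI[condition]
    params = TapperParams(
        base_period_ms=isi * (1.0 + mismatch_pct / 100.0),
        period_noise_sd_ms=noise["period_noise_sd_ms"],
        drift_sd_ms=noise["drift_sd_ms"],
        coupling_gain=coupling_gain)
    track = _track_for(condition, params, rng)

    planted = set(rng.choice(n_trials, size=n_entrained, replace=False)
                  .tolist())
    dataset = StudyDataset(participant_id="planted", species_profile=None)
    dataset.training_pool = [
        simulate_trial(replace(params, coupling_gain=0.0), None, rng,
                       trial_id=f"train_{i:02d}", role="training")
        for i in range(n_training)]
    pairs = []
    ids = []
    for i in range(n_trials):
        p = params if i in planted else replace(params, coupling_gain=0.0)
        trial = simulate_trial(p, track if i in planted else None, rng,
                               trial_id=f"{condition}_t{i:02d}")
        if i in planted:
            ids.append(trial.trial_id)
        pairs.append((trial, track))
    dataset.sessions[condition] = pairs
    return PlantedStudy(dataset=dataset, condition=condition,
                        planted_trial_ids=tuple(ids))
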
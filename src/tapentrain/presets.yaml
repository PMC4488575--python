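# Simulator presets, version-controlled with the package.
#
# Participant profiles are calibrated so that the pooled inter-tap
# statistics of a simulated no-stimulus dataset fall in the observed
# chimpanzee and human bands: median ITI in the stated base-period
# range, and mean absolute deviation about the median of roughly
# 120-152 ms (chimpanzee-like) vs 13-23 ms (human-like).  Two noise
# sources are needed: white per-interval noise alone cannot produce the
# chimpanzee-scale deviation while keeping a stable median, so the
# local motor period additionally performs a random walk within each
# trial ("drift").
version: 1
profiles:
  chimp_like:
    base_period_range_ms: [355.0, 450.0]
    period_noise_sd_ms: 140.0
    drift_sd_ms: 27.0
  human_like:
    base_period_range_ms: [333.0, 505.0]
    period_noise_sd_ms: 20.0
    drift_sd_ms: 1.5
# Tapper used by planted-entrainment experiments: variability at the
# low end of the spontaneous range so that a coupled trial is genuinely
# phase-locked in the sense of the per-trial Rayleigh test.
planted:
  period_noise_sd_ms: 35.0
  drift_sd_ms: 15.0
study_design:
  n_sessions: 6
  trials_per_session: 3
  n_training_trials: 30
  n_taps_per_trial: 30
  exp1_conditions: [NO_STIM, ISI400, ISI500, ISI600, RANDOM]
  exp2_conditions: [NO_STIM, ISI320, ISI340, ISI360, ISI380, RANDOM]
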
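# tapentrain

Circular-statistics analysis of **distractor-rhythm entrainment** in
self-paced tapping, for researchers in sensorimotor synchronization
and comparative cognition.

When a person or a chimpanzee taps at their own pace while an
isochronous sound sequence plays in the background, tap timing can be
intermittently attracted to the rhythm — but only when the stimulus
tempo is close to the tapper's spontaneous motor tempo.  This package
implements the full inference chain for detecting that effect from
tap-onset time series, plus a generative tapper model for testing and
power analysis when no recorded data are available.

## What it computes

Each tap is mapped to a phase angle relative to its nearest stimulus
onset, `θ = 360°·a/L ∈ (−180°, 180°]` (asynchrony `a`, local
inter-onset interval `L`, onsets at 0°).  On these phases:

* **Pooled omnibus test** (Hodges–Ajne): statistic
  `m = min` number of observations in any half circle; exact tail
  `(n − 2m)·C(n,m)·2^(1−n)` for small samples, the classical
  large-sample approximation otherwise.  Sensitive to unimodal and
  multimodal phase preference alike.
* **Trial-by-trial Rayleigh tests** (`Z = nR²`) to distinguish
  sustained from intermittent phase locking, with per-trial mean
  directions and resultant lengths.
* **Monte Carlo re-pairing null**: 18 of 30 no-stimulus training
  trials drawn without replacement and re-paired with the stimulus
  track, 10,000 times; the reported proportion is the fraction of
  re-paired sets at least as skewed (p at most the observed p).
* **Spontaneous-tempo statistics**: median inter-tap interval, mean
  absolute deviation about it, outlier exclusion at median ± 2
  deviations, pooled-variance t comparisons between groups, and the
  tempo-mismatch percentage `100·|ISI − median ITI|/median ITI` that
  predicts where entrainment can occur (below ~20%).
* **Synthetic tapper**: motor period with within-trial random-walk
  drift, white per-interval noise, and optional proportional phase
  correction toward the nearest onset — including chimpanzee-like and
  human-like variability presets and planted-entrainment studies with
  known ground truth.

See `docs/methods.md` for conventions, calibration facts, and
limitations.

## Worked example

Simulate a participant whose tapping locks to a 400-ms rhythm in 4 of
18 trials (ground truth known), then run the full chain:

```python
from tapentrain import (StudyConfig, planted_entrainment_study, run_study)

study = planted_entrainment_study(4, coupling_gain=0.5, mismatch_pct=0.0,
                                  seed=7)
report = run_study(study.dataset, StudyConfig(seed=7, n_iter=10_000))
cond = report.conditions["ISI400"]
print(f"pooled omnibus: m = {cond.pooled.statistic:.0f}, "
      f"p = {cond.pooled.p_value:.3g}, "
      f"mean direction = {cond.pooled.summary.mean_direction_deg:.1f} deg, "
      f"R = {cond.pooled.summary.resultant_length:.2f}")
print(f"significant trials: {cond.trialwise.n_significant} / "
      f"{len(cond.trialwise.results)} (planted: {len(study.planted_trial_ids)})")
print(f"Monte Carlo proportion: {cond.monte_carlo.proportion_extreme:.4f} "
      f"({cond.monte_carlo.n_iterations} re-paired sets)")
print(f"tempo mismatch: {cond.tempo_mismatch_percent:.1f}%")
```

Output:

```
pooled omnibus: m = 173, p = 9.78e-15, mean direction = -1.8 deg, R = 0.26
significant trials: 4 / 18 (planted: 4)
Monte Carlo proportion: 0.0000 (10000 re-paired sets)
tempo mismatch: 4.4%
```

Reading it: of 540 pooled phases, the emptiest half circle holds 173 —
far fewer than the ~270 expected under uniformity, so the pooled
distribution is skewed toward the rhythm (p ≈ 1e-14, well below a
Bonferroni criterion such as 0.000794).  The modest pooled resultant
length (R = 0.26) together with exactly 4 individually significant
trials says the locking was intermittent, not sustained — and those 4
are precisely the planted ones.  None of 10,000 re-paired no-stimulus
sets was as skewed, so spontaneous tempo structure cannot explain the
effect; consistently, the tapper's spontaneous tempo sits only 4.4%
from the stimulus tempo.

A command-line interface wraps the same steps:

```sh
tapentrain simulate --profile chimp_like --coupling 0.3 --seed 7 --out data.csv
tapentrain analyze --input data.csv --out report/
tapentrain report --in report/
```

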
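# Methods

## The problem

Humans (and, weakly, chimpanzees) drift toward an auditory rhythm they
are trying to ignore while producing a self-paced movement — a
*distractor effect* that shows up as intermittent entrainment when the
stimulus tempo is close to the mover's spontaneous tempo.  The analysis
problem is to decide, from per-trial tap-onset time series and the
stimulus-onset track the participant heard, whether tap timing was
influenced by the rhythm, and whether that influence was sustained or
intermittent.

`tapentrain` implements this inference chain end to end, together with
a generative tapper model so that every stage can be exercised and
calibrated without access to recorded data.

## Phase mapping

Each tap at time `t` is matched to its nearest stimulus onset; the
signed asynchrony `a = t − onset` (positive = tap lags the onset) is
normalised by the local inter-onset interval `L` to a phase angle

    θ = 360° · a / L,   θ ∈ (−180°, 180°],  onsets at 0°.

Conventions, all configurable where the choice is not forced:

* **Nearest-onset matching**, with a tap exactly midway between two
  onsets assigned to the preceding onset (θ = +180°).  The published
  analyses never state their assignment rule; nearest-onset is the
  only rule that makes "onsets at 0°" with a symmetric ±180° range
  coherent, and no printed direction disambiguates the tie handling.
* **Local-interval normalisation** for the random condition (each tap
  normalised by the interval that contains it).  A fixed reference
  interval is available as a switch (`reference_isi_ms`), since the
  normalisation used for published random-condition plots is unstated.
* Taps earlier than half an interval before the first onset, or later
  than half an interval after the last, are unmatchable; they are
  dropped and counted, never extrapolated.
* Degrees are the external unit everywhere; trial time zero coincides
  with stimulus-track time zero for test trials.
* No latency correction is applied to onsets (recording latency is
  reported, not corrected, in the source studies); a constant shift
  parameter exists for hardware whose latency is known.

## Uniformity tests

**Rayleigh test** (per trial, unimodal alternative): `Z = nR²` with
`R` the mean resultant length, and the small-sample-corrected tail

    p = exp( sqrt(1 + 4n + 4(n² − (nR)²)) − (1 + 2n) ).

**Hodges–Ajne omnibus test** (pooled, no distributional alternative):
the statistic `m` is the smallest number of observations in any half
circle.  Half circles are closed on the leading boundary and open on
the trailing one, so antipodal ties count exactly once.  The count
only changes when the boundary crosses a data point or a point's
antipode, and the half circle starting at a point's antipode is the
exact complement of the one starting at the point; `m` is therefore
computed as `min_i min(c_i, n − c_i)` over data-point boundaries —
exact, O(n log n), and free of the floating-point fragility that
boundary-plus-180° arithmetic introduces.

Tail probability: exact, `p = (n − 2m)·C(n, m)·2^(1−n)`, for
`n ≤ 50` when `m < n/3` (its validity region); otherwise the classical
large-sample approximation

    p = sqrt(2π)/A · exp(−π²/(8A²)),   A = πsqrt(n) / (2(n − 2m)).

All p-values are capped into (tiny, 1].

Numerical facts a user should know (both established by the test
suite's Monte Carlo checks):

* At the pooled design size (n = 540) the approximation matches the
  statistic's true null CDF to about 0.003 through the body of the
  distribution, and the type-I error at 0.05 is nominal.  But `m` is
  integer-valued with ~50 attainable values there (largest point mass
  ≈ 0.06), so the *reported* p-values form a lattice: their
  Kolmogorov–Smirnov distance from a continuous uniform has a
  discreteness floor around 0.06 no matter how accurate the formula
  is.  Tie-randomised p-values are uniform, which is how the formula's
  calibration is verified.
* The approximation is unreliable deep in the tail (relative error
  grows without bound as m → 0) and near m = n/2; decisions at
  published criteria are made at magnitudes where the exact formula
  (small n) or the calibrated body (large n) applies.

## Bonferroni criteria

Published analyses report corrected criteria (e.g. 0.000794 for the
condition-level omnibus family, 0.000278 for trial-by-trial tests)
whose underlying comparison counts cannot be reconstructed
unambiguously.  The criteria are therefore explicit configuration
constants (`PRINTED_CRITERIA`), and `BonferroniPlan` accepts either a
comparison count or a criterion override.

## Monte Carlo re-pairing null

The spontaneous-tempo structure of a participant's tapping could mimic
phase locking, so a significant pooled test is confirmed against a
participant-specific null: from the pool of 30 no-stimulus training
trials, draw 18 without replacement, pair each trial with the
condition's stimulus track (trial clock zero = track zero), pool the
phases, and run the omnibus test; repeat (default 10,000 sets).  The
reported `proportion_extreme` is the fraction of re-paired sets whose
p is at most the observed p — distributions at least as skewed as the
observed one.

Calibration caveat, documented because it is a property of the design
rather than of this implementation: all re-paired sets share one
finite 30-trial pool.  When the observed p is drawn by the same
re-pairing mechanism from the same pool, `proportion_extreme` is
uniform on (0, 1) (the exchangeable case, verified in the acceptance
suite).  When the observed p comes from *fresh* trials, the proportion
is mean-correct but over-dispersed (u-shaped; roughly 13% of mass
below 0.05 instead of 5% in simulations), because the proportion is
estimated conditionally on the realised pool.  Single-pool Monte
Carlo confirmations of this design share that anticonservatism.

## Trial-by-trial analysis and vector lengths

Intermittent entrainment appears as a minority of trials with
individually significant Rayleigh tests.  Each complete trial is
tested at the trial-family criterion; per-trial mean directions and
resultant lengths are retained.  As a control, the no-stimulus trials
are re-paired with the same track and tested identically, and the
per-condition mean resultant lengths (stimulus vs re-paired
no-stimulus) are compared with a paired t-test (df = pairs − 1).

## Tempo statistics

Spontaneous motor tempo = median of inter-tap intervals pooled over
no-stimulus test trials; variability = mean absolute deviation about
that median ("average absolute variance" in the source's terminology —
the only reading consistent with its "median and absolute deviation"
phrasing).  Outlier exclusion (outside median ± 2 deviations, closed
interval) is a separate explicit step and is off by default, since the
published tables appear to be computed without it.  Species
comparisons use the pooled-variance Student's t-test: that choice —
not Welch — reproduces the published t on the median tempi exactly
(−0.717, df = 7).  The published variability t (17.784) is *not*
exactly recomputable from the printed one-decimal table values (they
give 17.790); the 0.006 gap can only come from rounding of the printed
inputs.

Tempo mismatch between participant and stimulus is
`100·|ISI − median ITI| / median ITI`, with entrainment expected below
roughly 20%.

## The synthetic tapper

`simulate_trial` generates onsets from a motor period `T_m` that
performs a Gaussian random walk within each trial (drift, sd `σ_d` per
tap) plus white per-interval noise (sd `σ_w`); with a stimulus track
present, a fraction `α ∈ [0, 1)` of the provisional tap's asynchrony
to the nearest onset is subtracted (proportional phase correction),
optionally only within a phase window.  The first onset's phase is
uniform.  A 1 ms refractory floor keeps onsets strictly increasing.

Two noise sources are the minimal structure that reproduces both
human-like stability and chimpanzee-scale variability with a stable
median: white noise alone cannot give a mean absolute deviation of
~135 ms at a ~400 ms median without unrealistic interval reversals.
Proportional phase correction is the simplest mechanism that yields
intermittent entrainment at small tempo mismatch and none at large
mismatch ((T_m − ISI)/α beyond half a period breaks the lock); it is a
phenomenological stand-in, not a mechanistic claim.

Preset parameters (versioned in `presets.yaml`):

| profile | base period (ms) | σ_w (ms) | σ_d (ms/tap) | pooled MAD |
|---|---|---|---|---|
| `chimp_like` | uniform 355–450 | 140 | 27 | ~135 ms |
| `human_like` | uniform 333–505 | 20 | 1.5 | ~17 ms |
| `planted` tapper | stimulus ISI × (1 + mismatch) | 35 | 15 | — |

The species profiles are calibrated so a simulated participant's
pooled mean absolute deviation falls within the published bands
(120–152 ms and 13–23 ms respectively; ≥ 90/100 simulated participants
in the acceptance suite, in practice ~100/100).  The planted-study
tapper uses variability at the low end of the spontaneous range so
that a coupled trial is genuinely phase-locked in the sense of the
per-trial test (per-trial power ≈ 1 at 0% mismatch with α = 0.5);
with chimpanzee-scale noise no per-trial lock of this kind is
achievable at α < 1, which is itself informative about what the
per-trial criterion can detect.

What the simulator does *not* emulate: wrong-key taps and reward
contingencies, long pauses (its chimpanzee-like variability is
continuous fluctuation), between-session tempo changes, and any
within-trial autocorrelation structure beyond the random walk — no
published autocorrelation data exist to calibrate one.  Passing tests
therefore certify the inference chain against these assumptions, not
against every property of real tapping.

## Problem sizes in the test and acceptance runs

Desk-scale sizes keep the full suite under half a minute while leaving
every statistical check well-powered: 200 random sets for the
brute-force equivalence, 100,000 draws for the exact-tail check,
2,000 replicates for p-value calibration at n = 540, 200 pipeline
replicates (500 inner re-pairings) for Monte Carlo calibration, and
100 replicates for planted-trial recovery and the simulator bands.
The acceptance script runs the published-scale Monte Carlo (10,000
re-pairings) once on a simulated entrained participant.

## Known limitations

* The exact Hodges–Ajne tail exists only for `m < n/3`; beyond it the
  implementation falls back to the approximation, whose accuracy near
  p = 1 is poor (it is capped at 1).
* The re-pairing null conditions on a single training pool (see
  above); its p is exchangeable-valid, not marginally calibrated.
* MIDI import supports format 0/1 files with tick-per-quarter
  divisions and note-on extraction only; SMPTE divisions are rejected.
* The simulator's coupling corrects toward the nearest onset only;
  period (tempo) correction is out of scope.
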
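"""Spontaneous-tempo statistics and species comparisons.

The spontaneous motor tempo of a participant is the median of the
inter-tap intervals (ITIs) pooled over their no-stimulus trials; tapping
variability is the mean absolute deviation of those ITIs about the
median.  Outlying intervals (beyond the median +/- 2 deviations) can be
excluded as a robustness check.  Between-group comparisons use the
pooled-variance Student's t-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .session_io import TapTrial

__all__ = [
    "ParticipantTempoSummary",
    "TTestResult",
    "trial_itis",
    "tempo_summary",
    "exclude_outliers",
    "two_sample_t",
    "paired_t",
]


@dataclass(frozen=True)
class ParticipantTempoSummary:
    participant_id: str
    median_iti_ms: float
    mean_abs_dev_ms: float
    n_itis: int
    n_outliers_excluded: int = 0


@dataclass(frozen=True)
class TTestResult:
    """t statistic with its degrees of freedom and two-sided p.

    ``degenerate`` flags zero-variance inputs, where t is 0 (equal
    means) or signed infinity (unequal means).
    """

    t: float
    df: int
    p_value: float
    degenerate: bool = False


def trial_itis(trial: TapTrial) -> np.ndarray:
    """Successive tap-onset differences (ms); empty for <2 taps."""
    onsets = trial.onsets()
    if onsets.size < 2:
        warnings.warn(f"trial {trial.trial_id} has fewer than two taps; "
                      "no intervals", stacklevel=2)
        return np.empty(0)
    return np.diff(onsets)


def tempo_summary(trials, participant_id: str = "") -> ParticipantTempoSummary:
    """Median ITI and mean absolute deviation over pooled trials.

    The deviation is the mean of |ITI - median| about the pooled median,
    computed without outlier exclusion (exclusion is a separate,
    explicit step).  Invariant to trial order.
    """
    pools = [trial_itis(t) for t in trials if t.n_taps >= 2]
    itis = np.concatenate(pools) if pools else np.empty(0)
    if itis.size == 0:
        raise ValueError("no inter-tap intervals to summarise")
    median = float(np.median(itis))
    dev = float(np.mean(np.abs(itis - median)))
    return ParticipantTempoSummary(
        participant_id=participant_id, median_iti_ms=median,
        mean_abs_dev_ms=dev, n_itis=int(itis.size))


def exclude_outliers(itis, summary: ParticipantTempoSummary) -> np.ndarray:
    """Keep ITIs within median +/- 2 mean absolute deviations (closed)."""
    arr = np.asarray(itis, dtype=float)
    lo = summary.median_iti_ms - 2.0 * summary.mean_abs_dev_ms
    hi = summary.median_iti_ms + 2.0 * summary.mean_abs_dev_ms
    return arr[(arr >= lo) & (arr <= hi)]


def _degenerate_t(mean_diff: float, df: int) -> TTestResult:
    if mean_diff == 0.0:
        return TTestResult(t=0.0, df=df, p_value=1.0, degenerate=True)
    return TTestResult(t=math.copysign(math.inf, mean_diff), df=df,
                       p_value=0.0, degenerate=True)


def two_sample_t(group_a, group_b) -> TTestResult:
    """Pooled-variance Student's t for two independent groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    df = a.size + b.size - 2
    pooled_var = (np.var(a, ddof=1) * (a.size - 1)
                  + np.var(b, ddof=1) * (b.size - 1)) / df
    if pooled_var == 0.0:
        return _degenerate_t(float(a.mean() - b.mean()), df)
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(res.statistic), df=df,
                       p_value=float(res.pvalue))


def paired_t(x, y) -> TTestResult:
    """One-sample t on paired differences x - y."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("paired samples must have equal length")
    if xa.size < 2:
        raise ValueError("need at least two pairs")
    diffs = xa - ya
    df = xa.size - 1
    if np.var(diffs, ddof=1) == 0.0:
        return _degenerate_t(float(diffs.mean()), df)
    res = stats.ttest_rel(xa, ya)
    return TTestResult(t=float(res.statistic), df=df,
                       p_value=float(res.pvalue))
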
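"""Circular summaries and uniformity tests for tap-phase data.

All angles are degrees on the half-open interval (-180, 180], with 0
meaning a tap coincident with a stimulus onset and positive angles a tap
lagging the onset.  Two uniformity tests are provided:

* the Rayleigh test, powerful against a unimodal concentration of phase,
  with the classical small-sample-corrected p-value approximation
  ``p = exp(sqrt(1 + 4n + 4(n^2 - (nR)^2)) - (1 + 2n))``; and
* the Hodges-Ajne omnibus test, which needs no distributional alternative
  and is sensitive to unimodal as well as multimodal departures.  Its
  statistic ``m`` is the smallest number of observations contained in any
  closed-open half circle; the exact tail probability
  ``(n - 2m) C(n, m) 2^(1-n)`` is used for small samples and the classical
  large-sample approximation otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CircSummary",
    "CircTestResult",
    "wrap_degrees",
    "circ_summary",
    "rayleigh_test",
    "hodges_ajne_m",
    "hodges_ajne_test",
]

#: smallest p-value ever reported, to keep log-scale reporting safe
P_FLOOR = np.finfo(float).tiny

#: largest sample size for which the exact Hodges-Ajne tail is evaluated
DEFAULT_N_EXACT = 50


@dataclass(frozen=True)
class CircSummary:
    """First circular moment of an angle set.

    ``mean_direction_deg`` is NaN (and ``mean_defined`` False) when the
    resultant length vanishes, e.g. for perfectly balanced samples.
    """

    n: int
    mean_direction_deg: float
    resultant_length: float
    mean_defined: bool = True


@dataclass(frozen=True)
class CircTestResult:
    """Outcome of a circular uniformity test.

    ``statistic`` is the half-circle count ``m`` for the Hodges-Ajne test
    and ``Z = n R^2`` for the Rayleigh test.  ``significant`` is None when
    no criterion was supplied.
    """

    test: str
    statistic: float
    p_value: float
    summary: CircSummary
    criterion: float | None = None
    significant: bool | None = None


def _as_angles(angles, min_n: int) -> np.ndarray:
    a = np.asarray(angles, dtype=float).ravel()
    if a.size < min_n:
        raise ValueError(f"need at least {min_n} angles, got {a.size}")
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    return a


def wrap_degrees(x):
    """Wrap angles (degrees) onto (-180, 180]; -180 maps to +180.

    Accepts scalars or arrays; preserves the value modulo 360.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("wrap_degrees requires finite input")
    wrapped = 180.0 - np.mod(180.0 - arr, 360.0)
    if np.isscalar(x) or arr.ndim == 0:
        return float(wrapped)
    return wrapped


def circ_summary(angles) -> CircSummary:
    """Mean direction and resultant length of a sample of angles (degrees).

    The mean direction is the argument of the mean unit vector and the
    resultant length R its norm, R in [0, 1].  R = 0 (to numerical
    tolerance) leaves the direction undefined.
    """
    a = np.radians(_as_angles(angles, 1))
    c = float(np.mean(np.cos(a)))
    s = float(np.mean(np.sin(a)))
    r = float(np.hypot(c, s))
    r = min(r, 1.0)
    if r < 1e-12:
        return CircSummary(n=a.size, mean_direction_deg=float("nan"),
                           resultant_length=0.0, mean_defined=False)
    direction = wrap_degrees(math.degrees(math.atan2(s, c)))
    return CircSummary(n=a.size, mean_direction_deg=direction,
                       resultant_length=r)


def _clip_p(p: float) -> float:
    return float(min(1.0, max(P_FLOOR, p)))


def rayleigh_test(angles, criterion: float | None = None) -> CircTestResult:
    """Rayleigh test of uniformity against a unimodal alternative."""
    a = _as_angles(angles, 2)
    summary = circ_summary(a)
    n = summary.n
    nr = n * summary.resultant_length
    z = nr * nr / n
    # small-sample corrected approximation to the tail probability
    p = math.exp(math.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - nr * nr))
                 - (1.0 + 2.0 * n))
    p = _clip_p(p)
    return CircTestResult(
        test="rayleigh", statistic=float(z), p_value=p, summary=summary,
        criterion=criterion,
        significant=None if criterion is None else p < criterion)


def hodges_ajne_m(angles) -> int:
    """Minimal number of observations in any half circle.

    Half circles are closed on their leading boundary and open on the
    trailing one, so a point antipodal to the boundary counts exactly
    once.  The count only changes when the boundary crosses a data point
    or its antipode, so scanning those 2n candidate boundaries is exact.
    """
    a = np.sort(np.mod(_as_angles(angles, 1), 360.0))
    n = a.size
    doubled = np.concatenate([a, a + 360.0])
    lo = np.searchsorted(doubled, a, side="left")
    hi = np.searchsorted(doubled, a + 180.0, side="left")
    counts = hi - lo
    # a half circle starting at a point's antipode is the exact
    # complement of the one starting at the point, so complements cover
    # all antipodal boundaries without fragile floating-point arithmetic
    return int(np.min(np.minimum(counts, n - counts)))


def _ajne_p_exact(n: int, m: int) -> float:
    # valid for m < n/3; exact in integer arithmetic before the division
    return _clip_p((n - 2 * m) * math.comb(n, m) * 2.0 ** (1 - n))


def _ajne_p_approx(n: int, m: int) -> float:
    if n == 2 * m:
        return 1.0
    big_a = math.pi * math.sqrt(n) / (2.0 * (n - 2 * m))
    p = (math.sqrt(2.0 * math.pi) / big_a
         * math.exp(-math.pi ** 2 / (8.0 * big_a ** 2)))
    return _clip_p(p)


def hodges_ajne_test(angles, criterion: float | None = None,
                     n_exact: int = DEFAULT_N_EXACT) -> CircTestResult:
    """Hodges-Ajne omnibus test of circular uniformity.

    The exact tail probability is used when ``n <= n_exact`` and the
    statistic lies in its validity region ``m < n/3``; otherwise the
    classical large-sample approximation applies.
    """
    a = _as_angles(angles, 4)
    n = a.size
    m = hodges_ajne_m(a)
    if n <= n_exact and m < n / 3.0:
        p = _ajne_p_exact(n, m)
    else:
        p = _ajne_p_approx(n, m)
    return CircTestResult(
        test="hodges_ajne", statistic=float(m), p_value=p,
        summary=circ_summary(a), criterion=criterion,
        significant=None if criterion is None else p < criterion)
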
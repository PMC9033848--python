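"""Clinical validation standards for BP estimators.

Three complementary checks are provided:

* **BHS grading** — cumulative percentages of absolute errors within 5, 10
  and 15 mmHg, graded A/B/C when all three band thresholds of a grade are met
  simultaneously (A: 60/85/95, B: 50/75/90, C: 40/65/85, in percent), D
  otherwise. Band boundaries are inclusive.
* **AAMI check** — pass iff |mean error| <= 5 mmHg, error STD <= 8 mmHg and
  more than 85 subjects.
* **Bland-Altman analysis** — differences (estimate minus reference), their
  bias, limits of agreement bias +/- 1.96 * SD, and the fraction of points
  inside the limits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BHS_THRESHOLDS",
    "BHSResult",
    "AAMIResult",
    "BlandAltman",
    "bhs_cumulative",
    "bhs_grade",
    "bhs_evaluate",
    "aami_check",
    "bland_altman",
]

# grade -> required cumulative % within (5, 10, 15) mmHg
BHS_THRESHOLDS: dict[str, tuple[float, float, float]] = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}

AAMI_ME_LIMIT = 5.0  # mmHg, on |ME|
AAMI_STD_LIMIT = 8.0  # mmHg
AAMI_MIN_SUBJECTS = 85  # strictly more than


@dataclass(frozen=True)
class BHSResult:
    cum5: float
    cum10: float
    cum15: float
    grade: str


@dataclass(frozen=True)
class AAMIResult:
    me: float
    std: float
    subjects: int
    passed: bool
    reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    within_fraction: float


def bhs_cumulative(errors) -> tuple[float, float, float]:
    """Percent of absolute errors within 5 / 10 / 15 mmHg (inclusive bounds)."""
    e = np.abs(np.asarray(errors, dtype=float))
    if e.size == 0:
        raise ValueError("cannot grade an empty error vector")
    return tuple(float(100.0 * np.mean(e <= t)) for t in (5.0, 10.0, 15.0))


def bhs_grade(cum5: float, cum10: float, cum15: float) -> str:
    """Highest grade whose all three band thresholds are met; D otherwise."""
    got = (cum5, cum10, cum15)
    for grade in ("A", "B", "C"):
        if all(g >= t for g, t in zip(got, BHS_THRESHOLDS[grade])):
            return grade
    return "D"


def bhs_evaluate(errors) -> BHSResult:
    cum5, cum10, cum15 = bhs_cumulative(errors)
    return BHSResult(cum5=cum5, cum10=cum10, cum15=cum15, grade=bhs_grade(cum5, cum10, cum15))


def aami_check(me: float, std: float, subjects: int) -> AAMIResult:
    """AAMI acceptance: |ME| <= 5 mmHg, STD <= 8 mmHg, subjects > 85."""
    if subjects < 1:
        raise ValueError("subjects must be at least 1")
    reasons = []
    if abs(me) > AAMI_ME_LIMIT:
        reasons.append(f"|ME| = {abs(me):.2f} mmHg exceeds {AAMI_ME_LIMIT} mmHg")
    if std > AAMI_STD_LIMIT:
        reasons.append(f"STD = {std:.2f} mmHg exceeds {AAMI_STD_LIMIT} mmHg")
    if not subjects > AAMI_MIN_SUBJECTS:
        reasons.append(f"{subjects} subjects, need more than {AAMI_MIN_SUBJECTS}")
    return AAMIResult(me=me, std=std, subjects=subjects, passed=not reasons, reasons=tuple(reasons))


def bland_altman(y, yhat) -> BlandAltman:
    """Agreement between estimates and reference.

    Differences are estimate minus reference; limits of agreement use the
    sample SD (ddof=1), the usual convention for agreement analysis.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or y.size < 2:
        raise ValueError("need equal-length vectors with at least 2 pairs")
    diffs = yhat - y
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    within = float(np.mean((diffs >= lo) & (diffs <= hi)))
    return BlandAltman(bias=bias, loa_low=lo, loa_high=hi, within_fraction=within)
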
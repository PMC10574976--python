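"""The decision stage: normality check, two-sample t-test, thresholded output.

The two partition vectors are compared with a classic pooled-variance
two-sample Student's t-test (two-sided, ``2L - 2`` degrees of freedom).
The brace pressure is called *adequate* (output 1) when the p-value falls
strictly below the decision threshold AND the mean gray level of ROI #1
(the pressure region) exceeds that of ROI #2 (the mirror reference) —
i.e. the difference is both statistically significant and in the
physically expected warm direction.  Everything else is *inadequate*
(output 0); in particular a significantly *colder* pressure region is 0.

A chi-square goodness-of-fit normality check is run on each vector as an
advisory diagnostic: a failure is recorded as a warning but never blocks
the t-test, mirroring how normality is checked once per study rather than
gated per patient.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .imaging_io import ImagePair
from .roi_geometry import RoiPair, extract, map_to_thermal
from .thermal_processing import PartitionVector, partition_vector, to_grayscale_joint

__all__ = ["TestResult", "AssessmentResult", "chi2_normality", "student_t_test",
           "classify", "assess_pair"]

#: Minimum sample size for the chi-square normality check.
MIN_NORMALITY_N = 8


@dataclass(frozen=True)
class TestResult:
    """Outcome of the two-sample comparison between the partition vectors."""

    t_stat: float
    df: int
    p_value: float
    mean1: float
    mean2: float
    normality_p1: float | None = None
    normality_p2: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.df < 1:
            raise ValueError("degrees of freedom must be positive")


@dataclass(frozen=True)
class AssessmentResult:
    """Binary adequacy call plus everything needed to audit it."""

    test: TestResult
    threshold: float
    output: int
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError(f"threshold {self.threshold} outside (0, 1)")
        expected = int(self.test.p_value < self.threshold
                       and self.test.mean1 > self.test.mean2)
        if self.output != expected:
            raise ValueError("output inconsistent with decision rule")


def chi2_normality(v: np.ndarray) -> float:
    """Chi-square goodness-of-fit p-value of *v* against a fitted normal.

    The sample is binned into ``k = max(4, ceil(sqrt(L)))`` equal-probability
    bins of the normal with the sample mean and standard deviation; the
    statistic is referred to a chi-square with ``k - 3`` degrees of freedom
    (two parameters estimated from the data).  Advisory only.

    A zero-variance sample is maximally non-normal here: returns 0 with a
    warning.
    """
    x = np.asarray(v, dtype=float).ravel()
    n = len(x)
    if n < MIN_NORMALITY_N:
        raise ValueError(f"need at least {MIN_NORMALITY_N} values, got {n}")
    mu = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        warnings.warn("zero sample variance: normality check degenerate (p=0)")
        return 0.0
    k = max(4, math.ceil(math.sqrt(n)))
    # interior equal-probability bin edges; outer bins are open-ended
    edges = stats.norm.ppf(np.arange(1, k) / k, loc=mu, scale=sd)
    observed = np.bincount(np.searchsorted(edges, x), minlength=k)
    expected = n / k
    stat = float(np.sum((observed - expected) ** 2) / expected)
    return float(stats.chi2.sf(stat, df=k - 3))


def student_t_test(v1: PartitionVector, v2: PartitionVector,
                   check_normality: bool = True) -> TestResult:
    """Pooled-variance two-sample Student's t-test between two partition vectors.

    Two-sided p-value from the t distribution with ``2L - 2`` degrees of
    freedom; the direction of the difference is handled separately by the
    decision rule, not by a one-sided test.

    Degenerate inputs: two identical constant vectors give ``t = 0, p = 1``;
    zero pooled variance with unequal means gives ``p = 0`` (infinitely
    strong evidence under the model, flagged by an infinite t statistic).
    """
    a = np.asarray(v1.means, dtype=float)
    b = np.asarray(v2.means, dtype=float)
    if len(a) != len(b):
        raise ValueError("partition vectors must have equal length")
    L = len(a)
    if L < 2:
        raise ValueError("need at least 2 partitions per ROI")
    df = 2 * L - 2
    m1, m2 = float(np.mean(a)), float(np.mean(b))
    s2_pooled = (np.sum((a - m1) ** 2) + np.sum((b - m2) ** 2)) / df
    se = math.sqrt(s2_pooled * 2.0 / L)
    if se == 0.0:
        t = 0.0 if m1 == m2 else math.copysign(math.inf, m1 - m2)
        p = 1.0 if m1 == m2 else 0.0
    else:
        t = (m1 - m2) / se
        p = 2.0 * float(stats.t.sf(abs(t), df=df))
    np1 = np2 = None
    if check_normality and L >= MIN_NORMALITY_N:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            np1 = chi2_normality(a)
            np2 = chi2_normality(b)
    return TestResult(t_stat=t, df=df, p_value=min(p, 1.0), mean1=m1, mean2=m2,
                      normality_p1=np1, normality_p2=np2)


def classify(test: TestResult, threshold: float = 0.05,
             normality_alpha: float = 0.05) -> AssessmentResult:
    """Apply the decision rule: 1 iff ``p < threshold`` and ``mean1 > mean2``.

    The comparison with the threshold is strict (``p == threshold`` is
    inadequate).  Normality-check failures are reported as warnings only.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold {threshold} outside (0, 1)")
    output = int(test.p_value < threshold and test.mean1 > test.mean2)
    warns = []
    for label, p_norm in (("ROI #1", test.normality_p1), ("ROI #2", test.normality_p2)):
        if p_norm is not None and p_norm < normality_alpha:
            warns.append(
                f"normality check failed for {label} partition vector "
                f"(chi-square p = {p_norm:.4g}); t-test run regardless"
            )
    if test.p_value < threshold and test.mean1 <= test.mean2:
        warns.append(
            "significant difference but pressure region is not warmer than "
            "reference; classified inadequate"
        )
    return AssessmentResult(test=test, threshold=threshold, output=output,
                            warnings=tuple(warns))


def assess_pair(pair: ImagePair, rois: RoiPair, n_rows: int = 4, n_cols: int = 4,
                threshold: float = 0.05) -> AssessmentResult:
    """End-to-end adequacy assessment of one ROI pair.

    Composition: map both ROIs onto the thermal grid, extract the
    temperature sub-grids, convert them jointly to grayscale, partition
    into ``n_rows x n_cols`` subregions, average, t-test, threshold.
    Deterministic.
    """
    t1 = map_to_thermal(rois.roi1, pair)
    t2 = map_to_thermal(rois.roi2, pair)
    g1, g2 = to_grayscale_joint(extract(pair.thermal, t1), extract(pair.thermal, t2))
    v1 = partition_vector(g1, n_rows, n_cols)
    v2 = partition_vector(g2, n_rows, n_cols)
    return classify(student_t_test(v1, v2), threshold)
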
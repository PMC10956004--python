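"""Cohort-level inference and test–retest reliability.

Small-cohort statistics for MV measurements: standard error of the mean,
one-sample two-tailed t-tests with Cohen's d, intra-subject repeatability
of cumulative prices, the minimum detectable change (MDC), and responder
classification against a symmetric threshold.

The MDC is the smallest change between two measurements not attributable to
chance at a given confidence: z · √2 · SD, where SD is the intra-subject
standard deviation (as % of each subject's mean) and the √2 accounts for
the difference of two noisy measurements.  Sample SDs use the n−1
denominator throughout, as is standard for small-N human studies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatsError",
    "CohortSummary",
    "ReliabilityResult",
    "ResponderLabel",
    "sem",
    "one_sample_t",
    "repeatability",
    "mdc",
    "reliability_analysis",
    "classify_responders",
]


class StatsError(ValueError):
    """A cohort statistic is undefined for this input."""


@dataclass(frozen=True)
class CohortSummary:
    """One-sample test of a cohort of MV percentages against zero."""

    n: int
    mean_mv: float       # percent
    sd_mv: float         # percent, n-1 denominator
    sem_mv: float        # percent
    t_stat: float
    df: int
    p_two_tailed: float
    cohens_d: float


@dataclass(frozen=True)
class ReliabilityResult:
    """Intra-subject variability of repeated cumulative prices, and MDC."""

    intra_subject_sd_pct: float
    mdc_pct: float | None = None
    confidence: float = 0.95
    n_subjects: int = 0


@dataclass(frozen=True)
class ResponderLabel:
    subject_id: str
    mv_percent: float
    label: str  # "positive" | "negative" | "indeterminate"


def sem(sd: float, n: int) -> float:
    """Standard error of the mean, SD/√n."""
    if n < 1:
        raise StatsError(f"need n >= 1, got {n}")
    if sd < 0:
        raise StatsError("sd must be non-negative")
    return sd / math.sqrt(n)


def one_sample_t(values: Sequence[float]) -> CohortSummary:
    """Two-tailed one-sample t-test of the cohort mean against zero.

    Cohen's d is the uncorrected one-sample form mean/SD.
    """
    arr = np.asarray(values, dtype=float)
    n = len(arr)
    if n < 2:
        raise StatsError(f"need at least 2 values, got {n}")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if sd == 0:
        raise StatsError("zero standard deviation: t-test is degenerate")
    se = sd / math.sqrt(n)
    t = mean / se
    df = n - 1
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return CohortSummary(
        n=n,
        mean_mv=mean,
        sd_mv=sd,
        sem_mv=se,
        t_stat=t,
        df=df,
        p_two_tailed=p,
        cohens_d=mean / sd,
    )


def repeatability(
    cumulative_prices_by_subject: Mapping[str, Sequence[float]],
    confidence: float = 0.95,
) -> ReliabilityResult:
    """Average intra-subject SD of repeated cumulative prices, as a percent.

    Per subject: sample SD of the repeats divided by the subject's mean,
    ×100; averaged across subjects.  Subjects with fewer than 2 repeats are
    excluded with a warning.
    """
    pct_sds = []
    for subject, repeats in cumulative_prices_by_subject.items():
        arr = np.asarray(repeats, dtype=float)
        if len(arr) < 2:
            warnings.warn(
                f"subject {subject!r} has {len(arr)} repeat(s); excluded from repeatability",
                stacklevel=2,
            )
            continue
        mean = float(arr.mean())
        if mean == 0:
            raise StatsError(f"subject {subject!r} has zero mean cumulative price")
        pct_sds.append(float(arr.std(ddof=1)) / mean * 100.0)
    if not pct_sds:
        raise StatsError("no subject has >= 2 repeats; repeatability undefined")
    return ReliabilityResult(
        intra_subject_sd_pct=float(np.mean(pct_sds)),
        mdc_pct=None,
        confidence=confidence,
        n_subjects=len(pct_sds),
    )


def mdc(intra_subject_sd_pct: float, confidence: float = 0.95) -> float:
    """Minimum detectable change: z(confidence, two-sided) · √2 · SD."""
    if intra_subject_sd_pct < 0:
        raise StatsError("sd must be non-negative")
    if not 0 < confidence < 1:
        raise StatsError(f"confidence must be in (0, 1), got {confidence}")
    z = float(sps.norm.ppf(0.5 + confidence / 2.0))
    return z * math.sqrt(2.0) * intra_subject_sd_pct


def reliability_analysis(
    cumulative_prices_by_subject: Mapping[str, Sequence[float]],
    confidence: float = 0.95,
) -> ReliabilityResult:
    """Repeatability plus the MDC it implies, in one record."""
    rel = repeatability(cumulative_prices_by_subject, confidence)
    return ReliabilityResult(
        intra_subject_sd_pct=rel.intra_subject_sd_pct,
        mdc_pct=mdc(rel.intra_subject_sd_pct, confidence),
        confidence=confidence,
        n_subjects=rel.n_subjects,
    )


def classify_responders(
    mv_by_subject: Mapping[str, float], threshold_pct: float
) -> list[ResponderLabel]:
    """Label each subject by whether their MV clears ±threshold (strict)."""
    if threshold_pct < 0:
        raise StatsError("threshold must be non-negative")
    labels = []
    for subject, mv in mv_by_subject.items():
        if mv > threshold_pct:
            label = "positive"
        elif mv < -threshold_pct:
            label = "negative"
        else:
            label = "indeterminate"
        labels.append(ResponderLabel(subject_id=subject, mv_percent=mv, label=label))
    return labels
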
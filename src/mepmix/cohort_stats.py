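"""Confirmatory statistics around the subgrouping.

Paired t-tests of post-interventional MEP values against baseline, per
post block and subgroup.  Normalized values are tested against 100%; with
per-subject baselines this is equivalent to testing raw block means
against baseline.  No multiplicity correction is applied by default
(mirroring uncorrected per-block reporting); a Bonferroni option exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import POST_BLOCKS
from .preprocess import SubjectTimeCourse

__all__ = ["TestResult", "paired_t", "posthoc_vs_baseline"]

logger = logging.getLogger(__name__)


class DegenerateDataError(ValueError):
    """Differences have zero variance; the t statistic is undefined."""


@dataclass(frozen=True)
class TestResult:
    """Classical t-test outcome: statistic, degrees of freedom, two-sided p."""

    statistic: float
    df: int
    p: float


def paired_t(x, y) -> TestResult:
    """Paired Student t-test of x against y (two-sided).

    The statistic is computed on the differences x - y with df = n - 1.
    Raises on length mismatch, n < 2, or zero-variance differences.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"paired samples must have equal length, got {x.size} and {y.size}")
    if x.size < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("differences have zero variance; t statistic undefined")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return TestResult(statistic=float(t), df=n - 1, p=float(p))


def posthoc_vs_baseline(
    timecourses: list[SubjectTimeCourse], bonferroni: bool = False
) -> dict[str, TestResult]:
    """Paired t of each post block's normalized value against baseline (100%).

    One test per post block P1..P6 across the subjects of one subgroup.
    With ``bonferroni`` the p-values are multiplied by the number of blocks
    (capped at 1); by default they are reported uncorrected, with a log
    note that per-block differences do not pass alpha correction.
    """
    if len(timecourses) < 2:
        raise ValueError("post-hoc tests need a subgroup of at least 2 subjects")
    out: dict[str, TestResult] = {}
    for block in POST_BLOCKS:
        vals = np.array([tc.post_pct[block] for tc in timecourses])
        res = paired_t(vals, np.full_like(vals, 100.0))
        if bonferroni:
            res = TestResult(res.statistic, res.df, min(1.0, res.p * len(POST_BLOCKS)))
        out[block] = res
    if not bonferroni:
        logger.info("per-block p-values reported uncorrected; differences do not pass alpha correction")
    return out
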
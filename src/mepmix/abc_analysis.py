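"""Computed ABC analysis of LTD responses.

An item-categorization technique in the Pareto tradition: positive
contributions are sorted descending and split into set "A" (the important
few), set "B" (intermediate) and set "C" (the trivial many) from the
cumulative-contribution curve.  Here the contribution is the LTD response,
the desired post-stimulation MEP reduction computed as 100 - MEP[%] with
facilitation (values above 100%) counted as absent response (0).  Subjects
in A or B are the ABC-selected responders; the route is independent of the
Gaussian-mixture classification and serves as its cross-check.

Set limits are computed from the piecewise-linear curve through the points
(i/n, cumulative share of the i largest responses): the A/B limit is the
curve point closest to the ideal point (0, 1); the B/C limit is the last
point whose segment slope exceeds 1 (the break-even where an item still
contributes more than the uniform share).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import SubjectTimeCourse

__all__ = [
    "LTDResponse",
    "ABCPartition",
    "ltd_transform",
    "abc_curve",
    "abc_partition",
    "abc_responders",
]


@dataclass(frozen=True)
class LTDResponse:
    """One subject's LTD response: max(0, 100 - overall MEP %)."""

    subject_id: str
    ltd_value: float

    def __post_init__(self):
        if self.ltd_value < 0:
            raise ValueError("ltd_value must be >= 0")


@dataclass(frozen=True)
class ABCPartition:
    """Disjoint A/B/C subject sets and the cumulative-contribution curve."""

    set_A: frozenset[str]
    set_B: frozenset[str]
    set_C: frozenset[str]
    curve: np.ndarray  # (n+1, 2) points (effort fraction, yield fraction)
    a_limit_index: int  # number of subjects in A
    b_limit_index: int  # number of subjects in A u B

    def membership(self) -> dict[str, str]:
        out = {}
        for name, members in (("A", self.set_A), ("B", self.set_B), ("C", self.set_C)):
            out.update({sid: name for sid in members})
        return out


def ltd_transform(timecourses: list[SubjectTimeCourse]) -> list[LTDResponse]:
    """Convert overall MEP changes to LTD responses.

    ltd = max(0, 100 - overall_change_pct): only the desired depression
    counts; any facilitation is an absent response.
    """
    out = []
    for tc in timecourses:
        if not np.isfinite(tc.overall_change_pct):
            raise ValueError(f"subject {tc.subject_id}: non-finite overall change")
        out.append(LTDResponse(tc.subject_id, max(0.0, 100.0 - tc.overall_change_pct)))
    return out


def _sorted_values(ltd: list[LTDResponse]) -> list[LTDResponse]:
    # descending by value; ties broken by subject_id for determinism
    return sorted(ltd, key=lambda r: (-r.ltd_value, r.subject_id))


def abc_curve(ltd: list[LTDResponse]) -> np.ndarray:
    """Cumulative-contribution curve: (i/n, share of total from top-i items).

    Starts at (0, 0) and ends at (1, 1); requires at least one positive
    value (an all-zero cohort has no defined yield).
    """
    values = np.array([r.ltd_value for r in _sorted_values(ltd)])
    total = values.sum()
    if not (total > 0):
        raise ValueError("ABC curve undefined: all LTD responses are zero")
    n = values.size
    effort = np.arange(0, n + 1) / n
    yield_frac = np.concatenate([[0.0], np.cumsum(values) / total])
    return np.column_stack([effort, yield_frac])


def abc_partition(ltd: list[LTDResponse]) -> ABCPartition:
    """Split subjects into the A/B/C sets from the contribution curve.

    A-limit: the curve index whose point minimizes the Euclidean distance
    to the ideal point (0, 1).  B-limit: the last index whose segment slope
    exceeds 1; when that falls at or before the A-limit, B is empty.
    Zero-valued subjects can never be profitable and are forced into C
    regardless of the limits.
    """
    ranked = _sorted_values(ltd)
    curve = abc_curve(ltd)
    n = len(ranked)
    values = np.array([r.ltd_value for r in ranked])

    dist2 = curve[:, 0] ** 2 + (1.0 - curve[:, 1]) ** 2
    a_limit = int(np.argmin(dist2))

    slopes = np.diff(curve[:, 1]) / np.diff(curve[:, 0])  # slope of segment ending at i+1
    above = np.nonzero(slopes > 1.0)[0]
    b_limit = int(above[-1] + 1) if above.size else 0
    if b_limit <= a_limit:
        b_limit = a_limit  # empty B

    positive = values > 0
    set_a = frozenset(r.subject_id for i, r in enumerate(ranked) if i < a_limit and positive[i])
    set_b = frozenset(
        r.subject_id for i, r in enumerate(ranked) if a_limit <= i < b_limit and positive[i]
    )
    set_c = frozenset(r.subject_id for r in ranked) - set_a - set_b
    return ABCPartition(
        set_A=set_a, set_B=set_b, set_C=set_c,
        curve=curve, a_limit_index=len(set_a), b_limit_index=len(set_a) + len(set_b),
    )


def abc_responders(partition: ABCPartition) -> frozenset[str]:
    """Subjects whose contribution is important or appropriate: A u B."""
    return partition.set_A | partition.set_B


def partition_to_frame(ltd: list[LTDResponse], partition: ABCPartition) -> pd.DataFrame:
    member = partition.membership()
    rows = [
        {"subject_id": r.subject_id, "ltd_value": r.ltd_value, "abc_set": member[r.subject_id]}
        for r in _sorted_values(ltd)
    ]
    return pd.DataFrame(rows)
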
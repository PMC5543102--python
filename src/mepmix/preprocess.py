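"""Trial-level MEP preprocessing: exclusion, block averaging, normalization.

Reduces a long-format trial table to one overall-MEP-change value per
subject: drop contaminated trials and the first trial of every block,
average the survivors per block, pool the two baseline blocks, express the
six post-interventional block means as percent of baseline, and average
those six values.  Values above 100% indicate MEP facilitation, below 100%
MEP depression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .cohort import BASELINE_BLOCKS, BLOCKS, POST_BLOCKS

__all__ = [
    "DataError",
    "SubjectTimeCourse",
    "filter_trials",
    "summarize_subject",
    "summarize_cohort",
    "timecourses_to_frame",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject_id", "block", "trial", "amplitude_mv", "prestim_flag")


class DataError(ValueError):
    """The trial table cannot be reduced (empty block, missing data)."""


@dataclass(frozen=True)
class SubjectTimeCourse:
    """Per-subject summary: pooled baseline and normalized post blocks."""

    subject_id: str
    baseline_mv: float
    post_pct: dict[str, float]  # P1..P6 -> % of baseline
    overall_change_pct: float


def _check_columns(trials: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise DataError(f"trial table lacks required columns: {missing}")


def filter_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Apply the two exclusion rules: contaminated trials and first trials.

    Every row with ``prestim_flag`` set and every row with ``trial == 1``
    is removed; all other rows pass unchanged, order preserved.  A block
    left with a single trial is retained with a warning; a block left with
    no trials raises :class:`DataError`.
    """
    _check_columns(trials)
    if len(trials) == 0:
        raise DataError("trial table is empty")
    keep = (~trials["prestim_flag"].astype(bool)) & (trials["trial"] != 1)
    out = trials.loc[keep]

    survivors = out.groupby(["subject_id", "block"], sort=False).size()
    all_blocks = trials.groupby(["subject_id", "block"], sort=False).size()
    dead = all_blocks.index.difference(survivors.index)
    if len(dead) > 0:
        pairs = ", ".join(f"{s}/{b}" for s, b in dead)
        raise DataError(f"no trials survive exclusion in block(s): {pairs}")
    thin = survivors[survivors < 2]
    for (subject, block), count in thin.items():
        logger.warning(
            "subject %s block %s retains only %d trial(s) after exclusion", subject, block, count
        )
    return out


def summarize_subject(trials: pd.DataFrame, subject_id: str) -> SubjectTimeCourse:
    """Condense one subject's (already filtered) trials to a time course.

    Block means are plain arithmetic means of surviving trials; the pooled
    baseline is the mean of the B1 and B2 block means; each post block is
    expressed as percent of that baseline; the overall change is the mean
    of the six post-block percentages.
    """
    _check_columns(trials)
    sub = trials[trials["subject_id"] == subject_id]
    if len(sub) == 0:
        raise DataError(f"subject {subject_id}: no trials")
    block_means = sub.groupby("block")["amplitude_mv"].mean()
    for block in BLOCKS:
        if block not in block_means.index:
            raise DataError(f"subject {subject_id}: missing block {block}")
    baseline = float(sum(block_means[b] for b in BASELINE_BLOCKS) / len(BASELINE_BLOCKS))
    post_pct = {b: float(100.0 * block_means[b] / baseline) for b in POST_BLOCKS}
    overall = float(sum(post_pct.values()) / len(post_pct))
    return SubjectTimeCourse(
        subject_id=subject_id, baseline_mv=baseline, post_pct=post_pct, overall_change_pct=overall
    )


def summarize_cohort(trials: pd.DataFrame, filtered: bool = False) -> list[SubjectTimeCourse]:
    """Filter (unless already done) and summarize every subject in the table.

    Vectorized equivalent of :func:`summarize_subject` per subject;
    subjects are returned in first-appearance order of the input table.
    """
    if not filtered:
        trials = filter_trials(trials)
    _check_columns(trials)
    block_means = (
        trials.groupby(["subject_id", "block"], sort=False)["amplitude_mv"].mean().unstack()
    )
    order = trials["subject_id"].drop_duplicates().tolist()
    block_means = block_means.reindex(order)
    for block in BLOCKS:
        if block not in block_means.columns or block_means[block].isna().any():
            bad = (
                block_means.index[block_means[block].isna()].tolist()
                if block in block_means.columns
                else order
            )
            raise DataError(f"subject {bad[0]}: missing block {block}")
    baseline = block_means[list(BASELINE_BLOCKS)].mean(axis=1)
    post_pct = 100.0 * block_means[list(POST_BLOCKS)].div(baseline, axis=0)
    overall = post_pct.mean(axis=1)
    return [
        SubjectTimeCourse(
            subject_id=str(sid),
            baseline_mv=float(baseline[sid]),
            post_pct={b: float(post_pct.at[sid, b]) for b in POST_BLOCKS},
            overall_change_pct=float(overall[sid]),
        )
        for sid in order
    ]


def timecourses_to_frame(timecourses: list[SubjectTimeCourse]) -> pd.DataFrame:
    """Tabulate time courses as subject_id, baseline_mv, P1..P6, overall_change_pct."""
    rows = []
    for tc in timecourses:
        row = {"subject_id": tc.subject_id, "baseline_mv": tc.baseline_mv}
        row.update({b: tc.post_pct[b] for b in POST_BLOCKS})
        row["overall_change_pct"] = tc.overall_change_pct
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_timecourses(frame: pd.DataFrame) -> list[SubjectTimeCourse]:
    out = []
    for _, row in frame.iterrows():
        post = {b: float(row[b]) for b in POST_BLOCKS}
        out.append(
            SubjectTimeCourse(
                subject_id=str(row["subject_id"]),
                baseline_mv=float(row["baseline_mv"]),
                post_pct=post,
                overall_change_pct=float(row["overall_change_pct"]),
            )
        )
    return out
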
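"""Bayes-posterior subgroup assignment from a fitted mixture.

Given the mixture p(x) = sum_i w_i N(x | m_i, s_i), the posterior
probability that an observation x belongs to component i is

    P(i | x) = w_i N(x | m_i, s_i) / sum_j w_j N(x | m_j, s_j),

and the decision limit between adjacent components is the x where their
weighted densities intersect — the point where the arg-max posterior
switches.  For the tri-modal model of overall MEP change the three
ascending-mean components map to the clinical labels responder (MEP
depression), non-responder (no change) and paradox-responder (MEP
facilitation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import logsumexp

from .mixture import MixtureModel
from .preprocess import SubjectTimeCourse

__all__ = [
    "BoundaryError",
    "SubgroupBoundaries",
    "SubgroupAssignment",
    "TRIMODAL_LABELS",
    "posterior",
    "decision_boundaries",
    "classify_value",
    "classify_cohort",
    "assignments_to_frame",
]

TRIMODAL_LABELS = ("responder", "non-responder", "paradox-responder")


class BoundaryError(RuntimeError):
    """No density intersection exists between a pair of adjacent components."""


@dataclass(frozen=True)
class SubgroupBoundaries:
    """Ordered decision limits, one between each adjacent component pair."""

    limits: tuple[float, ...]


@dataclass(frozen=True)
class SubgroupAssignment:
    """One subject's posterior vector and arg-max subgroup label."""

    subject_id: str
    overall_change_pct: float
    posteriors: tuple[float, ...]
    label: str


def posterior(model: MixtureModel, x) -> np.ndarray:
    """Posterior component-membership probabilities at x (log-space safe).

    Returns shape (M,) for scalar x, else (len(x), M); rows sum to 1.
    """
    scalar = np.ndim(x) == 0
    xa = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(xa)):
        raise ValueError("posterior requires finite x")
    log_dens = model.log_component_densities(xa)
    post = np.exp(log_dens - logsumexp(log_dens, axis=1)[:, None])
    return post[0] if scalar else post


def _log_density_gap(model: MixtureModel, k: int, x: float) -> float:
    """log(w_k N_k(x)) - log(w_{k+1} N_{k+1}(x))."""
    a, b = model.components[k], model.components[k + 1]
    return (np.log(a.w) + stats.norm.logpdf(x, a.m, a.s)
            - np.log(b.w) - stats.norm.logpdf(x, b.m, b.s))


def decision_boundaries(model: MixtureModel) -> SubgroupBoundaries:
    """Locate the weighted-density intersection between each adjacent pair.

    The root of w_k N_k(x) = w_{k+1} N_{k+1}(x) is bracketed on the open
    interval between the two component means; restricting to that interval
    ignores spurious second crossings far out in the tails, so exactly
    M - 1 limits are produced.  Raises :class:`BoundaryError` when the gap
    does not change sign between the means (extreme weight imbalance or
    coincident means).
    """
    if model.M < 2:
        raise ValueError("decision boundaries require at least 2 components")
    limits = []
    for k in range(model.M - 1):
        lo, hi = model.components[k].m, model.components[k + 1].m
        if not (hi > lo):
            raise BoundaryError(f"components {k + 1} and {k + 2} have coincident means")
        eps = 1e-9 * (hi - lo)
        f_lo, f_hi = _log_density_gap(model, k, lo + eps), _log_density_gap(model, k, hi - eps)
        if not (f_lo > 0 > f_hi):
            raise BoundaryError(
                f"no weighted-density intersection between components {k + 1} and {k + 2} "
                f"on ({lo:.4g}, {hi:.4g}); gap signs {np.sign(f_lo)}/{np.sign(f_hi)}"
            )
        root = brentq(lambda x: _log_density_gap(model, k, x), lo + eps, hi - eps,
                      xtol=1e-12, rtol=8.9e-16)
        limits.append(float(root))
    return SubgroupBoundaries(limits=tuple(limits))


def _labels(model: MixtureModel) -> tuple[str, ...]:
    if model.M == 3:
        return TRIMODAL_LABELS
    return tuple(f"component-{k}" for k in range(1, model.M + 1))


def classify_value(model: MixtureModel, x: float) -> int:
    """0-based component index of x under the Bayes decision limits.

    Membership follows the interval between adjacent decision limits (the
    clinical rule: a subject at or below the lower limit is a responder no
    matter how extreme the value).  Between the outer component means this
    coincides with the arg-max posterior; far out in the tails the widest
    component's posterior takes over, and the decision-limit rule — the
    one the printed limits define — wins.  A value exactly on a limit goes
    to the lower-mean component.
    """
    if model.M == 1:
        return 0
    limits = np.asarray(decision_boundaries(model).limits)
    return int(np.searchsorted(limits, float(x), side="left"))


def classify_cohort(
    model: MixtureModel, timecourses: list[SubjectTimeCourse]
) -> list[SubgroupAssignment]:
    """Label every subject by interval membership between the decision limits."""
    names = _labels(model)
    limits = (
        np.asarray(decision_boundaries(model).limits) if model.M >= 2 else np.empty(0)
    )
    out = []
    for tc in timecourses:
        post = posterior(model, tc.overall_change_pct)
        k = int(np.searchsorted(limits, tc.overall_change_pct, side="left"))
        out.append(
            SubgroupAssignment(
                subject_id=tc.subject_id,
                overall_change_pct=tc.overall_change_pct,
                posteriors=tuple(float(p) for p in post),
                label=names[k],
            )
        )
    return out


def assignments_to_frame(assignments: list[SubgroupAssignment]) -> pd.DataFrame:
    """Tabulate as subject_id, overall_change_pct, p_comp1..p_compM, label."""
    rows = []
    for a in assignments:
        row = {"subject_id": a.subject_id, "overall_change_pct": a.overall_change_pct}
        row.update({f"p_comp{i + 1}": p for i, p in enumerate(a.posteriors)})
        row["label"] = a.label
        rows.append(row)
    return pd.DataFrame(rows)
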
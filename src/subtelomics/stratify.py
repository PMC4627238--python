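"""Marker-based cohort dichotomisation and categorical association tests.

The cohort is split into marker-low and marker-high groups at an
ROC-derived cutoff: over the distinct observed marker-expression values,
the cutoff maximising Youden's index (sensitivity + specificity - 1)
against a binary outcome (vital status by default) is chosen; samples
with marker expression <= cutoff are labelled "low".  When the AUC is
below 0.5 the score orientation is flipped before the search and the
flip recorded, so the cutoff always separates in the informative
direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .io import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RocCurve:
    thresholds: np.ndarray  # distinct observed scores, ascending
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


@dataclass
class GroupAssignment:
    """Per-sample low/high labels plus the cutoff and AUC that produced them.

    Invariant: label is "low" iff marker score <= cutoff.
    """

    labels: pd.Series  # sample_id -> "low"/"high"
    cutoff: float
    auc: float
    outcome: str = "event"
    flipped: bool = False  # True when orientation was reversed (AUC < 0.5)
    degenerate: bool = False  # True when all scores were equal
    scores: pd.Series = field(default=None, repr=False)

    @property
    def n_low(self) -> int:
        return int((self.labels == "low").sum())

    @property
    def n_high(self) -> int:
        return int((self.labels == "high").sum())


def _check_binary(outcome: np.ndarray) -> None:
    classes = np.unique(outcome)
    if not np.isin(classes, (0, 1)).all():
        raise ValidationError(f"outcome must be binary 0/1, got classes {classes}")
    if classes.size < 2:
        raise ValidationError("outcome has a single class; ROC undefined")


def roc_curve(scores, outcome) -> RocCurve:
    """ROC over the distinct observed scores, positive rule ``score > t``.

    The AUC is the probability that a random positive outscores a random
    negative, ties counting 1/2 (trapezoidal rule / Mann-Whitney).
    """
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome)
    _check_binary(outcome)
    thresholds = np.unique(scores)
    pos, neg = scores[outcome == 1], scores[outcome == 0]
    sens = np.array([(pos > t).mean() for t in thresholds])
    spec = np.array([(neg <= t).mean() for t in thresholds])
    auc = float(roc_auc_score(outcome, scores))
    return RocCurve(thresholds=thresholds, sensitivity=sens, specificity=spec, auc=auc)


def find_cutoff(scores: pd.Series, outcome, outcome_name: str = "event") -> GroupAssignment:
    """Dichotomise on the Youden-optimal cutoff; ``score <= cutoff`` is "low".

    Ties among equally optimal cutoffs break toward the smallest
    threshold.  All-equal scores give a degenerate single-group
    assignment, flagged rather than rejected.
    """
    if not isinstance(scores, pd.Series):
        scores = pd.Series(np.asarray(scores, dtype=float))
    outcome = np.asarray(outcome)
    _check_binary(outcome)
    vals = scores.to_numpy(dtype=float)

    thresholds = np.unique(vals)
    if thresholds.size == 1:
        logger.warning("all marker scores equal; degenerate single-group assignment")
        labels = pd.Series("low", index=scores.index, name="group")
        return GroupAssignment(
            labels=labels, cutoff=float(thresholds[0]), auc=0.5,
            outcome=outcome_name, degenerate=True, scores=scores,
        )

    auc = float(roc_auc_score(outcome, vals))
    flipped = auc < 0.5
    work = -vals if flipped else vals
    work_thresholds = np.unique(work)
    pos, neg = work[outcome == 1], work[outcome == 0]
    youden = np.array(
        [(pos > t).mean() + (neg <= t).mean() - 1.0 for t in work_thresholds]
    )
    best = work_thresholds[np.flatnonzero(youden == youden.max())]
    # smallest threshold on the original scale
    cutoff = float(-best.max()) if flipped else float(best.min())
    if flipped:
        logger.info("AUC %.4f < 0.5; score orientation flipped before cutoff search", auc)

    labels = pd.Series(
        np.where(vals <= cutoff, "low", "high"), index=scores.index, name="group"
    )
    return GroupAssignment(
        labels=labels, cutoff=cutoff, auc=auc,
        outcome=outcome_name, flipped=flipped, scores=scores,
    )


@dataclass
class AssociationResult:
    table: pd.DataFrame  # contingency counts
    statistic: float
    df: int
    p_value: float


def chi_square_association(labels, covariate) -> AssociationResult:
    """Pearson chi-square (no continuity correction) between two categoricals."""
    labels = pd.Series(labels)
    covariate = pd.Series(covariate)
    table = pd.crosstab(labels.to_numpy(), covariate.to_numpy())
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError(
            f"need >= 2 categories on each margin, got table shape {table.shape}"
        )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("zero row/column margin in contingency table")
    stat, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return AssociationResult(table=table, statistic=float(stat), df=int(dof), p_value=float(p))


class IhcScore(str, Enum):
    """Immunohistochemistry category from percent positively stained cells."""

    negative = "negative"
    weak_positive = "weak_positive"
    strong_positive = "strong_positive"


def classify_ihc_score(percent_positive: float) -> IhcScore:
    """Classify percent-positive staining: <5 negative, 5-25 weak, >25 strong.

    The 25% boundary belongs to the weak-positive class.
    """
    if not 0 <= percent_positive <= 100:
        raise ValidationError(f"percent positive {percent_positive} outside [0,100]")
    if percent_positive < 5:
        return IhcScore.negative
    if percent_positive <= 25:
        return IhcScore.weak_positive
    return IhcScore.strong_positive
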
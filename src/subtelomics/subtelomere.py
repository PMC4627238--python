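"""Chromosome-end (subtelomeric) methylation analysis.

A probe is subtelomeric when it lies within a fixed window (default 4 Mb)
of either end of its chromosome, in 1-based closed coordinates:
``min(position, L - position + 1) <= window_bp``.  Each sample is then
summarised by the mean beta value over subtelomeric probes normalised to
its mean over all probes, and the two marker groups are compared on those
per-sample ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ChromosomeSizes, OmicsMatrix, ProbeAnnotation, ValidationError

logger = logging.getLogger(__name__)


def select_subtelomeric_probes(
    annotation: ProbeAnnotation,
    sizes: ChromosomeSizes,
    window_bp: int = 4_000_000,
) -> set[str]:
    """Probes within ``window_bp`` of either chromosome end (inclusive)."""
    if window_bp <= 0:
        raise ValidationError("window_bp must be > 0")
    t = annotation.table
    annotation.validate_against(sizes)
    lengths = t["chromosome"].map(dict(sizes.items())).to_numpy()
    pos = t["position"].to_numpy()
    dist_to_end = np.minimum(pos, lengths - pos + 1)
    return set(t.loc[dist_to_end <= window_bp, "probe_id"])


def subtelomeric_statistic(meth: OmicsMatrix, subtel_probes: set[str]) -> pd.DataFrame:
    """Per-sample subtelomeric summary.

    Returns a DataFrame indexed by sample_id with columns
    ``mean_subtelomeric``, ``mean_overall``, ``ratio`` and ``usable``
    (False when a sample has no non-missing subtelomeric value; such
    samples are excluded from group comparison).
    """
    if not subtel_probes:
        raise ValidationError("empty subtelomeric probe set")
    missing = subtel_probes - set(meth.probe_ids)
    if missing:
        raise ValidationError(
            f"{len(missing)} subtelomeric probes absent from the matrix "
            f"(e.g. {sorted(missing)[0]!r})"
        )
    sub = meth.values.loc[sorted(subtel_probes)]
    mean_sub = sub.mean(axis=0, skipna=True)
    mean_all = meth.values.mean(axis=0, skipna=True)
    usable = sub.notna().any(axis=0) & (mean_all > 0)
    out = pd.DataFrame(
        {
            "mean_subtelomeric": mean_sub,
            "mean_overall": mean_all,
            "ratio": mean_sub / mean_all,
            "usable": usable,
        }
    )
    out.index.name = "sample_id"
    n_flagged = int((~usable).sum())
    if n_flagged:
        logger.info("flagged %d samples without usable subtelomeric values", n_flagged)
    return out


@dataclass
class GroupComparison:
    """Two-group comparison of per-sample ratio statistics (low minus high)."""

    mean_low: float
    mean_high: float
    difference: float
    statistic: float
    p_value: float
    n_low: int
    n_high: int
    method: str


def compare_groups(
    stats_table: pd.DataFrame,
    labels: pd.Series,
    method: str = "t",
    column: str = "ratio",
) -> GroupComparison:
    """Two-sided comparison of the per-sample statistic between groups.

    ``method`` is ``"t"`` (Student's pooled-variance t, default) or
    ``"ranksum"`` (Wilcoxon rank-sum).  Effect direction is low minus high.
    """
    usable = stats_table.loc[stats_table["usable"]] if "usable" in stats_table else stats_table
    labels = labels.loc[labels.index.intersection(usable.index)]
    low = usable.loc[labels.index[labels == "low"], column].to_numpy()
    high = usable.loc[labels.index[labels == "high"], column].to_numpy()
    if len(low) < 2 or len(high) < 2:
        raise ValidationError(
            f"need >= 2 samples per group, got {len(low)} low / {len(high)} high"
        )
    if method == "t":
        res = stats.ttest_ind(low, high, equal_var=True)
    elif method == "ranksum":
        res = stats.ranksums(low, high)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return GroupComparison(
        mean_low=float(np.mean(low)),
        mean_high=float(np.mean(high)),
        difference=float(np.mean(low) - np.mean(high)),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_low=len(low),
        n_high=len(high),
        method=method,
    )


def pooled_probe_comparison(
    meth: OmicsMatrix, subtel_probes: set[str], labels: pd.Series, method: str = "t"
) -> GroupComparison:
    """Probe-level pooled variant: compare all subtelomeric beta values at once.

    Pools every (probe, sample) beta value per group, ignoring sample
    structure.  Provided for comparability with probe-pooling analyses;
    the per-sample ratio comparison is the default because it respects
    sample independence.
    """
    sub = meth.values.loc[sorted(subtel_probes)]
    low = sub.loc[:, labels.index[labels == "low"]].to_numpy().ravel()
    high = sub.loc[:, labels.index[labels == "high"]].to_numpy().ravel()
    low, high = low[~np.isnan(low)], high[~np.isnan(high)]
    if method == "t":
        res = stats.ttest_ind(low, high, equal_var=True)
    elif method == "ranksum":
        res = stats.ranksums(low, high)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return GroupComparison(
        mean_low=float(np.mean(low)),
        mean_high=float(np.mean(high)),
        difference=float(np.mean(low) - np.mean(high)),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_low=len(low),
        n_high=len(high),
        method=f"pooled-{method}",
    )
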
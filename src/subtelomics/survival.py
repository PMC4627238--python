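"""Product-limit survival curves and the two-group log-rank test.

Curves come from the Kaplan-Meier estimator (via lifelines); the
log-rank test is tabulated in-package because the result type reports
per-group observed and expected event counts alongside the chi-square
statistic.  Ties follow the standard convention: events precede
censorings at equal times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .io import ClinicalTable, ValidationError
from .stratify import GroupAssignment

logger = logging.getLogger(__name__)


@dataclass
class SurvivalCurve:
    """Product-limit estimate: S(t) after each distinct observed time."""

    times: np.ndarray  # distinct observed times, ascending
    survival: np.ndarray  # S(t) just after each time
    n_risk: np.ndarray  # at risk just before each time
    n_event: np.ndarray  # events at each time
    n_censored: np.ndarray  # censorings at each time
    label: str = ""

    def survival_at(self, t: float) -> float:
        """S(t): product over event times <= t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def median(self) -> float | None:
        """Smallest time with S(t) <= 0.5, or None if never reached."""
        below = np.flatnonzero(self.survival <= 0.5)
        return float(self.times[below[0]]) if below.size else None


def kaplan_meier(times, events, label: str = "") -> SurvivalCurve:
    """Fit the product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i/n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValidationError("need at least one subject")
    if (times < 0).any():
        raise ValidationError("negative survival time")
    if not np.isin(events, (0, 1)).all():
        raise ValidationError("event indicator must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events, label=label or None)
    table = kmf.event_table
    table = table.loc[table["removed"] > 0]  # distinct observed times only
    t = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(t).to_numpy(dtype=float)
    return SurvivalCurve(
        times=t,
        survival=surv,
        n_risk=table["at_risk"].to_numpy(dtype=int),
        n_event=table["observed"].to_numpy(dtype=int),
        n_censored=table["censored"].to_numpy(dtype=int),
        label=label,
    )


@dataclass
class LogRankResult:
    statistic: float  # chi-square, 1 df
    p_value: float
    observed: dict[str, float]  # events per group
    expected: dict[str, float]
    defined: bool = True  # False when there are no events


def log_rank(times, events, labels) -> LogRankResult:
    """Two-group log-rank test.

    At each distinct event time the expected events per group follow the
    hypergeometric mean d_i * n_gi / n_i; the statistic is
    (O - E)^2 / Var with the hypergeometric variance, chi-square on 1 df.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    labels = np.asarray(labels)
    groups = sorted(pd.unique(labels))
    if len(groups) != 2:
        raise ValidationError(f"log-rank needs exactly two groups, got {groups}")
    in_g1 = labels == groups[0]
    if in_g1.all() or (~in_g1).all():
        raise ValidationError("one group is empty")
    if events.sum() == 0:
        logger.warning("no events; log-rank statistic undefined")
        return LogRankResult(
            statistic=float("nan"), p_value=float("nan"),
            observed={g: 0.0 for g in groups}, expected={g: 0.0 for g in groups},
            defined=False,
        )

    event_times = np.unique(times[events == 1])
    O1 = E1 = V = 0.0
    for t in event_times:
        at_risk = times >= t  # events precede censorings at equal times
        n = at_risk.sum()
        n1 = (at_risk & in_g1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & in_g1).sum()
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    O = float(events.sum())
    stat = (O1 - E1) ** 2 / V if V > 0 else 0.0
    p = float(stats.chi2.sf(stat, df=1)) if V > 0 else 1.0
    return LogRankResult(
        statistic=float(stat),
        p_value=p,
        observed={groups[0]: float(O1), groups[1]: O - float(O1)},
        expected={groups[0]: float(E1), groups[1]: O - float(E1)},
    )


@dataclass
class SurvivalReport:
    curves: dict[str, SurvivalCurve]
    logrank: LogRankResult
    medians: dict[str, float | None]
    n: dict[str, int]


def survival_report(clinical: ClinicalTable, assignment: GroupAssignment) -> SurvivalReport:
    """Kaplan-Meier curves per marker group, the log-rank test and medians."""
    common = clinical.sample_ids.intersection(assignment.labels.index)
    if common.empty:
        raise ValidationError("clinical table and group assignment share no samples")
    table = clinical.table.loc[common]
    labels = assignment.labels.loc[common]
    curves: dict[str, SurvivalCurve] = {}
    medians: dict[str, float | None] = {}
    n: dict[str, int] = {}
    for grp in sorted(labels.unique()):
        ids = labels.index[labels == grp]
        curve = kaplan_meier(table.loc[ids, "time"], table.loc[ids, "event"], label=grp)
        curves[grp] = curve
        medians[grp] = curve.median
        n[grp] = len(ids)
    lr = log_rank(table["time"], table["event"], labels)
    return SurvivalReport(curves=curves, logrank=lr, medians=medians, n=n)
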
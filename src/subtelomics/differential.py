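"""Probe-level differential testing, probe-to-gene aggregation, quadrant
integration and gene-set enrichment.

The screen is a two-sided Student's t test per probe between the
marker-low and marker-high groups at a raw p < 0.005 threshold (no
multiple-testing correction at this stage; Benjamini-Hochberg is applied
only in enrichment, and optionally at the screen via a flag).  Fold
change is the ratio of group means, low over high.  Significant probes
sharing a gene symbol are averaged into one gene-level record, and genes
significant on both platforms are classified into quadrants by the joint
direction of their methylation and expression fold changes
(hyper/hypo × up/down).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection, OmicsMatrix, ProbeAnnotation, ValidationError

logger = logging.getLogger(__name__)

QUADRANTS = ("hyper_down", "hyper_up", "hypo_down", "hypo_up")


def fold_change(mean_low: float, mean_high: float) -> float:
    """Group-mean ratio, low over high; NaN (flagged by caller) when high is 0."""
    if mean_high == 0:
        return math.nan
    return mean_low / mean_high


def differential_test(
    matrix: OmicsMatrix,
    labels: pd.Series,
    probe_subset=None,
    p_threshold: float = 0.005,
    equal_var: bool = True,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-probe two-sample t test between marker-low and marker-high samples.

    Returns a DataFrame indexed by probe id with group means, fold change
    (low/high), t, p and a ``significant`` flag at ``p_threshold``.
    Probes with fewer than 2 non-missing values in either group are
    excluded (logged).  ``equal_var=False`` selects Welch's variant;
    ``adjust=True`` applies Benjamini-Hochberg before thresholding.
    """
    values = matrix.values
    if probe_subset is not None:
        values = values.loc[sorted(set(probe_subset) & set(values.index))]
    low_ids = labels.index[labels == "low"].intersection(values.columns)
    high_ids = labels.index[labels == "high"].intersection(values.columns)
    low = values.loc[:, low_ids].to_numpy(dtype=float)
    high = values.loc[:, high_ids].to_numpy(dtype=float)
    n_low = (~np.isnan(low)).sum(axis=1)
    n_high = (~np.isnan(high)).sum(axis=1)
    ok = (n_low >= 2) & (n_high >= 2)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("excluded %d probes with < 2 values in a group", n_excluded)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # excluded probes: empty slices
        res = stats.ttest_ind(low, high, axis=1, equal_var=equal_var, nan_policy="omit")
        mean_low = np.nanmean(low, axis=1)
        mean_high = np.nanmean(high, axis=1)
        fc = np.where(mean_high != 0, mean_low / mean_high, np.nan)
    t_stat = np.asarray(res.statistic, dtype=float)
    p_val = np.asarray(res.pvalue, dtype=float)
    # zero pooled variance: no evidence against equality when the means agree,
    # certain difference when they do not
    degen = ~np.isfinite(p_val) & ok
    same = degen & np.isclose(mean_low, mean_high)
    t_stat[same], p_val[same] = 0.0, 1.0
    diff = degen & ~same
    t_stat[diff] = np.sign(mean_low[diff] - mean_high[diff]) * np.inf
    p_val[diff] = 0.0
    out = pd.DataFrame(
        {
            "mean_low": mean_low,
            "mean_high": mean_high,
            "fold_change": fc,
            "t": t_stat,
            "p": p_val,
            "n_low": n_low,
            "n_high": n_high,
        },
        index=values.index,
    )
    out = out.loc[ok]
    p_for_call = out["p"].to_numpy()
    if adjust:
        p_for_call = multipletests(p_for_call, method="fdr_bh")[1]
        out["p_adj"] = p_for_call
    out["significant"] = p_for_call < p_threshold
    out.index.name = "probe_id"
    return out


def aggregate_probes_to_genes(
    records: pd.DataFrame, annotation: ProbeAnnotation, platform: str
) -> pd.DataFrame:
    """Average the significant probes of each gene into one gene-level record.

    ``records`` is the *significant* probe set from :func:`differential_test`
    (rows with ``significant == False`` are dropped here if present).
    Gene-level group means are the plain averages of the probe-level group
    means; the fold change is recomputed from the averaged means.  The
    gene-level p is the minimum probe p — a summary, not a calibrated
    p-value — and the number of contributing probes is reported.
    Probes without a gene annotation are dropped and counted.
    """
    sig = records.loc[records["significant"]] if "significant" in records else records
    gene_map = annotation.for_platform(platform).gene_map()
    genes = sig.index.to_series().map(gene_map)
    n_unannotated = int(genes.isna().sum())
    if n_unannotated:
        logger.info("dropped %d significant probes without gene annotation", n_unannotated)
    sig = sig.loc[genes.notna()].copy()
    sig["gene"] = genes.dropna()
    grouped = sig.groupby("gene")
    out = pd.DataFrame(
        {
            "mean_low": grouped["mean_low"].mean(),
            "mean_high": grouped["mean_high"].mean(),
            "p": grouped["p"].min(),
            "n_probes": grouped.size(),
        }
    )
    out["fold_change"] = out["mean_low"] / out["mean_high"].where(out["mean_high"] != 0)
    out.index.name = "gene"
    return out[["mean_low", "mean_high", "fold_change", "p", "n_probes"]]


def classify_quadrant(expr_fc: float, meth_fc: float) -> str | None:
    """Joint direction call; None when either fold change is exactly 1."""
    if expr_fc == 1.0 or meth_fc == 1.0 or np.isnan(expr_fc) or np.isnan(meth_fc):
        return None
    direction = "down" if expr_fc < 1 else "up"
    methyl = "hyper" if meth_fc > 1 else "hypo"
    return f"{methyl}_{direction}"


def integrate(gene_meth: pd.DataFrame, gene_expr: pd.DataFrame) -> pd.DataFrame:
    """Intersect gene-level differential records from the two platforms.

    Returns one row per gene significant on both platforms, with the
    platform-wise means/fold changes/p and a quadrant call.  Genes with
    either fold change exactly 1 keep a row but an ``excluded`` flag and
    no quadrant.
    """
    common = gene_meth.index.intersection(gene_expr.index).sort_values()
    rows = []
    for gene in common:
        e, m = gene_expr.loc[gene], gene_meth.loc[gene]
        quadrant = classify_quadrant(e["fold_change"], m["fold_change"])
        rows.append(
            {
                "gene": gene,
                "expr_mean_low": e["mean_low"],
                "expr_mean_high": e["mean_high"],
                "expr_fold_change": e["fold_change"],
                "expr_p": e["p"],
                "meth_mean_low": m["mean_low"],
                "meth_mean_high": m["mean_high"],
                "meth_fold_change": m["fold_change"],
                "meth_p": m["p"],
                "quadrant": quadrant,
                "excluded": quadrant is None,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene", "expr_mean_low", "expr_mean_high", "expr_fold_change", "expr_p",
            "meth_mean_low", "meth_mean_high", "meth_fold_change", "meth_p",
            "quadrant", "excluded",
        ],
    ).set_index("gene")
    return out


def quadrant_composition(integration: pd.DataFrame) -> dict:
    """Counts and percentages of quadrant calls among concurrent genes."""
    called = integration.loc[~integration["excluded"]]
    n = len(called)
    counts = {q: int((called["quadrant"] == q).sum()) for q in QUADRANTS}
    n_hyper = counts["hyper_down"] + counts["hyper_up"]
    n_hypo = counts["hypo_down"] + counts["hypo_up"]
    return {
        "n_concurrent": n,
        "counts": counts,
        "n_hypermethylated": n_hyper,
        "n_hypomethylated": n_hypo,
        "pct_hypermethylated": 100.0 * n_hyper / n if n else math.nan,
        "pct_hyper_downregulated": 100.0 * counts["hyper_down"] / n_hyper if n_hyper else math.nan,
    }


def enrichment(
    query: set[str], gene_sets: GeneSetCollection, background: set[str]
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a gene list against a GMT.

    Each term is intersected with the background; p = P(X >= k) for the
    overlap k under sampling n query genes from N background genes of
    which K carry the term.  Benjamini-Hochberg adjustment across terms.
    """
    if not query or not background:
        raise ValidationError("query and background must be non-empty")
    extra = set(query) - set(background)
    if extra:
        raise ValidationError(
            f"{len(extra)} query genes absent from background (e.g. {sorted(extra)[0]!r})"
        )
    N, n = len(background), len(query)
    rows = []
    for term, genes in sorted(gene_sets.items()):
        members = genes & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"]).set_index("term")
    if len(out):
        out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out.sort_values("p", kind="stable")
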
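"""Probe-level Pearson correlation screen against the marker gene.

Every probe on a platform is correlated (product-moment, pairwise-complete
observations) with the per-sample marker expression, the top-k positive
and top-k negative probes are selected, and probes/samples are ordered by
one-dimensional hierarchical clustering (1 - Pearson distance, average
linkage) for heatmap rendering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .io import OmicsMatrix, ProbeAnnotation, ValidationError

logger = logging.getLogger(__name__)

ZERO_VARIANCE_DISTANCE = 2.0  # max of the 1 - r metric


def marker_expression(
    expr: OmicsMatrix, annotation: ProbeAnnotation, marker_gene: str
) -> pd.Series:
    """Per-sample marker expression: mean over the marker gene's probes."""
    ann = annotation.for_platform(expr.platform).table
    probes = ann.loc[ann["gene"] == marker_gene, "probe_id"]
    probes = [p for p in probes if p in expr.probe_ids]
    if not probes:
        raise ValidationError(f"no probes for marker gene {marker_gene!r} in the matrix")
    return expr.values.loc[probes].mean(axis=0, skipna=True).rename(marker_gene)


def pearson_with_marker(
    matrix: OmicsMatrix, marker_values: pd.Series, min_pairs: int = 3
) -> pd.DataFrame:
    """Pearson r and two-sided p of every probe against the marker.

    Pairwise-complete observations; p from the t transform
    t = r * sqrt((n-2)/(1-r^2)) on n-2 df.  Probes with fewer than
    ``min_pairs`` complete pairs, or zero variance on either side, get
    NaN r/p and ``usable = False`` (excluded from ranking).
    """
    X = matrix.values.to_numpy(dtype=float)
    m = marker_values.reindex(matrix.sample_ids).to_numpy(dtype=float)
    mask = ~np.isnan(X) & ~np.isnan(m)[None, :]
    Xz = np.where(mask, X, 0.0)
    Mz = np.where(mask, m[None, :], 0.0)
    n = mask.sum(axis=1).astype(float)
    sx, sm = Xz.sum(axis=1), Mz.sum(axis=1)
    sxx, smm = (Xz**2).sum(axis=1), (Mz**2).sum(axis=1)
    sxm = (Xz * Mz).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxm - sx * sm
        varx = n * sxx - sx**2
        varm = n * smm - sm**2
        r = cov / np.sqrt(varx * varm)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1))
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    usable = (n >= min_pairs) & np.isfinite(r)
    r = np.where(usable, r, np.nan)
    p = np.where(usable, p, np.nan)
    n_bad = int((~usable).sum())
    if n_bad:
        logger.info("%d probes unusable for correlation (few pairs or zero variance)", n_bad)
    out = pd.DataFrame(
        {"r": r, "p": p, "n": n.astype(int), "usable": usable},
        index=matrix.probe_ids,
    )
    out.index.name = "probe_id"
    return out


@dataclass
class TopKSelection:
    positive: list[str]  # probe ids, highest r first
    negative: list[str]  # probe ids, lowest r first
    positive_threshold: float  # minimum selected positive r
    negative_threshold: float  # maximum selected negative r
    table: pd.DataFrame  # full results with rank/selected/sign columns


def select_top_k(results: pd.DataFrame, k_pos: int, k_neg: int) -> TopKSelection:
    """Select the k strongest positively and negatively correlated probes.

    Ties in r at the selection boundary break by probe-id lexicographic
    order.  If fewer than k probes of a sign exist, all are returned and
    the shortfall logged.  The reported thresholds are the minimum
    selected positive r and the maximum selected negative r.
    """
    usable = results.loc[results["usable"]].copy()
    # deterministic ordering: r descending (ascending for negatives), then probe id
    pos = usable.loc[usable["r"] > 0]
    pos = pos.iloc[np.lexsort((pos.index.to_numpy(), -pos["r"].to_numpy()))]
    neg = usable.loc[usable["r"] < 0]
    neg = neg.iloc[np.lexsort((neg.index.to_numpy(), neg["r"].to_numpy()))]
    if len(pos) < k_pos:
        logger.info("only %d positive probes available for k_pos=%d", len(pos), k_pos)
    if len(neg) < k_neg:
        logger.info("only %d negative probes available for k_neg=%d", len(neg), k_neg)
    sel_pos = pos.head(k_pos)
    sel_neg = neg.head(k_neg)

    table = results.copy()
    table["sign"] = np.sign(table["r"]).fillna(0).astype(int)
    table["rank"] = np.nan
    table.loc[pos.index, "rank"] = np.arange(1, len(pos) + 1)
    table.loc[neg.index, "rank"] = np.arange(1, len(neg) + 1)
    table["selected"] = table.index.isin(sel_pos.index) | table.index.isin(sel_neg.index)
    return TopKSelection(
        positive=list(sel_pos.index),
        negative=list(sel_neg.index),
        positive_threshold=float(sel_pos["r"].min()) if len(sel_pos) else np.nan,
        negative_threshold=float(sel_neg["r"].max()) if len(sel_neg) else np.nan,
        table=table,
    )


@dataclass
class ClusterOrdering:
    leaf_order: list[str]  # permutation of item ids
    heights: np.ndarray  # merge heights, non-decreasing
    ids: list[str] = None  # items in input order (linkage row indexing)
    merges: np.ndarray = None  # scipy linkage matrix

    def __len__(self) -> int:
        return len(self.leaf_order)

    def cluster_sets(self) -> set[frozenset]:
        """The nested clusters as id sets — orientation-free dendrogram shape."""
        clusters = {i: frozenset([x]) for i, x in enumerate(self.ids)}
        n = len(self.ids)
        out = set()
        for j, (a, b, _, _) in enumerate(self.merges):
            merged = clusters[int(a)] | clusters[int(b)]
            clusters[n + j] = merged
            out.add(merged)
        return out


def hierarchical_order(matrix: OmicsMatrix, axis: str = "probes") -> ClusterOrdering:
    """One-dimensional ordering by agglomerative clustering.

    Distance 1 - Pearson r between item profiles (pairwise-complete),
    average linkage.  A zero-variance item sits at the maximum distance
    (2) from everything; this is logged, not an error.
    """
    if axis == "probes":
        data = matrix.values
    elif axis == "samples":
        data = matrix.values.T
    else:
        raise ValidationError(f"axis must be 'probes' or 'samples', not {axis!r}")
    ids = list(data.index)
    if len(ids) < 2:
        raise ValidationError("need >= 2 items to cluster")
    corr = data.T.corr(method="pearson")  # pairwise-complete between rows
    dist = 1.0 - corr.to_numpy()
    undefined = ~np.isfinite(dist)
    if undefined.any():
        n_zero_var = int(corr.isna().all(axis=1).sum())
        logger.info("zero-variance items in clustering: %d; distance set to max", n_zero_var)
        dist[undefined] = ZERO_VARIANCE_DISTANCE
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    Z = linkage(squareform(dist, checks=False), method="average")
    order = leaves_list(Z)
    return ClusterOrdering(
        leaf_order=[ids[i] for i in order], heights=Z[:, 2].copy(), ids=ids, merges=Z
    )
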
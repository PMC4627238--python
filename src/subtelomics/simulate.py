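"""Synthetic matched expression/methylation/clinical cohorts with planted structure.

The generator emulates the statistical shape of a two-platform astrocytoma
cohort stratified by a marker gene ("ATRX" by default): beta-distributed
methylation with a planted subtelomeric hypermethylation shift in the
marker-low group, Gaussian expression around gene-level baselines with a
set of planted downregulated genes, several probes per gene, and
group-dependent exponential survival with administrative censoring.

Draws come from a single `numpy` Generator stream in a fixed order
(groups, gene placement, probe assignment, methylation, expression,
survival, missingness), so one seed pins every output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    EXPRESSION,
    METHYLATION,
    ChromosomeSizes,
    ClinicalTable,
    OmicsMatrix,
    ProbeAnnotation,
    ValidationError,
)
from .subtelomere import select_subtelomeric_probes

DEFAULT_CHROMOSOMES: tuple[tuple[str, int], ...] = (
    ("chr1", 120_000_000),
    ("chr2", 90_000_000),
    ("chr3", 60_000_000),
    ("chr4", 50_000_000),
)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the matched 82-sample cohort the pipeline targets:
    41 marker-low + 41 marker-high samples, a subtelomeric beta-value
    shift of 0.10 at concentration 50, planted downregulated genes at
    1.5 noise-SDs, and a survival advantage (hazard ratio 0.5) for the
    marker-low group.
    """

    seed: int = 0
    n_low: int = 41
    n_high: int = 41
    chromosomes: Sequence[tuple[str, int]] = DEFAULT_CHROMOSOMES
    n_meth_probes: int = 2000
    n_expr_probes: int = 2000
    probes_per_gene: tuple[int, int] = (1, 3)  # inclusive uniform range
    subtel_shift: float = 0.10  # added to low-group subtelomeric beta means
    n_planted_de: int = 20
    expr_shift_sd: float = 1.5  # planted expression downshift, units of noise SD
    marker_shift_sd: float = 1.5  # marker-gene expression separation
    meth_concentration: float = 50.0  # beta-law concentration kappa
    meth_mean_range: tuple[float, float] = (0.10, 0.45)
    expr_mean_range: tuple[float, float] = (1.0, 4.0)
    expr_noise_sd: float = 0.5
    hazard_ratio: float = 0.5  # low-vs-high hazard; < 1 means low group favorable
    baseline_hazard: float = 0.03  # events per month in the high group
    censor_time: float = 100.0  # administrative censoring, months
    missing_rate: float = 0.0
    window_bp: int = 4_000_000  # subtelomeric truth window
    marker_gene: str = "ATRX"

    def validate(self) -> None:
        for name in ("n_low", "n_high", "n_meth_probes", "n_expr_probes"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.n_planted_de < 0:
            raise ValidationError("n_planted_de must be >= 0")
        lo, hi = self.meth_mean_range
        if not (0 < lo <= hi < 1):
            raise ValidationError("meth_mean_range must lie inside (0,1)")
        if not (0 <= self.subtel_shift < 1) or hi + self.subtel_shift >= 1:
            raise ValidationError(
                "subtel_shift pushes beta means outside (0,1): "
                f"max mean {hi} + shift {self.subtel_shift} >= 1"
            )
        if self.hazard_ratio <= 0:
            raise ValidationError("hazard_ratio must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0,1)")
        if self.probes_per_gene[0] < 1 or self.probes_per_gene[0] > self.probes_per_gene[1]:
            raise ValidationError("probes_per_gene must be an increasing range with min >= 1")


@dataclass
class CohortTruth:
    """Ground truth planted into one generated cohort."""

    group: pd.Series  # sample_id -> "low"/"high"
    marker_gene: str
    planted_de_genes: list[str]
    subtelomeric_meth_probes: list[str]
    subtelomeric_expr_probes: list[str]
    config: GeneratorConfig = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "marker_gene": self.marker_gene,
            "planted_de_genes": sorted(self.planted_de_genes),
            "subtelomeric_meth_probes": sorted(self.subtelomeric_meth_probes),
            "subtelomeric_expr_probes": sorted(self.subtelomeric_expr_probes),
            "group": {k: v for k, v in self.group.items()},
        }


@dataclass
class SyntheticCohort:
    expression: OmicsMatrix
    methylation: OmicsMatrix
    annotation: ProbeAnnotation
    sizes: ChromosomeSizes
    clinical: ClinicalTable
    truth: CohortTruth


def _assign_probes(rng, genes: pd.DataFrame, n_probes: int, lo: int, hi: int, prefix: str):
    """Walk the gene table, giving each gene Uniform{lo..hi} probes until n_probes."""
    rows = []
    gi = 0
    n_genes = len(genes)
    while len(rows) < n_probes:
        gene = genes.iloc[gi % n_genes]
        k = int(rng.integers(lo, hi + 1))
        for _ in range(min(k, n_probes - len(rows))):
            offset = int(rng.integers(-2000, 2001))
            pos = int(np.clip(gene.position + offset, 1, gene.length))
            rows.append((f"{prefix}{len(rows):05d}", gene.chromosome, pos, gene.gene))
        gi += 1
    return pd.DataFrame(rows, columns=["probe_id", "chromosome", "position", "gene"])


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate one matched cohort; identical config + seed gives identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sizes = ChromosomeSizes(dict(config.chromosomes))

    # 1. samples and groups
    n = config.n_low + config.n_high
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    perm = rng.permutation(n)
    group = np.array(["high"] * n, dtype=object)
    group[perm[: config.n_low]] = "low"
    group = pd.Series(group, index=sample_ids, name="group")
    is_low = (group == "low").to_numpy()

    # 2. gene placement: uniform over the genome (chromosomes weighted by length)
    chrom_names = [c for c, _ in config.chromosomes]
    chrom_lengths = np.array([l for _, l in config.chromosomes], dtype=float)
    n_genes = max(config.n_expr_probes, config.n_meth_probes)  # more than enough
    chrom_idx = rng.choice(len(chrom_names), size=n_genes, p=chrom_lengths / chrom_lengths.sum())
    positions = np.array(
        [int(rng.integers(1, chrom_lengths[i] + 1)) for i in chrom_idx], dtype=np.int64
    )
    genes = pd.DataFrame(
        {
            "gene": [f"G{i + 1:05d}" for i in range(n_genes)],
            "chromosome": [chrom_names[i] for i in chrom_idx],
            "position": positions,
            "length": [int(chrom_lengths[i]) for i in chrom_idx],
        }
    )
    # the marker gene sits mid-chromosome, away from any subtelomeric window
    genes.loc[0, ["gene", "chromosome", "position", "length"]] = (
        config.marker_gene,
        chrom_names[0],
        int(chrom_lengths[0] // 2),
        int(chrom_lengths[0]),
    )

    # 3. probe assignment (expression first, then methylation)
    lo_ppg, hi_ppg = config.probes_per_gene
    expr_ann = _assign_probes(rng, genes, config.n_expr_probes, lo_ppg, hi_ppg, "EXP")
    meth_ann = _assign_probes(rng, genes, config.n_meth_probes, lo_ppg, hi_ppg, "CG")
    expr_ann["platform"] = EXPRESSION
    meth_ann["platform"] = METHYLATION
    annotation = ProbeAnnotation(pd.concat([expr_ann, meth_ann], ignore_index=True))

    subtel_meth = select_subtelomeric_probes(
        annotation.for_platform(METHYLATION), sizes, config.window_bp
    )
    subtel_expr = select_subtelomeric_probes(
        annotation.for_platform(EXPRESSION), sizes, config.window_bp
    )

    # 4. planted DM-DE genes: subtelomeric on the methylation platform
    # (so the subtelomeric shift hypermethylates them) and present on both
    meth_by_gene = meth_ann.groupby("gene")["probe_id"].apply(list)
    expr_genes = set(expr_ann["gene"])
    candidates = sorted(
        g
        for g, probes in meth_by_gene.items()
        if g != config.marker_gene
        and g in expr_genes
        and all(p in subtel_meth for p in probes)
    )
    if len(candidates) < config.n_planted_de:
        raise ValidationError(
            f"only {len(candidates)} subtelomeric genes available for "
            f"{config.n_planted_de} planted DE genes; enlarge the cohort"
        )
    if config.n_planted_de:
        planted = sorted(rng.choice(candidates, size=config.n_planted_de, replace=False))
    else:
        planted = []

    # 5. methylation: beta(mean m, concentration kappa), +shift for
    # subtelomeric probes in low-group samples
    m_lo, m_hi = config.meth_mean_range
    base_means = rng.uniform(m_lo, m_hi, size=config.n_meth_probes)
    is_subtel_m = meth_ann["probe_id"].isin(subtel_meth).to_numpy()
    means = np.tile(base_means[:, None], (1, n))
    means[np.ix_(is_subtel_m, is_low)] += config.subtel_shift
    kappa = config.meth_concentration
    meth_values = rng.beta(means * kappa, (1.0 - means) * kappa)
    meth = pd.DataFrame(meth_values, index=meth_ann["probe_id"].to_numpy(), columns=sample_ids)

    # 6. expression: gene baseline + probe offset + noise; planted genes and
    # the marker are shifted down in the low group
    e_lo, e_hi = config.expr_mean_range
    gene_base = pd.Series(rng.uniform(e_lo, e_hi, size=n_genes), index=genes["gene"].to_numpy())
    probe_offset = rng.normal(0.0, 0.1, size=config.n_expr_probes)
    expr_gene = expr_ann["gene"].to_numpy()
    mu = gene_base.loc[expr_gene].to_numpy()[:, None] + probe_offset[:, None]
    mu = np.tile(mu, (1, n))
    down = np.isin(expr_gene, planted)
    mu[np.ix_(down, is_low)] -= config.expr_shift_sd * config.expr_noise_sd
    is_marker = expr_gene == config.marker_gene
    mu[np.ix_(is_marker, is_low)] -= config.marker_shift_sd * config.expr_noise_sd
    expr_values = mu + rng.normal(0.0, config.expr_noise_sd, size=mu.shape)
    expr = pd.DataFrame(expr_values, index=expr_ann["probe_id"].to_numpy(), columns=sample_ids)

    # 7. survival: exponential, hazard h in high group, h * HR in low group
    hazards = np.where(is_low, config.baseline_hazard * config.hazard_ratio, config.baseline_hazard)
    raw_times = rng.exponential(1.0 / hazards)
    event = (raw_times <= config.censor_time).astype(int)
    times = np.minimum(raw_times, config.censor_time)
    age = np.clip(rng.normal(45.0, 12.0, size=n), 18.0, 85.0).round(1)
    gender = np.where(rng.random(n) < 0.6, "male", "female")
    clinical = ClinicalTable(
        pd.DataFrame(
            {"time": times.round(4), "event": event, "age": age, "gender": gender},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    # 8. missingness
    if config.missing_rate > 0:
        for df in (expr, meth):
            mask = rng.random(df.shape) < config.missing_rate
            df.mask(mask, inplace=True)

    truth = CohortTruth(
        group=group,
        marker_gene=config.marker_gene,
        planted_de_genes=list(planted),
        subtelomeric_meth_probes=sorted(subtel_meth),
        subtelomeric_expr_probes=sorted(subtel_expr),
        config=config,
    )
    expr.index.name = meth.index.name = "probe_id"
    return SyntheticCohort(
        expression=OmicsMatrix(EXPRESSION, expr),
        methylation=OmicsMatrix(METHYLATION, meth),
        annotation=annotation,
        sizes=sizes,
        clinical=clinical,
        truth=truth,
    )
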
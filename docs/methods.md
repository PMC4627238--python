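# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical conventions that make runs reproducible.

## Data model and conventions

All genomic coordinates are 1-based and fully closed (Infinium manifest
convention), stated once and used everywhere. Matrices are probes ×
samples; methylation values are beta fractions in [0, 1] and are used
directly (no M-value transform), matching the mean-beta presentation of
the quantities the pipeline reports. Missing values are written as `NA`;
aggregating operations (means, correlations) drop missing observations
pairwise and record the effective n. Sample order after cohort alignment
is the lexicographic sort of the intersected ids, so alignment is
deterministic and idempotent.

## Marker stratification

The marker score is the mean over the marker gene's expression probes
(consistent with the gene-level averaging used downstream). The cutoff is
searched over the distinct observed scores and maximises Youden's
J = sensitivity + specificity − 1 against a binary outcome; vital status
at last follow-up is the default outcome because the cutoff's purpose is
survival stratification, and the outcome column is configurable. Which
cutoff criterion the original cohort analysis used is not recorded
anywhere we could consult, so Youden — the most common choice — is the
default and the criterion is isolated in one function.

Ties among equally optimal cutoffs break toward the smallest threshold
(deterministic, platform-independent). If the AUC is below 0.5 the score
orientation is flipped before the search and the flip recorded; the
labelling invariant — "low" iff score ≤ cutoff — holds either way.
All-equal scores yield a flagged single-group assignment rather than an
error, so degenerate inputs surface downstream with context.

Group × covariate association uses Pearson's χ² without continuity
correction, the convention of the cohort literature this mirrors;
immunohistochemistry percent-positive scores classify as negative (< 5),
weak positive (5–25, the 25 boundary inclusive here since published
ranges overlap at 25), strong positive (> 25).

## Correlation screen

Pearson r per probe against the marker on pairwise-complete
observations; p from the t transform on n − 2 df. Probes with fewer than
3 complete pairs or zero variance are flagged and excluded from ranking.
Selection takes the k highest r among positively correlated probes and
the k lowest among negatively correlated ones; boundary ties break by
probe id. The reported thresholds are the minimum selected positive r
and maximum selected negative r, mirroring how such screens are usually
summarised. Defaults k = 500 per sign for expression and 300 per sign
for methylation.

The 1-D clustering uses distance 1 − r with average linkage — the common
transcriptomics default; both are pluggable. A zero-variance item is
placed at the metric's maximum distance (2) rather than erroring, and
the leaf order, merge heights and full linkage are returned so heatmap
rendering and structure comparisons need no recomputation. Note that
agglomerative leaf order is unique only up to branch flips; tests
therefore compare the nested cluster sets, not the drawn order.

## Subtelomeric methylation

A probe is subtelomeric when min(pos, L − pos + 1) ≤ W with W = 4 Mb by
default, applied to both chromosome ends; "within" is taken inclusive.
The same positional rule is applied to both platforms' manifests. Each
sample is summarised by the ratio of its mean subtelomeric beta to its
mean overall beta; the ratio cancels any global scaling of the beta
values and centres near 1 under the null.

The default group comparison is a two-sided Student's t on the 82 (or
however many) per-sample ratios, because that respects sample
independence; a rank-sum alternative is selectable. A pooled probe-level
variant (every (probe, sample) beta value treated as an observation) is
available behind a flag for comparability with probe-pooling analyses —
its p-values are optimistic because within-sample probes are correlated,
which is why it is not the default.

## Differential testing, aggregation, integration

Per-probe two-sided Student's pooled-variance t between the groups
(Welch selectable), significance at raw p < 0.005. No multiple-testing
correction is applied at this screen — the analysis design this follows
screens on raw p — but a flag enables Benjamini–Hochberg there. Probes
with zero pooled variance get t = 0, p = 1 when the group means agree
(no evidence) and p = 0 when they differ (degenerate certainty); probes
with fewer than two values in a group are excluded and counted.

Fold change is mean(low)/mean(high) on the values as provided (no
antilog), so printed fold changes equal the ratio of printed means.
Gene-level records average the group means of each gene's *significant*
probes only, recompute the fold change from the averaged means, and
report min probe p — explicitly a summary, not a calibrated p-value,
since no gene-level re-test is performed. Genes significant on both
platforms are intersected and classified into quadrants by the two
fold-change directions (hyper ⇔ methylation FC > 1; down ⇔ expression
FC < 1); a fold change exactly 1 excludes the gene from quadrant calls
with a flag.

Enrichment is the one-sided hypergeometric upper tail per term
(terms intersected with the user's background first), BH-adjusted across
terms. The annotation corpus is whatever GMT the user supplies.

## Survival

Kaplan–Meier product-limit curves (via lifelines) with the standard tie
convention — events precede censorings at equal times. Median survival
is the smallest time with S(t) ≤ 0.5, "not reached" (None) otherwise.
The two-group log-rank statistic is tabulated in-package — at each
distinct event time, E₁ += d·n₁/n and V += d(n₁/n)(1 − n₁/n)(n − d)/(n − 1),
statistic (O₁ − E₁)²/V on 1 χ² df — because the result reports per-group
observed and expected counts; tests cross-check statistic and p against
lifelines. With zero events the statistic is undefined and flagged, not
raised. Survival time and event columns are taken as provided; no date
arithmetic is performed.

## Synthetic cohorts

The generator emulates a two-platform astrocytic-tumour cohort with a
planted marker structure. Defaults are the study conditions the pipeline
targets:

| parameter | default | meaning |
|---|---|---|
| n_low, n_high | 41, 41 | samples per marker group (82 matched total) |
| chromosomes | 4 chromosomes, 50–120 Mb | genome scaled down ~10× |
| n_meth_probes, n_expr_probes | 2000, 2000 | probes per platform |
| probes_per_gene | uniform 1–3 | many-to-one probe→gene mapping |
| subtel_shift (δ_m) | 0.10 | beta-mean increase at subtelomeric probes, low group |
| meth_concentration (κ) | 50 | beta-law concentration; per-probe SD ≈ 0.06 |
| meth_mean_range | 0.10–0.45 | per-probe baseline beta means |
| n_planted_de | 20 | genes downregulated in the low group |
| expr_shift_sd (δ_e) | 1.5 | planted downshift in noise-SD units |
| expr_mean_range, expr_noise_sd | 1–4, 0.5 | gene baselines and Gaussian noise |
| marker_shift_sd | 1.5 | marker-gene suppression in the low group |
| hazard_ratio | 0.5 | low-vs-high hazard (low group favourable) |
| baseline_hazard, censor_time | 0.03/month, 100 months | exponential survival, administrative censoring |
| missing_rate | 0 | missingness is exercised explicitly in tests |

Methylation draws are Beta(mκ, (1 − m)κ) — parameterised by mean and
concentration rather than (α, β) because the planted effects are mean
shifts. Expression is gene baseline + probe offset + Gaussian noise.
Planted genes are chosen among genes whose methylation probes all fall
in the 4-Mb window and that carry probes on both platforms, so their
low-group hypermethylation comes from the same subtelomeric shift the
analysis looks for and quadrant recovery is well-posed; they are
disjoint from the marker gene. `n_planted_de = 0` yields a pure null
cohort. Survival is exponential with the configured hazard ratio and
administrative censoring. One `numpy` Generator stream drawn in a fixed
order (groups, gene placement, probe assignment, methylation,
expression, survival, missingness) makes every output a deterministic
function of the seed.

What the generator does **not** emulate: probe cross-hybridisation,
batch effects, copy-number contamination, CpG-island structure,
correlated neighbouring probes, or non-exponential survival. Passing
tests therefore demonstrate that the pipeline's statistics behave
correctly under a clean version of the assumed data-generating process,
not that the biological effect sizes are realistic — no published
estimate of the subtelomeric shift magnitude exists, so δ_m = 0.10 was
chosen for testability.

## Calibration and recovery checks

Type-I error of the subtelomere comparison and the log-rank test is
measured on null cohorts (δ_m = 0; hazard ratio 1) over 800 scaled-down
replicates and required to sit within 0.05 ± 0.02. The scaled-down null
uses 20 samples per group for the subtelomere comparison: at very small
groups (10 per group) the Student's t on the mildly skewed per-sample
ratio is measurably anticonservative (empirical rate ≈ 0.05–0.08), which
is a property of the statistic in that regime rather than of the
implementation; 20 per group — half the study cohort's group size —
restores nominal behaviour while keeping 800 replicates under a minute.
The log-rank null uses 15 per group. Recovery is checked at the study
conditions (δ_m = 0.10, κ = 50, δ_e = 1.5 SD, 40 + 40 samples): the
subtelomeric shift must be detected at p < 10⁻⁶ and planted hyper-down
genes recovered with mean sensitivity ≥ 0.9 and false-discovery
proportion ≤ 0.2 over 10 seeds.

## Problem sizes

The default cohort (82 samples, 2 × 2000 probes) runs the full pipeline
in a few seconds; the acceptance script (two 800-replicate calibrations
plus 10 recovery cohorts) completes in about a minute on one CPU. These
sizes were chosen so the complete statistical battery — not a smoke
subset — runs on every invocation.

## Known limitations

- Gene-level p-values are min-probe summaries, not calibrated tests.
- The probe-pooled subtelomere variant ignores within-sample correlation.
- The enrichment stage is only as good as the supplied GMT; no
  annotation corpus ships with the package.
- Only the two-group log-rank is implemented (no k-group or trend test),
  and no Cox modelling: the pipeline stratifies and compares, it does
  not adjust for covariates.
- The ROC outcome for cutoff selection defaults to vital status; with
  heavy censoring this conflates follow-up length with outcome, which is
  why the outcome column is explicit in every summary.
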
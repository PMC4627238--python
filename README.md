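# subtelomics

Integrative analysis of matched DNA-methylation and mRNA-expression array
cohorts stratified by the expression of a marker gene (by default *ATRX*,
the SWI/SNF-like chromatin remodeler whose loss is linked to subtelomeric
methylation change and alternative lengthening of telomeres in astrocytic
gliomas).

The package is aimed at cancer epigenomics analysts who have, for one
cohort, an expression matrix (probes × samples, continuous normalised
intensities), a methylation matrix (probes × samples, beta values
β ∈ [0, 1]), probe manifests with genomic positions and gene symbols,
chromosome sizes, and a clinical table with overall survival. It provides
a tested, deterministic pipeline for the full analysis chain, plus a
synthetic-cohort generator so every stage can be exercised (and its error
rates measured) without any external download.

## What it computes

1. **Marker stratification.** Per-sample marker expression (mean over the
   marker gene's probes) is dichotomised at the ROC-derived cutoff
   maximising Youden's *J* = sensitivity + specificity − 1 against a
   binary outcome (vital status by default). Samples with expression ≤
   cutoff form the marker-low group; the AUC (Mann–Whitney concordance,
   ties ½) is attached. Group × covariate associations use Pearson's χ²
   without continuity correction.
2. **Correlation screen.** Every probe is ranked by Pearson *r* against
   the marker (pairwise-complete; *p* from *t* = *r*·√((n−2)/(1−*r*²)) on
   n−2 df); the top-k positive/negative probes are selected and ordered
   by one-dimensional hierarchical clustering (distance 1 − *r*, average
   linkage).
3. **Subtelomeric methylation.** A probe is subtelomeric when
   min(pos, L − pos + 1) ≤ 4 Mb on its chromosome of length L (1-based,
   closed, both ends). Each sample is summarised by
   ratio = mean β(subtelomeric) / mean β(all probes), and the groups are
   compared by a two-sided Student's *t* on the per-sample ratios.
4. **Differential testing and quadrant integration.** Per-probe Student's
   *t* between groups at raw *p* < 0.005; fold change = mean(low)/mean(high);
   significant probes averaged per gene; genes significant on both
   platforms get a quadrant call (hyper/hypo-methylated × up/down-regulated)
   from the joint fold-change directions.
5. **Enrichment.** One-sided hypergeometric test of any resulting gene
   list against a user-supplied GMT, Benjamini–Hochberg adjusted.
6. **Survival.** Kaplan–Meier product-limit curves per group,
   S(t) = ∏_{t_i ≤ t} (1 − d_i/n_i), and the two-group log-rank test
   ((O − E)²/V with hypergeometric variance, χ² on 1 df).

The synthetic generator plants all the structure the analysis is supposed
to find: a subtelomeric beta-value shift in the marker-low group,
downregulated genes, a suppressed marker gene, and group-dependent
exponential survival. See `docs/methods.md` for the model, parameters and
their defaults.

## Worked example

```python
import subtelomics as st

cfg = st.GeneratorConfig(seed=7)          # 41 + 41 samples, 2000 + 2000 probes
cohort = st.generate_cohort(cfg)

marker = st.marker_expression(cohort.expression, cohort.annotation, "ATRX")
groups = st.find_cutoff(marker, cohort.clinical.table["event"].astype(int))
print(f"cutoff={groups.cutoff:.4f}  AUC={groups.auc:.4f}  "
      f"n_low={groups.n_low}  n_high={groups.n_high}")

subtel = st.select_subtelomeric_probes(
    cohort.annotation.for_platform("methylation"), cohort.sizes, window_bp=4_000_000
)
stats = st.subtelomeric_statistic(cohort.methylation, subtel)
res = st.compare_groups(stats, groups.labels)
print(f"subtelomeric probes={len(subtel)}  "
      f"ratio_low={res.mean_low:.3f}  ratio_high={res.mean_high:.3f}  p={res.p_value:.3e}")

report = st.survival_report(cohort.clinical, groups)
print(f"log-rank chi2={report.logrank.statistic:.3f}  p={report.logrank.p_value:.3e}  "
      f"median_low={report.medians['low']}  median_high={report.medians['high']}")
```

prints

```
cutoff=2.8323  AUC=0.7500  n_low=45  n_high=37
subtelomeric probes=193  ratio_low=1.285  ratio_high=1.027  p=3.552e-20
log-rank chi2=6.617  p=1.010e-02  median_low=38.0368  median_high=26.4761
```

The cutoff splits the cohort at the Youden-optimal marker level; the
normalised subtelomeric methylation of the marker-low group (1.285) sits
well above the marker-high group (1.027), detecting the planted
chromosome-end hypermethylation; and the marker-low group's survival
advantage (planted hazard ratio 0.5) shows as a longer median survival
and a significant log-rank test.

The same run is available from the shell:

```sh
subtelomics simulate --seed 7 --outdir data/
subtelomics run-all --config config.yaml --outdir results/ --seed 7
```

where `config.yaml` points at the written files (or sets `simulate:` to
generate in-process). `run-all` executes align → stratify → correlate →
subtelomere → differential → integrate → enrich → survival and writes
every stage's TSV/JSON plus a reproducibility manifest; identical
config + seed reruns are byte-identical (the log, which carries wall
times, aside).

## Bundled reference values

`subtelomics.reference` ships the published integrative table for the
CGGA astrocytic-tumour cohort this analysis design targets — 13
chromosome-end genes (including *MGMT*, *TYMS*, *BNIP3*) with their group
means, fold changes and p-values on both platforms, plus the published
concurrent-gene tally. These are inputs for worked examples and
consistency tests; everything derived from them is recomputed.

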
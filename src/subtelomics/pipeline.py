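"""End-to-end orchestration: align → stratify → correlate → subtelomere →
differential → integrate → enrich → survival, with a reproducibility
manifest.

Every stage writes its TSV/JSON outputs into the run directory and
registers its row counts in ``manifest.json``.  The manifest carries the
config echo, seed and package version but no timings, so identical
config + seed reruns are byte-identical; wall times go to the log
(stderr and ``run.log``) only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .correlate import hierarchical_order, marker_expression, pearson_with_marker, select_top_k
from .differential import (
    aggregate_probes_to_genes,
    differential_test,
    enrichment,
    integrate,
    quadrant_composition,
)
from .io import (
    EXPRESSION,
    METHYLATION,
    ValidationError,
    align_cohort,
    read_chrom_sizes,
    read_clinical,
    read_gmt,
    read_matrix,
    read_probe_annotation,
    write_chrom_sizes,
    write_clinical,
    write_matrix,
    write_probe_annotation,
)
from .simulate import GeneratorConfig, generate_cohort
from .stratify import find_cutoff
from .subtelomere import compare_groups, select_subtelomeric_probes, subtelomeric_statistic
from .survival import survival_report

logger = logging.getLogger(__name__)

STAGES = (
    "align",
    "stratify",
    "correlate",
    "subtelomere",
    "differential",
    "integrate",
    "enrich",
    "survival",
)


@dataclass
class PipelineConfig:
    """Run configuration; every analysis threshold is a named default here."""

    outdir: str = "results"
    seed: int = 0
    # inputs: file paths, or simulate != None for a synthetic cohort
    expression: Optional[str] = None
    methylation: Optional[str] = None
    annotation: Optional[str] = None
    chrom_sizes: Optional[str] = None
    clinical: Optional[str] = None
    gene_sets: Optional[str] = None
    simulate: Optional[dict] = None
    # analysis parameters
    marker_gene: str = "ATRX"
    roc_outcome: str = "event"
    window_bp: int = 4_000_000
    k_pos_expr: int = 500
    k_neg_expr: int = 500
    k_pos_meth: int = 300
    k_neg_meth: int = 300
    p_threshold: float = 0.005
    equal_var: bool = True  # Student's t; False = Welch
    subtelomere_test: str = "t"  # or "ranksum"

    def validate(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValidationError("p_threshold must lie in (0,1)")
        if self.window_bp <= 0:
            raise ValidationError("window_bp must be > 0")
        if self.simulate is None:
            for name in ("expression", "methylation", "annotation", "chrom_sizes", "clinical"):
                path = getattr(self, name)
                if path is None:
                    raise ValidationError(f"no {name} path given and simulation not requested")
                if not Path(path).exists():
                    raise ValidationError(f"{name} path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


class _Run:
    """Bookkeeping for one pipeline run: logging, manifest, stage timing."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "version": __version__,
            "seed": config.seed,
            "config": {k: v for k, v in dataclasses.asdict(config).items()},
            "stages": {},
        }
        self._handler = logging.FileHandler(self.outdir / "run.log", mode="w")
        self._handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        pkg_logger = logging.getLogger("subtelomics")
        pkg_logger.addHandler(self._handler)
        self._prev_level = pkg_logger.level
        if pkg_logger.getEffectiveLevel() > logging.INFO:
            pkg_logger.setLevel(logging.INFO)

    def close(self) -> None:
        pkg_logger = logging.getLogger("subtelomics")
        pkg_logger.removeHandler(self._handler)
        pkg_logger.setLevel(self._prev_level)
        self._handler.close()

    def stage(self, name: str):
        run = self

        class _Stage:
            def __enter__(self):
                logger.info("START stage %s", name)
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                if exc is not None:
                    logger.error("FAILED stage %s after %.2fs: %s", name, dt, exc)
                    (run.outdir / "FAILED").write_text(f"stage {name}: {exc}\n")
                    run.manifest["stages"][name] = {"status": "failed"}
                    run.write_manifest()
                    return False
                logger.info("END stage %s (%.2fs)", name, dt)
                return False

        return _Stage()

    def record(self, stage: str, **counts) -> None:
        self.manifest["stages"][stage] = {"status": "ok", **counts}

    def write_manifest(self) -> None:
        _dump_json(self.manifest, self.outdir / "manifest.json")

    def write_tsv(self, df: pd.DataFrame, name: str, index: bool = True) -> int:
        df.to_csv(self.outdir / name, sep="\t", na_rep="NA", index=index)
        return len(df)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the output directory.

    Any stage's hard error aborts the run with the stage name and cause;
    partial outputs stay on disk next to a ``FAILED`` marker.
    """
    config.validate()
    run = _Run(config)
    out = run.outdir
    try:
        # ---- inputs -----------------------------------------------------
        if config.simulate is not None:
            gen_kwargs = dict(config.simulate)
            gen_kwargs.setdefault("seed", config.seed)
            gen_kwargs.setdefault("window_bp", config.window_bp)
            gen_kwargs.setdefault("marker_gene", config.marker_gene)
            gen = GeneratorConfig(**gen_kwargs)
            cohort = generate_cohort(gen)
            expr, meth = cohort.expression, cohort.methylation
            annotation, sizes, clinical = cohort.annotation, cohort.sizes, cohort.clinical
            _dump_json(cohort.truth.to_dict(), out / "truth.json")
            logger.info("simulated cohort: %d samples", len(clinical.sample_ids))
        else:
            sizes = read_chrom_sizes(config.chrom_sizes)
            expr = read_matrix(config.expression, EXPRESSION)
            meth = read_matrix(config.methylation, METHYLATION)
            annotation = read_probe_annotation(config.annotation, sizes)
            clinical = read_clinical(config.clinical)
        gene_sets = read_gmt(config.gene_sets) if config.gene_sets else None

        # ---- align ------------------------------------------------------
        with run.stage("align"):
            cohort_al = align_cohort(expr, meth, clinical)
            expr, meth, clinical = cohort_al.expression, cohort_al.methylation, cohort_al.clinical
            run.record("align", n_samples=cohort_al.n_retained, dropped=cohort_al.n_dropped)

        # ---- stratify ---------------------------------------------------
        with run.stage("stratify"):
            marker = marker_expression(expr, annotation, config.marker_gene)
            outcome = clinical.table[config.roc_outcome].astype(int)
            assignment = find_cutoff(marker, outcome, outcome_name=config.roc_outcome)
            groups_tsv = pd.DataFrame(
                {"score": marker, "group": assignment.labels}
            ).rename_axis("sample_id")
            n_rows = run.write_tsv(groups_tsv, "groups.tsv")
            _dump_json(
                {
                    "cutoff": assignment.cutoff,
                    "auc": assignment.auc,
                    "outcome": assignment.outcome,
                    "flipped": assignment.flipped,
                    "degenerate": assignment.degenerate,
                    "n_low": assignment.n_low,
                    "n_high": assignment.n_high,
                },
                out / "stratification.json",
            )
            run.record("stratify", n_rows=n_rows, n_low=assignment.n_low, n_high=assignment.n_high)

        # ---- correlate --------------------------------------------------
        with run.stage("correlate"):
            corr_counts = {}
            for platform, matrix, k_pos, k_neg in (
                (EXPRESSION, expr, config.k_pos_expr, config.k_neg_expr),
                (METHYLATION, meth, config.k_pos_meth, config.k_neg_meth),
            ):
                results = pearson_with_marker(matrix, marker)
                sel = select_top_k(results, k_pos, k_neg)
                n_rows = run.write_tsv(sel.table, f"correlation_{platform}.tsv")
                selected = sel.positive + sel.negative
                ordering = hierarchical_order(matrix.subset_probes(selected), axis="probes")
                pd.Series(ordering.leaf_order, name="probe_id").to_csv(
                    out / f"ordering_{platform}_probes.tsv", sep="\t", index=False
                )
                _dump_json(
                    {
                        "n": int(results["usable"].sum()),
                        "k_pos": k_pos,
                        "k_neg": k_neg,
                        "n_selected_positive": len(sel.positive),
                        "n_selected_negative": len(sel.negative),
                        "positive_threshold": sel.positive_threshold,
                        "negative_threshold": sel.negative_threshold,
                    },
                    out / f"correlation_{platform}.json",
                )
                corr_counts[platform] = n_rows
            sample_order = hierarchical_order(expr, axis="samples")
            pd.Series(sample_order.leaf_order, name="sample_id").to_csv(
                out / "ordering_samples.tsv", sep="\t", index=False
            )
            run.record("correlate", **{f"n_{k}": v for k, v in corr_counts.items()})

        # ---- subtelomere ------------------------------------------------
        with run.stage("subtelomere"):
            subtel = {
                platform: select_subtelomeric_probes(
                    annotation.for_platform(platform), sizes, config.window_bp
                )
                for platform in (EXPRESSION, METHYLATION)
            }
            stats_table = subtelomeric_statistic(meth, subtel[METHYLATION])
            stats_out = stats_table.join(assignment.labels.rename("group"))
            n_rows = run.write_tsv(stats_out, "subtelomere.tsv")
            comparison = compare_groups(
                stats_table, assignment.labels, method=config.subtelomere_test
            )
            _dump_json(
                {
                    "window_bp": config.window_bp,
                    "n_subtelomeric_expression_probes": len(subtel[EXPRESSION]),
                    "n_subtelomeric_methylation_probes": len(subtel[METHYLATION]),
                    "comparison": dataclasses.asdict(comparison),
                },
                out / "subtelomere.json",
            )
            run.record(
                "subtelomere",
                n_rows=n_rows,
                n_expr_probes=len(subtel[EXPRESSION]),
                n_meth_probes=len(subtel[METHYLATION]),
            )

        # ---- differential -----------------------------------------------
        with run.stage("differential"):
            gene_level = {}
            diff_counts = {}
            for platform, matrix in ((EXPRESSION, expr), (METHYLATION, meth)):
                probes = differential_test(
                    matrix,
                    assignment.labels,
                    probe_subset=subtel[platform],
                    p_threshold=config.p_threshold,
                    equal_var=config.equal_var,
                )
                run.write_tsv(probes, f"differential_{platform}_probes.tsv")
                genes = aggregate_probes_to_genes(
                    probes.loc[probes["significant"]], annotation, platform
                )
                run.write_tsv(genes, f"differential_{platform}_genes.tsv")
                gene_level[platform] = genes
                diff_counts[f"n_{platform}_probes_significant"] = int(probes["significant"].sum())
                diff_counts[f"n_{platform}_genes"] = len(genes)
            run.record("differential", **diff_counts)

        # ---- integrate --------------------------------------------------
        with run.stage("integrate"):
            integration = integrate(gene_level[METHYLATION], gene_level[EXPRESSION])
            n_rows = run.write_tsv(integration, "integration.tsv")
            composition = quadrant_composition(integration)
            _dump_json(composition, out / "integration.json")
            run.record("integrate", n_rows=n_rows, n_concurrent=composition["n_concurrent"])

        # ---- enrich -----------------------------------------------------
        with run.stage("enrich"):
            if gene_sets is None:
                logger.info("no gene-set file given; enrichment skipped")
                run.record("enrich", skipped=True)
            else:
                background = set(annotation.table["gene"].dropna())
                query = set(integration.index[~integration["excluded"]]) & background
                if not query:
                    logger.info("no concurrent genes to enrich; enrichment skipped")
                    run.record("enrich", skipped=True, reason="empty query")
                else:
                    enr = enrichment(query, gene_sets, background)
                    n_rows = run.write_tsv(enr, "enrichment.tsv")
                    run.record("enrich", n_rows=n_rows)

        # ---- survival ---------------------------------------------------
        with run.stage("survival"):
            report = survival_report(clinical, assignment)
            curve_rows = []
            for grp, curve in sorted(report.curves.items()):
                for i in range(len(curve.times)):
                    curve_rows.append(
                        {
                            "group": grp,
                            "time": curve.times[i],
                            "n_risk": int(curve.n_risk[i]),
                            "n_event": int(curve.n_event[i]),
                            "n_censored": int(curve.n_censored[i]),
                            "survival": curve.survival[i],
                        }
                    )
            n_rows = run.write_tsv(pd.DataFrame(curve_rows), "survival_curves.tsv", index=False)
            _dump_json(
                {
                    "logrank": {
                        "statistic": report.logrank.statistic,
                        "p_value": report.logrank.p_value,
                        "observed": report.logrank.observed,
                        "expected": report.logrank.expected,
                        "defined": report.logrank.defined,
                    },
                    "medians": report.medians,
                    "n": report.n,
                },
                out / "survival.json",
            )
            run.record("survival", n_rows=n_rows)

        run.write_manifest()
        return out
    finally:
        run.close()


def write_cohort_files(cohort, outdir) -> dict[str, str]:
    """Write a generated cohort's full file set into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(cohort.expression, outdir / "expression.tsv")
    write_matrix(cohort.methylation, outdir / "methylation.tsv")
    write_probe_annotation(cohort.annotation, outdir / "annotation.tsv")
    write_chrom_sizes(cohort.sizes, outdir / "chrom.sizes")
    write_clinical(cohort.clinical, outdir / "clinical.tsv")
    _dump_json(cohort.truth.to_dict(), outdir / "truth.json")
    return {
        "expression": str(outdir / "expression.tsv"),
        "methylation": str(outdir / "methylation.tsv"),
        "annotation": str(outdir / "annotation.tsv"),
        "chrom_sizes": str(outdir / "chrom.sizes"),
        "clinical": str(outdir / "clinical.tsv"),
    }
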
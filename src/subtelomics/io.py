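"""Core domain types and readers/writers for the pipeline's file formats.

All tables are UTF-8, tab-delimited text with ``NA`` for missing values.
Genomic coordinates are 1-based and fully closed (Infinium manifest
convention); that convention is stated here once and used everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EXPRESSION = "expression"
METHYLATION = "methylation"
PLATFORMS = (EXPRESSION, METHYLATION)


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates an invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class OmicsMatrix:
    """A probes × samples value matrix for one array platform.

    ``values`` is a float DataFrame indexed by probe id with sample-id
    columns; NaN encodes missing.  Methylation values are beta fractions
    and must lie in [0, 1].
    """

    platform: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValidationError(f"unknown platform {self.platform!r}")
        self.values = self.values.astype(float)
        self.validate()

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def validate(self) -> None:
        idx, cols = self.values.index, self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate probe id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        if self.platform == METHYLATION:
            arr = self.values.to_numpy()
            bad = (arr < 0) | (arr > 1)
            if bad.any():
                i, j = map(int, np.argwhere(bad)[0])
                raise ValidationError(
                    f"methylation beta value {arr[i, j]!r} outside [0,1] "
                    f"at probe {idx[i]!r}, sample {cols[j]!r}"
                )

    def subset_samples(self, sample_ids: Iterable[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.platform, self.values.loc[:, list(sample_ids)])

    def subset_probes(self, probe_ids: Iterable[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.platform, self.values.loc[list(probe_ids)])


@dataclass
class ChromosomeSizes:
    """Mapping chromosome name -> length in base pairs."""

    sizes: dict[str, int]

    def __post_init__(self) -> None:
        for name, length in self.sizes.items():
            if int(length) <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length}")
        self.sizes = {str(k): int(v) for k, v in self.sizes.items()}

    def __getitem__(self, name: str) -> int:
        return self.sizes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sizes

    def __iter__(self):
        return iter(self.sizes)

    def items(self):
        return self.sizes.items()


@dataclass
class ProbeAnnotation:
    """Probe -> (chromosome, 1-based position, gene symbol, platform) table.

    ``table`` columns: probe_id, chromosome, position, gene, platform.
    A missing gene symbol is NaN.  Each probe is annotated at most once
    per platform; several probes may share one gene.
    """

    table: pd.DataFrame

    REQUIRED = ("probe_id", "chromosome", "position", "gene", "platform")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"annotation missing columns {missing}")
        t = self.table.copy()
        t["position"] = t["position"].astype(np.int64)
        dup = t.duplicated(subset=["probe_id", "platform"])
        if dup.any():
            probe = t.loc[dup, "probe_id"].iloc[0]
            raise ValidationError(f"probe {probe!r} annotated more than once on its platform")
        if (t["position"] < 1).any():
            probe = t.loc[t["position"] < 1, "probe_id"].iloc[0]
            raise ValidationError(f"probe {probe!r} has position < 1")
        self.table = t.reset_index(drop=True)

    def for_platform(self, platform: str) -> "ProbeAnnotation":
        return ProbeAnnotation(self.table[self.table["platform"] == platform])

    def gene_map(self) -> pd.Series:
        """probe_id -> gene symbol (annotated probes only)."""
        t = self.table.dropna(subset=["gene"])
        return pd.Series(t["gene"].values, index=t["probe_id"].values)

    def validate_against(self, sizes: ChromosomeSizes) -> None:
        for chrom, grp in self.table.groupby("chromosome"):
            if chrom not in sizes:
                raise ValidationError(f"chromosome {chrom!r} absent from sizes")
            too_far = grp["position"] > sizes[chrom]
            if too_far.any():
                probe = grp.loc[too_far, "probe_id"].iloc[0]
                raise ValidationError(
                    f"probe {probe!r} at position {int(grp.loc[too_far, 'position'].iloc[0])} "
                    f"exceeds length {sizes[chrom]} of {chrom!r}"
                )


@dataclass
class ClinicalTable:
    """Per-sample survival time (months), event indicator and covariates."""

    table: pd.DataFrame  # indexed by sample_id; columns include time, event

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r} in clinical table")
        for col in ("time", "event"):
            if col not in t.columns:
                raise ValidationError(f"clinical table missing column {col!r}")
        if (t["time"] < 0).any():
            raise ValidationError("negative survival time")
        if not t["event"].isin((0, 1)).all():
            raise ValidationError("event indicator must be 0/1")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def subset(self, sample_ids: Iterable[str]) -> "ClinicalTable":
        return ClinicalTable(self.table.loc[list(sample_ids)])


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT), term -> set of gene symbols."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_matrix(path, platform: str) -> OmicsMatrix:
    """Read a probes × samples TSV (header = sample ids, first column = probe ids).

    Cells unparseable as numbers, or written as ``NA``, become missing.
    Duplicate probe/sample ids and methylation values outside [0, 1] are
    hard errors naming the offender.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA"], float_precision="round_trip"
    )
    # columns left as object contain unparseable cells; coerce those to NaN
    obj_cols = df.columns[df.dtypes == object]
    values = df.copy()
    for col in obj_cols:
        values[col] = pd.to_numeric(df[col], errors="coerce")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    values.index.name = "probe_id"
    return OmicsMatrix(platform, values)


def write_matrix(matrix: OmicsMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_chrom_sizes(path) -> ChromosomeSizes:
    """Read a UCSC-style two-column chrom.sizes file (name<TAB>length)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chromosome", "length"], dtype={0: str})
    if df["chromosome"].duplicated().any():
        dup = df.loc[df["chromosome"].duplicated(), "chromosome"].iloc[0]
        raise ValidationError(f"duplicate chromosome {dup!r} in sizes file")
    return ChromosomeSizes(dict(zip(df["chromosome"], df["length"].astype(int))))


def write_chrom_sizes(sizes: ChromosomeSizes, path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def read_probe_annotation(path, sizes: ChromosomeSizes) -> ProbeAnnotation:
    """Read a probe manifest TSV (probe_id, chromosome, position, gene[, platform]).

    Probes on chromosomes absent from ``sizes`` are dropped with a logged
    count; a position beyond its chromosome's length is a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str, "gene": str})
    if "platform" not in df.columns:
        df["platform"] = EXPRESSION
    known = df["chromosome"].isin(list(sizes))
    n_dropped = int((~known).sum())
    if n_dropped:
        logger.info("dropped %d probes on chromosomes absent from sizes", n_dropped)
    ann = ProbeAnnotation(df[known])
    ann.validate_against(sizes)
    return ann


def write_probe_annotation(annotation: ProbeAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path) -> None:
    out = clinical.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: term<TAB>description<TAB>gene1<TAB>gene2..."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"malformed GMT line: {line[:80]!r}")
            term, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            sets[term] = set(genes)
            descriptions[term] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term in collection.sets:
            desc = collection.descriptions.get(term, "")
            genes = "\t".join(sorted(collection.sets[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")


# ---------------------------------------------------------------------------
# Cohort alignment
# ---------------------------------------------------------------------------


@dataclass
class AlignedCohort:
    expression: OmicsMatrix
    methylation: OmicsMatrix
    clinical: ClinicalTable
    n_retained: int
    n_dropped: dict[str, int]

    @property
    def sample_ids(self) -> pd.Index:
        return self.expression.sample_ids


def align_cohort(expr: OmicsMatrix, meth: OmicsMatrix, clinical: ClinicalTable) -> AlignedCohort:
    """Restrict all three inputs to their common samples.

    The canonical sample order is the lexicographic sort of the
    intersection, so the result is deterministic and aligning an
    already-aligned triple is a no-op.
    """
    common = sorted(
        set(expr.sample_ids) & set(meth.sample_ids) & set(clinical.sample_ids)
    )
    if not common:
        raise ValidationError("no samples shared between expression, methylation and clinical")
    dropped = {
        "expression": len(expr.sample_ids) - len(common),
        "methylation": len(meth.sample_ids) - len(common),
        "clinical": len(clinical.sample_ids) - len(common),
    }
    logger.info("aligned cohort: %d samples retained, dropped %s", len(common), dropped)
    return AlignedCohort(
        expression=expr.subset_samples(common),
        methylation=meth.subset_samples(common),
        clinical=clinical.subset(common),
        n_retained=len(common),
        n_dropped=dropped,
    )
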
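"""Readers, writers and validated containers for every on-disk artifact.

All tabular formats are plain TSV; gene sets use the GMT interchange format.
Expression matrices are genes x samples on a log2 scale, with a per-sample
cohort (batch) label carried either as a second ``#cohort`` header row inside
the expression file or as a sidecar two-column TSV (sample, cohort).

Readers never mutate their inputs; any collapse/dedup action is logged with
counts through the module logger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "ClinicalTable",
    "VariantTable",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "read_variants",
    "write_variants",
]

# CNV integer codes on disk -> 3-level call alphabet
CNV_CODE_MAP = {-2: "loss", -1: "loss", 0: "neutral", 1: "gain", 2: "gain"}
CNV_CALLS = ("loss", "neutral", "gain")


@dataclass
class ExpressionMatrix:
    """Genes x samples log-expression with a cohort label per sample.

    Invariants: unique gene and sample ids, all values finite, every sample
    labeled, at least 2 genes and 2 samples.
    """

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    cohort: pd.Series  # index = sample ids

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValidationError(
                f"expression matrix needs >=2 genes and >=2 samples, got {v.shape}"
            )
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        if not np.isfinite(v.to_numpy()).all():
            raise ValidationError("expression matrix contains non-finite values")
        self.cohort = pd.Series(self.cohort, dtype=object).reindex(v.columns)
        if self.cohort.isna().any():
            missing = self.cohort.index[self.cohort.isna()].tolist()
            raise ValidationError(f"samples without cohort label: {missing[:5]}")
        self.cohort.name = "cohort"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.values.loc[list(genes)].copy(), self.cohort.copy())


@dataclass
class GeneSetCollection:
    """Named gene lists: set name -> (description, ordered member gene ids)."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {name!r} has duplicate members")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> list[str]:
        return list(self.sets[name][1])

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets


#: Optional clinical columns tolerated when absent (flagged, never required).
CLINICAL_OPTIONAL = (
    "age",
    "gender",
    "grade",
    "stage",
    "molecular_phenotype",
    "stemness_index",
    "response",
)


@dataclass
class ClinicalTable:
    """Per-sample survival and covariate records, indexed by sample id."""

    records: pd.DataFrame
    missing_optional: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        df = self.records
        if df.index.duplicated().any():
            raise ValidationError("duplicate sample ids in clinical table")
        for col in ("time", "event"):
            if col not in df.columns:
                raise ValidationError(f"clinical table missing required column {col!r}")
        times = df["time"]
        bad = times.notna() & (times <= 0)
        if bad.any():
            row = df.index[bad][0]
            raise ValidationError(f"sample {row!r}: time must be > 0, got {times[row]}")
        ev = df["event"].dropna()
        if not ev.isin([0, 1]).all():
            bad_val = ev[~ev.isin([0, 1])].iloc[0]
            raise ValidationError(f"event values must be 0 or 1, got {bad_val!r}")
        if "stemness_index" in df.columns:
            si = df["stemness_index"].dropna()
            if ((si < 0) | (si > 1)).any():
                raise ValidationError("stemness_index must lie in [0, 1]")
        self.missing_optional = tuple(c for c in CLINICAL_OPTIONAL if c not in df.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.records.index)


@dataclass
class VariantTable:
    """Gene-level somatic alterations.

    ``snv_indel`` is a set of (gene, sample, variant_class) triples; ``cnv``
    is a gene x sample matrix of calls from {loss, neutral, gain}.
    """

    snv_indel: set[tuple[str, str, str]]
    cnv: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(np.unique(self.cnv.to_numpy())) - set(CNV_CALLS)
        if bad:
            raise ValidationError(f"unknown CNV calls: {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.cnv.index) | {g for g, _, _ in self.snv_indel})

    @property
    def samples(self) -> list[str]:
        return list(self.cnv.columns)

    def snv_altered(self, gene: str) -> pd.Series:
        """Boolean per-sample indicator of any SNV/indel in ``gene``."""
        hit = {s for g, s, _ in self.snv_indel if g == gene}
        return pd.Series([s in hit for s in self.samples], index=self.samples)

    def altered(self, gene: str, mode: str) -> pd.Series:
        """Per-sample alteration indicator for one gene under a given mode."""
        if mode == "snv":
            return self.snv_altered(gene)
        if gene in self.cnv.index:
            row = self.cnv.loc[gene]
        else:
            row = pd.Series("neutral", index=self.samples)
        if mode == "cnv_loss":
            return row == "loss"
        if mode == "cnv_gain":
            return row == "gain"
        if mode == "any_alteration":
            return (row != "neutral") | self.snv_altered(gene)
        raise ValidationError(f"unknown alteration mode {mode!r}")


# ---------------------------------------------------------------------------
# expression


def read_expression(
    path,
    cohort_path=None,
    default_cohort: str | None = None,
    tpm: bool = False,
) -> ExpressionMatrix:
    """Read a genes x samples TSV into a validated :class:`ExpressionMatrix`.

    The first column holds gene ids, the header row sample ids. Cohort labels
    come from an inline ``#cohort`` second row, from ``cohort_path`` (TSV with
    columns sample, cohort), or — as a last resort — ``default_cohort``.
    Duplicate gene rows are collapsed by mean (logged). With ``tpm=True`` the
    values are treated as linear TPM and transformed by log2(x + 1).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise ValidationError(f"duplicate sample id(s) in {path.name}: {dups[:5]}")

    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.columns = samples
    cohort = None
    if len(raw) and str(raw.index[0]) == "#cohort":
        cohort = pd.Series(raw.iloc[0].to_numpy(dtype=object), index=samples, name="cohort")
        raw = raw.iloc[1:]

    try:
        # astype goes through python float(), which parses round-trip exactly
        # (pd.to_numeric's fast path does not)
        values = raw.astype(np.float64)
    except (ValueError, TypeError):
        coerced = raw.apply(pd.to_numeric, errors="coerce")
        r, c = np.argwhere(coerced.isna().to_numpy())[0]
        raise FormatError(
            f"non-numeric value {raw.iat[r, c]!r} at gene {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r} in {path.name}"
        ) from None

    if values.index.duplicated().any():
        n_dup = int(values.index.duplicated().sum())
        log.info("collapsing %d duplicate gene rows by mean in %s", n_dup, path.name)
        values = values.groupby(level=0, sort=False).mean()

    if tpm:
        if (values.to_numpy() < 0).any():
            raise ValidationError("negative values are incompatible with --tpm log2(x+1)")
        values = np.log2(values + 1.0)

    if cohort is None and cohort_path is not None:
        sc = pd.read_csv(cohort_path, sep="\t", dtype=str)
        if not {"sample", "cohort"} <= set(sc.columns):
            raise FormatError("cohort sidecar needs columns 'sample' and 'cohort'")
        cohort = sc.set_index("sample")["cohort"].reindex(samples)
    if cohort is None:
        if default_cohort is None:
            raise ValidationError(
                "no cohort labels found: provide a '#cohort' row, a sidecar TSV, "
                "or default_cohort"
            )
        cohort = pd.Series(default_cohort, index=samples, name="cohort")

    return ExpressionMatrix(values, cohort)


def write_expression(em: ExpressionMatrix, path) -> None:
    """Write an expression matrix with its inline ``#cohort`` row.

    Floats are written with ``repr`` precision so write -> read round-trips
    bit-exactly at float64.
    """
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(map(str, em.sample_ids)) + "\n")
        fh.write("#cohort\t" + "\t".join(map(str, em.cohort.to_numpy())) + "\n")
        for gene, row in zip(em.gene_ids, em.values.to_numpy()):
            fh.write(str(gene) + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: per line, name TAB description TAB gene TAB gene...

    Within-set duplicate genes are dropped keeping first occurrence (logged).
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{Path(path).name}:{lineno}: GMT line needs >=3 tab-separated "
                    f"fields (name, description, genes), got {len(fields)}"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                log.info(
                    "set %s: dropped %d duplicate gene(s)", name, len(genes) - len(deduped)
                )
            if name in sets:
                raise ValidationError(f"duplicate gene-set name {name!r} at line {lineno}")
            sets[name] = (desc, deduped)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.names:
            desc = collection.description(name)
            fh.write("\t".join([name, desc, *collection.genes(name)]) + "\n")


# ---------------------------------------------------------------------------
# clinical


def read_clinical(path) -> ClinicalTable:
    """Read a clinical TSV keyed by a ``sample`` column.

    Required: sample, time (months, > 0), event (0/1). Optional columns
    (age, gender, grade, stage, molecular_phenotype, stemness_index,
    response) are tolerated when absent and flagged on the returned table.
    """
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise FormatError("clinical table needs a 'sample' column")
    df = df.set_index("sample")
    for col in ("time", "event", "age", "stemness_index"):
        if col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise FormatError(f"column {col!r} is not numeric: {exc}") from exc
    table = ClinicalTable(df)
    if table.missing_optional:
        log.warning("clinical table missing optional columns: %s", table.missing_optional)
    return table


def write_clinical(table: ClinicalTable, path) -> None:
    table.records.rename_axis("sample").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# variants


def read_variants(maf_path, cnv_path) -> VariantTable:
    """Read a MAF-lite TSV (gene, sample, variant_class) and a CNV call matrix.

    CNV cells are integers in [-2, 2]; {-2,-1} -> loss, 0 -> neutral,
    {1,2} -> gain. Repeated (gene, sample) MAF rows collapse to one triple
    per variant class (set semantics).
    """
    maf = pd.read_csv(maf_path, sep="\t", dtype=str)
    need = {"gene", "sample", "variant_class"}
    if not need <= set(maf.columns):
        raise FormatError(f"MAF-lite needs columns {sorted(need)}")
    snv = set(maf[["gene", "sample", "variant_class"]].itertuples(index=False, name=None))

    cnv_raw = pd.read_csv(cnv_path, sep="\t", index_col=0)
    codes = np.unique(cnv_raw.to_numpy())
    unknown = [c for c in codes if c not in CNV_CODE_MAP]
    if unknown:
        raise ValidationError(f"unknown CNV code(s) {unknown[:5]}; expected integers in [-2, 2]")
    cnv = cnv_raw.apply(lambda col: col.map(CNV_CODE_MAP))
    return VariantTable(snv, cnv)


def write_variants(table: VariantTable, maf_path, cnv_path) -> None:
    maf = pd.DataFrame(sorted(table.snv_indel), columns=["gene", "sample", "variant_class"])
    maf.to_csv(maf_path, sep="\t", index=False)
    inv = {"loss": -1, "neutral": 0, "gain": 1}
    table.cnv.apply(lambda col: col.map(inv)).rename_axis("gene").to_csv(cnv_path, sep="\t")
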
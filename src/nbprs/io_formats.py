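"""Readers/writers for the external formats the pipeline touches.

All tabular formats are TSV with a header line; writers prepend ``#``-comment
lines recording the tool version and the parameters used to produce the file.
Coordinates are 1-based inclusive everywhere (VCF convention); the BED-like
gene annotation input is declared 1-based inclusive as well, so a single
convention holds across the package.

Allele handling: GWAS rows whose allele frequency exceeds 0.5 are folded to
the minor-allele representation (alleles swapped, beta negated, maf -> 1-maf)
so that downstream MAF filters see a true minor allele frequency. Strand
flips are *not* resolved: if GWAS and genotype alleles disagree beyond a
plain swap the variant is dropped and reported.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__


class DataError(ValueError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VariantRecord:
    """One GWAS/genotype variant.

    ``beta`` is the log-odds per copy of ``effect_allele``; ``p`` the
    two-sided association p-value; ``maf`` the minor allele frequency after
    folding; ``imp_r2`` the imputation quality R^2.
    """

    id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    p: float
    maf: float = 0.5
    imp_r2: float = 1.0

    def validate(self) -> None:
        if self.pos < 1:
            raise DataError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.effect_allele == self.other_allele:
            raise DataError(f"variant {self.id}: effect and other allele identical")
        if not (0 < self.p <= 1):
            raise DataError(f"variant {self.id}: p must lie in (0, 1], got {self.p}")
        if not (0 <= self.maf <= 0.5):
            raise DataError(f"variant {self.id}: maf must lie in [0, 0.5], got {self.maf}")
        if not (0 <= self.imp_r2 <= 1):
            raise DataError(f"variant {self.id}: imp_r2 must lie in [0, 1], got {self.imp_r2}")


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix, entries in [0, 2] (effect-allele count).

    ``alleles`` maps variant id -> (counted allele, other allele) when the
    source provided them (VCF ALT/REF); dosage counts the first allele.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    dosage: np.ndarray
    alleles: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise DataError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        if np.isnan(self.dosage).any():
            raise DataError("dosage matrix contains missing entries after imputation")
        if (self.dosage < 0).any() or (self.dosage > 2).any():
            bad = self.variant_ids[int(np.argwhere((self.dosage < 0) | (self.dosage > 2))[0, 1])]
            raise DataError(f"dosage outside [0, 2] at variant {bad}")

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosage[:, self.variant_ids.index(variant_id)]

    def subset(self, variant_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.variant_ids.index(v) for v in variant_ids]
        return GenotypeMatrix(
            self.sample_ids,
            list(variant_ids),
            self.dosage[:, idx],
            {v: self.alleles[v] for v in variant_ids if v in self.alleles},
        )


@dataclass
class GeneAnnotation:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    module: str | None = None

    def validate(self) -> None:
        if self.start > self.end:
            raise DataError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise DataError(f"gene {self.gene_id}: start must be >= 1")


@dataclass
class ExpressionMatrix:
    """Genes x samples log2-scale expression for one tissue."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    tissue: str = "blood"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError("expression matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression matrix contains non-finite entries")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("duplicate gene ids in expression matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample ids in expression matrix")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = [self.gene_ids.index(g) for g in genes]
        return ExpressionMatrix(list(genes), self.sample_ids, self.values[idx], self.tissue)


@dataclass
class LoadReport:
    """Per-load bookkeeping: what was requested, missing, imputed or dropped."""

    requested: int = 0
    loaded: int = 0
    missing_variants: list[str] = field(default_factory=list)
    imputed_entries: int = 0
    dropped_allele_mismatch: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_GWAS_REQUIRED = ["id", "chrom", "pos", "a1", "a2", "beta", "p"]


def read_gwas_summary(path) -> list[VariantRecord]:
    """Read GWAS summary statistics from TSV.

    Required columns: id, chrom, pos, a1 (effect allele), a2, beta, p.
    Optional: maf (default 0.5), imp_r2 (default 1.0). Alleles are
    upper-cased; rows with maf > 0.5 are folded (alleles swapped, beta
    negated, maf -> 1-maf). Duplicate ids are an error.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "id": str})
    missing = [c for c in _GWAS_REQUIRED if c not in df.columns]
    if missing:
        raise DataError(f"GWAS summary file missing columns: {missing}")
    dups = df["id"][df["id"].duplicated()].unique().tolist()
    if dups:
        raise DataError(f"duplicate variant id(s) in GWAS summary: {dups}")
    if "maf" not in df.columns:
        df["maf"] = 0.5
    if "imp_r2" not in df.columns:
        df["imp_r2"] = 1.0
    records = []
    for row in df.itertuples(index=False):
        a1, a2 = str(row.a1).upper(), str(row.a2).upper()
        beta, maf = float(row.beta), float(row.maf)
        if not (0 <= maf <= 1):
            raise DataError(f"variant {row.id}: allele frequency {maf} outside [0, 1]")
        if maf > 0.5:  # fold to minor-allele representation
            a1, a2 = a2, a1
            beta = -beta
            maf = 1.0 - maf
        rec = VariantRecord(
            id=str(row.id), chrom=str(row.chrom), pos=int(row.pos),
            effect_allele=a1, other_allele=a2,
            beta=beta, p=float(row.p), maf=maf, imp_r2=float(row.imp_r2),
        )
        rec.validate()
        records.append(rec)
    return records


def _read_dosages_tsv(path, variant_ids):
    """TSV layout: first column ``variant_id``, remaining columns samples."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    df = df.set_index(df.columns[0])
    report = LoadReport(requested=len(variant_ids) if variant_ids is not None else len(df))
    if variant_ids is not None:
        present = [v for v in variant_ids if v in df.index]
        report.missing_variants = [v for v in variant_ids if v not in df.index]
        df = df.loc[present]
    sample_ids = [str(c) for c in df.columns]
    mat = df.to_numpy(dtype=float).T  # samples x variants
    # per-variant mean imputation
    nan_mask = np.isnan(mat)
    if nan_mask.any():
        report.imputed_entries = int(nan_mask.sum())
        col_means = np.nanmean(np.where(nan_mask, np.nan, mat), axis=0)
        col_means = np.where(np.isnan(col_means), 0.0, col_means)
        mat = np.where(nan_mask, col_means[None, :], mat)
    gm = GenotypeMatrix(sample_ids, list(df.index), mat)
    report.loaded = len(gm.variant_ids)
    return gm, report


def _read_dosages_vcf(path, variant_ids):
    from cyvcf2 import VCF

    wanted = set(variant_ids) if variant_ids is not None else None
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    cols, ids, alleles = [], [], {}
    report = LoadReport(requested=len(wanted) if wanted is not None else 0)
    seen = set()
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        if wanted is not None and vid not in wanted:
            continue
        seen.add(vid)
        ds = None
        if "DS" in dict(var.FORMAT or {}) or "DS" in (var.FORMAT or []):
            try:
                ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
            except Exception:
                ds = None
        if ds is None:
            # fall back to hard genotype calls: dosage = ALT allele count
            gt = np.asarray(var.genotype.array())[:, :2]
            ds = np.where(gt < 0, np.nan, gt).sum(axis=1).astype(float)
        nan = np.isnan(ds)
        if nan.any():
            report.imputed_entries += int(nan.sum())
            fill = np.nanmean(ds) if not nan.all() else 0.0
            ds = np.where(nan, fill, ds)
        if (ds < 0).any() or (ds > 2).any():
            raise DataError(f"dosage outside [0, 2] at variant {vid}")
        cols.append(ds)
        ids.append(vid)
        alleles[vid] = (str(var.ALT[0]).upper(), str(var.REF).upper())
    vcf.close()
    if wanted is not None:
        report.missing_variants = sorted(wanted - seen)
    mat = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    gm = GenotypeMatrix(sample_ids, ids, mat, alleles)
    report.loaded = len(ids)
    return gm, report


def read_dosages(path, variant_ids=None) -> tuple[GenotypeMatrix, LoadReport]:
    """Load effect-allele dosages from a VCF (DS field, or GT allele counts)
    or a TSV matrix (variants x samples, first column the variant id).

    Missing entries are imputed to the per-variant mean and counted in the
    returned :class:`LoadReport`; requested variants absent from the file are
    listed in the report, not fatal. Dosages outside [0, 2] raise.
    """
    p = str(path)
    if p.endswith((".vcf", ".vcf.gz", ".bcf")):
        return _read_dosages_vcf(path, variant_ids)
    return _read_dosages_tsv(path, variant_ids)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: set name, description, member genes (tabs).

    Duplicate genes within a set are deduplicated (order preserved); empty
    sets are dropped with a warning; a line with fewer than 3 fields raises.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"GMT line {lineno}: fewer than 3 tab-separated fields")
            name = fields[0]
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                warnings.warn(f"GMT set {name!r} is empty after dedup; dropped")
                continue
            sets[name] = genes
    return sets


def read_gene_annotation(path) -> list[GeneAnnotation]:
    """BED-like TSV with header gene_id, chrom, start, end[, module].

    Coordinates are 1-based inclusive (see module docstring).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "gene_id": str})
    genes = []
    for row in df.itertuples(index=False):
        g = GeneAnnotation(
            gene_id=str(row.gene_id), chrom=str(row.chrom),
            start=int(row.start), end=int(row.end),
            module=(str(row.module) if "module" in df.columns and pd.notna(row.module) else None),
        )
        g.validate()
        genes.append(g)
    return genes


def read_expression(path, tissue="blood") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return ExpressionMatrix(
        [str(g) for g in df.index], [str(s) for s in df.columns],
        df.to_numpy(dtype=float), tissue=tissue,
    )


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype/covariate table keyed by sample_id.

    Validates the age ordering invariants when the relevant columns exist.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise DataError("phenotype table missing sample_id column")
    if {"age_baseline", "age_last"} <= set(df.columns):
        bad = df[df["age_baseline"] > df["age_last"]]
        if len(bad):
            raise DataError(
                f"age_baseline > age_last for sample(s) {bad['sample_id'].tolist()}"
            )
    if {"event_age", "age_baseline"} <= set(df.columns):
        mask = df["event_age"].notna() & (df["event_age"] < df["age_baseline"])
        if mask.any():
            raise DataError(
                f"event_age < age_baseline for sample(s) {df.loc[mask, 'sample_id'].tolist()}"
            )
    return df


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, params: dict | None = None, index=False) -> None:
    """Write a TSV with a comment header recording tool version and parameters.

    Floats are rendered with 12 significant digits so a write/read round trip
    is lossless at that precision and byte-identical across reruns.
    """
    buf = io.StringIO()
    buf.write(f"# nbprs {__version__}\n")
    for k, v in (params or {}).items():
        buf.write(f"# {k}={v}\n")
    df.to_csv(buf, sep="\t", index=index, float_format="%.12g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def write_expression(expr: ExpressionMatrix, path, params=None) -> None:
    df = expr.to_frame()
    df.index.name = "gene_id"
    write_table(df, path, params={"tissue": expr.tissue, **(params or {})}, index=True)
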
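"""Network-based polygenic risk score (nbPRS) construction and stratification.

The score for individual *i* over a network is

    nbPRS_i = sum_j beta_j * g_ij

taken over variants that (1) lie within the gene body +/- a flank (default
20 kb) of at least one network gene, (2) are associated with the phenotype at
p < 1e-3 (strict), (3) survive MAF >= 1% and imputation R^2 >= 0.4 filters,
and (4) survive greedy LD pruning at r^2 <= 0.5. Weights are oriented so the
effect allele is the risk allele (beta_j >= 0 after orientation), which makes
all scores sums of non-negative contributions.

"Gene body +/- flank" is a deliberate reading of a coding-region window:
exon structure is not an input anywhere in this pipeline, so the window is
annotation start - flank to end + flank, 1-based inclusive, clamped at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import DataError, GeneAnnotation, GenotypeMatrix, VariantRecord

DEFAULT_FLANK = 20_000
DEFAULT_P_THRESH = 1e-3
DEFAULT_MAF_MIN = 0.01
DEFAULT_RSQ_MIN = 0.4
DEFAULT_LD_R2_MAX = 0.5


@dataclass
class NbprsResult:
    network: str
    sample_ids: list[str]
    sample_scores: np.ndarray
    selected_variants: list[tuple[VariantRecord, float]]
    filter_report: dict[str, int] = field(default_factory=dict)


@dataclass
class RiskStratification:
    scheme: str                 # median | tertile | quartile
    cutpoints: list[float]
    labels: list[str]           # per-sample low | high | excluded

    def mask(self, which: str) -> np.ndarray:
        return np.array([l == which for l in self.labels])


def map_variants_to_network(
    variants: list[VariantRecord],
    genes: list[GeneAnnotation],
    network: str,
    flank: int = DEFAULT_FLANK,
) -> list[VariantRecord]:
    """Keep variants lying within ``[start - flank, end + flank]`` (1-based
    inclusive, lower bound clamped at 1) of >= 1 gene of the given module.

    A variant inside several overlapping gene windows appears once.
    """
    net_genes = [g for g in genes if g.module == network]
    if not net_genes:
        raise DataError(f"network {network!r} has no genes in the annotation")
    windows: dict[str, list[tuple[int, int]]] = {}
    for g in net_genes:
        windows.setdefault(g.chrom, []).append((max(1, g.start - flank), g.end + flank))
    kept = []
    for v in variants:
        for lo, hi in windows.get(v.chrom, ()):
            if lo <= v.pos <= hi:
                kept.append(v)
                break
    return kept


def filter_variants(
    variants: list[VariantRecord],
    p_thresh: float = DEFAULT_P_THRESH,
    maf_min: float = DEFAULT_MAF_MIN,
    rsq_min: float = DEFAULT_RSQ_MIN,
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Significance / MAF / imputation-quality filters.

    The significance filter is a strict inequality (p < p_thresh); the MAF
    rule removes maf < maf_min (so maf == maf_min is kept) and the imputation
    rule removes imp_r2 < rsq_min. Returns the survivors and a per-stage
    removal count report. An empty result is a warning, not an error: the
    score is then identically 0.
    """
    report = {"input": len(variants)}
    after_p = [v for v in variants if v.p < p_thresh]
    report["removed_p"] = len(variants) - len(after_p)
    after_maf = [v for v in after_p if v.maf >= maf_min]
    report["removed_maf"] = len(after_p) - len(after_maf)
    after_rsq = [v for v in after_maf if v.imp_r2 >= rsq_min]
    report["removed_imp_r2"] = len(after_maf) - len(after_rsq)
    report["kept"] = len(after_rsq)
    if not after_rsq:
        warnings.warn("no variants survive filtering; nbPRS will be 0 for all samples")
    return after_rsq, report


def _genomic_order(variants):
    return sorted(variants, key=lambda v: (v.chrom, v.pos, v.id))


def ld_prune(
    genotypes: GenotypeMatrix,
    variants: list[VariantRecord],
    r2_max: float = DEFAULT_LD_R2_MAX,
) -> list[VariantRecord]:
    """Greedy LD pruning on dosage r^2.

    Candidates are ranked by ascending GWAS p (ties broken by position, then
    id). The best-ranked remaining variant is kept and every remaining
    same-chromosome variant with r^2 > r2_max against it is removed; repeat.
    Output is returned in genomic order. Zero-variance dosage vectors have
    undefined r^2 and are removed with a warning.
    """
    cols = {}
    usable = []
    for v in variants:
        if v.id not in genotypes.variant_ids:
            raise DataError(f"variant {v.id} missing from genotype matrix")
        g = genotypes.column(v.id)
        if np.std(g) == 0:
            warnings.warn(f"variant {v.id} has zero dosage variance; removed from pruning")
            continue
        cols[v.id] = g - g.mean()
        usable.append(v)
    ranked = sorted(usable, key=lambda v: (v.p, v.pos, v.id))
    kept, removed = [], set()
    for v in ranked:
        if v.id in removed:
            continue
        kept.append(v)
        gv = cols[v.id]
        denom_v = np.dot(gv, gv)
        for w in ranked:
            if w.id in removed or w.id == v.id or w.chrom != v.chrom:
                continue
            gw = cols[w.id]
            r2 = np.dot(gv, gw) ** 2 / (denom_v * np.dot(gw, gw))
            if r2 > r2_max:
                removed.add(w.id)
        removed.add(v.id)  # mark processed
    return _genomic_order(kept)


def compute_nbprs(
    genotypes: GenotypeMatrix,
    selected: list[VariantRecord],
    network: str = "network",
) -> NbprsResult:
    """Weighted dosage sum over the selected variants.

    Weights are oriented so beta >= 0: a negative beta is flipped together
    with its dosage (g -> 2 - g), leaving the score invariant. When the
    genotype matrix carries allele labels, a variant whose effect allele is
    the matrix's *other* allele gets its dosage flipped; any other allele
    disagreement drops the variant with a warning.
    """
    n = len(genotypes.sample_ids)
    scores = np.zeros(n)
    used: list[tuple[VariantRecord, float]] = []
    dropped = 0
    for v in selected:
        if v.id not in genotypes.variant_ids:
            raise DataError(f"selected variant {v.id} missing from genotype matrix")
        g = genotypes.column(v.id)
        if v.id in genotypes.alleles:
            counted, other = genotypes.alleles[v.id]
            if v.effect_allele == counted and v.other_allele == other:
                pass
            elif v.effect_allele == other and v.other_allele == counted:
                g = 2.0 - g
            else:
                warnings.warn(
                    f"variant {v.id}: alleles {v.effect_allele}/{v.other_allele} do not "
                    f"match genotype alleles {counted}/{other}; dropped"
                )
                dropped += 1
                continue
        beta = v.beta
        if beta < 0:  # risk-allele orientation
            beta, g = -beta, 2.0 - g
        scores += beta * g
        used.append((v, beta))
    if not used:
        warnings.warn("no selected variants usable; nbPRS is 0 for all samples")
    return NbprsResult(
        network=network,
        sample_ids=list(genotypes.sample_ids),
        sample_scores=scores,
        selected_variants=used,
        filter_report={"selected": len(selected), "used": len(used),
                       "dropped_allele_mismatch": dropped},
    )


def stratify(scores: np.ndarray, scheme: str = "quartile") -> RiskStratification:
    """Assign low/high/excluded risk labels by empirical quantile cutpoints.

    Quantiles use the linear-interpolation definition. Median: score <=
    median -> low, else high. Quartile: score <= Q1 -> low, score >= Q3 ->
    high, strictly between -> excluded; tertile analogously with T1/T2.
    Boundary samples fall inclusively into the extreme groups so those groups
    stay non-empty under ties.
    """
    scores = np.asarray(scores, dtype=float)
    if scheme not in ("median", "tertile", "quartile"):
        raise DataError(f"unknown stratification scheme {scheme!r}")
    if len(scores) < 8:
        raise DataError("stratification needs at least 8 samples")
    if np.ptp(scores) == 0:
        raise DataError("all scores identical; quantile stratification is degenerate")
    if scheme == "median":
        cut = [float(np.quantile(scores, 0.5))]
        labels = ["low" if s <= cut[0] else "high" for s in scores]
    elif scheme == "quartile":
        q1, q3 = np.quantile(scores, [0.25, 0.75])
        cut = [float(q1), float(q3)]
        labels = ["low" if s <= q1 else "high" if s >= q3 else "excluded" for s in scores]
    else:
        t1, t2 = np.quantile(scores, [1 / 3, 2 / 3])
        cut = [float(t1), float(t2)]
        labels = ["low" if s <= t1 else "high" if s >= t2 else "excluded" for s in scores]
    strat = RiskStratification(scheme=scheme, cutpoints=cut, labels=labels)
    if not strat.mask("low").any() or not strat.mask("high").any():
        raise DataError("degenerate stratification: an extreme group is empty")
    return strat


def build_nbprs(
    variants: list[VariantRecord],
    genes: list[GeneAnnotation],
    genotypes: GenotypeMatrix,
    network: str,
    flank: int = DEFAULT_FLANK,
    p_thresh: float = DEFAULT_P_THRESH,
    maf_min: float = DEFAULT_MAF_MIN,
    rsq_min: float = DEFAULT_RSQ_MIN,
    r2_max: float = DEFAULT_LD_R2_MAX,
) -> NbprsResult:
    """Full pipeline: map -> filter -> LD-prune -> score.

    The order is fixed: mapping and the cheap threshold filters run before
    pruning because pruning depends on which candidates remain.
    """
    mapped = map_variants_to_network(variants, genes, network, flank)
    filtered, report = filter_variants(mapped, p_thresh, maf_min, rsq_min)
    pruned = ld_prune(genotypes, filtered, r2_max) if filtered else []
    result = compute_nbprs(genotypes, pruned, network=network)
    result.filter_report = {
        "mapped": len(mapped), **report,
        "removed_ld": len(filtered) - len(pruned),
        **result.filter_report,
    }
    return result
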
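"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates, at configurable scale:

* **LD-blocked genotypes** — variants arranged in blocks; within a block two
  latent AR(1) Gaussian haplotypes are thresholded per-variant at the MAF
  quantile and summed into a 0/1/2 dosage (a Gaussian copula), so block
  correlation strength maps directly onto dosage r^2 and LD pruning has
  something real to prune. Blocks are independent of each other and each
  block is laid out inside exactly one gene body on a single pseudo
  chromosome.
* **Risk-concentrated GWAS** — a configurable fraction of variants inside
  network-gene bodies carry a positive effect (risk-allele orientation);
  everything else is null with uniform p.
* **Two-tissue module-structured expression** — one latent factor per module
  per sample, shared across tissues only for the preserved modules; genes
  load on their module factor with Uniform(0.4, 0.9) loadings.
* **Proportional-hazards survival** — Weibull event times with the hazard
  multiplied by ``hr_true`` for the high stratum, plus independent uniform
  censoring calibrated to the requested censoring fraction.
* **Expression-correlated traits** — positive-control traits built from the
  mean expression of a chosen subnetwork plus pure-noise negative controls.

Every generator is deterministic given (config, seed) and exposes its ground
truth (causal variants, true HR, preserved modules, trait loadings) so
recovery tests can grade the pipeline against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import (
    DataError,
    ExpressionMatrix,
    GeneAnnotation,
    GenotypeMatrix,
    VariantRecord,
)

_GENE_SPACING = 100_000
_GENE_LENGTH = 20_000


@dataclass
class SyntheticConfig:
    """Knobs for the synthetic cohort; defaults give a mid-sized study with a
    clearly preserved, AD-associated M14-like network."""

    n_samples: int = 2000
    n_blocks: int = 40
    snps_per_block: int = 8
    rho: float = 0.8                      # AR(1) latent correlation within a block
    maf_range: tuple = (0.05, 0.5)
    n_genes: int = 300
    modules: dict = field(default_factory=lambda: {"M14": 60, "M2": 40})
    frac_causal: float = 0.3
    beta_sd: float = 0.15                 # log-odds scale
    n_gwas: int = 10_000                  # pseudo-GWAS n for p-value conversion
    hr_true: float = 2.0
    baseline_hazard: tuple = (1.5, 15.0)  # Weibull shape, scale (years)
    censor_rate: float = 0.8
    module_ad_effect: float = 0.5         # eigengene shift per unit of driver
    preserve_modules: list = field(default_factory=lambda: ["M14"])
    trait_loading: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_causal", "censor_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise DataError(f"{name} must lie in [0, 1], got {v}")
        if not (0 <= self.rho < 1):
            raise DataError(f"rho must lie in [0, 1), got {self.rho}")
        if self.hr_true <= 0:
            raise DataError(f"hr_true must be positive, got {self.hr_true}")
        if sum(self.modules.values()) > self.n_genes:
            raise DataError("module gene counts exceed n_genes")
        if self.n_blocks > self.n_genes:
            raise DataError("need at least one gene per block")


def make_genes(config: SyntheticConfig) -> list[GeneAnnotation]:
    """Genes tiled along one pseudo-chromosome; the first genes belong to the
    configured modules (in insertion order), the remainder are unassigned
    background."""
    genes = []
    labels: list[str | None] = []
    for mod, count in config.modules.items():
        labels.extend([mod] * count)
    labels.extend([None] * (config.n_genes - len(labels)))
    for i, mod in enumerate(labels):
        start = i * _GENE_SPACING + 10_000
        genes.append(GeneAnnotation(
            gene_id=f"G{i:04d}", chrom="1", start=start,
            end=start + _GENE_LENGTH, module=mod,
        ))
    return genes


def simulate_genotypes(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, list[VariantRecord]]:
    """Gaussian-copula LD-block genotypes.

    Each of two latent haplotypes per sample is a block-wise AR(1) Gaussian;
    an allele is carried when the latent value falls below the per-variant
    MAF quantile, so marginal allele frequencies equal the drawn MAFs and
    within-block dosage correlation increases monotonically with ``rho``.
    Block *b*'s variants are placed inside gene *b*'s body.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    genes = make_genes(config)
    n, k = config.n_samples, config.snps_per_block
    records: list[VariantRecord] = []
    dosage_cols = []
    for b in range(config.n_blocks):
        gene = genes[b]
        mafs = rng.uniform(*config.maf_range, size=k)
        thresh = stats.norm.ppf(mafs)
        # two haplotypes, each an AR(1) chain across the block
        hap_dos = np.zeros((n, k))
        for _ in range(2):
            z = np.empty((n, k))
            z[:, 0] = rng.standard_normal(n)
            for j in range(1, k):
                z[:, j] = config.rho * z[:, j - 1] + np.sqrt(1 - config.rho ** 2) * rng.standard_normal(n)
            hap_dos += (z < thresh[None, :]).astype(float)
        dosage_cols.append(hap_dos)
        positions = np.linspace(gene.start + 100, gene.end - 100, k).astype(int)
        for j in range(k):
            records.append(VariantRecord(
                id=f"rs{b:03d}_{j:02d}", chrom=gene.chrom, pos=int(positions[j]),
                effect_allele="A", other_allele="G",
                beta=0.0, p=1.0, maf=float(mafs[j]), imp_r2=1.0,
            ))
    dosage = np.concatenate(dosage_cols, axis=1)
    sample_ids = [f"S{i:05d}" for i in range(n)]
    gm = GenotypeMatrix(sample_ids, [r.id for r in records], dosage,
                        {r.id: ("A", "G") for r in records})
    return gm, records


def simulate_gwas(
    variants: list[VariantRecord],
    genes: list[GeneAnnotation],
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> list[VariantRecord]:
    """Fill in beta and p.

    A fraction ``frac_causal`` of variants inside module-gene bodies get
    beta ~ |Normal(0, beta_sd^2)| (risk-allele orientation); their p is the
    two-sided normal p of z = beta / se with se = 1/sqrt(2 maf (1-maf)
    n_gwas). All other variants are null: beta = 0 and p ~ Uniform(0, 1).
    Ground truth is recoverable as beta != 0.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    net_bodies = [(g.chrom, g.start, g.end) for g in genes if g.module is not None]

    def in_network(v):
        return any(c == v.chrom and s <= v.pos <= e for c, s, e in net_bodies)

    out = []
    for v in variants:
        causal = in_network(v) and rng.uniform() < config.frac_causal
        if causal:
            beta = abs(rng.normal(0.0, config.beta_sd))
            se = 1.0 / np.sqrt(2 * v.maf * (1 - v.maf) * config.n_gwas)
            p = float(2 * stats.norm.sf(beta / se))
            p = max(p, 1e-300)
        else:
            beta = 0.0
            p = float(rng.uniform())
            p = max(p, 1e-300)
        out.append(VariantRecord(
            id=v.id, chrom=v.chrom, pos=v.pos,
            effect_allele=v.effect_allele, other_allele=v.other_allele,
            beta=beta, p=p, maf=v.maf, imp_r2=v.imp_r2,
        ))
    return out


def simulate_expression(
    config: SyntheticConfig,
    eigengene_drivers: dict[str, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
    n_samples: int | None = None,
) -> tuple[dict[str, ExpressionMatrix], dict]:
    """Two-tissue factor-model expression.

    Per module *m* and tissue, a per-sample latent factor ``f_m``; preserved
    modules share one factor across tissues, non-preserved modules draw
    independent factors. A driver (e.g. standardized nbPRS or AD status)
    adds ``module_ad_effect * driver`` to the module factor. Gene *g* in *m*
    is ``loading_g * f_m + sqrt(1 - loading_g^2) * noise`` with loadings
    Uniform(0.4, 0.9); background genes are pure noise.
    Returns {"blood": ..., "brain": ...} and a ground-truth dict.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    n = n_samples if n_samples is not None else config.n_samples
    genes = make_genes(config)
    sample_ids = [f"S{i:05d}" for i in range(n)]
    module_genes: dict[str, list[str]] = {}
    for g in genes:
        if g.module is not None:
            module_genes.setdefault(g.module, []).append(g.gene_id)

    shared = {m: rng.standard_normal(n) for m in config.modules}
    loadings = {m: rng.uniform(0.4, 0.9, size=len(gl)) for m, gl in module_genes.items()}
    truth = {"preserve_modules": list(config.preserve_modules),
             "module_ad_effect": config.module_ad_effect,
             "loadings": loadings}
    matrices = {}
    factors_by_tissue = {}
    for tissue in ("blood", "brain"):
        vals = rng.standard_normal((config.n_genes, n))  # background noise
        factors = {}
        for m, gl in module_genes.items():
            f = shared[m] if m in config.preserve_modules else rng.standard_normal(n)
            if eigengene_drivers and m in eigengene_drivers:
                d = np.asarray(eigengene_drivers[m], dtype=float)
                f = f + config.module_ad_effect * (d - d.mean()) / (d.std() or 1.0)
            factors[m] = f
            lo = loadings[m]
            idx = [int(g[1:]) for g in gl]
            noise = rng.standard_normal((len(gl), n))
            vals[idx, :] = lo[:, None] * f[None, :] + np.sqrt(1 - lo ** 2)[:, None] * noise
        factors_by_tissue[tissue] = factors
        matrices[tissue] = ExpressionMatrix(
            [g.gene_id for g in genes], sample_ids, vals, tissue=tissue,
        )
    truth["factors"] = factors_by_tissue
    return matrices, truth


def _calibrate_uniform_censor(times: np.ndarray, censor_rate: float) -> float:
    """Upper bound c of Uniform(0, c) censoring giving ~censor_rate censored.

    P(C < T) = E[min(T/c, 1)] is decreasing in c; solve by bisection on the
    empirical times.
    """
    if censor_rate <= 0:
        return float(np.inf)
    lo, hi = 1e-6, float(times.max()) * 100
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        frac = float(np.minimum(times / mid, 1.0).mean())
        if frac > censor_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_survival(
    indicator: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    baseline_ages: np.ndarray | None = None,
):
    """Weibull proportional-hazards event times for a 0/1 stratum indicator.

    Hazard for the high stratum is multiplied by ``hr_true``; inverting the
    Weibull survival function gives t = scale * (-log U / hr^x)^(1/shape).
    Independent Uniform(0, c) censoring with c calibrated to the requested
    censoring fraction. Returns (time, event, event_age) with event_age =
    baseline age + time.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed + 3)
    indicator = np.asarray(indicator, dtype=float)
    n = len(indicator)
    shape, scale = config.baseline_hazard
    u = rng.uniform(size=n)
    times = scale * (-np.log(u) / config.hr_true ** indicator) ** (1.0 / shape)
    if config.censor_rate > 0:
        c = _calibrate_uniform_censor(times, config.censor_rate)
        censor = rng.uniform(0, c, size=n)
        event = (times <= censor).astype(int)
        obs = np.minimum(times, censor)
    else:
        event = np.ones(n, dtype=int)
        obs = times
    if baseline_ages is None:
        baseline_ages = rng.normal(70.0, 5.0, size=n)
    return obs, event, baseline_ages + obs


def simulate_traits(
    expr: ExpressionMatrix,
    subnetwork_genes: list[str],
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    n_noise_traits: int = 3,
):
    """Positive-control trait from subnetwork mean expression + noise traits.

    trait_pos = trait_loading * mean(subnetwork expression per sample) +
    Normal(0, 1) noise; ``n_noise_traits`` additional pure-noise columns act
    as negative controls. Returns (DataFrame-like dict of columns, truth).
    """
    import pandas as pd

    if not subnetwork_genes:
        raise DataError("subnetwork gene list is empty")
    missing = [g for g in subnetwork_genes if g not in expr.gene_ids]
    if missing:
        raise DataError(f"subnetwork genes absent from expression: {missing}")
    rng = rng or np.random.default_rng(config.seed + 4)
    idx = [expr.gene_ids.index(g) for g in subnetwork_genes]
    base = expr.values[idx].mean(axis=0)
    n = len(expr.sample_ids)
    cols = {"trait_pos": config.trait_loading * base + rng.standard_normal(n)}
    for i in range(n_noise_traits):
        cols[f"trait_null{i}"] = rng.standard_normal(n)
    df = pd.DataFrame(cols, index=expr.sample_ids)
    df.index.name = "sample_id"
    truth = {"trait_loading": config.trait_loading, "subnetwork": list(subnetwork_genes)}
    return df, truth


def simulate_cohort(config: SyntheticConfig) -> dict:
    """Convenience end-to-end draw used by the pipeline and tests.

    Generates genotypes, GWAS, nbPRS ground truth strata, expression driven
    by the standardized score, survival, and traits — all from one seed.
    Returns a dict of artifacts plus a ``truth`` sub-dict.
    """
    from . import score as score_mod

    config.validate()
    rng = np.random.default_rng(config.seed)
    genotypes, variants = simulate_genotypes(config, rng)
    genes = make_genes(config)
    gwas = simulate_gwas(variants, genes, config, rng)
    network = next(iter(config.modules))
    result = score_mod.build_nbprs(gwas, genes, genotypes, network)
    strat = score_mod.stratify(result.sample_scores, "quartile")
    z = (result.sample_scores - result.sample_scores.mean())
    z = z / (z.std() or 1.0)
    exprs, expr_truth = simulate_expression(config, {network: z}, rng)
    high = strat.mask("high").astype(float)
    time, event, event_age = simulate_survival(high, config, rng)
    causal = [v.id for v in gwas if v.beta != 0]
    return {
        "genotypes": genotypes, "gwas": gwas, "genes": genes,
        "nbprs": result, "stratification": strat,
        "expression": exprs, "time": time, "event": event, "event_age": event_age,
        "truth": {"causal_variants": causal, "hr_true": config.hr_true,
                  **expr_truth},
    }
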
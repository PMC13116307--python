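"""Downstream biology: endophenotype logistic associations, rank-transformed
neuropathology trait profiling, and hypergeometric gene-set enrichment of
up/down differentially expressed gene lists.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .io_formats import DataError, ExpressionMatrix

_BLOM_OFFSET = 3.0 / 8.0


def associate_endophenotype(
    trait: np.ndarray,
    strata: np.ndarray,
    covariates: pd.DataFrame | None = None,
):
    """Logistic regression of the high-risk stratum on a standardized trait.

    The trait is scaled to unit variance so the odds ratio is per SD.
    Returns (odds_ratio, (ci_lo, ci_hi), p). Perfect separation raises.
    """
    y = np.asarray(strata, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise DataError("strata must be a 0/1 indicator (high = 1)")
    t = np.asarray(trait, dtype=float)
    sd = t.std(ddof=0)
    if sd == 0:
        raise DataError("constant trait")
    t = (t - t.mean()) / sd
    X = t[:, None]
    if covariates is not None:
        X = np.column_stack([X, np.asarray(covariates, dtype=float)])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            model = sm.Logit(y, sm.add_constant(X)).fit(disp=0, maxiter=100)
    except (PerfectSeparationError, RuntimeWarning, np.linalg.LinAlgError) as err:
        raise DataError(f"logistic fit failed (separation or collinearity): {err}")
    if not model.mle_retvals.get("converged", True) or np.abs(model.params[1]) > 15:
        raise DataError("perfect separation: logistic coefficient diverges")
    beta = float(model.params[1])
    se = float(model.bse[1])
    return (
        float(np.exp(beta)),
        (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))),
        float(model.pvalues[1]),
    )


def adjust_and_rank_trait(
    trait: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
) -> np.ndarray:
    """Covariate-adjusted rank-based inverse-normal transform of a trait.

    The trait is residualized on age and sex (OLS over non-missing values),
    ranked with average ranks for ties, and mapped through
    Phi^-1((r - 3/8) / (n + 1/4)) (the Blom offset). Missing values stay
    missing in the output.
    """
    trait = np.asarray(trait, dtype=float)
    ok = np.isfinite(trait) & np.isfinite(age) & np.isfinite(sex)
    if ok.sum() < 10:
        raise DataError(f"need >= 10 non-missing values, have {int(ok.sum())}")
    if np.ptp(trait[ok]) == 0:
        raise DataError("constant trait: rank transform is degenerate")
    X = sm.add_constant(np.column_stack([np.asarray(age, float)[ok],
                                         np.asarray(sex, float)[ok]]))
    resid = trait[ok] - X @ np.linalg.lstsq(X, trait[ok], rcond=None)[0]
    ranks = stats.rankdata(resid, method="average")
    n = len(ranks)
    quantiles = stats.norm.ppf((ranks - _BLOM_OFFSET) / (n + 1 - 2 * _BLOM_OFFSET))
    out = np.full(len(trait), np.nan)
    out[ok] = quantiles
    return out


def _tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def associate_expression_trait(
    expr: ExpressionMatrix,
    transformed_trait: np.ndarray,
    covariates: pd.DataFrame | None = None,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene OLS of the transformed trait on expression (+ covariates).

    Returns a frame with gene, beta, p and a significance tier matching the
    conventional ***/**/* cutoffs at 0.001/0.01/0.05.
    """
    t = np.asarray(transformed_trait, dtype=float)
    ok = np.isfinite(t)
    if ok.sum() < 10:
        raise DataError(f"need >= 10 overlapping samples, have {int(ok.sum())}")
    genes = genes if genes is not None else expr.gene_ids
    rows = []
    cov = np.asarray(covariates, dtype=float)[ok] if covariates is not None else None
    for g in genes:
        x = expr.values[expr.gene_ids.index(g)][ok]
        X = x[:, None] if cov is None else np.column_stack([x, cov])
        model = sm.OLS(t[ok], sm.add_constant(X)).fit()
        beta, p = float(model.params[1]), float(model.pvalues[1])
        rows.append({"gene": g, "beta": beta, "p": p, "tier": _tier(p)})
    return pd.DataFrame(rows)


def enrich(
    gene_list: list[str],
    gene_sets: dict[str, list[str]],
    universe: list[str],
    direction: str = "up",
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a gene list against gene sets.

    Sets are intersected with the universe; a set with empty intersection is
    skipped with a warning. The upper-tail p is P(X >= overlap) for X
    hypergeometric(universe, set, list); BH adjustment is applied across the
    surviving sets. ``gene_list`` must be a subset of ``universe``.
    """
    uni = set(universe)
    lst = set(gene_list)
    if not lst <= uni:
        raise DataError(f"gene list members outside the universe: {sorted(lst - uni)[:5]}")
    rows = []
    for name, members in gene_sets.items():
        inset = set(members) & uni
        if not inset:
            warnings.warn(f"gene set {name!r} has no overlap with the universe; skipped")
            continue
        overlap = len(inset & lst)
        p = float(stats.hypergeom.sf(overlap - 1, len(uni), len(inset), len(lst)))
        rows.append({
            "set_name": name, "overlap": overlap, "set_size": len(inset),
            "list_size": len(lst), "universe_size": len(uni),
            "p_hyper": min(p, 1.0), "direction": direction,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["q_bh"] = multipletests(df["p_hyper"], method="fdr_bh")[1]
    else:
        df["q_bh"] = pd.Series(dtype=float)
    return df
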
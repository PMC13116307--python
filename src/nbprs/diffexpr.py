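"""Per-gene differential expression between low- and high-nbPRS strata with
empirical-Bayes variance moderation, and sample-size-weighted Z meta-analysis
across studies.

The moderation follows the standard empirical-Bayes scheme for gene-wise
linear models: residual variances s_g^2 with df_g degrees of freedom are
assumed scaled-chi-squared around a prior s0^2 with d0 prior degrees of
freedom; (d0, s0^2) are estimated by matching the first two moments of
log s_g^2 (digamma/trigamma relations, trigamma inverse by Newton), and the
posterior variance

    s~_g^2 = (d0 s0^2 + df_g s_g^2) / (d0 + df_g)

replaces s_g^2 in the t-statistic, which then has df_g + d0 degrees of
freedom. When the observed spread of log s^2 is no larger than expected by
chance, d0 = +inf and every gene is shrunk fully to the common value.

The meta-analysis combines per-study signed z-scores with square-root
sample-size weights:

    z_i = sign(logFC_i) * Phi^-1(1 - p_i / 2),   w_i = sqrt(n_i)
    Z = sum(w_i z_i) / sqrt(sum(w_i^2))

Study n is, by default, the number of samples actually contrasted (low +
high group sizes); the full-cohort convention is available via the weights
argument since both appear in practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_formats import DataError, ExpressionMatrix

_P_FLOOR = 1e-300


@dataclass
class GeneFits:
    """Per-gene OLS results for one study: the stratum coefficient (logFC on
    the log2 expression scale), residual variance, shared residual df, and
    the unscaled variance factor of the stratum contrast."""

    genes: list[str]
    beta: np.ndarray
    s2: np.ndarray
    df_resid: float
    contrast_var_factor: float
    n: int


def _design_matrix(stratum: np.ndarray, covariates: pd.DataFrame | None):
    x = np.asarray(stratum, dtype=float)
    cols = [np.ones_like(x), x]
    names = ["intercept", "stratum"]
    if covariates is not None:
        for c in covariates.columns:
            cols.append(np.asarray(covariates[c], dtype=float))
            names.append(str(c))
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify the offending columns for the error message
        bad = []
        for j in range(2, X.shape[1]):
            sub = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(names[j])
        raise DataError(f"rank-deficient design; collinear column(s): {bad or names}")
    return X, names


def fit_gene_models(
    expr: ExpressionMatrix,
    stratum: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> GeneFits:
    """Ordinary least squares of every gene on the stratum indicator
    (high = 1) plus covariates, vectorized across genes."""
    X, _ = _design_matrix(stratum, covariates)
    n, p = X.shape
    if n != len(expr.sample_ids):
        raise DataError("stratum/covariate length does not match expression samples")
    if n <= p + 1:
        raise DataError(f"too few samples ({n}) for {p} design columns")
    Y = expr.values.T                       # samples x genes
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ X.T @ Y                # p x genes
    resid = Y - X @ coef
    df = n - p
    s2 = (resid ** 2).sum(axis=0) / df
    return GeneFits(
        genes=list(expr.gene_ids), beta=coef[1], s2=s2, df_resid=float(df),
        contrast_var_factor=float(xtx_inv[1, 1]), n=n,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton on the monotone function."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from the ensemble of log residual variances.

    Returns (d0, s0sq); d0 = inf means the spread of log s^2 is fully
    explained by chi-squared sampling noise and variances are pooled.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 10:
        raise DataError("need >= 10 genes with positive residual variance")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    n = len(e)
    ebar = float(e.mean())
    evar = float(((e - ebar) ** 2).sum() / (n - 1))
    excess = evar - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        # spread of log s^2 explained by sampling noise alone: full pooling.
        # The pooled value is the geometric mean, so that in the degenerate
        # all-equal case the moderated t reduces to the ordinary t exactly.
        d0 = np.inf
        s0sq = float(np.exp(z.mean()))
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0sq = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


def ebayes_moderate(fits: GeneFits, study: str = "", n_study: int | None = None) -> pd.DataFrame:
    """Moderated t-statistics and p-values for one study's gene fits.

    Columns: gene, logFC, t_mod, p, df_total, s2_post, study, n_study.
    """
    if len(fits.genes) < 10:
        raise DataError("empirical-Bayes moderation needs >= 10 genes")
    d0, s0sq = estimate_prior(fits.s2, fits.df_resid)
    df_g = fits.df_resid
    if np.isinf(d0):
        s2_post = np.full_like(fits.s2, s0sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0sq + df_g * fits.s2) / (d0 + df_g)
        df_total = df_g + d0
    t_mod = fits.beta / np.sqrt(s2_post * fits.contrast_var_factor)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2 * stats.t.sf(np.abs(t_mod), df_total)
    return pd.DataFrame({
        "gene": fits.genes, "logFC": fits.beta, "t_mod": t_mod,
        "p": np.maximum(p, _P_FLOOR),
        "df_total": df_total, "s2_post": s2_post,
        "study": study, "n_study": n_study if n_study is not None else fits.n,
    })


def signed_z(logfc: float, p: float) -> float:
    """Two-sided p and effect direction -> signed normal quantile."""
    if not (0 <= p <= 1):
        raise DataError(f"p-value {p} outside [0, 1]")
    if p == 0:
        warnings.warn("p of 0 clipped to 1e-300 for z conversion")
        p = _P_FLOOR
    return float(np.sign(logfc) * stats.norm.isf(p / 2.0))


def meta_sample_weighted(
    study_results: list[pd.DataFrame],
    study_ns: list[float] | None = None,
) -> pd.DataFrame:
    """Sample-size-weighted Z meta-analysis across studies.

    Each element of ``study_results`` needs columns gene, logFC, p (the
    ebayes_moderate output qualifies). ``study_ns`` overrides the per-study
    n (defaults to each frame's n_study column). Genes are combined over
    the studies that report them. Output columns: gene, z_meta, p_meta,
    studies_used, direction_string.
    """
    if not study_results:
        raise DataError("no study results supplied")
    if study_ns is not None and len(study_ns) != len(study_results):
        raise DataError("study_ns length must match study_results")
    per_gene: dict[str, list[tuple[float, float, str]]] = {}
    order: list[str] = []
    for i, df in enumerate(study_results):
        if study_ns is not None:
            n_i = float(study_ns[i])
        elif "n_study" in df.columns:
            n_i = float(df["n_study"].iloc[0])
        else:
            raise DataError(f"study {i}: no sample size available")
        if n_i <= 0:
            raise DataError(f"study {i}: non-positive sample size {n_i}")
        label = str(df["study"].iloc[0]) if "study" in df.columns else f"study{i}"
        for row in df.itertuples(index=False):
            g = str(row.gene)
            if g not in per_gene:
                per_gene[g] = []
                order.append(g)
            per_gene[g].append((signed_z(float(row.logFC), float(row.p)), n_i, label))
    rows = []
    for g in order:
        entries = per_gene[g]
        z = np.array([e[0] for e in entries])
        w = np.sqrt(np.array([e[1] for e in entries]))
        z_meta = float(np.sum(w * z) / np.sqrt(np.sum(w ** 2)))
        p_meta = float(max(2 * stats.norm.sf(abs(z_meta)), _P_FLOOR))
        rows.append({
            "gene": g, "z_meta": z_meta, "p_meta": p_meta,
            "studies_used": ",".join(e[2] for e in entries),
            "direction_string": "".join("+" if zi >= 0 else "-" for zi in z),
        })
    return pd.DataFrame(rows)


def volcano_table(
    results: pd.DataFrame,
    logfc_col: str = "logFC",
    p_col: str = "p",
    p_thresh: float = 1e-3,
) -> tuple[pd.DataFrame, dict]:
    """Flag genes up/down/neutral at the significance threshold; report counts."""
    out = results.copy()
    if len(out) == 0:
        out["flag"] = pd.Series(dtype=str)
        return out, {"up": 0, "down": 0, "neutral": 0}
    sig = out[p_col] < p_thresh
    out["flag"] = np.where(sig & (out[logfc_col] > 0), "up",
                           np.where(sig & (out[logfc_col] < 0), "down", "neutral"))
    counts = out["flag"].value_counts().to_dict()
    return out, {"up": counts.get("up", 0), "down": counts.get("down", 0),
                 "neutral": counts.get("neutral", 0)}
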
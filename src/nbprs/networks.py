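"""Module eigengenes, eigengene-phenotype association, and a simplified
cross-tissue module-preservation Z-summary.

The eigengene of a module is the first principal component of its genes'
expression across samples (genes standardized first), standardized and
sign-oriented so it correlates positively with mean module expression. A
network is called AD-associated when the eigengene's regression on case
status (adjusting for age and sex) has p < 0.05.

Preservation is summarized by two permutation z-statistics: *density*
(mean off-diagonal |cor| among module genes in the test tissue) and
*connectivity* (correlation of intramodular connectivity between reference
and test tissue), each z-scored against random same-size gene sets, with
Z_summary their mean. Z_summary > 5 is the conventional preserved-module
threshold. This is a deliberately simplified two-statistic composite: only
the threshold decision is consumed downstream, and the threshold is a
parameter, not a constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .io_formats import DataError, ExpressionMatrix

PRESERVED_ZSUMMARY = 5.0


@dataclass
class Eigengene:
    module: str
    sample_values: np.ndarray          # mean 0, sd 1
    explained_variance_fraction: float
    orientation_sign: int


@dataclass
class PreservationResult:
    module: str
    z_density: float
    z_connectivity: float
    z_summary: float
    n_perm: int
    seed: int


def _standardize_rows(values: np.ndarray, gene_ids: list[str]):
    sd = values.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(gene_ids, keep) if not k]
        warnings.warn(f"zero-variance gene(s) dropped: {dropped}")
    vals = values[keep]
    vals = (vals - vals.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return vals, [g for g, k in zip(gene_ids, keep) if k]


def compute_eigengene(expr: ExpressionMatrix, module_genes: list[str], module: str = "") -> Eigengene:
    """First principal component of the module's standardized expression.

    Scores are standardized to mean 0, sd 1 across samples. The sign is
    chosen so the eigengene correlates non-negatively with the mean module
    expression profile; if that correlation is exactly zero (an
    antisymmetric module), the tie breaks toward positive correlation with
    the first listed gene.
    """
    present = [g for g in module_genes if g in expr.gene_ids]
    if len(present) < 2:
        raise DataError(f"module {module or module_genes}: need >= 2 genes in expression")
    idx = [expr.gene_ids.index(g) for g in present]
    vals, kept = _standardize_rows(expr.values[idx], present)
    if vals.shape[0] < 2:
        raise DataError("fewer than 2 usable genes after dropping zero-variance rows")
    # SVD of genes x samples: right singular vector = sample scores
    u, s, vt = np.linalg.svd(vals, full_matrices=False)
    scores = vt[0]
    evf = float(s[0] ** 2 / np.sum(s ** 2))
    scores = (scores - scores.mean()) / scores.std(ddof=0)
    mean_profile = vals.mean(axis=0)
    c = float(np.dot(scores, mean_profile))
    if abs(c) < 1e-10:                       # orientation tie-break
        c = float(np.dot(scores, vals[0]))
    sign = -1 if c < 0 else 1
    return Eigengene(module=module, sample_values=sign * scores,
                     explained_variance_fraction=evf, orientation_sign=sign)


def associate_eigengene(
    eigengene: Eigengene,
    status: np.ndarray,
    covariates: np.ndarray | None = None,
    alpha: float = 0.05,
):
    """OLS of the eigengene on case status (+ covariates).

    Returns (effect, partial_r, p, selected): the status coefficient, the
    partial correlation of eigengene with status given covariates, the
    two-sided p, and whether the network passes the association threshold.
    """
    status = np.asarray(status, dtype=float)
    if np.ptp(status) == 0:
        raise DataError("status is constant; association undefined")
    X = status[:, None]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        X = np.column_stack([X, cov])
    model = sm.OLS(eigengene.sample_values, sm.add_constant(X)).fit()
    effect = float(model.params[1])
    t = float(model.tvalues[1])
    df = float(model.df_resid)
    partial_r = float(np.sign(t) * np.sqrt(t ** 2 / (t ** 2 + df))) if df > 0 else np.sign(t)
    p = float(model.pvalues[1])
    return effect, partial_r, p, p < alpha


def _module_stats(ref: np.ndarray, test: np.ndarray):
    """(density in test, connectivity correlation ref vs test) for one gene set."""
    cr = np.abs(np.corrcoef(ref))
    ct = np.abs(np.corrcoef(test))
    k = cr.shape[0]
    off = ~np.eye(k, dtype=bool)
    density = float(ct[off].mean())
    kim_ref = cr[off].reshape(k, k - 1).sum(axis=1)
    kim_test = ct[off].reshape(k, k - 1).sum(axis=1)
    if np.std(kim_ref) == 0 or np.std(kim_test) == 0:
        conn = 0.0
    else:
        conn = float(np.corrcoef(kim_ref, kim_test)[0, 1])
    return density, conn


def module_preservation_zsummary(
    expr_ref: ExpressionMatrix,
    expr_test: ExpressionMatrix,
    module_genes: list[str],
    n_perm: int = 200,
    seed: int = 0,
    module: str = "",
) -> PreservationResult:
    """Permutation Z-summary of module preservation between two tissues.

    Observed density and connectivity (see module docstring) are z-scored
    against ``n_perm`` random gene sets of the same size drawn from the
    genes shared by both tissues; Z_summary is the mean of the two z's.
    """
    if n_perm < 50:
        raise DataError("n_perm must be >= 50 for a usable null")
    shared = [g for g in expr_ref.gene_ids if g in set(expr_test.gene_ids)]
    present = [g for g in module_genes if g in shared]
    if len(present) < 3:
        raise DataError("module needs >= 3 genes present in both tissues")
    if len(present) > len(shared):
        raise DataError("module larger than the shared gene universe")

    ref_df = expr_ref.to_frame()
    test_df = expr_test.to_frame()

    def stats_for(genes):
        return _module_stats(ref_df.loc[genes].to_numpy(), test_df.loc[genes].to_numpy())

    obs_d, obs_c = stats_for(present)
    rng = np.random.default_rng(seed)
    shared_arr = np.array(shared)
    null_d = np.empty(n_perm)
    null_c = np.empty(n_perm)
    for i in range(n_perm):
        pick = rng.choice(shared_arr, size=len(present), replace=False)
        null_d[i], null_c[i] = stats_for(list(pick))
    zd = float((obs_d - null_d.mean()) / (null_d.std(ddof=1) or np.nan))
    zc = float((obs_c - null_c.mean()) / (null_c.std(ddof=1) or np.nan))
    return PreservationResult(
        module=module, z_density=zd, z_connectivity=zc,
        z_summary=float((zd + zc) / 2.0), n_perm=n_perm, seed=seed,
    )
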
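"""Cox proportional-hazards comparison of AD conversion between low- and
high-nbPRS strata, with the cohort exclusion rules, covariate adjustment,
cluster-robust family variance, and APOE-stratified sensitivity analyses.

Time origin is the baseline exam (time-on-study scale); baseline age enters
as a covariate. Family structure is handled as cluster-robust (grouped
sandwich) variance rather than a frailty term. Efron tie handling is the
default, Breslow is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from .io_formats import DataError


@dataclass
class CoxFit:
    log_hr: float
    se: float
    robust_se: float | None
    hr: float
    ci95: tuple
    p: float
    ties_method: str
    n_events: int
    n: int
    covariate_effects: dict


def apply_exclusions(
    pheno: pd.DataFrame,
    exclude_prevalent_ad: bool = True,
    exclude_baseline_over: float | None = 75.0,
    exclude_last_under: float | None = 65.0,
) -> tuple[pd.DataFrame, dict]:
    """Cohort exclusions for the conversion analysis.

    Three independently toggleable rules: (a) prevalent AD at baseline,
    (b) age at baseline > 75, (c) age at last exam < 65. Returns the
    retained table and per-rule removal counts.
    """
    report = {"input": len(pheno)}
    keep = pd.Series(True, index=pheno.index)
    if exclude_prevalent_ad and "diagnosis_baseline" in pheno.columns:
        rule = pheno["diagnosis_baseline"] == "AD"
        report["removed_prevalent_ad"] = int((keep & rule).sum())
        keep &= ~rule
    if exclude_baseline_over is not None and "age_baseline" in pheno.columns:
        rule = pheno["age_baseline"] > exclude_baseline_over
        report["removed_age_baseline"] = int((keep & rule).sum())
        keep &= ~rule
    if exclude_last_under is not None and "age_last" in pheno.columns:
        rule = pheno["age_last"] < exclude_last_under
        report["removed_age_last"] = int((keep & rule).sum())
        keep &= ~rule
    out = pheno[keep].copy()
    report["retained"] = len(out)
    return out, report


def _records_frame(records: pd.DataFrame, covariate_names) -> pd.DataFrame:
    df = records.copy()
    for col in ("time", "event", "stratum"):
        if col not in df.columns:
            raise DataError(f"survival records missing column {col!r}")
    if (df["time"] <= 0).any():
        raise DataError("non-positive survival times")
    df["high"] = (df["stratum"] == "high").astype(float)
    if not set(df["stratum"]) <= {"low", "high"}:
        raise DataError("stratum must be low/high (drop excluded samples first)")
    for c in covariate_names:
        if c not in df.columns:
            raise DataError(f"missing covariate column {c!r}")
    return df


def fit_cox(
    records: pd.DataFrame,
    covariate_names: list[str] | None = None,
    ties: str = "efron",
    cluster_by: str | None = None,
) -> CoxFit:
    """Cox PH fit of the high-vs-low stratum effect.

    ``records`` needs columns time, event, stratum (low/high) plus any
    covariates. With ``cluster_by``, the grouped sandwich (cluster-robust)
    standard error is used for the CI and Wald p. Raises on monotone
    likelihood (all events confined to one stratum).
    """
    covariate_names = list(covariate_names or [])
    if ties not in ("efron", "breslow"):
        raise DataError(f"ties must be efron or breslow, got {ties!r}")
    df = _records_frame(records, covariate_names)
    ev = df[df["event"] == 1]
    if len(ev) == 0 or ev["high"].nunique() < 2:
        raise DataError(
            "monotone likelihood: all events fall in one stratum "
            f"(events: high={int((ev['high'] == 1).sum())}, low={int((ev['high'] == 0).sum())})"
        )
    cols = ["time", "event", "high"] + covariate_names
    robust = cluster_by is not None
    fit_df = df[cols + ([cluster_by] if robust else [])]
    from lifelines.exceptions import ConvergenceError

    cph = CoxPHFitter()
    try:
        cph.fit(
            fit_df, duration_col="time", event_col="event",
            cluster_col=cluster_by if robust else None,
            robust=robust,
            fit_options={"precision": 1e-9, "max_steps": 500},
        )
    except (ConvergenceError, np.linalg.LinAlgError) as err:
        raise DataError(f"Cox partial-likelihood fit did not converge: {err}") from err
    # Efron and Breslow partial likelihoods coincide exactly when no event
    # times are tied; warn if a breslow request actually has ties.
    if ties == "breslow" and df.loc[df["event"] == 1, "time"].duplicated().any():
        import warnings

        warnings.warn("tied event times present; Efron weights used for breslow request")
    log_hr = float(cph.params_["high"])
    se_used = float(cph.standard_errors_["high"])
    lo, hi = log_hr - 1.96 * se_used, log_hr + 1.96 * se_used
    from scipy import stats as sps

    p = float(2 * sps.norm.sf(abs(log_hr / se_used)))
    return CoxFit(
        log_hr=log_hr, se=se_used, robust_se=se_used if robust else None,
        hr=float(np.exp(log_hr)), ci95=(float(np.exp(lo)), float(np.exp(hi))),
        p=p, ties_method=ties, n_events=int(df["event"].sum()), n=len(df),
        covariate_effects={c: float(cph.params_[c]) for c in covariate_names},
    )


def apoe_sensitivity(
    records: pd.DataFrame,
    covariate_names: list[str] | None = None,
    ties: str = "efron",
    cluster_by: str | None = None,
) -> pd.DataFrame:
    """Three sensitivity fits: APOE e4 carriers only, non-carriers only, and
    pooled with the carrier flag as a covariate.

    A subgroup in which a stratum has no events yields an NA row with the
    reason rather than an error.
    """
    covariate_names = list(covariate_names or [])
    if "apoe_e4" not in records.columns:
        raise DataError("records missing apoe_e4 carrier flag")
    rows = []
    subsets = {
        "carriers": records[records["apoe_e4"] == 1],
        "non_carriers": records[records["apoe_e4"] == 0],
        "pooled_apoe_covariate": records,
    }
    for name, sub in subsets.items():
        covs = covariate_names + (["apoe_e4"] if name.startswith("pooled") else [])
        try:
            fit = fit_cox(sub, covs, ties=ties, cluster_by=cluster_by)
            rows.append({"analysis": name, "hr": fit.hr, "ci_lo": fit.ci95[0],
                         "ci_hi": fit.ci95[1], "p": fit.p,
                         "n": fit.n, "n_events": fit.n_events, "note": ""})
        except DataError as err:
            rows.append({"analysis": name, "hr": np.nan, "ci_lo": np.nan,
                         "ci_hi": np.nan, "p": np.nan, "n": len(sub),
                         "n_events": int(sub.get("event", pd.Series(dtype=int)).sum()),
                         "note": str(err)})
    return pd.DataFrame(rows)


def km_curves(records: pd.DataFrame):
    """Kaplan-Meier estimates per stratum (Greenwood CIs) and logrank p.

    Returns (DataFrame with stratum/time/survival/ci_lo/ci_hi, logrank p).
    With no events the survival functions are identically 1 and the logrank
    p is 1.
    """
    df = _records_frame(records, [])
    frames = []
    for label, sub in df.groupby("stratum"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(label))
        sf = kmf.survival_function_
        ci = kmf.confidence_interval_survival_function_
        out = pd.DataFrame({
            "stratum": label,
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(),
            "ci_lo": ci.iloc[:, 0].to_numpy(),
            "ci_hi": ci.iloc[:, 1].to_numpy(),
        })
        frames.append(out)
    if df["event"].sum() == 0:
        p = 1.0
    else:
        lo = df[df["stratum"] == "low"]
        hi = df[df["stratum"] == "high"]
        p = float(logrank_test(lo["time"], hi["time"], lo["event"], hi["event"]).p_value)
    return pd.concat(frames, ignore_index=True), p
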
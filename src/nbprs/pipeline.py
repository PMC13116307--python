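"""Config-driven orchestration of the full synthetic analysis.

Stages run in a fixed order — (1) network selection, (2) nbPRS construction
and stratification, (3) survival, (4) differential expression / meta /
profiling — each writing its outputs plus a manifest recording parameters,
input hashes, the stage seed and the package version. A rerun with the same
config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, diffexpr, networks, profiling, score, survival, synthetic_data
from .io_formats import DataError, write_table

_SCHEMES = ("median", "tertile", "quartile")

DEFAULT_CONFIG = {
    "seed": 0,
    "n_samples": 600,
    "n_blocks": 20,
    "snps_per_block": 6,
    "rho": 0.8,
    "n_genes": 120,
    "modules": {"M14": 40, "M2": 25},
    "frac_causal": 0.3,
    "hr_true": 2.0,
    "censor_rate": 0.8,
    "module_ad_effect": 0.5,
    "network": "M14",
    "scheme": "quartile",
    "flank": 20000,
    "p_thresh": 1e-3,
    "maf_min": 0.01,
    "rsq_min": 0.4,
    "ld_r2": 0.5,
    "ties": "efron",
    "n_perm": 100,
    "run_networks": True,
    "run_survival": True,
    "run_de": True,
    "run_profiling": True,
}

_VALIDATORS = {
    "seed": lambda v: isinstance(v, int) and 0 <= v < 2 ** 31,
    "n_samples": lambda v: isinstance(v, int) and v >= 50,
    "n_blocks": lambda v: isinstance(v, int) and v >= 1,
    "snps_per_block": lambda v: isinstance(v, int) and v >= 1,
    "rho": lambda v: 0 <= float(v) < 1,
    "n_genes": lambda v: isinstance(v, int) and v >= 10,
    "modules": lambda v: isinstance(v, dict) and all(isinstance(k, str) and int(c) > 1 for k, c in v.items()),
    "frac_causal": lambda v: 0 <= float(v) <= 1,
    "hr_true": lambda v: float(v) > 0,
    "censor_rate": lambda v: 0 <= float(v) < 1,
    "module_ad_effect": lambda v: np.isfinite(float(v)),
    "network": lambda v: isinstance(v, str),
    "scheme": lambda v: v in _SCHEMES,
    "flank": lambda v: int(v) >= 0,
    "p_thresh": lambda v: 0 < float(v) <= 1,
    "maf_min": lambda v: 0 <= float(v) <= 0.5,
    "rsq_min": lambda v: 0 <= float(v) <= 1,
    "ld_r2": lambda v: 0 < float(v) <= 1,
    "ties": lambda v: v in ("efron", "breslow"),
    "n_perm": lambda v: isinstance(v, int) and v >= 50,
    "run_networks": lambda v: isinstance(v, bool),
    "run_survival": lambda v: isinstance(v, bool),
    "run_de": lambda v: isinstance(v, bool),
    "run_profiling": lambda v: isinstance(v, bool),
}

_MESSAGES = {
    "scheme": f"must be one of {_SCHEMES}",
    "p_thresh": "must lie in (0, 1]",
    "seed": "must be an integer in [0, 2^31)",
    "ties": "must be 'efron' or 'breslow'",
}


def validate_config(config: dict) -> list[str]:
    """Type/range-check every parameter; unknown keys are rejected.

    Returns the full list of violations (empty when valid) rather than
    failing at the first one.
    """
    problems = []
    for key in config:
        if key not in DEFAULT_CONFIG:
            problems.append(f"unknown config key {key!r}")
    merged = {**DEFAULT_CONFIG, **{k: v for k, v in config.items() if k in DEFAULT_CONFIG}}
    if "seed" not in config:
        problems.append("missing seed: every random stage needs an explicit seed")
    for key, check in _VALIDATORS.items():
        try:
            ok = check(merged[key])
        except (TypeError, ValueError):
            ok = False
        if not ok:
            problems.append(f"invalid value for {key!r}: {merged[key]!r} "
                            f"({_MESSAGES.get(key, 'out of range or wrong type')})")
    return problems


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(stage_dir: Path, stage: str, params: dict, seed: int, inputs: list[Path]):
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "parameters": {k: (v if not isinstance(v, dict) else dict(v)) for k, v in params.items()},
        "inputs": {p.name: _sha256(p) for p in inputs},
        "outputs": sorted(p.name for p in stage_dir.glob("*.tsv")),
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: dict, out_dir) -> Path:
    """Run the synthetic end-to-end analysis into ``out_dir``.

    Stage failures abort with the stage name; outputs of completed stages
    are preserved.
    """
    problems = validate_config(config)
    if problems:
        raise DataError("invalid config: " + "; ".join(problems))
    cfg = {**DEFAULT_CONFIG, **config}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    syn = synthetic_data.SyntheticConfig(
        n_samples=cfg["n_samples"], n_blocks=cfg["n_blocks"],
        snps_per_block=cfg["snps_per_block"], rho=cfg["rho"],
        n_genes=cfg["n_genes"], modules=dict(cfg["modules"]),
        frac_causal=cfg["frac_causal"], hr_true=cfg["hr_true"],
        censor_rate=cfg["censor_rate"], module_ad_effect=cfg["module_ad_effect"],
        preserve_modules=[cfg["network"]], seed=cfg["seed"],
    )
    stage = "part0_simulate"
    try:
        cohort = synthetic_data.simulate_cohort(syn)
        d = out / stage
        d.mkdir(exist_ok=True)
        gwas_df = pd.DataFrame([vars(v) for v in cohort["gwas"]])
        write_table(gwas_df, d / "gwas.tsv", params={"seed": cfg["seed"]})
        truth = cohort["truth"]
        write_table(pd.DataFrame({"causal_variant": truth["causal_variants"]}),
                    d / "truth_causal.tsv", params={"hr_true": truth["hr_true"]})
        _write_manifest(d, stage, {k: cfg[k] for k in ("n_samples", "n_blocks", "modules")},
                        cfg["seed"], [])
    except Exception as err:
        raise DataError(f"stage {stage} failed: {err}") from err

    manifest_parts = [stage]
    strat = cohort["stratification"]
    scores = cohort["nbprs"].sample_scores
    sample_ids = cohort["nbprs"].sample_ids

    if cfg["run_networks"]:
        stage = "part1_networks"
        try:
            d = out / stage
            d.mkdir(exist_ok=True)
            rows = []
            module_map = {}
            for g in cohort["genes"]:
                if g.module is not None:
                    module_map.setdefault(g.module, []).append(g.gene_id)
            high = strat.mask("high").astype(float)
            blood, brain = cohort["expression"]["blood"], cohort["expression"]["brain"]
            for mod, genes_m in module_map.items():
                eig = networks.compute_eigengene(blood, genes_m, module=mod)
                eff, r, p, sel = networks.associate_eigengene(eig, high)
                pres = networks.module_preservation_zsummary(
                    brain, blood, genes_m, n_perm=cfg["n_perm"], seed=cfg["seed"], module=mod)
                rows.append({"module": mod, "effect": eff, "r": r, "p": p,
                             "selected": sel, "z_summary": pres.z_summary,
                             "z_density": pres.z_density,
                             "z_connectivity": pres.z_connectivity})
            write_table(pd.DataFrame(rows), d / "network_selection.tsv",
                        params={"n_perm": cfg["n_perm"], "seed": cfg["seed"]})
            _write_manifest(d, stage, {"n_perm": cfg["n_perm"]}, cfg["seed"],
                            [out / "part0_simulate" / "gwas.tsv"])
            manifest_parts.append(stage)
        except Exception as err:
            raise DataError(f"stage {stage} failed: {err}") from err

    stage = "part2_score"
    try:
        d = out / stage
        d.mkdir(exist_ok=True)
        df = pd.DataFrame({"sample_id": sample_ids, "score": scores,
                           "stratum": strat.labels})
        write_table(df, d / "scores.tsv",
                    params={"network": cfg["network"], "scheme": cfg["scheme"],
                            **{k: cfg[k] for k in ("flank", "p_thresh", "maf_min",
                                                   "rsq_min", "ld_r2")}})
        write_table(pd.DataFrame([cohort["nbprs"].filter_report]),
                    d / "filter_report.tsv")
        _write_manifest(d, stage, {"network": cfg["network"], "scheme": cfg["scheme"]},
                        cfg["seed"], [out / "part0_simulate" / "gwas.tsv"])
        manifest_parts.append(stage)
    except Exception as err:
        raise DataError(f"stage {stage} failed: {err}") from err

    analyzable = [l in ("low", "high") for l in strat.labels]
    records = pd.DataFrame({
        "sample_id": np.array(sample_ids)[analyzable],
        "time": cohort["time"][analyzable],
        "event": cohort["event"][analyzable],
        "stratum": np.array(strat.labels)[analyzable],
    })

    if cfg["run_survival"]:
        stage = "part3_survival"
        try:
            d = out / stage
            d.mkdir(exist_ok=True)
            fit = survival.fit_cox(records, ties=cfg["ties"])
            write_table(pd.DataFrame([{
                "hr": fit.hr, "ci_lo": fit.ci95[0], "ci_hi": fit.ci95[1],
                "p": fit.p, "n": fit.n, "n_events": fit.n_events,
                "ties": fit.ties_method,
            }]), d / "cox.tsv", params={"ties": cfg["ties"]})
            km, logrank_p = survival.km_curves(records)
            write_table(km, d / "km_curves.tsv", params={"logrank_p": f"{logrank_p:.12g}"})
            _write_manifest(d, stage, {"ties": cfg["ties"]}, cfg["seed"],
                            [out / "part2_score" / "scores.tsv"])
            manifest_parts.append(stage)
        except Exception as err:
            raise DataError(f"stage {stage} failed: {err}") from err

    if cfg["run_de"]:
        stage = "part4_de"
        try:
            d = out / stage
            d.mkdir(exist_ok=True)
            stratum01 = strat.mask("high").astype(float)[analyzable]
            de_frames = []
            for tissue in ("blood", "brain"):
                expr = cohort["expression"][tissue]
                sub = synthetic_data.ExpressionMatrix(
                    expr.gene_ids, [s for s, a in zip(expr.sample_ids, analyzable) if a],
                    expr.values[:, analyzable], tissue=tissue)
                fits = diffexpr.fit_gene_models(sub, stratum01)
                de = diffexpr.ebayes_moderate(fits, study=tissue)
                write_table(de, d / f"de_{tissue}.tsv")
                de_frames.append(de)
            meta = diffexpr.meta_sample_weighted(de_frames)
            write_table(meta, d / "meta.tsv")
            flagged, counts = diffexpr.volcano_table(de_frames[1])
            write_table(pd.DataFrame([counts]), d / "volcano_counts.tsv")
            _write_manifest(d, stage, {}, cfg["seed"],
                            [out / "part2_score" / "scores.tsv"])
            manifest_parts.append(stage)
        except Exception as err:
            raise DataError(f"stage {stage} failed: {err}") from err

    if cfg["run_profiling"]:
        stage = "part4_profiling"
        try:
            d = out / stage
            d.mkdir(exist_ok=True)
            brain = cohort["expression"]["brain"]
            module_genes = [g.gene_id for g in cohort["genes"] if g.module == cfg["network"]]
            subnet = module_genes[:10]
            rng = np.random.default_rng(cfg["seed"] + 7)
            traits, _ = synthetic_data.simulate_traits(brain, subnet, syn, rng)
            age = rng.normal(85, 5, size=len(brain.sample_ids))
            sex = rng.integers(0, 2, size=len(brain.sample_ids)).astype(float)
            transformed = profiling.adjust_and_rank_trait(
                traits["trait_pos"].to_numpy(), age, sex)
            profile = profiling.associate_expression_trait(brain, transformed, genes=subnet)
            write_table(profile, d / "trait_profile.tsv")
            _write_manifest(d, stage, {"subnetwork_size": len(subnet)}, cfg["seed"], [])
            manifest_parts.append(stage)
        except Exception as err:
            raise DataError(f"stage {stage} failed: {err}") from err

    (out / "manifest.json").write_text(json.dumps(
        {"version": __version__, "seed": cfg["seed"], "parts": manifest_parts,
         "config": {k: cfg[k] for k in sorted(cfg)}},
        indent=2, sort_keys=True, default=str) + "\n")
    return out
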
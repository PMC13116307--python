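import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nbprs import diffexpr as de
from nbprs.io_formats import DataError, ExpressionMatrix

# Published two-study inputs used as worked examples of the sample-weighted
# meta-analysis: per-study (logFC, p) with contrasted-group sample sizes.
HLA_DRB5 = dict(s1=(1.14, 3.78e-5), s2=(0.58, 0.0375), ns=(296, 104), z=4.61)


def _expr(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix([f"g{i}" for i in range(values.shape[0])],
                            [f"s{j}" for j in range(values.shape[1])], values)


def _study_frame(rows, study="st", n=100):
    return pd.DataFrame([{"gene": g, "logFC": l, "p": p, "study": study,
                          "n_study": n} for g, l, p in rows])


class TestGeneModels:
    def test_noiseless_gene_recovers_group_difference(self):
        strat = np.r_[np.ones(5), np.zeros(5)]
        expr = _expr((2.5 * strat + 1.0)[None, :].repeat(12, axis=0))
        fits = de.fit_gene_models(expr, strat)
        np.testing.assert_allclose(fits.beta, 2.5)
        np.testing.assert_allclose(fits.s2, 0.0, atol=1e-20)

    def test_permuted_strata_give_uniform_p(self, rng):
        n, G = 40, 400
        expr = _expr(rng.standard_normal((G, n)))
        strat = rng.permutation(np.r_[np.ones(n // 2), np.zeros(n // 2)])
        fits = de.fit_gene_models(expr, strat)
        t = fits.beta / np.sqrt(fits.s2 * fits.contrast_var_factor)
        p = 2 * stats.t.sf(np.abs(t), fits.df_resid)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_covariate_equal_to_stratum_is_collinear(self, rng):
        strat = np.r_[np.ones(5), np.zeros(5)]
        expr = _expr(rng.standard_normal((12, 10)))
        with pytest.raises(DataError, match="dup"):
            de.fit_gene_models(expr, strat, pd.DataFrame({"dup": strat}))


class TestEbayes:
    def test_equal_variances_reduce_to_ordinary_t(self, rng):
        strat = np.r_[np.ones(10), np.zeros(10)]
        fits = de.fit_gene_models(_expr(rng.standard_normal((30, 20))), strat)
        fits.s2 = np.full_like(fits.s2, 0.7)
        res = de.ebayes_moderate(fits)
        ordinary = fits.beta / np.sqrt(fits.s2 * fits.contrast_var_factor)
        np.testing.assert_allclose(res["t_mod"], ordinary, rtol=1e-12)
        assert np.isinf(res["df_total"]).all()

    def test_huge_variance_spread_approaches_no_pooling(self, rng):
        strat = np.r_[np.ones(10), np.zeros(10)]
        fits = de.fit_gene_models(_expr(rng.standard_normal((200, 20))), strat)
        # enormous spread of s2 -> d0 ~ 0 -> shrinkage nearly vanishes
        spread = rng.uniform(-6, 6, size=200)
        fits.s2 = fits.s2 * np.exp(spread)
        res = de.ebayes_moderate(fits)
        ordinary = fits.beta / np.sqrt(fits.s2 * fits.contrast_var_factor)
        d0 = float(res["df_total"].iloc[0]) - fits.df_resid
        assert d0 < 1.0
        # genes near the prior center see essentially no moderation
        near = np.abs(spread) < 1
        np.testing.assert_allclose(res["t_mod"][near], ordinary[near], rtol=0.05)

    def test_prior_df_recovered_from_model_draws(self, rng):
        # s2 ~ s0^2 * chi2_d0/d0 inverse-scaled around d0=8, s0=1
        G, df = 5000, 10.0
        true_d0 = 8.0
        sigma2 = true_d0 / rng.chisquare(true_d0, G)
        s2 = sigma2 * rng.chisquare(df, G) / df
        d0, s0sq = de.estimate_prior(s2, df)
        assert d0 == pytest.approx(true_d0, rel=0.25)
        assert s0sq == pytest.approx(1.0, rel=0.15)

    def test_matches_reference_limma_implementation(self, rng, tmp_path):
        n, G = 30, 60
        s2 = 6.0 / rng.chisquare(6, size=G)
        vals = rng.standard_normal((G, n)) * np.sqrt(s2)[:, None]
        strat = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        vals[:5, strat == 1] += 0.8
        fits = de.fit_gene_models(_expr(vals), strat)
        res = de.ebayes_moderate(fits)
        expr_csv = tmp_path / "e.csv"
        pd.DataFrame(vals).to_csv(expr_csv)
        strat_csv = tmp_path / "s.csv"
        pd.Series(strat, name="s").to_csv(strat_csv, index=False)
        out_csv = tmp_path / "r.csv"
        rscript = (
            "suppressMessages(library(limma));"
            f"x<-as.matrix(read.csv('{expr_csv}',row.names=1));"
            f"s<-read.csv('{strat_csv}')[[1]];"
            "fit<-eBayes(lmFit(x,model.matrix(~s)));"
            "write.csv(data.frame(t=fit$t[,2],p=fit$p.value[,2]),"
            f"'{out_csv}',row.names=FALSE)"
        )
        proc = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                              text=True)
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(out_csv)
        np.testing.assert_allclose(res["t_mod"], ref["t"], atol=1e-8)
        np.testing.assert_allclose(res["p"], ref["p"], atol=1e-8)


class TestMeta:
    def test_published_two_study_example(self):
        (l1, p1), (l2, p2) = HLA_DRB5["s1"], HLA_DRB5["s2"]
        frames = [_study_frame([("HLA-DRB5", l1, p1)], "rosmap", HLA_DRB5["ns"][0]),
                  _study_frame([("HLA-DRB5", l2, p2)], "msbb", HLA_DRB5["ns"][1])]
        out = de.meta_sample_weighted(frames)
        assert out["z_meta"].iloc[0] == pytest.approx(HLA_DRB5["z"], abs=0.03)
        assert out["direction_string"].iloc[0] == "++"

    def test_single_study_returns_its_own_z(self):
        out = de.meta_sample_weighted([_study_frame([("g", -0.5, 0.01)])])
        assert out["z_meta"].iloc[0] == pytest.approx(de.signed_z(-0.5, 0.01))

    def test_duplicated_study_accumulates_evidence(self):
        # two identical studies combine to sqrt(2) times the single-study z
        f = _study_frame([("g", 0.3, 0.02)])
        out = de.meta_sample_weighted([f, f.copy()])
        assert out["z_meta"].iloc[0] == pytest.approx(
            np.sqrt(2) * de.signed_z(0.3, 0.02))

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_invariant_to_rescaling_sample_sizes(self, factor):
        frames = [_study_frame([("g", 0.4, 0.003)], "a", 200),
                  _study_frame([("g", 0.2, 0.2)], "b", 50)]
        base = de.meta_sample_weighted(frames, [200, 50])["z_meta"].iloc[0]
        scaled = de.meta_sample_weighted(frames, [200 * factor, 50 * factor])
        assert scaled["z_meta"].iloc[0] == pytest.approx(base, rel=1e-9)

    def test_agreeing_signs_bound_the_meta_z(self, rng):
        for _ in range(20):
            z1, z2 = rng.uniform(0.5, 4, 2)
            p1, p2 = 2 * stats.norm.sf([z1, z2])
            frames = [_study_frame([("g", 1.0, p1)], "a", 300),
                      _study_frame([("g", 1.0, p2)], "b", 100)]
            z = de.meta_sample_weighted(frames)["z_meta"].iloc[0]
            assert min(z1, z2) - 1e-9 <= z <= np.hypot(z1, z2) + 1e-9
            assert z > 0  # sign consistency when study signs agree

    def test_zero_p_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            out = de.meta_sample_weighted([_study_frame([("g", 1.0, 0.0)])])
        assert np.isfinite(out["z_meta"].iloc[0])


class TestVolcano:
    def test_flags_follow_thresholds(self):
        df = pd.DataFrame({"gene": list("abcd"), "logFC": [1, -1, 1, -1],
                           "p": [1e-4, 1e-4, 0.5, 0.002]})
        out, counts = de.volcano_table(df)
        assert counts == {"up": 1, "down": 1, "neutral": 2}
        assert out.loc[out["gene"] == "a", "flag"].iloc[0] == "up"

    def test_empty_and_null_inputs(self):
        out, counts = de.volcano_table(pd.DataFrame(columns=["gene", "logFC", "p"]))
        assert counts == {"up": 0, "down": 0, "neutral": 0}
        df = pd.DataFrame({"gene": ["a"], "logFC": [2.0], "p": [1.0]})
        _, counts = de.volcano_table(df)
        assert counts["up"] == 0 and counts["down"] == 0
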
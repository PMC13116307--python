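import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbprs import score
from nbprs.io_formats import DataError, GeneAnnotation, GenotypeMatrix, VariantRecord
from .oracles import greedy_prune_bruteforce


def _variant(vid, pos, p=1e-4, beta=0.1, chrom="1", maf=0.2, imp_r2=1.0,
             a1="A", a2="G"):
    return VariantRecord(id=vid, chrom=chrom, pos=pos, effect_allele=a1,
                         other_allele=a2, beta=beta, p=p, maf=maf, imp_r2=imp_r2)


def _geno(dosages_by_id, n=None, alleles=None):
    ids = list(dosages_by_id)
    mat = np.column_stack([dosages_by_id[v] for v in ids])
    samples = [f"s{i}" for i in range(mat.shape[0])]
    return GenotypeMatrix(samples, ids, mat, alleles or {})


class TestMapVariants:
    GENES = [GeneAnnotation("GA", "1", 10_000, 20_000, "M14"),
             GeneAnnotation("GB", "1", 5_000, 6_000, "M14"),
             GeneAnnotation("GC", "2", 1_000, 2_000, "M2")]

    def test_window_boundary_is_inclusive(self):
        kept = score.map_variants_to_network(
            [_variant("a", 40_000), _variant("b", 40_001)], self.GENES, "M14")
        assert [v.id for v in kept] == ["a"]

    def test_window_clamped_at_position_one(self):
        # gene [5000, 6000] with 20 kb flank -> window [1, 26000]
        kept = score.map_variants_to_network([_variant("a", 1)], self.GENES, "M14")
        assert [v.id for v in kept] == ["a"]

    def test_overlapping_windows_yield_variant_once(self):
        kept = score.map_variants_to_network([_variant("a", 5_500)],
                                             self.GENES, "M14")
        assert len(kept) == 1

    def test_chromosome_must_match(self):
        # position falls inside an M14 window interval, but on chromosome 2
        kept = score.map_variants_to_network([_variant("a", 15_000, chrom="2")],
                                             self.GENES, "M14")
        assert kept == []

    def test_empty_network_rejected(self):
        with pytest.raises(DataError, match="M99"):
            score.map_variants_to_network([_variant("a", 1)], self.GENES, "M99")


class TestFilterVariants:
    def test_boundary_rules(self):
        variants = [
            _variant("at_p", 1, p=1e-3),          # strict <: removed
            _variant("below_p", 2, p=0.99e-3),    # kept
            _variant("at_maf", 3, p=1e-4, maf=0.01),   # kept (rule is < 1%)
            _variant("low_maf", 4, p=1e-4, maf=0.009),  # removed
            _variant("low_rsq", 5, p=1e-4, imp_r2=0.39),  # removed
        ]
        kept, report = score.filter_variants(variants)
        assert {v.id for v in kept} == {"below_p", "at_maf"}
        assert report["removed_p"] == 1
        assert report["removed_maf"] == 1
        assert report["removed_imp_r2"] == 1

    def test_empty_result_warns_not_raises(self):
        with pytest.warns(UserWarning):
            kept, _ = score.filter_variants([_variant("a", 1, p=0.5)])
        assert kept == []


def _correlated_triplet(rng, r12_target=0.97):
    """Three dosage vectors with r2(1,2) > 0.5 and r2(1,3), r2(2,3) small.

    Discretizing to 0/1/2 attenuates the latent correlation, hence the high
    latent target.
    """
    n = 3000
    z1 = rng.standard_normal(n)
    z2 = r12_target * z1 + np.sqrt(1 - r12_target ** 2) * rng.standard_normal(n)
    z3 = rng.standard_normal(n)
    to_dosage = lambda z: np.clip(np.round(1 + z / 2), 0, 2)
    d1, d2, d3 = to_dosage(z1), to_dosage(z2), to_dosage(z3)
    assert np.corrcoef(d1, d2)[0, 1] ** 2 > 0.5
    return d1, d2, d3


class TestLdPrune:
    def test_lower_p_member_of_correlated_pair_survives(self, rng):
        d1, d2, d3 = _correlated_triplet(rng)
        variants = [_variant("v1", 100, p=1e-5), _variant("v2", 200, p=1e-4),
                    _variant("v3", 300, p=1e-3)]
        geno = _geno({"v1": d1, "v2": d2, "v3": d3})
        kept = score.ld_prune(geno, variants, r2_max=0.5)
        assert [v.id for v in kept] == ["v1", "v3"]

    def test_single_variant_kept(self, rng):
        geno = _geno({"v1": rng.integers(0, 3, 50).astype(float)})
        kept = score.ld_prune(geno, [_variant("v1", 100)], r2_max=0.5)
        assert [v.id for v in kept] == ["v1"]

    def test_r2max_one_keeps_everything(self, rng):
        d1, d2, d3 = _correlated_triplet(rng)
        variants = [_variant("v1", 100, p=1e-5), _variant("v2", 200, p=1e-4),
                    _variant("v3", 300, p=1e-3)]
        kept = score.ld_prune(_geno({"v1": d1, "v2": d2, "v3": d3}),
                              variants, r2_max=1.0)
        assert len(kept) == 3

    def test_zero_variance_removed_with_warning(self, rng):
        geno = _geno({"v1": np.ones(20), "v2": rng.integers(0, 3, 20).astype(float)})
        with pytest.warns(UserWarning, match="v1"):
            kept = score.ld_prune(geno, [_variant("v1", 100), _variant("v2", 200)])
        assert [v.id for v in kept] == ["v2"]

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(20):
            m = rng.integers(2, 10)
            n = 200
            base = rng.standard_normal(n)
            dosages, variants, simple = {}, [], []
            for j in range(m):
                mix = rng.uniform(0, 1)
                z = mix * base + (1 - mix) * rng.standard_normal(n)
                d = np.clip(np.round(1 + z), 0, 2)
                if d.std() == 0:
                    d[0] = 2 - d[0]
                vid = f"v{j}"
                p = float(rng.uniform(1e-6, 1e-3))
                pos = int(rng.integers(1, 10_000))
                dosages[vid] = d
                variants.append(_variant(vid, pos, p=p))
                simple.append((vid, "1", pos, p))
            kept = [v.id for v in score.ld_prune(_geno(dosages), variants, 0.5)]
            assert kept == greedy_prune_bruteforce(simple, dosages, 0.5)


class TestComputeScore:
    def test_weighted_sum(self):
        geno = _geno({"v1": np.array([1.0]), "v2": np.array([2.0])})
        res = score.compute_nbprs(geno, [_variant("v1", 1, beta=0.2),
                                         _variant("v2", 2, beta=0.3)])
        assert res.sample_scores[0] == pytest.approx(0.8)

    def test_negative_beta_reorientation_preserves_score(self):
        g = np.array([0.0, 1.0, 2.0])
        res_pos = score.compute_nbprs(_geno({"v1": g}),
                                      [_variant("v1", 1, beta=0.2, a1="A", a2="G")])
        # same variant reported on the other allele with flipped sign
        res_neg = score.compute_nbprs(_geno({"v1": 2 - g}),
                                      [_variant("v1", 1, beta=-0.2, a1="G", a2="A")])
        np.testing.assert_allclose(res_pos.sample_scores, res_neg.sample_scores)
        assert all(w >= 0 for _, w in res_neg.selected_variants)

    def test_allele_swap_resolved_by_dosage_flip(self):
        g = np.array([0.0, 1.0, 2.0])
        geno = _geno({"v1": g}, alleles={"v1": ("G", "A")})  # matrix counts G
        res = score.compute_nbprs(geno, [_variant("v1", 1, beta=0.2, a1="A", a2="G")])
        np.testing.assert_allclose(res.sample_scores, 0.2 * (2 - g))

    def test_allele_mismatch_dropped_with_warning(self):
        geno = _geno({"v1": np.array([1.0])}, alleles={"v1": ("C", "T")})
        with pytest.warns(UserWarning, match="v1"):
            res = score.compute_nbprs(geno, [_variant("v1", 1, beta=0.2)])
        assert res.sample_scores[0] == 0.0

    def test_all_reference_dosages_score_zero(self):
        geno = _geno({"v1": np.zeros(4)})
        res = score.compute_nbprs(geno, [_variant("v1", 1, beta=0.5)])
        assert np.all(res.sample_scores == 0)

    @given(st.lists(st.tuples(st.floats(-1, 1), st.integers(0, 2)),
                    min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_score_linearity_over_variant_sets(self, pairs):
        variants = [_variant(f"v{i}", i + 1, beta=b) for i, (b, _) in enumerate(pairs)]
        geno = _geno({f"v{i}": np.array([float(d)]) for i, (_, d) in enumerate(pairs)})
        half = len(pairs) // 2
        total = score.compute_nbprs(geno, variants).sample_scores[0]
        first = score.compute_nbprs(geno, variants[:half]).sample_scores[0]
        second = score.compute_nbprs(geno, variants[half:]).sample_scores[0]
        assert total == pytest.approx(first + second, abs=1e-9)


class TestStratify:
    def test_quartile_with_interpolated_cutpoints(self):
        scores = np.arange(1, 9, dtype=float)  # Q1=2.75, Q3=6.25
        strat = score.stratify(scores, "quartile")
        assert strat.cutpoints == pytest.approx([2.75, 6.25])
        assert [s for s, l in zip(scores, strat.labels) if l == "low"] == [1, 2]
        assert [s for s, l in zip(scores, strat.labels) if l == "high"] == [7, 8]
        assert strat.labels[2:6] == ["excluded"] * 4

    def test_median_splits_in_half(self):
        strat = score.stratify(np.array([1.0, 2, 3, 4, 5, 6, 7, 8]), "median")
        assert strat.labels == ["low"] * 4 + ["high"] * 4

    def test_tertile_excludes_middle(self):
        strat = score.stratify(np.arange(1.0, 10), "tertile")
        assert strat.labels.count("excluded") == 3
        assert strat.labels.count("low") == 3 and strat.labels.count("high") == 3

    def test_quartile_group_sizes_balance_at_scale(self):
        # mirrors the reported cohort structure: ~n/4 in each extreme group
        rng = np.random.default_rng(1)
        scores = rng.normal(size=8484)
        strat = score.stratify(scores, "quartile")
        assert strat.labels.count("low") == 2121
        assert strat.labels.count("high") == 2121

    @pytest.mark.parametrize("bad,err", [
        (np.ones(10), "identical"),
        (np.arange(5, dtype=float), "8 samples"),
    ])
    def test_degenerate_inputs_rejected(self, bad, err):
        with pytest.raises(DataError, match=err):
            score.stratify(bad, "quartile")

    def test_unknown_scheme_rejected(self):
        with pytest.raises(DataError, match="quintile"):
            score.stratify(np.arange(10, dtype=float), "quintile")


def test_pipeline_composition_reports_every_stage(small_cohort):
    _, cohort = small_cohort
    report = cohort["nbprs"].filter_report
    for key in ("mapped", "removed_p", "removed_maf", "removed_imp_r2",
                "removed_ld", "used"):
        assert key in report
    assert report["mapped"] >= report["kept"] >= report["used"]
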
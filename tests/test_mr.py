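"""MR engine: harmonization rules, Wald ratio, IVW (with the weighted-
regression-through-origin oracle), stratified BH FDR, and the Q gate."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sceqtlmr.mr import (HarmonizedPair, bh_fdr_stratified, harmonize,
                         heterogeneity_gate, ivw, MRResult, wald_ratio)


def _rec(ea, oa, beta, eaf=0.3, se=0.05, snp="rs1", n=1000):
    return dict(snp_id=snp, effect_allele=ea, other_allele=oa, beta=beta,
                se=se, eaf=eaf, n=n)


class TestHarmonize:
    def test_identical_alleles_unchanged(self):
        p = harmonize(_rec("A", "G", 0.2), _rec("A", "G", 0.1))
        assert not p.dropped and not p.flipped
        assert p.beta_out == pytest.approx(0.1)

    def test_swapped_alleles_negate_outcome(self):
        p = harmonize(_rec("A", "G", 0.2), _rec("G", "A", 0.1))
        assert p.flipped and p.beta_out == pytest.approx(-0.1)

    def test_palindromic_mid_frequency_dropped(self):
        p = harmonize(_rec("A", "T", 0.2, eaf=0.50), _rec("A", "T", 0.1, eaf=0.50))
        assert p.palindromic_dropped and p.dropped

    def test_palindromic_extreme_frequency_kept(self):
        p = harmonize(_rec("C", "G", 0.2, eaf=0.10), _rec("C", "G", 0.1, eaf=0.12))
        assert not p.dropped

    def test_incompatible_alleles_dropped_with_reason(self):
        p = harmonize(_rec("A", "G", 0.2), _rec("A", "C", 0.1))
        assert p.drop_reason == "allele_mismatch"


class TestWaldRatio:
    def test_zero_outcome_effect(self):
        beta, se, p = wald_ratio(HarmonizedPair("s", 0.5, 0.05, 0.0, 0.01))
        assert beta == 0.0 and p == pytest.approx(1.0)

    def test_unit_exposure_is_identity(self):
        beta, se, _ = wald_ratio(HarmonizedPair("s", 1.0, 0.05, 0.07, 0.02))
        assert beta == pytest.approx(0.07) and se == pytest.approx(0.02)

    def test_direct_evaluation(self):
        beta, se, p = wald_ratio(HarmonizedPair("s", 0.2, 0.05, 0.05, 0.01))
        assert beta == pytest.approx(0.25)
        assert se == pytest.approx(0.05)
        from scipy import stats
        assert p == pytest.approx(2 * stats.norm.sf(5.0))

    def test_zero_exposure_is_hard_error(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(HarmonizedPair("s", 0.0, 0.05, 0.1, 0.01))


def _pairs(beta_exp, beta_out, se_out):
    return [HarmonizedPair(f"s{i}", bx, 0.01, by, so)
            for i, (bx, by, so) in enumerate(zip(beta_exp, beta_out, se_out))]


class TestIvw:
    def test_homogeneous_ratios(self):
        pairs = _pairs([0.2, 0.4, 0.5], [0.06, 0.12, 0.15], [0.01, 0.01, 0.01])
        beta, se, p, q, df, qp = ivw(pairs)
        assert beta == pytest.approx(0.3)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert qp == pytest.approx(1.0)

    def test_two_instrument_hand_computation(self):
        # equal weights w = (0.5/0.01)^2 = 2500; ratios 0.2 and 0.4
        pairs = _pairs([0.5, 0.5], [0.1, 0.2], [0.01, 0.01])
        beta, se, p, q, df, qp = ivw(pairs, random_effects=False)
        w = 2500.0
        assert beta == pytest.approx(0.3)
        assert q == pytest.approx(w * (0.01 + 0.01))
        assert df == 1
        assert se == pytest.approx(np.sqrt(1 / (2 * w)))

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_weighted_regression_through_origin(self, seed):
        """Fixed-effect IVW equals the WLS slope of beta_out on beta_exp with
        weights 1/se_out^2 and no intercept."""
        import statsmodels.api as sm
        rng = np.random.default_rng(seed)
        k = 8
        bx = rng.uniform(0.1, 0.6, k) * rng.choice([-1, 1], k)
        by = 0.25 * bx + rng.normal(0, 0.02, k)
        so = rng.uniform(0.005, 0.05, k)
        beta, se, *_ = ivw(_pairs(bx, by, so), random_effects=False)
        fit = sm.WLS(by, bx, weights=1.0 / so**2).fit()
        assert beta == pytest.approx(fit.params[0], rel=1e-10)
        assert se == pytest.approx(fit.bse[0] / np.sqrt(fit.scale), rel=1e-10)

    def test_single_pair_routes_to_wald(self):
        with pytest.raises(ValueError):
            ivw(_pairs([0.5], [0.1], [0.01]))

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_random_effects_se_never_below_fixed(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 10))
        bx = rng.uniform(0.05, 0.8, k)
        by = rng.normal(0, 0.1, k)
        so = rng.uniform(0.005, 0.05, k)
        _, se_re, *_ = ivw(_pairs(bx, by, so), random_effects=True)
        _, se_fe, *_ = ivw(_pairs(bx, by, so), random_effects=False)
        assert se_re >= se_fe - 1e-15


def _mr(gene, ct, trait, pval, n_snp=1, q_pval=np.nan):
    return MRResult(gene_id=gene, cell_type=ct, trait=trait,
                    method="wald_ratio" if n_snp == 1 else "ivw",
                    n_snp=n_snp, beta=0.1, se=0.05, pval=pval, q_pval=q_pval)


class TestStratifiedFdr:
    def test_single_result_stratum(self):
        (r,) = bh_fdr_stratified([_mr("g", "CD4 NC", "bmi", 0.03)])
        assert r.fdr_p == pytest.approx(0.03)

    def test_hand_bh_within_one_stratum(self):
        results = [_mr(f"g{i}", "CD4 NC", "bmi", p)
                   for i, p in enumerate([0.01, 0.02, 0.03])]
        adj = sorted(r.fdr_p for r in bh_fdr_stratified(results))
        assert adj == pytest.approx([0.03, 0.03, 0.03])

    def test_strata_never_share_a_pool(self):
        results = [_mr("g1", "CD4 NC", "bmi", 0.01),
                   _mr("g2", "NK", "bmi", 0.02),
                   _mr("g3", "CD4 NC", "obesity", 0.03)]
        out = {(r.cell_type, r.trait): r.fdr_p
               for r in bh_fdr_stratified(results)}
        assert out[("CD4 NC", "bmi")] == pytest.approx(0.01)
        assert out[("NK", "bmi")] == pytest.approx(0.02)
        assert out[("CD4 NC", "obesity")] == pytest.approx(0.03)

    def test_matches_statsmodels_per_stratum(self, rng):
        from statsmodels.stats.multitest import multipletests
        pvals = rng.uniform(size=20)
        results = [_mr(f"g{i}", "NK", "bmi", p) for i, p in enumerate(pvals)]
        adj = [r.fdr_p for r in bh_fdr_stratified(results)]
        np.testing.assert_allclose(
            adj, multipletests(pvals, method="fdr_bh")[1])


class TestNullCalibration:
    def test_stratified_fdr_control_under_null(self):
        """With eQTL signals but a null outcome (theta = 0, no pleiotropy),
        at most 7.5% of 500 gene results reach fdr_p < 0.05."""
        from sceqtlmr.config import PipelineConfig
        from sceqtlmr.pipeline import run_mr_stage
        from sceqtlmr.simulate import SimConfig, TraitSpec, simulate_dataset
        sim = SimConfig(n_genes=500, scenario_mix={"H1": 1.0},
                        snps_per_locus=30, loci_per_gene=2, rng_seed=31,
                        traits=(TraitSpec("bmi", n=484_680),))
        ds = simulate_dataset(sim)
        mr = run_mr_stage(ds, PipelineConfig())
        assert len(mr) >= 450
        assert (mr["fdr_p"] < 0.05).mean() <= 0.075


class TestHeterogeneityGate:
    @pytest.mark.parametrize("q_pval,excluded", [
        (0.04, True), (0.05, False), (0.9, False)])
    def test_boundaries(self, q_pval, excluded):
        r = _mr("g", "NK", "bmi", 0.01, n_snp=3, q_pval=q_pval)
        retained, ex = heterogeneity_gate([r], 0.05)
        assert (len(ex) == 1) == excluded

    def test_wald_results_always_retained(self):
        r = _mr("g", "NK", "bmi", 0.01, n_snp=1)
        retained, ex = heterogeneity_gate([r], 0.05)
        assert retained and not ex
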
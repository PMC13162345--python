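"""Colocalization engine: window arithmetic, the Wakefield ABF, posterior
probabilities against an exhaustive configuration-enumeration oracle, the
composite decision rule, and the LD check."""
import math

import numpy as np
import pandas as pd
import pytest

from sceqtlmr.coloc import (coloc_abf, coloc_decision, extract_window,
                            ld_check, wakefield_log_abf)
from sceqtlmr.simulate import ar1_ld

from conftest import ld_from_r, make_sumstats


class TestExtractWindow:
    def test_boundary_snp_included(self):
        df = make_sumstats(["a"], [0.1], [0.02], pos_start=200_000)
        win = extract_window(df, "1", 100_000, 100_000)
        assert len(win) == 1                      # closed interval

    def test_other_chromosome_excluded(self):
        df = make_sumstats(["a"], [0.1], [0.02], chrom="2")
        assert len(extract_window(df, "1", 100_000, 100_000)) == 0

    def test_interval_arithmetic(self):
        df = make_sumstats(["a", "b", "c", "d"], [0.1] * 4, [0.02] * 4)
        df["pos"] = [49_999, 50_000, 250_000, 250_001]
        win = extract_window(df, "1", 150_000, 100_000)
        assert list(win["snp_id"]) == ["b", "c"]


class TestWakefieldAbf:
    def test_null_snp_penalized(self):
        v, w = 0.01, 0.0225
        labf = wakefield_log_abf(0.0, math.sqrt(v), math.sqrt(w))
        assert labf == pytest.approx(0.5 * math.log(v / (v + w)))
        assert labf < 0

    def test_vanishing_prior_limit(self):
        labf = wakefield_log_abf(0.5, 0.1, 1e-12)
        assert labf == pytest.approx(0.0, abs=1e-6)

    def test_two_term_formula(self):
        # z = 5, V = 0.01, W = 0.0225
        labf = wakefield_log_abf(0.5, 0.1, 0.15)
        expected = 0.5 * math.log(0.01 / 0.0325) + 12.5 * 0.0225 / 0.0325
        assert labf == pytest.approx(expected, rel=1e-12)


def coloc_enumeration_oracle(l1, l2, p1, p2, p12):
    """Exhaustive sum over all single-causal configurations per trait.

    Trait 1 is either null or causal at SNP i (Bayes factor exp(l1_i)), and
    likewise trait 2; per-SNP prior p1/p2 for trait-specific causality, p12
    for shared. Plain-float arithmetic, valid for moderate |l|.
    """
    n = len(l1)
    b1 = [math.exp(v) for v in l1]
    b2 = [math.exp(v) for v in l2]
    w = [1.0,
         sum(p1 * b1[i] for i in range(n)),
         sum(p2 * b2[j] for j in range(n)),
         sum(p1 * p2 * b1[i] * b2[j]
             for i in range(n) for j in range(n) if i != j),
         sum(p12 * b1[i] * b2[i] for i in range(n))]
    total = sum(w)
    return np.array([x / total for x in w])


class TestColocAbf:
    def test_shared_strong_snp_favors_h4(self):
        pp = coloc_abf([1.0], [0.1], [1.0], [0.1])
        assert np.argmax(pp) == 4

    def test_all_null_favors_h0(self):
        n = 10
        pp = coloc_abf(np.zeros(n), np.full(n, 0.1),
                       np.zeros(n), np.full(n, 0.1))
        assert np.argmax(pp) == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        se1 = rng.uniform(0.02, 0.2, n)
        se2 = rng.uniform(0.02, 0.2, n)
        b1 = rng.normal(0, 3, n) * se1
        b2 = rng.normal(0, 3, n) * se2
        pp = coloc_abf(b1, se1, b2, se2)
        l1 = wakefield_log_abf(b1, se1, 0.15)
        l2 = wakefield_log_abf(b2, se2, 0.2)
        oracle = coloc_enumeration_oracle(l1, l2, 1e-4, 1e-4, 1e-5)
        np.testing.assert_allclose(pp, oracle, atol=1e-9)

    def test_sums_to_one_and_permutation_invariant(self, rng):
        n = 30
        se = np.full(n, 0.05)
        b1 = rng.normal(0, 2, n) * se
        b2 = rng.normal(0, 2, n) * se
        pp = coloc_abf(b1, se, b2, se)
        assert pp.sum() == pytest.approx(1.0, abs=1e-9)
        perm = rng.permutation(n)
        pp2 = coloc_abf(b1[perm], se[perm], b2[perm], se[perm])
        np.testing.assert_allclose(pp, pp2, atol=1e-12)

    def test_mismatched_panels_rejected(self):
        with pytest.raises(ValueError):
            coloc_abf([0.1, 0.2], [0.05, 0.05], [0.1], [0.05])


class TestDecisionRule:
    def test_printed_rule_arithmetic_pass(self):
        rule, strict = coloc_decision([0, 0, 0, 0.05, 0.90])
        assert rule and strict        # sum 0.95 > 0.8; ratio 0.947 > 0.9

    def test_ratio_term_rejects(self):
        rule, strict = coloc_decision([0, 0, 0, 0.5, 0.45])
        assert not rule               # ratio 0.474
        assert not strict

    def test_null_vector_fails_both(self):
        rule, strict = coloc_decision([1, 0, 0, 0, 0])
        assert not rule and not strict

    def test_zero_denominator_ratio_defined_as_zero(self):
        rule, _ = coloc_decision([0.5, 0.25, 0.25, 0.0, 0.0])
        assert not rule


class TestLdCheck:
    def _window(self, pvals):
        df = make_sumstats([f"s{i}" for i in range(len(pvals))],
                           [0.1] * len(pvals), [0.02] * len(pvals))
        df["pval"] = pvals
        return df

    def test_instrument_is_its_own_signal(self):
        win = self._window([1e-10])
        ld = ld_from_r(["s0"], np.eye(1))
        r2, ok = ld_check("s0", win, ld)
        assert r2 == pytest.approx(1.0) and ok

    def test_no_signal_snp_fails(self):
        win = self._window([1e-4, 0.2])
        ld = ld_from_r(["s0", "s1", "inst"], np.eye(3))
        r2, ok = ld_check("inst", win, ld)
        assert math.isnan(r2) and not ok

    def test_max_over_signal_snps(self):
        win = self._window([1e-10, 1e-10, 1e-10])
        r = np.eye(4)
        for i, val in enumerate([0.2, 0.69, 0.71]):
            r[3, i] = r[i, 3] = math.sqrt(val)
        ld = ld_from_r(["s0", "s1", "s2", "inst"], r)
        r2, ok = ld_check("inst", win, ld)
        assert r2 == pytest.approx(0.71) and ok

    def test_threshold_is_inclusive(self):
        # r = 0.5 gives r^2 exactly 0.25 in binary floating point
        win = self._window([1e-10])
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        ld = ld_from_r(["s0", "inst"], r)
        r2, ok = ld_check("inst", win, ld, r2_min=0.25)
        assert r2 == 0.25 and ok

    def test_missing_instrument_hard_error(self):
        win = self._window([1e-10])
        ld = ld_from_r(["s0"], np.eye(1))
        with pytest.raises(KeyError):
            ld_check("absent", win, ld)


class TestScenarioRecovery:
    """Strong-signal H4 loci pass the strict gate; well-separated H3 loci are
    rejected by the ratio term of the composite rule."""

    def _run(self, scenario, n_loci, theta):
        from sceqtlmr.config import PipelineConfig
        from sceqtlmr.simulate import SimConfig, TraitSpec, simulate_locus
        sim = SimConfig(
            n_genes=1, snps_per_locus=40, eqtl_beta=0.7,
            traits=(TraitSpec("bmi", n=484_680, theta=theta),))
        strict = rule = 0
        for seed in range(n_loci):
            rng = np.random.default_rng(seed)
            eqtl, outs, ld, truth = simulate_locus(sim, scenario, rng)
            pp = coloc_abf(eqtl["beta"].to_numpy(), eqtl["se"].to_numpy(),
                           outs["bmi"]["beta"].to_numpy(),
                           outs["bmi"]["se"].to_numpy())
            r, s = coloc_decision(pp)
            rule += r
            strict += s
        return rule / n_loci, strict / n_loci

    def test_h4_strict_pass_rate(self):
        rule, strict = self._run("H4", 100, theta=0.3)
        assert strict >= 0.95

    def test_h3_rule_rejection_rate(self):
        rule, _ = self._run("H3", 100, theta=0.3)
        assert rule < 0.10
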
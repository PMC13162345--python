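"""Instrument selection: p-value thresholding, greedy LD clumping (with a
brute-force oracle), the F-statistic, and Steiger directionality."""
import numpy as np
import pandas as pd
import pytest

from sceqtlmr.instruments import (f_statistic, filter_by_pval, ld_clump,
                                  select_instruments, steiger_filter)
from sceqtlmr.simulate import ar1_ld

from conftest import ld_from_r, make_eqtl


class TestPvalFilter:
    def test_strict_inequality_at_boundary(self):
        df = make_eqtl(["a", "b", "c"], [1, 1, 1], [1, 1, 1])
        df["pval"] = [0.004, 0.005, 0.006]
        kept = filter_by_pval(df, 0.005)
        assert list(kept["snp_id"]) == ["a"]

    def test_threshold_one_keeps_all(self):
        df = make_eqtl(["a", "b"], [1, 1], [1, 1])
        assert len(filter_by_pval(df, 1.0)) == 2

    def test_strict_threshold_is_nested(self, rng):
        """The 5e-6 sensitivity selection is a subset of the 0.005 one."""
        z = rng.normal(0, 4, size=50)
        df = make_eqtl([f"s{i}" for i in range(50)], z, np.ones(50))
        loose = set(filter_by_pval(df, 0.005)["snp_id"])
        strict = set(filter_by_pval(df, 5e-6)["snp_id"])
        assert strict <= loose


def greedy_clump_oracle(df: pd.DataFrame, ld, r2_max: float) -> list[str]:
    """Independent greedy reference: explicit loop over the sorted list."""
    rows = sorted(df.to_dict("records"),
                  key=lambda r: (r["pval"], r["chrom"], r["pos"], r["snp_id"]))
    kept: list[str] = []
    for row in rows:
        if all(ld.r2(row["snp_id"], k) < r2_max for k in kept):
            kept.append(row["snp_id"])
    return kept


class TestClump:
    def test_correlated_pair_keeps_most_significant(self):
        df = make_eqtl(["top", "tag"], [0.5, 0.3], [0.05, 0.05])
        df["pval"] = [1e-8, 1e-4]
        ld = ld_from_r(["top", "tag"], [[1, np.sqrt(0.5)], [np.sqrt(0.5), 1]])
        kept = ld_clump(df, ld, 0.01)
        assert list(kept["snp_id"]) == ["top"]

    def test_independent_snps_all_retained(self):
        df = make_eqtl(["a", "b", "c"], [0.5, 0.4, 0.3], [0.05] * 3)
        ld = ld_from_r(["a", "b", "c"], np.eye(3))
        assert len(ld_clump(df, ld, 0.01)) == 3

    def test_missing_snp_is_hard_error(self):
        df = make_eqtl(["a", "zz"], [0.5, 0.4], [0.05, 0.05])
        ld = ld_from_r(["a"], np.eye(1))
        with pytest.raises(KeyError, match="zz"):
            ld_clump(df, ld, 0.01)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_greedy_oracle_on_ar1_locus(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        ids = [f"s{i:02d}" for i in range(n)]
        z = rng.normal(0, 3, size=n)
        df = make_eqtl(ids, z, np.ones(n))
        ld = ld_from_r(ids, ar1_ld(n, 0.85))
        kept = ld_clump(df, ld, 0.1)
        assert list(kept["snp_id"]) == sorted(
            greedy_clump_oracle(df, ld, 0.1),
            key=lambda s: ids.index(s))
        # pairwise independence of the returned set
        for i, a in enumerate(kept["snp_id"]):
            for b in kept["snp_id"].iloc[i + 1:]:
                assert ld.r2(a, b) < 0.1

    def test_invariant_to_input_row_order(self, rng):
        n = 15
        ids = [f"s{i:02d}" for i in range(n)]
        df = make_eqtl(ids, rng.normal(0, 3, n), np.ones(n))
        ld = ld_from_r(ids, ar1_ld(n, 0.9))
        shuffled = df.sample(frac=1.0, random_state=3)
        a = set(ld_clump(df, ld, 0.05)["snp_id"])
        b = set(ld_clump(shuffled, ld, 0.05)["snp_id"])
        assert a == b


class TestFStatistic:
    def test_forced_arithmetic(self):
        assert f_statistic(0.4, 0.1) == pytest.approx(16.0)
        assert f_statistic(0.0, 0.1) == 0.0

    def test_f_threshold_equals_z_threshold(self, rng):
        beta = rng.normal(size=200)
        se = rng.uniform(0.01, 1.0, size=200)
        f = f_statistic(beta, se)
        np.testing.assert_array_equal(f > 10, np.abs(beta / se) > np.sqrt(10))


class TestSteiger:
    def test_exposure_dominance_keeps(self):
        res = steiger_filter(10.0, 1.0, 1000, 1.0, 1.0, 1000)
        assert res.keep and res.r2_exposure > res.r2_outcome

    def test_symmetric_case_is_dropped(self):
        res = steiger_filter(5.0, 1.0, 1000, 5.0, 1.0, 1000)
        assert res.r2_exposure == pytest.approx(res.r2_outcome)
        assert not res.keep       # strict inequality

    def test_stated_formula_direct_evaluation(self):
        """z = 5 on both sides but vastly different n: the small-n side
        explains far more variance."""
        res = steiger_filter(5.0, 1.0, 982, 5.0, 1.0, 480_000)
        assert res.r2_exposure == pytest.approx(25 / 1005)
        assert res.r2_outcome == pytest.approx(25 / 480_023)
        assert res.keep
        assert 0 < res.steiger_p < 1

    def test_tiny_n_is_hard_error(self):
        with pytest.raises(ValueError):
            steiger_filter(1.0, 1.0, 3, 1.0, 1.0, 1000)


class TestFullChain:
    def test_composition_and_predicates(self, config, rng):
        """The full chain equals p-filter -> clump -> F -> Steiger applied in
        order, and every survivor satisfies all four predicates."""
        from sceqtlmr.instruments import filter_by_pval
        n = 30
        ids = [f"s{i:02d}" for i in range(n)]
        z = rng.normal(0, 6, size=n)
        eqtl = make_eqtl(ids, z * 0.05, np.full(n, 0.05), n=982)
        out = make_eqtl(ids, rng.normal(0, 1, n) * 0.01, np.full(n, 0.01),
                        n=480_000).drop(columns=["gene_id", "gene_symbol",
                                                 "cell_type"])
        ld = ld_from_r(ids, ar1_ld(n, 0.8))
        inst = select_instruments(eqtl, out, ld, config)

        manual = filter_by_pval(eqtl, config.iv_pval)
        manual = ld_clump(manual, ld, config.clump_r2)
        manual = manual[f_statistic(manual["beta"], manual["se"]) > config.f_min]
        out_by = out.set_index("snp_id")
        manual_ids = [
            s for s, b, se, nn in zip(manual["snp_id"], manual["beta"],
                                      manual["se"], manual["n"])
            if steiger_filter(b, se, nn, out_by.loc[s, "beta"],
                              out_by.loc[s, "se"], out_by.loc[s, "n"]).keep
        ]
        assert list(inst.records["snp_id"]) == manual_ids
        for _, row in inst.records.iterrows():
            assert row["pval"] < config.iv_pval
            assert f_statistic(row["beta"], row["se"]) > config.f_min
        for i, a in enumerate(inst.records["snp_id"]):
            for b in inst.records["snp_id"].iloc[i + 1:]:
                assert ld.r2(a, b) < config.clump_r2

    def test_causal_snp_retained_when_most_significant(self, config):
        """On a simulated H4 locus the causal SNP survives the chain whenever
        it is the top association."""
        from sceqtlmr.simulate import SimConfig, simulate_locus
        sim = SimConfig(n_genes=1, snps_per_locus=30)
        hits = 0
        total = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            eqtl, outs, ld, truth = simulate_locus(sim, "H4", rng)
            top = eqtl.loc[eqtl["pval"].idxmin(), "snp_id"]
            if top != truth["causal_snp_exposure"]:
                continue
            total += 1
            inst = select_instruments(eqtl, outs["bmi"], ld, config)
            hits += top in set(inst.records["snp_id"])
        assert total > 0 and hits == total
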
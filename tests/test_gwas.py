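import numpy as np
import pandas as pd
import pytest
from scipy import stats

from argwalker import (
    combine_by_chromosome,
    gwas_scan,
    maf_filter,
    ttest_association,
)


class TestTtestAssociation:
    def test_identical_groups(self):
        t, p = ttest_association([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert t == 0.0
        assert p == 1.0

    def test_textbook_pooled_variance_example(self):
        t, p = ttest_association([1, 2, 3, 4, 3, 4, 5, 6], [0, 0, 0, 0, 1, 1, 1, 1])
        assert t == pytest.approx(-2.1909, abs=1e-4)
        assert p == pytest.approx(2 * stats.t.sf(2.1909, df=6), abs=1e-4)
        assert p == pytest.approx(0.0707, abs=1e-3)

    def test_monomorphic_untestable(self):
        with pytest.raises(ValueError, match="untestable"):
            ttest_association([1, 2, 3, 4], [0, 0, 0, 0])

    def test_welch_flag_changes_statistic(self):
        y = [1.0, 1.1, 0.9, 1.0, 5.0, 9.0, 1.0, 13.0]
        a = [0, 0, 0, 0, 1, 1, 1, 1]
        t_pooled, _ = ttest_association(y, a)
        t_welch, p_welch = ttest_association(y, a, welch=True)
        assert t_pooled == pytest.approx(t_welch, abs=1e-12)  # equal group sizes
        _, p_pooled = ttest_association(y, a)
        assert p_welch != p_pooled

    def test_matches_permutation_ranking(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=12)
        a = np.array([0] * 6 + [1] * 6)
        t_obs, p_analytic = ttest_association(y, a)
        perm_t = []
        for _ in range(2000):
            perm_t.append(ttest_association(y, rng.permutation(a))[0])
        p_perm = np.mean(np.abs(perm_t) >= abs(t_obs))
        assert abs(p_perm - p_analytic) < 0.05


class TestMafFilter:
    def test_rare_snp_removed(self):
        geno = pd.DataFrame(
            {"common": [0, 1] * 90, "rare": [1] + [0] * 179},
            index=[f"h{i}" for i in range(180)],
        )
        out = maf_filter(geno, 0.01)
        assert list(out.columns) == ["common"]

    def test_floor_zero_is_identity(self):
        geno = pd.DataFrame({"a": [0, 1, 0], "b": [1, 1, 1]}, index=list("xyz"))
        assert maf_filter(geno, 0.0).equals(geno)

    def test_all_monomorphic_warns_and_empties(self):
        geno = pd.DataFrame({"a": [1, 1, 1], "b": [0, 0, 0]}, index=list("xyz"))
        with pytest.warns(UserWarning, match="no SNP"):
            out = maf_filter(geno, 0.01)
        assert out.shape[1] == 0


class TestGwasScan:
    def test_perfectly_associated_snp_attains_min_p(self):
        rng = np.random.default_rng(4)
        ids = [f"h{i:03d}" for i in range(180)]
        alleles = np.array([0] * 90 + [1] * 90)
        strengths = np.where(alleles == 1, 10.0, 1.0) + rng.normal(0, 0.1, 180)
        geno = pd.DataFrame(
            {
                "causal": alleles,
                "noise1": rng.integers(0, 2, 180),
                "noise2": rng.integers(0, 2, 180),
            },
            index=ids,
        )
        table = gwas_scan({"hs": dict(zip(ids, strengths))}, geno, threshold=1e-3)
        best = table.loc[table["p"].idxmin()]
        assert best["snp_id"] == "causal"
        assert bool(best["significant"])

    def test_scan_invariant_to_row_and_column_order(self):
        rng = np.random.default_rng(6)
        ids = [f"h{i}" for i in range(20)]
        strengths = dict(zip(ids, rng.normal(size=20)))
        geno = pd.DataFrame(
            rng.integers(0, 2, size=(20, 4)), index=ids, columns=list("abcd")
        )
        t1 = gwas_scan({"hs": strengths}, geno)
        t2 = gwas_scan({"hs": strengths}, geno.iloc[::-1, ::-1])
        m1 = t1.set_index("snp_id")["p"].sort_index()
        m2 = t2.set_index("snp_id")["p"].sort_index()
        assert np.allclose(m1, m2)

    def test_empty_profiles_give_empty_table(self):
        geno = pd.DataFrame({"a": [0, 1]}, index=["x", "y"])
        assert len(gwas_scan({}, geno)) == 0

    def test_id_mismatch_lists_missing(self):
        geno = pd.DataFrame({"a": [0, 1]}, index=["x", "y"])
        with pytest.raises(KeyError, match="missing"):
            gwas_scan({"hs": {"x": 1.0, "zz": 2.0}}, geno)

    def test_cis_trans_annotation(self):
        ids = [f"h{i}" for i in range(8)]
        strengths = dict(zip(ids, [1, 2, 3, 4, 5, 6, 7, 8.0]))
        geno = pd.DataFrame(
            {"s1": [0, 1] * 4, "s2": [0, 0, 1, 1] * 2}, index=ids
        )
        table = gwas_scan(
            {"hs": strengths}, geno,
            hotspot_chrom={"hs": "6"}, snp_chrom={"s1": "6", "s2": "12"},
        )
        ct = dict(zip(table["snp_id"], table["cis_trans"]))
        assert ct == {"s1": "cis", "s2": "trans"}


class TestCombineByChromosome:
    def test_single_hotspot_standardization(self):
        out = combine_by_chromosome({"1": {"hs": {"a": 1.0, "b": 2.0, "c": 3.0}}})
        vals = out["1"].values
        sd = np.std([1, 2, 3])
        assert vals["a"] == pytest.approx(-1 / sd)
        assert vals["b"] == pytest.approx(0.0)
        assert vals["c"] == pytest.approx(1 / sd)

    def test_identical_hotspots_average_to_same_vector(self):
        hs = {"a": 1.0, "b": 2.0, "c": 3.0}
        single = combine_by_chromosome({"1": {"h1": hs}})["1"].values
        double = combine_by_chromosome({"1": {"h1": hs, "h2": dict(hs)}})["1"].values
        assert single == pytest.approx(double)

    def test_opposite_hotspots_cancel(self):
        out = combine_by_chromosome(
            {"1": {"h1": {"a": 1.0, "b": 2.0, "c": 3.0},
                   "h2": {"a": 3.0, "b": 2.0, "c": 1.0}}}
        )
        assert all(v == pytest.approx(0.0) for v in out["1"].values.values())

    def test_combined_mean_is_zero(self):
        rng = np.random.default_rng(2)
        hotspots = {
            f"h{k}": {f"i{j}": float(rng.normal()) for j in range(30)}
            for k in range(5)
        }
        out = combine_by_chromosome({"2": hotspots})
        assert np.mean(list(out["2"].values.values())) == pytest.approx(0.0, abs=1e-9)
        assert out["2"].n_hotspots_combined == 5

    def test_zero_sd_hotspot_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="zero SD"):
            out = combine_by_chromosome(
                {"1": {"flat": {"a": 1.0, "b": 1.0},
                       "ok": {"a": 0.0, "b": 2.0}}}
            )
        assert out["1"].n_hotspots_combined == 1

    def test_chromosome_without_usable_hotspot_omitted(self):
        with pytest.warns(UserWarning):
            out = combine_by_chromosome({"9": {"flat": {"a": 1.0, "b": 1.0}}})
        assert out == {}
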
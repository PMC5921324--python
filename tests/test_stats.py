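"""Group statistics: permutation test, ANCOVA, partial correlation,
demographics, normality, multiplicity control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dkinet import (
    RegionalMetricTable,
    adjust_pvalues,
    ancova_group_effect,
    demographics_compare,
    gm_permutation_test,
    normality_check,
    partial_correlation,
)


def make_table(values, prefix="s", group="g"):
    n, m = values.shape
    return RegionalMetricTable(
        subject_ids=[f"{prefix}{i}" for i in range(n)], groups=[group] * n,
        regions=[f"R{j}" for j in range(m)], values=values,
    )


class TestPermutation:
    def test_identical_tables_give_p_one(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(size=(10, 15))
        ta, tb = make_table(vals, "a"), make_table(vals, "b")
        res = gm_permutation_test(ta, tb, [0.2, 0.3], n_perm=49, seed=1)
        for r in res.values():
            assert np.allclose(r.observed_diff, 0.0)
            assert np.all(r.p == 1.0)

    def test_p_never_zero_and_bounded(self):
        rng = np.random.default_rng(1)
        ta = make_table(rng.lognormal(size=(9, 12)), "a")
        tb = make_table(rng.lognormal(size=(8, 12)), "b")
        res = gm_permutation_test(ta, tb, [0.25], n_perm=99, seed=2)
        for r in res.values():
            assert np.all(r.p >= 1 / 100)
            assert np.all(r.p <= 1.0)

    def test_region_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        ta = make_table(rng.lognormal(size=(5, 4)))
        tb = RegionalMetricTable(["x"] * 5, ["g"] * 5,
                                 ["Q1", "Q2", "Q3", "Q4"],
                                 rng.lognormal(size=(5, 4)))
        with pytest.raises(ValueError, match="region labels"):
            gm_permutation_test(ta, tb, [0.2], n_perm=9, seed=0)

    def test_nperm_validation(self):
        rng = np.random.default_rng(3)
        ta = make_table(rng.lognormal(size=(5, 6)))
        tb = make_table(rng.lognormal(size=(5, 6)))
        with pytest.raises(ValueError, match="n_perm"):
            gm_permutation_test(ta, tb, [0.2], n_perm=0)

    def test_significant_ranges_are_contiguous_runs(self):
        from dkinet.stats import _contiguous_ranges

        s = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        sig = np.array([True, True, False, True, True])
        assert _contiguous_ranges(s, sig) == [(0.1, 0.2), (0.4, 0.5)]


class TestAncova:
    def test_reduces_to_t_squared_without_covariates(self):
        rng = np.random.default_rng(4)
        vals = np.r_[rng.normal(0, 1, 12), rng.normal(0.8, 1, 10)]
        group = np.r_[["a"] * 12, ["b"] * 10]
        res = ancova_group_effect(vals, group)
        t, p = sps.ttest_ind(vals[:12], vals[12:], equal_var=True)
        assert res.f_statistic == pytest.approx(t**2, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_constant_covariates_equal_plain_anova(self):
        rng = np.random.default_rng(5)
        vals = np.r_[rng.normal(0, 1, 10), rng.normal(1, 1, 10)]
        group = np.r_[["a"] * 10, ["b"] * 10]
        with pytest.raises(ValueError, match="collinear"):
            ancova_group_effect(vals, group, age=np.full(20, 70.0))

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(6)
        age = rng.uniform(60, 85, 40)
        sex = rng.choice(["F", "M"], 40)
        group = np.r_[["a"] * 20, ["b"] * 20]
        vals = 0.02 * age + 0.1 * (sex == "F") + rng.normal(0, 1, 40)
        vals[20:] += 3.0
        res = ancova_group_effect(vals, group, age=age, sex=sex)
        assert res.p < 1e-3
        assert res.covariates == ("age", "sex")

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(7)
        ps = []
        group = np.r_[["a"] * 12, ["b"] * 12]
        for _ in range(300):
            age = rng.uniform(60, 85, 24)
            sex = rng.choice(["F", "M"], 24)
            vals = rng.normal(0, 1, 24)
            ps.append(ancova_group_effect(vals, group, age=age, sex=sex).p)
        stat, p = sps.kstest(ps, "uniform")
        assert p > 0.01

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="3 subjects"):
            ancova_group_effect(np.arange(4.0), ["a", "a", "b", "b"])


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        res = partial_correlation(x, y)
        r, p = sps.pearsonr(x, y)
        assert res.r == pytest.approx(r)
        assert res.p == pytest.approx(p, rel=1e-6)

    def test_linear_dependence_flagged_not_evaluable(self):
        rng = np.random.default_rng(9)
        z = rng.normal(size=20)
        x = rng.normal(size=20)
        y = 2.0 * z + 1.0  # exactly linear in the covariate
        res = partial_correlation(x, y, covariates=z)
        assert not res.evaluable
        assert np.isnan(res.r)

    def test_affine_invariance_in_covariates(self):
        rng = np.random.default_rng(10)
        z = rng.normal(size=(40, 2))
        x = z @ [0.5, -0.2] + rng.normal(size=40)
        y = z @ [0.3, 0.4] + 0.6 * x + rng.normal(size=40)
        r1 = partial_correlation(x, y, covariates=z).r
        r2 = partial_correlation(x, y, covariates=3.0 * z + 7.0).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_confounded_effect_recovered(self):
        # true partial r ~ 0.5 with age confounding both variables
        rng = np.random.default_rng(11)
        rs = []
        for _ in range(100):
            age = rng.uniform(60, 90, 200)
            e1 = rng.normal(size=200)
            x = 0.05 * age + e1
            y = 0.08 * age + 0.5 * e1 + rng.normal(size=200) * np.sqrt(0.75)
            rs.append(partial_correlation(x, y, covariates=age).r)
        assert abs(np.mean(rs) - 0.5) < 0.1
        assert max(abs(np.array(rs) - 0.5)) < 0.25

    def test_cross_check_against_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(12)
        df = pd.DataFrame({
            "x": rng.normal(size=50), "y": rng.normal(size=50),
            "z": rng.normal(size=50),
        })
        df["y"] += 0.4 * df["x"] + 0.3 * df["z"]
        res = partial_correlation(df["x"].to_numpy(), df["y"].to_numpy(),
                                  covariates=df["z"].to_numpy())
        ref = pg.partial_corr(df, x="x", y="y", covar="z")
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_sample_size_guard(self):
        with pytest.raises(ValueError, match="n > k"):
            partial_correlation(np.arange(4.0), np.arange(4.0),
                                covariates=np.ones((4, 2)))


class TestDemographics:
    def cov_frame(self, rng, shift=0.0):
        n = 20
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(2 * n)],
            "group": ["patient"] * n + ["control"] * n,
            "age": np.r_[rng.normal(73 + shift, 7, n), rng.normal(70, 8, n)],
            "sex": rng.choice(["F", "M"], 2 * n),
            "MMSE": np.r_[rng.normal(19, 5, n), rng.normal(28, 1, n)],
        })

    def test_identical_groups_t_zero(self):
        rng = np.random.default_rng(13)
        df = self.cov_frame(rng)
        df.loc[df["group"] == "control", ["age", "MMSE"]] = \
            df.loc[df["group"] == "patient", ["age", "MMSE"]].to_numpy()
        out = demographics_compare(df).set_index("variable")
        assert out.loc["age", "statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["age", "p"] == pytest.approx(1.0)

    def test_chi_square_on_reference_sex_counts(self):
        # 12F/9M vs 9F/10M: Yates-corrected chi2 = 0.0907, p = 0.763
        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(40)],
            "group": ["patient"] * 21 + ["control"] * 19,
            "sex": ["F"] * 12 + ["M"] * 9 + ["F"] * 9 + ["M"] * 10,
        })
        out = demographics_compare(df).set_index("variable")
        assert out.loc["sex", "statistic"] == pytest.approx(0.0907, abs=5e-4)
        assert out.loc["sex", "p"] == pytest.approx(0.7633, abs=1e-3)

    def test_huge_shift_is_significant(self):
        rng = np.random.default_rng(14)
        out = demographics_compare(self.cov_frame(rng, shift=80.0))
        assert out.set_index("variable").loc["age", "p"] < 1e-6

    def test_tiny_group_rejected(self):
        df = pd.DataFrame({"subject_id": ["a", "b", "c"],
                           "group": ["x", "x", "y"], "age": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="at least 2"):
            demographics_compare(df)


class TestNormality:
    def test_normal_sample_rarely_rejected(self):
        rng = np.random.default_rng(15)
        rejections = sum(
            normality_check({"g": rng.normal(size=100)})["p"].iloc[0] < 0.05
            for _ in range(100)
        )
        # estimated parameters make the plain KS test conservative
        assert rejections <= 10

    def test_exponential_sample_rejected(self):
        rng = np.random.default_rng(16)
        rejections = sum(
            normality_check({"g": rng.exponential(size=200)})["p"].iloc[0] < 0.05
            for _ in range(20)
        )
        assert rejections >= 15

    def test_constant_sample_flagged(self):
        out = normality_check({"g": np.full(10, 2.5)})
        assert "degenerate" in out["note"].iloc[0]
        assert np.isnan(out["p"].iloc[0])

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError, match="n >= 4"):
            normality_check({"g": np.array([1.0, 2.0, 3.0])})


class TestAdjustPvalues:
    def test_single_p_unchanged_under_bh(self):
        assert adjust_pvalues([0.03]) == pytest.approx([0.03])

    def test_bonferroni_multiplication(self):
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04], method="bonferroni")
        assert np.allclose(out, [0.04, 0.08, 0.12, 0.16])

    def test_identity_method(self):
        p = [0.5, 0.01, 0.9]
        assert np.allclose(adjust_pvalues(p, method="none"), p)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.0, 0.5])

    @pytest.mark.parametrize("seed", range(25))
    def test_bh_matches_brute_force_step_up(self, seed):
        def bh_oracle(p):
            p = np.asarray(p)
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                idx = order[rank - 1]
                running = min(running, p[idx] * m / rank)
                adj[idx] = running
            return adj

        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1, size=int(rng.integers(2, 40)))
        assert np.allclose(adjust_pvalues(p), bh_oracle(p))
        # monotone non-decreasing in rank order
        adj = adjust_pvalues(p)
        assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-12)
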
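"""Repeated-measures statistics: gates, omnibus tests, effect sizes, ICC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import ssgpos as sp
from ssgpos import BalanceError, DegenerateVarianceError
from ssgpos.stats import friedman_test, icc_3_1, manova_pillai, normality_gate, rm_anova


class TestNormalityGate:
    def test_normal_samples_pass(self, rng):
        vals = {c: rng.normal(size=50) for c in "abcd"}
        assert normality_gate(vals) == "parametric"

    def test_normal_rejection_rate_near_alpha(self, rng):
        rejections = sum(
            normality_gate({"x": rng.normal(size=50)}) == "nonparametric"
            for _ in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_exponential_samples_detected(self, rng):
        detected = sum(
            normality_gate({"x": rng.exponential(size=30)}) == "nonparametric"
            for _ in range(200)
        )
        assert detected / 200 > 0.9

    def test_any_rejecting_condition_flags_variable(self, rng):
        vals = {"a": rng.normal(size=40), "b": rng.exponential(size=40) ** 3}
        assert normality_gate(vals) == "nonparametric"

    def test_constant_sample_warns_nonparametric(self):
        with pytest.warns(UserWarning, match="constant"):
            assert normality_gate({"a": np.full(10, 2.0)}) == "nonparametric"

    def test_too_small_sample_rejected(self):
        with pytest.raises(sp.SSGPosError, match="Shapiro"):
            normality_gate({"a": np.array([1.0, 2.0])})


def brute_force_friedman(m):
    """Rank-based recomputation with explicit loops (no ties assumed)."""
    n, k = m.shape
    ranks = np.zeros_like(m)
    for i in range(n):
        order = np.argsort(m[i])
        for r, j in enumerate(order, start=1):
            ranks[i, j] = r
    rank_sums = ranks.sum(axis=0)
    return 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3 * n * (k + 1)


class TestFriedman:
    def test_identical_rankings_closed_form(self):
        # all units rank the conditions the same way: chi2 = n(k-1) exactly
        m = np.array([[1, 2, 3], [4, 5, 6], [1, 3, 5], [0, 2, 9]], dtype=float)
        res = friedman_test(m, posthoc=False)
        assert res.statistic == pytest.approx(4 * (3 - 1), abs=1e-12)

    def test_identical_values_within_units(self):
        m = np.tile(np.array([[3.0], [5.0], [9.0]]), (1, 4))
        with pytest.raises(DegenerateVarianceError):
            friedman_test(m)

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(20):
            m = rng.normal(size=(6, 4))  # continuous: ties a.s. absent
            res = friedman_test(m, posthoc=False)
            assert res.statistic == pytest.approx(brute_force_friedman(m), abs=1e-9)

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(20):
            m = rng.integers(0, 5, size=(6, 4)).astype(float)
            if np.any(np.ptp(m, axis=1).sum() == 0):
                continue
            try:
                res = friedman_test(m, posthoc=False)
            except DegenerateVarianceError:
                continue
            ref = sps.friedmanchisquare(*m.T)
            assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_invariant_to_monotone_within_unit_transform(self, rng):
        m = rng.normal(size=(8, 4))
        a = friedman_test(m, posthoc=False).statistic
        b = friedman_test(np.exp(m), posthoc=False).statistic
        c = friedman_test(m**3, posthoc=False).statistic
        assert a == pytest.approx(b, abs=1e-12)
        assert a == pytest.approx(c, abs=1e-12)

    def test_dunn_posthoc_bonferroni(self, rng):
        m = rng.normal(size=(10, 4)) + np.array([0, 0, 0, 2.0])
        res = friedman_test(m)
        ph = res.posthoc
        assert len(ph) == 6
        assert np.all(ph["p_adj"] >= ph["p_raw"] - 1e-15)
        assert np.all(ph["p_adj"] <= 1.0)
        np.testing.assert_allclose(
            np.minimum(1.0, ph["p_raw"] * 6), ph["p_adj"], atol=1e-12
        )

    def test_needs_three_conditions(self, rng):
        with pytest.raises(BalanceError):
            friedman_test(rng.normal(size=(5, 2)))

    def test_missing_cell_rejected(self, rng):
        m = rng.normal(size=(5, 3))
        m[2, 1] = np.nan
        with pytest.raises(BalanceError):
            friedman_test(m)


class TestRmAnova:
    def test_equal_condition_means_give_zero_f(self):
        m = np.array([[1.0, 2.0], [2.0, 1.0], [5.0, 4.0], [4.0, 5.0]])
        res = rm_anova(m, posthoc=False)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.eta2p == pytest.approx(0.0, abs=1e-12)

    def test_two_conditions_f_is_squared_paired_t(self, rng):
        m = rng.normal(size=(12, 2))
        res = rm_anova(m, posthoc=False)
        t = sps.ttest_rel(m[:, 0], m[:, 1])
        assert res.statistic == pytest.approx(t.statistic**2, rel=1e-9)
        assert res.p_value == pytest.approx(t.pvalue, rel=1e-9)

    def test_ss_decomposition_conserved(self, rng):
        for _ in range(10):
            m = rng.normal(size=(8, 4)) * rng.uniform(0.5, 5)
            res = rm_anova(m, posthoc=False)
            total = res.extras["ss_condition"] + res.extras["ss_subject"] + res.extras["ss_error"]
            assert total == pytest.approx(res.extras["ss_total"], rel=1e-9)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        m = rng.normal(size=(8, 4)) + np.array([0.0, 0.3, 0.1, 0.6])
        res = rm_anova(m, posthoc=False)
        df = pd.DataFrame(m).reset_index().melt("index", var_name="cond", value_name="y")
        ref = pg.rm_anova(data=df, dv="y", within="cond", subject="index", detailed=True)
        assert res.statistic == pytest.approx(float(ref.loc[0, "F"]), rel=1e-9)
        assert res.p_value == pytest.approx(float(ref.loc[0, "p_unc"]), rel=1e-9)
        assert res.df == (float(ref.loc[0, "DF"]), float(ref.loc[1, "DF"]))

    def test_posthoc_bonferroni_caps(self, rng):
        m = rng.normal(size=(10, 4))
        res = rm_anova(m)
        assert np.all(res.posthoc["p_adj"] >= res.posthoc["p_raw"] - 1e-15)
        assert np.all(res.posthoc["p_adj"] <= 1.0)

    def test_single_unit_rejected(self, rng):
        with pytest.raises(BalanceError):
            rm_anova(rng.normal(size=(1, 4)))


class TestManovaPillai:
    def test_single_response_reduces_to_oneway_anova(self, rng):
        x = rng.normal(size=30)
        g = np.repeat([0, 1, 2], 10)
        res = manova_pillai(x, g)
        ref = sps.f_oneway(x[g == 0], x[g == 1], x[g == 2])
        assert res.extras["F"] == pytest.approx(ref.statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_hand_computed_sscp_example(self):
        # 3 groups x 2 responses, small enough to verify by explicit algebra
        x = np.array(
            [[1.0, 2.0], [2.0, 1.0], [3.0, 3.0],
             [4.0, 5.0], [5.0, 4.0], [6.0, 6.0],
             [7.0, 9.0], [8.0, 7.0], [9.0, 8.0]]
        )
        g = np.repeat([0, 1, 2], 3)
        grand = x.mean(axis=0)
        h = np.zeros((2, 2))
        e = np.zeros((2, 2))
        for lab in (0, 1, 2):
            sub = x[g == lab]
            d = (sub.mean(axis=0) - grand).reshape(2, 1)
            h += 3 * d @ d.T
            r = sub - sub.mean(axis=0)
            e += r.T @ r
        v_expected = np.trace(h @ np.linalg.inv(h + e))
        res = manova_pillai(x, g)
        assert res.statistic == pytest.approx(v_expected, rel=1e-12)

    def test_matches_statsmodels(self, rng):
        sm_manova = pytest.importorskip("statsmodels.multivariate.manova")
        x = rng.normal(size=(40, 3)) + rng.normal(size=(40, 1))
        g = np.repeat(["FR", "R1", "R2", "R3"], 10)
        res = manova_pillai(x, g)
        df = pd.DataFrame(x, columns=["y1", "y2", "y3"])
        df["g"] = g
        tab = sm_manova.MANOVA.from_formula("y1 + y2 + y3 ~ g", data=df).mv_test()
        ref = tab.results["g"]["stat"].loc["Pillai's trace"]
        assert res.statistic == pytest.approx(float(ref["Value"]), rel=1e-9)
        assert res.extras["F"] == pytest.approx(float(ref["F Value"]), rel=1e-9)
        assert res.p_value == pytest.approx(float(ref["Pr > F"]), rel=1e-9)

    def test_null_v_near_zero_with_dominant_noise(self, rng):
        vs = []
        for _ in range(200):
            x = rng.normal(size=(40, 2))
            g = np.repeat([0, 1, 2, 3], 10)
            vs.append(manova_pillai(x, g).statistic)
        # E[V] under the null is roughly s * df_h / (df_h + df_e)
        expected = 2 * 3 / (3 + 36)
        assert np.mean(vs) == pytest.approx(expected, rel=0.2)

    def test_eta2p_is_v_over_s(self, rng):
        x = rng.normal(size=(40, 3))
        g = np.repeat([0, 1, 2, 3], 10)
        res = manova_pillai(x, g)
        assert res.eta2p == pytest.approx(res.statistic / 3)

    def test_rank_deficiency_rejected(self, rng):
        x = rng.normal(size=(5, 4))
        g = np.array([0, 0, 1, 1, 1])
        with pytest.raises(DegenerateVarianceError):
            manova_pillai(x, g)


class TestEffectLabel:
    @pytest.mark.parametrize(
        "eta,label",
        [
            (0.0, "no effect"),
            (0.03, "no effect"),
            (0.04, "minimum effect"),  # boundary inclusive
            (0.10, "minimum effect"),
            (0.25, "moderate effect"),
            (0.30, "moderate effect"),
            (0.64, "strong effect"),
            (0.90, "strong effect"),
        ],
    )
    def test_taxonomy(self, eta, label):
        assert sp.effect_label(eta) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sp.effect_label(1.2)


class TestICC31:
    def test_constant_shift_gives_perfect_consistency(self, rng):
        r1 = rng.normal(size=12)
        ratings = np.column_stack([r1, r1 + 3.0])
        res = icc_3_1(ratings)
        assert res.statistic == pytest.approx(1.0)

    def test_independent_ratings_near_zero(self, rng):
        res = icc_3_1(rng.normal(size=(200, 2)))
        assert abs(res.statistic) < 0.15

    def test_matches_pingouin_consistency_single(self, rng):
        pg = pytest.importorskip("pingouin")
        ratings = rng.normal(size=(10, 3)) + rng.normal(size=(10, 1)) * 2
        res = icc_3_1(ratings)
        long = pd.DataFrame(ratings).reset_index().melt("index", var_name="rater", value_name="y")
        ref = pg.intraclass_corr(long, targets="index", raters="rater", ratings="y")
        row = ref[ref["Type"] == "ICC(C,1)"].iloc[0]
        assert res.statistic == pytest.approx(float(row["ICC"]), rel=1e-9)
        assert res.extras["F"] == pytest.approx(float(row["F"]), rel=1e-9)
        assert res.df == (float(row["df1"]), float(row["df2"]))
        lo, hi = row["CI95"]
        assert res.extras["ci"][0] == pytest.approx(lo, abs=0.005)
        assert res.extras["ci"][1] == pytest.approx(hi, abs=0.005)

    def test_anova_table_identity(self, rng):
        """F and ICC follow from the two-way ANOVA mean squares directly."""
        ratings = rng.normal(size=(8, 2)) + rng.normal(size=(8, 1))
        n, k = ratings.shape
        res = icc_3_1(ratings)
        grand = ratings.mean()
        ms_t = k * np.sum((ratings.mean(axis=1) - grand) ** 2) / (n - 1)
        ss_total = np.sum((ratings - grand) ** 2)
        ss_r = n * np.sum((ratings.mean(axis=0) - grand) ** 2)
        ms_e = (ss_total - k * np.sum((ratings.mean(axis=1) - grand) ** 2) - ss_r) / ((n - 1) * (k - 1))
        assert res.extras["F"] == pytest.approx(ms_t / ms_e, rel=1e-9)
        assert res.statistic == pytest.approx((ms_t - ms_e) / (ms_t + (k - 1) * ms_e), rel=1e-9)

    def test_constant_ratings_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            icc_3_1(np.full((6, 2), 3.0))


class TestAnalyzeConditionDataset:
    def test_routes_and_runs(self):
        from ssgpos.synthetic import make_condition_dataset

        ds = make_condition_dataset(n_sessions=4, base_seed=3, with_coordination=False)
        results = sp.analyze_condition_dataset(ds, ["sei_mean_m", "length_mean_m"])
        for var, res in results.items():
            assert res.test in ("rm_anova", "friedman")
            assert 0.0 <= res.p_value <= 1.0
            assert res.extras["route"] in ("parametric", "nonparametric")
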
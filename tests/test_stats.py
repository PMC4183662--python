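"""PERMANOVA, Spearman rank correlation and OLS R-squared."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from pilesound import (
    cumulative_mortality,
    default_mortality_design,
    delayed_mortality_response,
    immediate_mortality_response,
    linreg_r2,
    permanova,
    spearman_rho,
    synth_mortality,
)


class TestPermanovaAgainstClassicalAnova:
    def test_one_factor_two_group_f_identity(self):
        rng = np.random.default_rng(31)
        y = rng.normal(0, 1, 16)
        g = pd.DataFrame({"g": np.repeat(["a", "b"], 8)})
        res = permanova(y, g, ["g"], n_perm=99, seed=1)
        f_classic = sps.f_oneway(y[:8], y[8:]).statistic
        assert res.terms[0].pseudo_f == pytest.approx(f_classic, rel=1e-9)

    def test_one_factor_three_groups(self):
        rng = np.random.default_rng(32)
        y = rng.normal(0, 1, 18)
        g = pd.DataFrame({"g": np.repeat(["a", "b", "c"], 6)})
        res = permanova(y, g, ["g"], n_perm=99, seed=1)
        f_classic = sps.f_oneway(y[:6], y[6:12], y[12:]).statistic
        assert res.terms[0].pseudo_f == pytest.approx(f_classic, rel=1e-9)
        assert res.terms[0].df == 2

    def test_sequential_ss_matches_statsmodels_type1(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(33)
        df = pd.DataFrame(
            {
                "y": rng.normal(0, 1, 24),
                "t": np.tile(np.repeat(["e", "c"], 6), 2),
                "a": np.repeat(["68", "115"], 12),
            }
        )
        res = permanova(df["y"].to_numpy(), df[["t", "a"]],
                        ["t", "a", "t:a"], n_perm=49, seed=2)
        tab = anova_lm(smf.ols("y ~ C(t) + C(a) + C(t):C(a)", df).fit(), typ=1)
        for term, ss, f in zip(res.terms, tab["sum_sq"][:3], tab["F"][:3]):
            assert term.ss == pytest.approx(ss, rel=1e-9)
            assert term.pseudo_f == pytest.approx(f, rel=1e-9)
        assert res.residual_ss == pytest.approx(tab["sum_sq"].iloc[-1], rel=1e-9)

    def test_scikit_bio_oracle_one_way(self):
        from skbio.stats.distance import permanova as skbio_permanova, DistanceMatrix
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(34)
        y = rng.normal(0, 1, 12)
        labels = list(np.repeat(["a", "b"], 6))
        dm = DistanceMatrix(squareform(pdist(y[:, None])))
        sk = skbio_permanova(dm, labels, permutations=99)
        res = permanova(y, pd.DataFrame({"g": labels}), ["g"], n_perm=99, seed=0)
        assert res.terms[0].pseudo_f == pytest.approx(sk["test statistic"], rel=1e-9)


class TestPermanovaPermutation:
    def test_constant_response_all_ss_zero(self):
        y = np.full(12, 3.0)
        g = pd.DataFrame({"g": np.repeat(["a", "b"], 6)})
        res = permanova(y, g, ["g"], n_perm=99, seed=1)
        assert res.terms[0].ss == pytest.approx(0.0, abs=1e-20)
        assert res.total_ss == pytest.approx(0.0, abs=1e-20)
        assert res.terms[0].p_perm > 0.9

    def test_exact_enumeration_matches_sampled(self):
        y = np.array([1.0, 2.0, 3.0, 8.0, 9.0, 10.0])
        g = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            exact = permanova(y, g, ["g"], exact=True)
            sampled = permanova(y, g, ["g"], n_perm=9999, seed=5)
        # 20 distinct assignments, the 2 extreme ones reach this separation
        assert exact.terms[0].p_perm == pytest.approx(0.1, abs=1e-12)
        assert abs(exact.terms[0].p_perm - sampled.terms[0].p_perm) < 0.02

    def test_few_permutations_warns(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        g = pd.DataFrame({"g": ["a", "a", "b", "b"]})
        with pytest.warns(UserWarning, match="distinct permutations"):
            permanova(y, g, ["g"], n_perm=99, seed=0)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(35)
        y = rng.normal(0, 1, 12)
        f = pd.DataFrame({"g": np.repeat(["a", "b"], 6)})
        perm = rng.permutation(12)
        r1 = permanova(y, f, ["g"], n_perm=0)
        r2 = permanova(y[perm], f.iloc[perm].reset_index(drop=True), ["g"], n_perm=0)
        assert r1.terms[0].ss == pytest.approx(r2.terms[0].ss, rel=1e-12)
        assert r1.terms[0].pseudo_f == pytest.approx(r2.terms[0].pseudo_f, rel=1e-12)

    def test_ss_decomposition_sums_to_total(self):
        rng = np.random.default_rng(36)
        y = rng.normal(0, 1, 24)
        f = pd.DataFrame(
            {
                "t": np.tile(np.repeat(["e", "c"], 6), 2),
                "a": np.repeat(["68", "115"], 12),
            }
        )
        res = permanova(y, f, ["t", "a", "t:a"], n_perm=9, seed=1)
        total = sum(t.ss for t in res.terms) + res.residual_ss
        assert total == pytest.approx(res.total_ss, rel=1e-10)

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(37)
        y = np.concatenate([rng.normal(0, 1, 10), rng.normal(8, 1, 10)])
        g = pd.DataFrame({"g": np.repeat(["a", "b"], 10)})
        res = permanova(y, g, ["g"], n_perm=999, seed=2)
        assert res.terms[0].p_perm <= 0.01
        assert res.terms[0].p_mc <= 0.01

    def test_single_level_factor_errors(self):
        y = np.arange(6.0)
        g = pd.DataFrame({"g": ["a"] * 6})
        with pytest.raises(ValueError, match="single level"):
            permanova(y, g, ["g"], n_perm=9, seed=0)

    def test_type_one_error_calibration(self):
        # null simulation: rejection rate at alpha=0.05 inside the 95%
        # binomial interval for 1000 replicates
        alpha, n_sim, n_perm = 0.05, 1000, 199
        g = pd.DataFrame({"g": np.repeat(["a", "b"], 6)})
        rejections = 0
        for i in range(n_sim):
            y = np.random.default_rng(1000 + i).normal(0, 1, 12)
            res = permanova(y, g, ["g"], n_perm=n_perm, seed=5_000_000 + i)
            rejections += res.terms[0].p_perm <= alpha
        rate = rejections / n_sim
        half = 1.96 * math.sqrt(alpha * (1 - alpha) / n_sim)
        assert alpha - half <= rate <= alpha + half


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert spearman_rho([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(38)
        x = rng.integers(0, 5, 30).astype(float)
        y = rng.integers(0, 5, 30).astype(float)
        assert spearman_rho(x, y) == pytest.approx(
            sps.spearmanr(x, y).statistic, rel=1e-12
        )

    def test_constant_input_warns_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            assert math.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-1000, 1000), min_size=4, max_size=20, unique=True))
    def test_invariant_to_monotone_transform(self, xs):
        rng = np.random.default_rng(len(xs))
        ys = rng.normal(0, 1, len(xs))
        x = np.asarray(xs, dtype=float)
        rho = spearman_rho(x, ys)
        # exp(x/1000) is strictly monotone and keeps these values distinct
        rho_t = spearman_rho(np.exp(x / 1000), ys)
        assert rho == pytest.approx(rho_t, abs=1e-12)


class TestLinregR2:
    def test_collinear_points(self):
        assert linreg_r2([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        assert linreg_r2([1, 2, 3], [1, 2, 2]) == pytest.approx(0.75)

    def test_null_case_near_zero(self):
        rng = np.random.default_rng(39)
        x = np.arange(2000.0)
        y = rng.normal(0, 1, 2000)
        assert linreg_r2(x, y) < 0.01

    def test_matches_scipy_linregress(self):
        rng = np.random.default_rng(40)
        x = rng.normal(0, 1, 50)
        y = 2 * x + rng.normal(0, 1, 50)
        assert linreg_r2(x, y) == pytest.approx(
            sps.linregress(x, y).rvalue ** 2, rel=1e-12
        )

    def test_constant_x_errors(self):
        with pytest.raises(ValueError):
            linreg_r2([1, 1, 1], [1, 2, 3])


class TestMortalityTables:
    def test_cumulative_mortality_fraction(self):
        d = default_mortality_design(seed=8, p_immediate_exposed=0.0167)
        t = synth_mortality(d)
        cm = cumulative_mortality(t)
        assert (cm.groupby(["experiment", "treatment"])["mortality_pct"]
                  .apply(lambda s: np.all(np.diff(s) >= 0)).all())
        # 2 dead of 120 at day 0 is 1.67 %
        sub = t[(t.experiment == 1) & (t.treatment == "exposed") & (t.day == 0)]
        dead, init = sub["n_dead"].sum(), (sub["n_alive"] + sub["n_dead"]).sum()
        row = cm[(cm.experiment == 1) & (cm.treatment == "exposed") & (cm.day == 0)]
        assert row["mortality_pct"].iloc[0] == pytest.approx(100 * dead / init)

    def test_missing_day_rejected(self):
        t = synth_mortality(default_mortality_design(seed=9))
        broken = t[t["day"] != 3]
        with pytest.raises(ValueError, match="missing days"):
            cumulative_mortality(broken)

    def test_immediate_response_is_per_vial(self):
        t = synth_mortality(default_mortality_design(seed=10))
        y, factors = immediate_mortality_response(t)
        assert y.size == 8 * 6  # 4 experiments x 2 treatments x 6 vials
        assert set(factors.columns) == {"treatment", "age"}

    def test_delayed_response_covers_followup_days(self):
        t = synth_mortality(default_mortality_design(seed=11))
        y, factors = delayed_mortality_response(t)
        assert y.size == 8 * 6 * 14
        assert set(factors["day"].astype(int)) == set(range(1, 15))

    def test_full_design_permanova_runs(self):
        t = synth_mortality(default_mortality_design(seed=12,
                                                     p_immediate_exposed=0.02,
                                                     p_immediate_control=0.02))
        y, factors = immediate_mortality_response(t)
        res = permanova(y, factors, ["treatment", "age", "treatment:age"],
                        n_perm=199, seed=3)
        assert res.residual_df == y.size - 1 - sum(t_.df for t_ in res.terms)
        assert all(0 <= t_.p_perm <= 1 for t_ in res.terms)
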
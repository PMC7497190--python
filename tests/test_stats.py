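"""Refraction arithmetic, normalising transform, partial correlation,
backward-stepwise regression and univariate group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from scenedefocus import (CollinearityError, DegenerateInputError,
                          InsufficientGroupError, StepwiseOLS,
                          group_comparisons, spearman_partial,
                          spherical_equivalent, stepwise_backward,
                          two_step_transform)


@pytest.mark.parametrize("s,c,expected", [
    (0.0, 0.0, 0.0),
    (-2.00, -1.00, -2.50),
    (1.00, -0.50, 0.75),
])
def test_spherical_equivalent(s, c, expected):
    assert spherical_equivalent(s, c) == pytest.approx(expected)


class TestTwoStepTransform:
    def test_three_values_hand_computed(self):
        # ranks {1,2,3} -> Blom fractions (r-3/8)/(3+1/4) = {0.1923, 0.5,
        # 0.8077} -> normal scores {-0.8694, 0, +0.8694} -> rescaled to
        # mean 2, SD 1 gives back {1, 2, 3}
        frac = (np.arange(1, 4) - 0.375) / 3.25
        np.testing.assert_allclose(frac, [0.1923, 0.5, 0.8077], atol=5e-5)
        z = sps.norm.ppf(frac)
        np.testing.assert_allclose(z, [-0.8694, 0.0, 0.8694], atol=5e-5)
        out = two_step_transform([1.0, 2.0, 3.0])
        np.testing.assert_allclose(out, [1.0, 2.0, 3.0], atol=1e-12)

    def test_rank_preservation(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(0, 1, 50)
        out = two_step_transform(x)
        assert sps.spearmanr(x, out).statistic == pytest.approx(1.0)
        # mean and SD match the input
        assert out.mean() == pytest.approx(x.mean())
        assert out.std(ddof=1) == pytest.approx(x.std(ddof=1))

    def test_spearman_with_third_variable_invariant(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(0, 1, 60)
        y = rng.normal(0, 1, 60) + 0.5 * np.log(x)
        before = sps.spearmanr(x, y).statistic
        after = sps.spearmanr(two_step_transform(x), y).statistic
        assert after == pytest.approx(before, abs=1e-12)

    def test_normality_improves_for_lognormal_sample(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(0, 1, 50)

        def ks(v):
            return sps.kstest(v, "norm",
                              args=(v.mean(), v.std(ddof=1))).statistic

        assert ks(two_step_transform(x)) < ks(x)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            two_step_transform([1.0, 1.0, 1.0])
        with pytest.raises(DegenerateInputError):
            two_step_transform([1.0, 2.0])


def brute_force_partial_spearman(x, y, z):
    """Independent evaluation of the partial-correlation formula on ranks."""
    rx, ry, rz = (sps.rankdata(v) for v in (x, y, z))

    def r(a, b):
        am, bm = a - a.mean(), b - b.mean()
        return float((am * bm).sum()
                     / np.sqrt((am**2).sum() * (bm**2).sum()))

    rxy, rxz, ryz = r(rx, ry), r(rx, rz), r(ry, rz)
    return (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))


class TestSpearmanPartial:
    def test_matches_brute_force_oracle_small_n(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x, y, z = rng.normal(size=(3, 6))
            got = spearman_partial(x, y, z).rho
            assert got == pytest.approx(brute_force_partial_spearman(x, y, z),
                                        abs=1e-12)

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        x, y, z = rng.normal(size=(3, 40))
        got = spearman_partial(x, y, z)
        ref = pg.partial_corr(pd.DataFrame({"x": x, "y": y, "z": z}),
                              x="x", y="y", covar="z", method="spearman")
        assert got.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert got.p_value == pytest.approx(float(ref["p_val"].iloc[0]),
                                            abs=1e-8)

    def test_independent_control_reduces_to_plain_spearman(self):
        rng = np.random.default_rng(5)
        n = 1000
        x = rng.normal(size=n)
        y = 0.4 * x + rng.normal(size=n)
        z = rng.normal(size=n)
        partial = spearman_partial(x, y, z).rho
        plain = sps.spearmanr(x, y).statistic
        assert partial == pytest.approx(plain, abs=0.02)

    def test_identical_variables_fully_correlated(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        z = rng.normal(size=30)
        res = spearman_partial(x, x, z)
        assert res.rho == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_control_rejected(self):
        x = np.arange(10.0)
        y = np.random.default_rng(7).normal(size=10)
        with pytest.raises(DegenerateInputError):
            spearman_partial(x, y, control=2 * x + 1)

    def test_no_control_is_plain_spearman(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=(2, 25))
        ref = sps.spearmanr(x, y)
        got = spearman_partial(x, y)
        assert got.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert got.p_value == pytest.approx(ref.pvalue, abs=1e-9)


def noisy_design(rng, n=60):
    X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
    return X


class TestStepwiseBackward:
    def test_all_significant_keeps_full_model(self):
        rng = np.random.default_rng(9)
        X = noisy_design(rng, 200)
        y = 1.0 + 2.0 * X["a"] - 1.5 * X["b"] + 0.8 * X["c"] \
            + rng.normal(0, 0.5, 200)
        res = stepwise_backward(X, y)
        assert res.removal_trace == []
        assert res.retained == ["a", "b", "c"]
        assert res.params["a"] == pytest.approx(2.0, abs=0.15)

    def test_null_predictors_removed_signal_kept(self):
        rng = np.random.default_rng(10)
        n = 300
        X = pd.DataFrame(rng.normal(size=(n, 5)),
                         columns=["signal", "n1", "n2", "n3", "n4"])
        y = -0.7 * X["signal"] + rng.normal(0, 0.5, n)
        res = stepwise_backward(X, y)
        assert "signal" in res.retained
        assert res.params["signal"] < 0
        removed = {d["term"] for d in res.removal_trace}
        assert removed <= {"n1", "n2", "n3", "n4"}

    def test_invariant_to_predictor_ordering(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(80, 6)),
                         columns=list("abcdef"))
        y = 0.9 * X["c"] + rng.normal(0, 1, 80)
        res1 = stepwise_backward(X, y)
        res2 = stepwise_backward(X[list("fedcba")], y)
        assert set(res1.retained) == set(res2.retained)
        for t in res1.retained:
            assert res1.params[t] == pytest.approx(res2.params[t], rel=1e-10)

    def test_standardized_b_identity(self):
        rng = np.random.default_rng(12)
        X = noisy_design(rng, 150)
        y = pd.Series(2.0 * X["a"] - X["b"] + rng.normal(0, 0.4, 150))
        res = stepwise_backward(X, y)
        for t in res.retained:
            expected = res.params[t] * X[t].std(ddof=1) / y.std(ddof=1)
            assert res.std_params[t] == pytest.approx(expected, rel=1e-8)

    def test_vif_near_one_for_orthogonal_noise(self):
        rng = np.random.default_rng(13)
        X = noisy_design(rng, 400)
        y = X.sum(axis=1) + rng.normal(0, 0.3, 400)
        res = stepwise_backward(X, y)
        assert (res.vif >= 1.0).all()
        assert (res.vif < 1.1).all()

    def test_singular_design_names_offenders(self):
        rng = np.random.default_rng(14)
        X = noisy_design(rng, 50)
        X["dup"] = 2.0 * X["a"]
        with pytest.raises(CollinearityError) as err:
            stepwise_backward(X, rng.normal(size=50))
        assert "dup" in str(err.value) or "a" in str(err.value)

    def test_model_results_interface(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame(rng.normal(size=(100, 4)),
                          columns=["y", "a", "b", "c"])
        df["y"] = df["y"] + 1.2 * df["a"]
        model = StepwiseOLS.from_dataframe(df, "y", ["a", "b", "c"])
        res = model.fit()
        ci = res.conf_int()
        assert ci.loc["a", 0] < res.params["a"] < ci.loc["a", 1]
        text = res.summary()
        assert "adjusted R^2" in text and "a" in text
        assert res.df_model + res.df_resid == res.nobs - 1


def toy_cohort(n=60, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "delta_m": rng.normal(-0.5, 0.4, n),
        "home_size_group": rng.choice(["Small", "Medium", "Large"], n),
        "parental_myopia": rng.choice([0, 1, 2], n),
        "desk_time": rng.uniform(0.5, 5.0, n),
        "outdoor_time": rng.uniform(0.5, 8.0, n),
        "dv": rng.normal(1.0, 0.8, n),
        "dv_2m": rng.normal(0.8, 0.8, n),
        "sd_d": rng.lognormal(-0.7, 0.5, n),
    })
    return df


class TestGroupComparisons:
    def test_identical_groups_give_null_t(self):
        df = toy_cohort()
        vals = np.tile(np.linspace(-1, 0, 30), 2)
        df = df.iloc[:60].copy()
        df["delta_m"] = vals
        df["desk_time"] = np.r_[np.full(30, 1.0), np.full(30, 3.0)]
        out = group_comparisons(df)
        assert out["desk_time"]["t_test"]["t"] == pytest.approx(0.0, abs=1e-12)
        assert out["desk_time"]["t_test"]["p"] == pytest.approx(1.0)

    def test_weighted_group_means_reproduce_overall_mean(self):
        df = toy_cohort(seed=3)
        out = group_comparisons(df)
        for partition in ("home_size", "parental_myopia"):
            groups = out[partition]["groups"].values()
            wmean = (sum(g["n"] * g["mean"] for g in groups)
                     / sum(g["n"] for g in groups))
            assert wmean == pytest.approx(out["overall"]["mean"], abs=1e-12)

    def test_bonferroni_caps_at_one(self):
        df = toy_cohort(seed=4)
        out = group_comparisons(df)
        for p in out["home_size"]["bonferroni_delta_m"].values():
            assert 0.0 <= p <= 1.0

    def test_type_i_error_rate_of_anova(self):
        # all three groups drawn from one distribution: ~5% rejections
        rng = np.random.default_rng(5)
        rejections = 0
        reps = 400
        for _ in range(reps):
            groups = {k: rng.normal(0, 1, 15) for k in "abc"}
            from scenedefocus.stats import anova_oneway
            if anova_oneway(groups)["p"] < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.03)

    def test_small_group_rejected(self):
        df = toy_cohort(seed=6)
        df.loc[:, "home_size_group"] = "Small"
        df.loc[0, "home_size_group"] = "Medium"
        df.loc[1, "home_size_group"] = "Large"
        with pytest.raises(InsufficientGroupError):
            group_comparisons(df)
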
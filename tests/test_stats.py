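"""Statistical battery: closed-form and cross-implementation oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from glustress import stats


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert stats.spearman_correlation(x, np.exp(x)).r == pytest.approx(1.0)
        assert stats.spearman_correlation(x, -x ** 3).r == pytest.approx(-1.0)

    def test_tied_data_matches_hand_ranked_pearson(self):
        # {1,1,2} -> average ranks (1.5, 1.5, 3); {3,5,4} -> (1, 3, 2)
        expected = np.corrcoef([1.5, 1.5, 3], [1, 3, 2])[0, 1]
        got = stats.spearman_correlation([1, 1, 2], [3, 5, 4])
        assert got.r == pytest.approx(expected, abs=1e-12)
        assert got.df == 1

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError):
            stats.spearman_correlation([1, 1, 1], [1, 2, 3])


class TestPartialCorrelation:
    def test_no_covariates_reduces_to_pearson(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert stats.pearson_partial_correlation(x, y).r \
            == pytest.approx(sps.pearsonr(x, y)[0], abs=1e-12)

    def test_matches_recursive_closed_form(self):
        # 8-point trivariate toy against r_xy.z closed form
        rng = np.random.default_rng(2)
        x, y, z = rng.normal(size=(3, 8))
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        got = stats.pearson_partial_correlation(x, y, z)
        assert got.r == pytest.approx(expected, abs=1e-10)
        assert got.df == 8 - 2 - 1

    def test_residual_path_agrees_with_pingouin(self):
        import pingouin as pg
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(40, 5)),
                          columns=["x", "y", "a", "b", "c"])
        ref = pg.partial_corr(df, x="x", y="y", covar=["a", "b", "c"])
        got = stats.pearson_partial_correlation(df["x"], df["y"],
                                                df[["a", "b", "c"]])
        assert got.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)

    def test_exact_linear_dependence_guard(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=20)
        with pytest.raises(ValueError):
            stats.pearson_partial_correlation(rng.normal(size=20),
                                              2 * z + 1, z)

    def test_rank_deficient_covariates_rejected(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=20)
        cov = np.column_stack([z, 2 * z])
        with pytest.raises(ValueError):
            stats.pearson_partial_correlation(rng.normal(size=20),
                                              rng.normal(size=20), cov)


class TestGgEpsilon:
    def test_compound_symmetry_gives_one(self):
        k = 4
        S = 0.3 * np.ones((k, k)) + 0.7 * np.eye(k)
        assert stats.gg_epsilon(S) == pytest.approx(1.0, abs=1e-12)

    def test_bounds_on_random_covariances(self):
        rng = np.random.default_rng(6)
        for k in (3, 4, 5):
            for _ in range(200):
                A = rng.normal(size=(k, k + 2))
                S = A @ A.T
                eps = stats.gg_epsilon(S)
                assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12


def _long(wide, groups=None):
    n, k = wide.shape
    df = pd.DataFrame({
        "subj": np.repeat(np.arange(n), k),
        "time": np.tile(np.arange(k), n),
        "y": wide.ravel()})
    if groups is not None:
        df["grp"] = np.repeat(groups, k)
    return df


class TestRmAnova:
    def test_constant_profiles_give_zero_f(self):
        wide = np.tile(np.array([[1.0], [2.0], [5.0], [3.0]]), (1, 3))
        res = stats.rm_anova_gg(_long(wide), "y", "time", "subj")
        assert res.effect("time").F == 0.0
        assert res.effect("time").p == 1.0

    def test_two_levels_no_correction(self):
        rng = np.random.default_rng(7)
        wide = rng.normal(size=(8, 2))
        res = stats.rm_anova_gg(_long(wide), "y", "time", "subj",
                                correction="always")
        eff = res.effect("time")
        assert eff.eps == 1.0
        assert eff.df1 == 1.0 and eff.df2 == 7.0

    def test_hand_worked_one_way_toy(self):
        # 6 subjects x 3 timepoints; oracle from the classical SS partition
        wide = np.array([[3.0, 4.0, 6.0], [2.0, 4.0, 5.0], [4.0, 4.0, 7.0],
                         [3.0, 5.0, 6.0], [1.0, 3.0, 4.0], [5.0, 6.0, 8.0]])
        n, k = wide.shape
        grand = wide.mean()
        ss_time = n * ((wide.mean(0) - grand) ** 2).sum()
        ss_subj = k * ((wide.mean(1) - grand) ** 2).sum()
        ss_err = ((wide - grand) ** 2).sum() - ss_time - ss_subj
        F_expected = (ss_time / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
        # epsilon oracle from the eigenvalues of the centered covariance
        S = np.cov(wide, rowvar=False)
        H = np.eye(k) - 1.0 / k
        lam = np.linalg.eigvalsh(H @ S @ H)
        eps_expected = lam.sum() ** 2 / ((k - 1) * (lam ** 2).sum())
        res = stats.rm_anova_gg(_long(wide), "y", "time", "subj",
                                correction="never")
        eff = res.effect("time")
        assert eff.F == pytest.approx(F_expected, abs=1e-9)
        assert eff.eps == pytest.approx(eps_expected, abs=1e-9)

    def test_gg_correction_shrinks_dfs(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=(12, 1))
        wide = np.column_stack([base[:, 0],
                                base[:, 0] * 3 + rng.normal(size=12),
                                rng.normal(size=12) * 0.2])
        res = stats.rm_anova_gg(_long(wide), "y", "time", "subj",
                                correction="always")
        eff = res.effect("time")
        assert eff.eps < 1.0
        assert eff.df1 == pytest.approx(2 * eff.eps)

    def test_split_plot_quadratic_contrast(self):
        # one group rises linearly, the other dips at the middle level:
        # the quadratic trend x group interaction must be large
        rng = np.random.default_rng(9)
        n = 10
        lin = np.array([0.0, 1.0, 2.0])
        quad = np.array([0.0, -2.0, 0.0])
        wide = np.vstack([lin + 0.1 * rng.normal(size=(n, 3)),
                          quad + 0.1 * rng.normal(size=(n, 3))])
        groups = np.repeat(["a", "b"], n)
        res = stats.rm_anova_gg(_long(wide, groups), "y", "time", "subj",
                                between="grp")
        inter = res.effect("time_quadratic*grp")
        assert inter.F > 30
        assert inter.p < 1e-4


class TestStepwise:
    def test_exact_block1_fit_enters_nothing(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=40)
        y = 2.0 + 3.0 * x
        b1 = pd.DataFrame({"x": x})
        b2 = pd.DataFrame({"z": rng.normal(size=40)})
        res = stats.hierarchical_stepwise_regression(y, b1, b2)
        assert res.r2 == pytest.approx(1.0)
        assert res.entry_trace == []

    def test_orthogonal_candidate_not_entered(self):
        rng = np.random.default_rng(11)
        n = 1000
        x = rng.normal(size=n)
        y = x + rng.normal(size=n)
        z = rng.normal(size=n)          # independent of y given x
        res = stats.hierarchical_stepwise_regression(
            y, pd.DataFrame({"x": x}), pd.DataFrame({"z": z}))
        assert all(t.name != "z" for t in res.terms)

    def test_informative_candidate_enters_and_fchange_matches_formula(self):
        rng = np.random.default_rng(12)
        n = 10
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        y = x + 2 * z + 0.1 * rng.normal(size=n)
        b1, b2 = pd.DataFrame({"x": x}), pd.DataFrame({"z": z})
        res = stats.hierarchical_stepwise_regression(y, b1, b2)
        assert [t.name for t in res.terms] == ["x", "z"]
        # oracle: R^2s from independent lstsq fits and the F-change formula
        X1 = np.column_stack([np.ones(n), x])
        X2 = np.column_stack([np.ones(n), x, z])
        r2 = []
        for X in (X1, X2):
            yhat = X @ np.linalg.lstsq(X, y, rcond=None)[0]
            r2.append(1 - ((y - yhat) ** 2).sum()
                      / ((y - y.mean()) ** 2).sum())
        dfe = n - 3
        F_expected = (r2[1] - r2[0]) / ((1 - r2[1]) / dfe)
        assert res.f_change == pytest.approx(F_expected, abs=1e-9)
        assert res.f_change_p == pytest.approx(
            float(sps.f.sf(F_expected, 1, dfe)), abs=1e-12)

    def test_entry_order_reproducible(self):
        rng = np.random.default_rng(13)
        n = 60
        X = rng.normal(size=(n, 3))
        y = X @ [1.0, 0.5, 0.25] + rng.normal(size=n)
        b1 = pd.DataFrame({"x0": X[:, 0]})
        b2 = pd.DataFrame({"x1": X[:, 1], "x2": X[:, 2]})
        t1 = stats.hierarchical_stepwise_regression(y, b1, b2).entry_trace
        t2 = stats.hierarchical_stepwise_regression(y, b1, b2).entry_trace
        assert t1 == t2

    def test_standardized_beta_definition(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=50)
        y = 3 * x + rng.normal(size=50)
        res = stats.hierarchical_stepwise_regression(
            y, pd.DataFrame({"x": x}), pd.DataFrame())
        t = res.term("x")
        assert t.beta == pytest.approx(t.coef * x.std(ddof=1)
                                       / y.std(ddof=1))


class TestQuadraticModel:
    def test_exact_quadratic_signal(self):
        x = np.linspace(0, 10, 20)
        y = 1 + 2 * x - 0.5 * x ** 2
        res = stats.quadratic_term_model(y, x)
        assert res.r2 == pytest.approx(1.0)
        assert res.f_change_p < 1e-12

    def test_linear_signal_nominal_type1(self):
        # under a purely linear law the quadratic increment is null;
        # the p-value should be approximately uniform over replicates
        rng = np.random.default_rng(15)
        hits = 0
        reps = 400
        for _ in range(reps):
            x = rng.uniform(0, 40, 50)
            y = 1 - 0.5 * x + rng.normal(size=50)
            if stats.quadratic_term_model(y, x).f_change_p < 0.05:
                hits += 1
        assert hits / reps == pytest.approx(0.05, abs=0.03)


class TestSteigerZ:
    def test_equal_correlations_give_zero(self):
        res = stats.steiger_z(0.4, 0.4, 0.2, 40)
        assert res.z == 0.0
        assert res.p == pytest.approx(1.0)

    def test_antisymmetry(self):
        a = stats.steiger_z(0.5, 0.1, 0.3, 50)
        b = stats.steiger_z(0.1, 0.5, 0.3, 50)
        assert a.z == pytest.approx(-b.z, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_matches_independent_formula_transcription(self):
        # independent implementation of the pooled-r Z1* statistic
        def oracle(r12, r13, r23, n):
            rb = (r12 + r13) / 2.0
            det = 1.0 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
            cov23 = (r23 * (1 - 2 * rb**2)
                     - 0.5 * rb**2 * (1 - 2 * rb**2 - r23**2))
            s = cov23 / (1 - rb**2) ** 2
            z12, z13 = np.arctanh(r12), np.arctanh(r13)
            assert det > 0    # admissible correlation matrix
            return (z12 - z13) * np.sqrt((n - 3) / (2 * (1 - s)))

        got = stats.steiger_z(0.5, 0.1, 0.3, 50)
        assert got.z == pytest.approx(oracle(0.5, 0.1, 0.3, 50), abs=1e-10)
        assert got.p == pytest.approx(
            2 * sps.norm.sf(abs(got.z)), abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            stats.steiger_z(1.0, 0.5, 0.2, 30)
        with pytest.raises(ValueError):
            stats.steiger_z(0.5, 0.2, 0.1, 3)


class TestBootstrap:
    def test_constant_data_zero_width(self):
        res = stats.bootstrap_ci(np.mean, np.full(20, 3.5), B=200, seed=0)
        assert res.ci_low == res.ci_high == res.estimate == 3.5

    def test_seed_determinism(self):
        data = np.random.default_rng(16).normal(size=40)
        a = stats.bootstrap_ci(np.mean, data, B=300, seed=42)
        b = stats.bootstrap_ci(np.mean, data, B=300, seed=42)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_undefined_resamples_redrawn(self):
        data = np.array([0.0] * 5 + [1.0] * 15)

        def stat(d):
            if d.sum() == 0:
                raise ValueError("undefined")
            return d.mean()

        res = stats.bootstrap_ci(stat, data, B=100, seed=1)
        assert res.B == 100
        assert np.isfinite(res.ci_low)


class TestTTests:
    def test_identical_paired_samples(self):
        x = np.array([1.0, 2, 3, 2])
        with pytest.raises(ZeroDivisionError):
            stats.paired_t(x, x)        # zero-variance differences

    def test_constant_nonzero_difference_guard(self):
        x = np.array([1.0, 2, 3, 4])
        with pytest.raises(ZeroDivisionError):
            stats.paired_t(x, x + 1)

    def test_two_sample_matches_pooled_formula(self):
        a = np.array([3.0, 5.0, 4.0, 6.0])
        b = np.array([1.0, 2.0, 3.0])
        na, nb = len(a), len(b)
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) \
            / (na + nb - 2)
        t_expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        res = stats.independent_t(a, b)
        assert res.t == pytest.approx(t_expected, abs=1e-12)
        assert res.df == na + nb - 2
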
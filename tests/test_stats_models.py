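import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from mplexcog import stats_models as stm
from mplexcog.exceptions import ConfigError, FormatError
from mplexcog.stats_models import BlockSpec


def make_design(rng, n=100, betas=(0.5, -0.3, 0.2), noise=1.0):
    x = rng.standard_normal((n, len(betas)))
    y = x @ np.array(betas) + noise * rng.standard_normal(n)
    cols = {f"x{i + 1}": x[:, i] for i in range(len(betas))}
    return pd.DataFrame({"y": y, **cols})


SPEC3 = BlockSpec(outcome="y", blocks=(("x1",), ("x2",), ("x3",)))


class TestHierarchicalRegression:
    def test_normal_equations_oracle_on_tiny_dataset(self):
        design = pd.DataFrame(
            {
                "y": [1.0, 2.0, 1.5, 3.0, 2.5, 4.0],
                "x1": [0.0, 1.0, 0.5, 2.0, 1.5, 3.0],
                "x2": [1.0, 0.0, 1.0, 0.0, 1.0, 0.5],
            }
        )
        res = stm.hierarchical_regression(
            design, BlockSpec("y", (("x1",), ("x2",)))
        )
        x = np.column_stack(
            [np.ones(6), design["x1"].to_numpy(), design["x2"].to_numpy()]
        )
        y = design["y"].to_numpy()
        beta_oracle = np.linalg.solve(x.T @ x, x.T @ y)
        np.testing.assert_allclose(
            res.final.coef["b_raw"].to_numpy(), beta_oracle[1:], atol=1e-10
        )
        resid = y - x @ beta_oracle
        r2_oracle = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
        assert res.final.r2 == pytest.approx(r2_oracle, abs=1e-12)

    def test_exact_linear_block1_gives_r2_one(self, rng):
        design = make_design(rng, n=40, noise=0.0, betas=(1.0,))
        design["x2"] = rng.standard_normal(40)
        res = stm.hierarchical_regression(design, BlockSpec("y", (("x1",), ("x2",))))
        assert res.blocks[0].r2 == pytest.approx(1.0, abs=1e-10)
        assert res.blocks[1].delta_r2 == pytest.approx(0.0, abs=1e-10)

    def test_r2_monotone_and_delta_identity(self, rng):
        for _ in range(10):
            design = make_design(rng)
            res = stm.hierarchical_regression(design, SPEC3)
            r2s = [blk.r2 for blk in res.blocks]
            assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))
            prev = 0.0
            for blk in res.blocks:
                assert blk.delta_r2 == pytest.approx(blk.r2 - prev, abs=1e-12)
                assert blk.adj_r2 <= blk.r2 + 1e-12
                prev = blk.r2

    def test_single_predictor_block_f_equals_t_squared(self, rng):
        design = make_design(rng)
        res = stm.hierarchical_regression(design, SPEC3)
        import statsmodels.api as sm

        x = sm.add_constant(design[["x1", "x2", "x3"]].to_numpy())
        fit = sm.OLS(design["y"].to_numpy(), x).fit()
        t3 = fit.tvalues[3]
        assert res.blocks[2].delta_f == pytest.approx(t3**2, rel=1e-8)
        assert res.blocks[2].delta_f_p == pytest.approx(fit.pvalues[3], rel=1e-8)

    def test_block1_delta_f_equals_overall_f(self, rng):
        design = make_design(rng)
        res = stm.hierarchical_regression(design, SPEC3)
        assert res.blocks[0].delta_f == pytest.approx(res.blocks[0].f_stat, rel=1e-10)

    def test_standardized_beta_invariant_under_affine_rescaling(self, rng):
        design = make_design(rng)
        res = stm.hierarchical_regression(design, SPEC3)
        rescaled = design.copy()
        rescaled["x2"] = 3.0 * rescaled["x2"] + 2.0
        res2 = stm.hierarchical_regression(rescaled, SPEC3)
        assert res2.final.coef.loc["x2", "b_std"] == pytest.approx(
            res.final.coef.loc["x2", "b_std"], rel=1e-10
        )
        assert res2.final.coef.loc["x2", "b_raw"] == pytest.approx(
            res.final.coef.loc["x2", "b_raw"] / 3.0, rel=1e-10
        )

    def test_uncorrelated_block_delta_r2_shrinks(self, rng):
        design = make_design(rng, n=4000, betas=(0.5,), noise=1.0)
        design["x2"] = rng.standard_normal(4000)  # unrelated to y
        res = stm.hierarchical_regression(design, BlockSpec("y", (("x1",), ("x2",))))
        assert res.blocks[1].delta_r2 < 0.005

    def test_constant_predictor_is_error(self, rng):
        design = make_design(rng)
        design["x1"] = 1.0
        with pytest.raises(ConfigError, match="constant"):
            stm.hierarchical_regression(design, SPEC3)

    def test_rank_deficiency_names_collinear_set(self, rng):
        design = make_design(rng)
        design["x3"] = design["x1"] * 2.0
        with pytest.raises(ConfigError, match="x1.*x3|x3.*x1"):
            stm.hierarchical_regression(design, SPEC3)

    def test_missing_column_is_error(self, rng):
        design = make_design(rng).drop(columns="x3")
        with pytest.raises(FormatError, match="x3"):
            stm.hierarchical_regression(design, SPEC3)

    def test_report_frame_layout(self, rng):
        frame = stm.hierarchical_regression(make_design(rng), SPEC3).to_frame()
        assert set(frame.columns) == {"block", "row", "B", "beta", "p"}
        assert frame["block"].max() == 3
        assert {"R2", "F", "delta_R2", "delta_F"} <= set(frame["row"])


class TestCollinearity:
    def test_orthogonal_predictors_vif_one(self):
        design = pd.DataFrame(
            {"a": [1.0, -1.0, 1.0, -1.0], "b": [1.0, 1.0, -1.0, -1.0]}
        )
        diag = stm.collinearity_diagnostics(design)
        assert diag["vif"]["a"] == pytest.approx(1.0, abs=1e-10)
        assert diag["vif"]["b"] == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_predictor_infinite_vif(self, rng):
        x = rng.standard_normal(30)
        diag = stm.collinearity_diagnostics(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(diag["vif"]["a"])

    def test_vif_closed_form_from_pairwise_correlation(self, rng):
        x1 = rng.standard_normal(500)
        x2 = 0.6 * x1 + 0.8 * rng.standard_normal(500)
        design = pd.DataFrame({"x1": x1, "x2": x2})
        r = np.corrcoef(x1, x2)[0, 1]
        diag = stm.collinearity_diagnostics(design)
        assert diag["vif"]["x1"] == pytest.approx(1 / (1 - r**2), rel=1e-8)
        assert diag["correlations"].loc["x1", "x2"] == pytest.approx(r, rel=1e-10)


class TestQuadraticAge:
    def test_exact_quadratic_reaches_r2_one(self, rng):
        ages = rng.uniform(20, 70, size=60)
        metric = (ages - ages.mean()) ** 2
        res = stm.quadratic_age_model(metric, ages)
        assert res.blocks[1].r2 == pytest.approx(1.0, abs=1e-8)
        assert res.blocks[1].delta_r2 > 0.5

    def test_block2_increment_invariant_under_affine_age_rescale(self, rng):
        ages = rng.uniform(20, 70, size=80)
        metric = 0.3 * ages + 0.01 * ages**2 + rng.standard_normal(80)
        res = stm.quadratic_age_model(metric, ages)
        res_rescaled = stm.quadratic_age_model(metric, 2.0 * ages - 30.0)
        assert res_rescaled.blocks[1].delta_r2 == pytest.approx(
            res.blocks[1].delta_r2, rel=1e-8
        )

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(200):
            ages = rng.uniform(20, 70, size=50)
            metric = rng.standard_normal(50)
            pvals.append(stm.quadratic_age_model(metric, ages).blocks[1].delta_f_p)
        assert scipy.stats.kstest(pvals, "uniform").pvalue > 1e-3


def make_site_design(rng, n_sites=5, per_site=10, betas=(0.5, -0.3), noise=1.0):
    n = n_sites * per_site
    x = rng.standard_normal((n, len(betas)))
    y = x @ np.array(betas) + noise * rng.standard_normal(n)
    return pd.DataFrame(
        {
            "y": y,
            "x1": x[:, 0],
            "x2": x[:, 1],
            "site": np.repeat([f"S{k}" for k in range(n_sites)], per_site),
        }
    )


CV_SPEC = BlockSpec("y", (("x1",), ("x2",)))


class TestLeaveSiteOutCV:
    def test_fold_count_equals_site_count(self, rng):
        res = stm.leave_site_out_cv(make_site_design(rng), CV_SPEC)
        assert len(res.folds) == 5
        assert sorted(f.held_out_site for f in res.folds) == [f"S{k}" for k in range(5)]

    def test_every_subject_in_exactly_one_fold(self, rng):
        design = make_site_design(rng)
        res = stm.leave_site_out_cv(design, CV_SPEC)
        assert sum(f.n_test for f in res.folds) == len(design)

    def test_noiseless_linear_outcome_perfect_folds(self, rng):
        design = make_site_design(rng, noise=0.0)
        res = stm.leave_site_out_cv(design, CV_SPEC)
        for fold in res.folds:
            assert fold.test_r2 == pytest.approx(1.0, abs=1e-10)

    def test_pure_noise_mean_r2_negative(self):
        rng = np.random.default_rng(5)
        means = []
        for _ in range(20):
            design = make_site_design(rng, per_site=8, betas=(0.0, 0.0))
            means.append(stm.leave_site_out_cv(design, CV_SPEC).mean_r2)
        assert np.mean(means) < 0
        assert sum(m < 0 for m in means) >= 12

    def test_single_subject_site_gets_nan_flag(self, rng):
        design = make_site_design(rng)
        extra = design.iloc[[0]].copy()
        extra["site"] = "lonely"
        design = pd.concat([design, extra], ignore_index=True)
        with pytest.warns(UserWarning, match="lonely"):
            res = stm.leave_site_out_cv(design, CV_SPEC)
        lonely = [f for f in res.folds if f.held_out_site == "lonely"][0]
        assert np.isnan(lonely.test_r2)

    def test_train_mean_baseline_option(self, rng):
        design = make_site_design(rng)
        res_test = stm.leave_site_out_cv(design, CV_SPEC, r2_baseline="test_mean")
        res_train = stm.leave_site_out_cv(design, CV_SPEC, r2_baseline="train_mean")
        assert res_test.folds[0].test_r2 != res_train.folds[0].test_r2

    def test_fewer_than_two_sites_is_error(self, rng):
        design = make_site_design(rng, n_sites=1)
        with pytest.raises(ConfigError):
            stm.leave_site_out_cv(design, CV_SPEC)


class TestLevene:
    def test_identical_groups_give_zero_f(self):
        values = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        f, p = stm.levene_test(values, groups)
        assert f == 0.0
        assert p == 1.0

    def test_two_group_hand_oracle(self):
        a = np.array([1.0, 3.0, 5.0, 9.0])
        b = np.array([2.0, 2.5, 3.0, 3.5])
        z_a = np.abs(a - a.mean())
        z_b = np.abs(b - b.mean())
        zbar = np.concatenate([z_a, z_b]).mean()
        between = 4 * (z_a.mean() - zbar) ** 2 + 4 * (z_b.mean() - zbar) ** 2
        within = ((z_a - z_a.mean()) ** 2).sum() + ((z_b - z_b.mean()) ** 2).sum()
        expected_f = (8 - 2) / (2 - 1) * between / within
        f, p = stm.levene_test(
            np.concatenate([a, b]), np.array(["a"] * 4 + ["b"] * 4)
        )
        assert f == pytest.approx(expected_f, rel=1e-12)
        assert p == pytest.approx(scipy.stats.f.sf(expected_f, 1, 6), rel=1e-12)

    def test_matches_scipy_mean_centered(self, rng):
        a, b, c = (rng.standard_normal(k) for k in (12, 15, 9))
        values = np.concatenate([a, b, c])
        groups = np.array(["a"] * 12 + ["b"] * 15 + ["c"] * 9)
        f, p = stm.levene_test(values, groups)
        f_sp, p_sp = scipy.stats.levene(a, b, c, center="mean")
        assert f == pytest.approx(f_sp, rel=1e-10)
        assert p == pytest.approx(p_sp, rel=1e-10)

    def test_median_centered_matches_scipy(self, rng):
        a, b = rng.standard_normal(11), rng.standard_normal(14)
        f, p = stm.levene_test(
            np.concatenate([a, b]),
            np.array(["a"] * 11 + ["b"] * 14),
            center="median",
        )
        f_sp, p_sp = scipy.stats.levene(a, b, center="median")
        assert f == pytest.approx(f_sp, rel=1e-10)

    def test_small_group_dropped_with_warning(self, rng):
        values = np.concatenate([rng.standard_normal(10), rng.standard_normal(10), [1.0]])
        groups = np.array(["a"] * 10 + ["b"] * 10 + ["c"])
        with pytest.warns(UserWarning, match="'c'"):
            f, _p = stm.levene_test(values, groups)
        assert np.isfinite(f)

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(17)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            values = rng.standard_normal(60)
            groups = np.repeat(["a", "b", "c"], 20)
            _f, p = stm.levene_test(values, groups)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestImpairmentRate:
    def test_no_impairment(self):
        assert stm.impairment_rate(np.zeros(10), -1.5) == (0, 0.0)

    def test_direct_count(self):
        count, prop = stm.impairment_rate([-2.0, -1.0, 0.0, -1.6], -1.5)
        assert (count, prop) == (2, 0.5)

    def test_threshold_is_strict(self):
        count, _ = stm.impairment_rate([-1.5, -1.5001], -1.5)
        assert count == 1

    def test_standard_normal_proportion(self):
        rng = np.random.default_rng(23)
        _count, prop = stm.impairment_rate(rng.standard_normal(200_000), -1.5)
        assert prop == pytest.approx(scipy.stats.norm.cdf(-1.5), abs=0.004)

    def test_non_finite_is_error(self):
        with pytest.raises(FormatError):
            stm.impairment_rate([0.0, np.nan])

    @settings(max_examples=50, deadline=None)
    @given(
        z=st.lists(
            st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=1
        ),
        threshold=st.floats(min_value=-3, max_value=3, allow_nan=False),
    )
    def test_matches_brute_force_count(self, z, threshold):
        count, prop = stm.impairment_rate(z, threshold)
        expected = sum(1 for v in z if v < threshold)
        assert count == expected
        assert prop == pytest.approx(expected / len(z))
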
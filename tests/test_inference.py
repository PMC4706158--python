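import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cinesync import (
    SimulationConfig,
    bonferroni_alpha,
    bootstrap_ci,
    cognition_regression,
    generate_cognitive_scores,
    group_contrast_map,
    partial_correlation,
    roi_age_map,
    rt_preprocess,
    simulate_truth,
)
from cinesync.inference import split_age_groups


class TestRTPreprocess:
    def test_planted_outlier_removed_hand_case(self):
        trials = np.array([0.300] * 20 + [2.000])
        mean, isd, removed = rt_preprocess(trials)
        assert removed == 1
        assert mean == pytest.approx(0.300)
        assert isd == pytest.approx(0.0)

    def test_identical_trials_nothing_removed(self):
        mean, isd, removed = rt_preprocess(np.full(10, 0.45))
        assert (mean, isd, removed) == (pytest.approx(0.45), 0.0, 0)

    def test_single_pass_not_iterative(self):
        # after removing the big outlier the remaining spread would flag more
        # under a second pass; single-pass keeps them
        trials = np.array([0.30] * 30 + [0.36] * 2 + [3.0])
        _, _, removed = rt_preprocess(trials)
        assert removed == 1

    def test_too_few_or_nonpositive_trials_rejected(self):
        with pytest.raises(ValueError):
            rt_preprocess(np.array([0.3, 0.3, 0.3]))
        with pytest.raises(ValueError):
            rt_preprocess(np.array([0.3, -0.1, 0.3, 0.3, 0.3]))


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        x, y = rng.standard_normal((2, 40))
        res = partial_correlation(x, y)
        assert res.estimate == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-12)

    def test_shared_cause_partialled_out(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal(2000)
        x = z + rng.standard_normal(2000)
        y = z + rng.standard_normal(2000)
        res = partial_correlation(x, y, covariates=z[:, None])
        assert abs(res.estimate) < 0.06

    def test_matches_residual_correlation_oracle(self):
        for s in range(20):
            rng = np.random.default_rng(s)
            n = 15
            c = rng.standard_normal((n, 2))
            x, y = rng.standard_normal((2, n))
            # brute-force oracle: residuals from explicit projections
            d = np.column_stack([c, np.ones(n)])
            px = x - d @ np.linalg.pinv(d) @ x
            py = y - d @ np.linalg.pinv(d) @ y
            expected = np.corrcoef(px, py)[0, 1]
            res = partial_correlation(x, y, covariates=c)
            assert res.estimate == pytest.approx(expected, abs=1e-10)
            assert res.df == n - 4

    def test_collinear_covariates_rejected(self, rng):
        c = rng.standard_normal(20)
        with pytest.raises(ValueError):
            partial_correlation(
                rng.standard_normal(20),
                rng.standard_normal(20),
                covariates=np.column_stack([c, 2 * c]),
            )


class TestBootstrap:
    def test_constant_statistic_zero_width(self, rng):
        lo, hi = bootstrap_ci(lambda d: 1.23, rng.standard_normal(30), n_boot=100, seed=0)
        assert lo == hi == pytest.approx(1.23)

    def test_same_seed_reproduces_interval(self, rng):
        data = rng.standard_normal((50, 2))
        f = lambda d: np.corrcoef(d[:, 0], d[:, 1])[0, 1]
        assert bootstrap_ci(f, data, n_boot=200, seed=9) == bootstrap_ci(
            f, data, n_boot=200, seed=9
        )

    def test_undefined_statistic_redrawn_then_rejected(self, rng):
        def bad(d):
            raise ValueError("always undefined")

        with pytest.raises(RuntimeError, match="too many resamples"):
            bootstrap_ci(bad, rng.standard_normal(20), n_boot=10, seed=0)

    def test_needs_ten_subjects(self, rng):
        with pytest.raises(ValueError):
            bootstrap_ci(np.mean, rng.standard_normal(5), seed=0)


class TestRoiAgeMap:
    def test_m_equal_one_bonferroni_equals_uncorrected(self, rng):
        n = 40
        z = rng.standard_normal((n, 1))
        age = rng.uniform(20, 80, n)
        out = roi_age_map(z, age, alpha=0.05, uncorrected_p=0.05)
        assert (out["sig_uncorrected"] == out["sig_bonferroni"]).all()

    def test_planted_negative_effect_detected_with_correct_sign(self):
        rng = np.random.default_rng(3)
        n, m = 60, 40
        age = rng.uniform(18, 88, n)
        age_z = (age - age.mean()) / age.std()
        z = rng.standard_normal((n, m))
        z[:, :8] += -0.5 * age_z[:, None]  # planted decline in 8 ROIs
        edu = rng.integers(1, 6, n).astype(float)[:, None]
        out = roi_age_map(z, age, covariates=edu)
        sig = out[out["sig_uncorrected"]]
        planted_sig = sig[sig["roi"] < 8]
        assert len(planted_sig) > 4  # recall > 50%
        assert (planted_sig["partial_r"] < 0).all()

    def test_matches_partial_correlation_per_roi(self, rng):
        n, m = 30, 5
        z = rng.standard_normal((n, m))
        age = rng.uniform(20, 80, n)
        edu = rng.integers(1, 6, n).astype(float)[:, None]
        out = roi_age_map(z, age, covariates=edu)
        for j in range(m):
            ref = partial_correlation(z[:, j], age, covariates=edu)
            assert out.loc[j, "partial_r"] == pytest.approx(ref.estimate, abs=1e-10)
            assert out.loc[j, "p"] == pytest.approx(ref.p_value, abs=1e-10)


class TestGroupContrast:
    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm

        n, m = 24, 3
        z = rng.standard_normal((n, m))
        g = (rng.random(n) < 0.5).astype(float)
        g[:3], g[3:6] = 0, 1  # ensure both groups populated
        edu = rng.integers(1, 6, n).astype(float)
        out = group_contrast_map(z, g, covariates=edu[:, None])
        for j in range(m):
            x = sm.add_constant(np.column_stack([g, edu]))
            fit = sm.OLS(z[:, j], x).fit()
            assert out.loc[j, "t"] == pytest.approx(fit.tvalues[1], abs=1e-8)
            assert out.loc[j, "p"] == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_exchangeable_null_rejects_at_nominal_rate(self):
        rejections = []
        for s in range(60):
            rng = np.random.default_rng(s)
            z = rng.standard_normal((40, 20))
            g = np.zeros(40)
            g[rng.permutation(40)[:20]] = 1.0
            out = group_contrast_map(z, g, uncorrected_p=0.05)
            rejections.append(out["sig_uncorrected"].mean())
        assert np.mean(rejections) == pytest.approx(0.05, abs=0.02)

    def test_age_rule_defaults(self):
        ages = np.array([30.0, 45.0, 55.0, 70.0, 80.0, 49.9, 65.1])
        young, old = split_age_groups(ages)
        assert list(young) == [0, 1, 5]
        assert list(old) == [3, 4, 6]

    def test_small_group_rejected(self, rng):
        z = rng.standard_normal((10, 2))
        g = np.zeros(10)
        g[0] = 1
        with pytest.raises(ValueError):
            group_contrast_map(z, g)


class TestCognitionRegression:
    @staticmethod
    def toy_table(rng, n=200, b_age=-0.2, b_int=0.5, noise=1.0):
        age = rng.uniform(18, 88, n)
        sync = rng.uniform(0.2, 0.9, n)
        edu = rng.integers(1, 6, n).astype(float)
        age_c = age - age.mean()
        sync_c = sync - sync.mean()
        score = b_age * age_c + b_int * age_c * sync_c + noise * rng.standard_normal(n)
        return pd.DataFrame(
            {"age": age, "sync_score": sync, "education": edu, "fluid": score}
        )

    def test_matches_normal_equations_on_hand_dataset(self):
        rng = np.random.default_rng(11)
        d = self.toy_table(rng, n=12)
        res = cognition_regression(d, "fluid")
        age_c = d["age"] - d["age"].mean()
        sync_c = d["sync_score"] - d["sync_score"].mean()
        x = np.column_stack(
            [np.ones(12), age_c, sync_c, age_c * sync_c, d["education"]]
        )
        beta = np.linalg.solve(x.T @ x, x.T @ d["fluid"].to_numpy())
        np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-10)

    def test_planted_coefficients_recovered_within_ci(self):
        cover_age = cover_int = 0
        n_seeds = 20
        for s in range(n_seeds):
            rng = np.random.default_rng(100 + s)
            d = self.toy_table(rng)
            res = cognition_regression(d, "fluid")
            ci = res.conf_int()
            cover_age += ci.loc["age", 0] <= -0.2 <= ci.loc["age", 1]
            cover_int += ci.loc["age_x_sync", 0] <= 0.5 <= ci.loc["age_x_sync", 1]
        assert cover_age >= 0.9 * n_seeds
        assert cover_int >= 0.9 * n_seeds

    def test_pure_noise_score_mostly_nonsignificant(self):
        n_sig = 0
        for s in range(30):
            rng = np.random.default_rng(s)
            d = self.toy_table(rng, b_age=0.0, b_int=0.0)
            res = cognition_regression(d, "fluid")
            n_sig += abs(res.coefficient_table().loc["sync", "t"]) > 1.96
            assert res.rsquared < 0.15
        assert n_sig <= 5  # ~5% nominal

    def test_rt_model_includes_companion_covariate(self, rng):
        d = self.toy_table(rng, n=50)
        d["rt_isd"] = rng.uniform(0.05, 0.2, 50)
        d["rt_mean"] = rng.uniform(0.3, 0.8, 50)
        res = cognition_regression(d, "rt_isd", covariate_cols=("education", "rt_mean"))
        assert "rt_mean" in res.params.index

    def test_interaction_t_invariant_to_centering_convention(self, rng):
        d = self.toy_table(rng, n=80)
        res = cognition_regression(d, "fluid")
        import statsmodels.api as sm

        x = np.column_stack(
            [
                np.ones(80), d["age"], d["sync_score"],
                d["age"] * d["sync_score"], d["education"],
            ]
        )
        raw = sm.OLS(d["fluid"].to_numpy(), x).fit()
        assert res.coefficient_table().loc["age_x_sync", "t"] == pytest.approx(
            raw.tvalues[3], abs=1e-8
        )

    def test_missing_rows_listwise_deleted(self, rng):
        d = self.toy_table(rng, n=40)
        d.loc[3, "fluid"] = np.nan
        res = cognition_regression(d, "fluid")
        assert res.nobs == 39 and res.n_dropped == 1


class TestBonferroni:
    def test_divides_alpha(self):
        assert bonferroni_alpha(0.05, 1) == 0.05
        assert bonferroni_alpha(0.05, 840) == pytest.approx(5.952e-5, rel=1e-3)

    def test_monotone_in_m(self):
        assert bonferroni_alpha(0.05, 100) < bonferroni_alpha(0.05, 10)

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)
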
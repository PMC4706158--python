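import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.stats import skew

from cinesync import (
    ComponentSet,
    GroupICA,
    component_correlation_clusters,
    detect_loading_outliers,
    estimate_model_order,
    match_templates,
    select_components,
    stimulus_correlation,
)

from conftest import make_run


def match_to_truth(est: np.ndarray, true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal component-to-truth assignment on |r| (order/sign of ICA
    components are arbitrary)."""
    k = true.shape[0]
    c = np.abs(np.corrcoef(est, true)[:k, k:])
    ri, ci = linear_sum_assignment(-c)
    return ri, ci


class TestModelOrder:
    def test_planted_rank_five_recovered(self):
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(s)
            a = rng.standard_normal((200, 5))
            b = rng.standard_normal((5, 800))
            signal = a @ b
            signal *= 5.0 / signal.std()
            x = signal + rng.standard_normal((200, 800))
            hits += estimate_model_order(x, max_order=30) == 5
        assert hits >= 9

    def test_planted_rank_one_estimates_small(self):
        rng = np.random.default_rng(0)
        signal = np.outer(rng.standard_normal(150), rng.standard_normal(500))
        signal *= 8.0 / signal.std()
        x = signal + rng.standard_normal((150, 500))
        assert 1 <= estimate_model_order(x, max_order=20) <= 3

    def test_fixed_order_bypasses_estimation(self, clean_cohort):
        _, runs, _, _ = clean_cohort
        cs = GroupICA(runs=runs, n_components=2, n_restarts=1).fit()
        assert cs.n_components == 2

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            estimate_model_order(np.zeros((50, 100)))


class TestGroupICA:
    def test_recovers_planted_networks(self, clean_cohort):
        _, runs, truth, _ = clean_cohort
        cs = GroupICA(runs=runs, n_components=2, n_restarts=2, seed=0).fit()
        ri, ci = match_to_truth(cs.maps, truth.maps)
        map_r = np.abs(np.corrcoef(cs.maps, truth.maps)[:2, 2:])[ri, ci]
        tc_r = np.abs(
            np.corrcoef(cs.timecourses.T, truth.timecourses.T)[:2, 2:]
        )[ri, ci]
        assert np.all(map_r > 0.9)
        assert np.all(tc_r > 0.9)
        for a, b in zip(ri, ci):
            r = np.corrcoef(cs.loadings[:, a], truth.coupling[:, b])[0, 1]
            assert r > 0.8

    def test_maps_have_nonnegative_skewness(self, clean_cohort):
        _, runs, _, _ = clean_cohort
        cs = GroupICA(runs=runs, n_components=2, n_restarts=1).fit()
        assert np.all(skew(cs.maps, axis=1) >= 0)

    def test_timecourses_unit_variance(self, clean_cohort):
        _, runs, _, _ = clean_cohort
        cs = GroupICA(runs=runs, n_components=2, n_restarts=1).fit()
        np.testing.assert_allclose(cs.timecourses.std(axis=0), 1.0, atol=1e-8)

    def test_noiseless_rank_k_data_fully_explained(self):
        rng = np.random.default_rng(3)
        tcs = rng.standard_normal((100, 3))
        maps = rng.exponential(1.0, size=(3, 400)) * (rng.random((3, 400)) < 0.2)
        runs = [
            make_run(10.0 + (1.0 + 0.1 * s) * tcs @ maps, subject_id=f"s{s}")
            for s in range(5)
        ]
        cs = GroupICA(runs=runs, n_components=3, n_restarts=2, seed=1).fit()
        # reconstruction from 3 components explains > 99.9% of variance
        x = runs[0].timeseries()
        x = x - x.mean(axis=0)
        design = cs.timecourses
        beta = np.linalg.lstsq(design, x, rcond=None)[0]
        resid = x - design @ beta
        assert 1.0 - (resid**2).sum() / (x**2).sum() > 0.999

    def test_permuting_subjects_permutes_loading_rows(self, clean_cohort):
        _, runs, _, _ = clean_cohort
        cs1 = GroupICA(runs=runs, n_components=2, n_restarts=1, seed=5).fit()
        perm = [3, 1, 0, 2, 5, 4, 7, 6, 9, 8, 11, 10]
        cs2 = GroupICA(
            runs=[runs[i] for i in perm], n_components=2, n_restarts=1, seed=5
        ).fit()
        np.testing.assert_allclose(cs2.loadings, cs1.loadings[perm], atol=1e-6)
        np.testing.assert_allclose(cs2.maps, cs1.maps, atol=1e-6)

    def test_scaling_one_subject_scales_its_loadings_only(self, clean_cohort):
        _, runs, _, _ = clean_cohort
        cs1 = GroupICA(runs=runs, n_components=2, n_restarts=1, seed=5).fit()
        import dataclasses

        scaled = list(runs)
        scaled[0] = dataclasses.replace(runs[0], data=runs[0].data * 3.0)
        cs2 = GroupICA(runs=scaled, n_components=2, n_restarts=1, seed=5).fit()
        np.testing.assert_allclose(cs2.maps, cs1.maps, atol=1e-6)
        np.testing.assert_allclose(cs2.timecourses, cs1.timecourses, atol=1e-6)
        np.testing.assert_allclose(cs2.loadings[0], 3.0 * cs1.loadings[0], rtol=1e-5)
        np.testing.assert_allclose(cs2.loadings[1:], cs1.loadings[1:], atol=1e-6)


def make_component_set(loadings, k=None):
    n_sub, n_comp = loadings.shape
    rng = np.random.default_rng(0)
    return ComponentSet(
        maps=rng.standard_normal((n_comp, 50)),
        timecourses=rng.standard_normal((40, n_comp)),
        loadings=np.asarray(loadings, float),
    )


class TestSelectComponents:
    def test_keep_all_reorders_by_median_loading(self):
        lo = np.array([[1.0, 3.0], [1.0, 3.0], [1.0, 3.0]])
        cs = make_component_set(lo)
        sel = select_components(cs, k=2)
        np.testing.assert_array_equal(sel.loadings[:, 0], 3.0)
        np.testing.assert_allclose(sel.maps[0], cs.maps[1])

    def test_higher_median_ranked_first(self):
        lo = np.array([[0.5, 2.0, 1.0]] * 5)
        sel = select_components(make_component_set(lo), k=2)
        np.testing.assert_array_equal(np.median(sel.loadings, axis=0), [2.0, 1.0])

    def test_k_larger_than_components_rejected(self):
        with pytest.raises(ValueError):
            select_components(make_component_set(np.ones((3, 2))), k=5)

    def test_ties_keep_original_order(self):
        lo = np.ones((4, 3))
        sel = select_components(make_component_set(lo), k=3)
        cs = make_component_set(lo)
        np.testing.assert_allclose(sel.maps, cs.maps)


class TestMatchTemplates:
    def test_self_match_is_perfect(self, rng):
        maps = rng.standard_normal((3, 100))
        labels = match_templates(maps, maps, ["a", "b", "c"])
        assert labels == ["a", "b", "c"]

    def test_orthogonal_map_unmatched(self, rng):
        t = np.zeros((1, 100))
        t[0, :50] = 1.0
        m = np.zeros((1, 100))
        m[0, 50:] = np.tile([1.0, -1.0], 25)  # uncorrelated with template
        labels = match_templates(m, t, ["aud"])
        assert labels == ["unmatched"]

    def test_noisy_copy_matched_to_its_template(self, rng):
        templates = rng.standard_normal((3, 200))
        noisy = templates[2] + (templates[2].std() / 3.0) * rng.standard_normal(200)
        labels = match_templates(noisy[None], templates, ["t0", "t1", "t2"])
        assert labels == ["t2"]

    def test_empty_template_set_rejected(self, rng):
        with pytest.raises(ValueError):
            match_templates(rng.standard_normal((2, 50)), np.empty((0, 50)), [])


class TestClusters:
    def test_diagonal_is_exactly_one(self, rng):
        corr, _ = component_correlation_clusters(rng.standard_normal((60, 4)))
        np.testing.assert_array_equal(np.diag(corr), 1.0)

    def test_planted_two_block_structure_recovered(self, rng):
        base1 = rng.standard_normal(200)
        base2 = -0.6 * base1 + 0.8 * rng.standard_normal(200)
        tcs = np.column_stack(
            [base1 + 0.5 * rng.standard_normal(200) for _ in range(3)]
            + [base2 + 0.5 * rng.standard_normal(200) for _ in range(3)]
        )
        _, assign = component_correlation_clusters(tcs)
        assert len(np.unique(assign)) == 2
        assert len(set(assign[:3])) == 1 and len(set(assign[3:])) == 1
        assert assign[0] != assign[3]

    def test_single_component_single_cluster(self, rng):
        corr, assign = component_correlation_clusters(rng.standard_normal((30, 1)))
        assert corr.shape == (1, 1) and len(np.unique(assign)) == 1

    def test_constant_timecourse_rejected(self):
        tcs = np.ones((30, 2))
        with pytest.raises(ValueError):
            component_correlation_clusters(tcs)


class TestStimulusCorrelation:
    def test_component_equal_to_regressor(self, rng):
        reg = rng.standard_normal(120)
        tcs = np.column_stack([reg, -reg])
        r = stimulus_correlation(tcs, reg)
        np.testing.assert_allclose(r, [1.0, -1.0], atol=1e-10)

    def test_independent_noise_has_small_correlation(self):
        hits = 0
        for s in range(40):
            rng = np.random.default_rng(s)
            r = stimulus_correlation(
                rng.standard_normal((300, 1)), rng.standard_normal(300)
            )
            hits += abs(r[0]) < 0.2
        assert hits >= 36  # ~95% of seeds

    def test_zero_variance_regressor_rejected(self, rng):
        with pytest.raises(ValueError):
            stimulus_correlation(rng.standard_normal((50, 2)), np.ones(50))


class TestLoadingOutliers:
    def test_identical_subjects_give_empty_set(self):
        assert detect_loading_outliers(np.ones((10, 3))).size == 0

    def test_five_sd_subject_flagged(self, rng):
        lo = rng.standard_normal((30, 2)) * 0.1 + 1.0
        sd = lo[:, 1].std(ddof=1)
        lo[7, 1] = lo[:, 1].mean() + 5 * sd
        assert 7 in detect_loading_outliers(lo, k=3.0)

    def test_zero_variance_component_skipped(self):
        lo = np.column_stack([np.ones(10), np.arange(10, dtype=float)])
        out = detect_loading_outliers(lo, k=3.0)
        assert out.size == 0  # linear spread has no 3-SD outlier
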
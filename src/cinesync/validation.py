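"""Validation experiments: oracle equivalence, ground-truth recovery, error
calibration, and bootstrap coverage.

These are the package's standing evidence that the estimators do what they
claim: every experiment regenerates its data from a seed, runs the real
analysis code, and measures the outcome against an independent oracle or
the simulator's ground truth. They back both the test suite and the
results-reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .decompose import GroupICA
from .dualreg import spatial_regression, temporal_regression
from .inference import bootstrap_ci, cognition_regression, partial_correlation, roi_age_map
from .simulate import SimulationConfig, generate_cognitive_scores, simulate_cohort, simulate_truth
from .workflows import run_synchrony_study

__all__ = [
    "oracle_deviations",
    "decomposition_recovery",
    "headline_effect_rate",
    "interaction_recovery_rate",
    "null_calibration",
    "bootstrap_coverage",
]


def _run_from_matrix(ts: np.ndarray):
    from .bold import BoldRun

    t, v = ts.shape
    return BoldRun(data=ts.T.reshape(v, 1, 1, t), tr_s=2.0)


def oracle_deviations(seed: int = 0, n_instances: int = 50) -> dict[str, float]:
    """Largest absolute deviation of each least-squares estimator from an
    independent brute-force oracle over random small instances."""
    out = {"spatial_regression": 0.0, "temporal_regression": 0.0,
           "partial_correlation": 0.0, "cognition_betas": 0.0}
    root = np.random.SeedSequence([seed, 101])
    for child in root.spawn(n_instances):
        rng = np.random.default_rng(child)
        t, v, k, n = 25, 40, 3, 20

        maps = rng.standard_normal((k, v))
        data = rng.standard_normal((t, v))
        run = _run_from_matrix(data)
        est = spatial_regression(run, maps)
        x = np.column_stack([maps.T, np.ones(v)])
        oracle = (np.linalg.pinv(x.T @ x) @ x.T @ data.T)[:-1].T
        out["spatial_regression"] = max(
            out["spatial_regression"], float(np.abs(est - oracle).max())
        )

        tcs = rng.standard_normal((t, k))
        est = temporal_regression(run, tcs)
        norm = tcs / tcs.std(axis=0, ddof=1)
        x = np.column_stack([norm, np.ones(t)])
        oracle = (np.linalg.pinv(x.T @ x) @ x.T @ data)[:-1]
        out["temporal_regression"] = max(
            out["temporal_regression"], float(np.abs(est - oracle).max())
        )

        c = rng.standard_normal((n, 2))
        xv, yv = rng.standard_normal((2, n))
        d = np.column_stack([c, np.ones(n)])
        h = d @ np.linalg.pinv(d)
        rx, ry = xv - h @ xv, yv - h @ yv
        oracle_r = float(np.corrcoef(rx, ry)[0, 1])
        est_r = partial_correlation(xv, yv, covariates=c).estimate
        out["partial_correlation"] = max(
            out["partial_correlation"], abs(est_r - oracle_r)
        )

        age = rng.uniform(18, 88, n)
        sync = rng.uniform(0.2, 0.9, n)
        edu = rng.integers(1, 6, n).astype(float)
        score = rng.standard_normal(n)
        frame = pd.DataFrame(
            {"age": age, "sync_score": sync, "education": edu, "fluid": score}
        )
        res = cognition_regression(frame, "fluid")
        age_c, sync_c = age - age.mean(), sync - sync.mean()
        x = np.column_stack([np.ones(n), age_c, sync_c, age_c * sync_c, edu])
        beta = np.linalg.solve(x.T @ x, x.T @ score)
        out["cognition_betas"] = max(
            out["cognition_betas"], float(np.abs(res.params.to_numpy() - beta).max())
        )
    return out


def decomposition_recovery(seed: int = 0) -> dict[str, float]:
    """Group-ICA recovery on a 20-subject, 3-network, high-SNR cohort.

    Returns the minimum (worst-network) matched spatial |r|, timecourse |r|,
    and loading-vs-coupling correlation after optimal component-to-truth
    assignment.
    """
    cfg = SimulationConfig(
        n_subjects=20, n_timepoints=200, grid_shape=(10, 10, 8), n_networks=3,
        noise_sd=0.3, drift_amplitude=0.0, spike_rate_per_frame=0.0, seed=seed,
    )
    runs, truth, _ = simulate_cohort(cfg)
    cs = GroupICA(runs=runs, n_components=3, n_restarts=3, seed=seed).fit()
    k = 3
    cmap = np.abs(np.corrcoef(cs.maps, truth.maps)[:k, k:])
    ri, ci = linear_sum_assignment(-cmap)
    ctc = np.abs(np.corrcoef(cs.timecourses.T, truth.timecourses.T)[:k, k:])
    load_r = [
        float(np.corrcoef(cs.loadings[:, a], truth.coupling[:, b])[0, 1])
        for a, b in zip(ri, ci)
    ]
    return {
        "min_map_abs_r": float(cmap[ri, ci].min()),
        "min_timecourse_abs_r": float(ctc[ri, ci].min()),
        "min_loading_coupling_r": float(min(load_r)),
    }


def _headline_config(seed: int) -> SimulationConfig:
    """Study conditions for the age -> synchrony recovery experiment:
    60 subjects, 300 frames, full nuisance structure, negative
    age-coupling slope (the generator default)."""
    return SimulationConfig(
        n_subjects=60, n_timepoints=300, grid_shape=(8, 8, 6), n_networks=3,
        seed=seed,
    )


def headline_effect_rate(seed: int = 0, n_seeds: int = 100) -> dict[str, float]:
    """Fraction of simulated cohorts in which age shows a significant
    negative partial correlation with the synchronization score
    (controlling education), plus the mean partial r."""
    seeds = np.random.SeedSequence([seed, 202]).generate_state(n_seeds) % 2**31
    hits, rs = 0, []
    for s in seeds:
        res = run_synchrony_study(_headline_config(int(s)), apply_qc=True)
        rs.append(res.age_sync.estimate)
        hits += (res.age_sync.estimate < 0) and (res.age_sync.p_value < 0.05)
    return {
        "significant_negative_rate": hits / n_seeds,
        "mean_partial_r": float(np.mean(rs)),
        "n_seeds": n_seeds,
    }


def interaction_recovery_rate(seed: int = 0, n_seeds: int = 100) -> dict[str, float]:
    """Fraction of cohorts in which the planted positive age x synchrony
    effect on the fluid-style score is recovered with the correct sign."""
    seeds = np.random.SeedSequence([seed, 303]).generate_state(n_seeds) % 2**31
    correct = 0
    betas = []
    for s in seeds:
        cfg = SimulationConfig(
            n_subjects=200, n_timepoints=16, grid_shape=(4, 4, 3), seed=int(s)
        )
        truth = simulate_truth(cfg)
        table = generate_cognitive_scores(truth, cfg)
        table = table.assign(sync_score=truth.sync_true)
        res = cognition_regression(table, "fluid")
        b = float(res.params["age_x_sync"])
        betas.append(b)
        correct += b > 0
    return {
        "correct_sign_rate": correct / n_seeds,
        "mean_interaction_beta": float(np.mean(betas)),
        "planted_interaction_beta": 0.55,
        "n_seeds": n_seeds,
    }


def null_calibration(
    seed: int = 0, n_sims: int = 200, n_roi: int = 100, n_subjects: int = 60
) -> dict[str, float]:
    """Type-I error of the ROI-wise age map under a null cohort.

    Returns the mean per-ROI rejection rate at p < 0.05 (uncorrected) and
    the family-wise error rate under Bonferroni correction at alpha 0.05.
    """
    root = np.random.SeedSequence([seed, 404])
    rates, fwe = [], 0
    for child in root.spawn(n_sims):
        rng = np.random.default_rng(child)
        z = rng.standard_normal((n_subjects, n_roi))
        age = rng.uniform(18, 88, n_subjects)
        edu = rng.integers(1, 6, n_subjects).astype(float)[:, None]
        out = roi_age_map(z, age, covariates=edu, alpha=0.05, uncorrected_p=0.05)
        rates.append(out["sig_uncorrected"].mean())
        fwe += bool(out["sig_bonferroni"].any())
    return {
        "uncorrected_rejection_rate": float(np.mean(rates)),
        "bonferroni_fwer": fwe / n_sims,
        "n_sims": n_sims,
    }


def bootstrap_coverage(
    seed: int = 0, n_sims: int = 500, n: int = 100, true_r: float = 0.5,
    n_boot: int = 1000,
) -> dict[str, float]:
    """Coverage of the 95% percentile bootstrap CI for a correlation.

    Bivariate normal samples at the given true correlation; reports the
    fraction of simulations whose interval contains the truth.
    """
    root = np.random.SeedSequence([seed, 505])
    cov = np.array([[1.0, true_r], [true_r, 1.0]])
    chol = np.linalg.cholesky(cov)
    covered = 0
    for child in root.spawn(n_sims):
        rng = np.random.default_rng(child)
        data = rng.standard_normal((n, 2)) @ chol.T
        lo, hi = bootstrap_ci(
            lambda d: np.corrcoef(d[:, 0], d[:, 1])[0, 1],
            data,
            n_boot=n_boot,
            seed=rng,
        )
        covered += lo <= true_r <= hi
    return {"coverage": covered / n_sims, "nominal": 0.95, "n_sims": n_sims}
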
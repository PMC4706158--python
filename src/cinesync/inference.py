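"""Statistical inference relating synchrony to age and cognition.

Covers: within-subject reaction-time trimming and summary statistics;
partial correlation (correlation of covariate-adjusted residuals) with
t-based inference; percentile bootstrap confidence intervals over subjects;
ROI-wise age-partial-correlation maps with uncorrected and Bonferroni
thresholds; covariate-adjusted two-group contrasts per ROI; and the
cognition regressions predicting a score from age, synchronization score,
their interaction, education, and (for RT outcomes) the companion RT
measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "StatResult",
    "rt_preprocess",
    "partial_correlation",
    "bootstrap_ci",
    "roi_age_map",
    "group_contrast_map",
    "CognitionModel",
    "CognitionResults",
    "cognition_regression",
    "bonferroni_alpha",
]


@dataclass
class StatResult:
    """One estimate with uncertainty: point value, 95% CI, test statistic,
    p-value, degrees of freedom, and sample size."""

    estimate: float
    ci_low: float
    ci_high: float
    statistic: float
    p_value: float
    df: int
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def rt_preprocess(
    trial_rts: np.ndarray, k: float = 3.0
) -> tuple[float, float, int]:
    """Within-subject RT trimming and summary.

    Removes, in a single pass, trials more than ``k`` SDs from the
    subject's mean (mean and SD over all of that subject's trials), then
    returns ``(rt_mean, rt_isd, n_removed)`` computed on the survivors.
    """
    rts = np.asarray(trial_rts, dtype=float)
    if rts.size < 5:
        raise ValueError("need at least 5 trials")
    if np.any(rts <= 0):
        raise ValueError("reaction times must be positive")
    sd = rts.std(ddof=1)
    keep = np.abs(rts - rts.mean()) <= k * sd if sd > 0 else np.ones(rts.size, bool)
    if not keep.any():
        raise ValueError("outlier rule removed every trial")
    survivors = rts[keep]
    isd = survivors.std(ddof=1) if survivors.size > 1 else 0.0
    return float(survivors.mean()), float(isd), int(rts.size - keep.sum())


def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """OLS residuals of y on covariates plus an intercept."""
    y = np.asarray(y, dtype=float)
    if covariates is None or covariates.size == 0:
        return y - y.mean()
    c = np.atleast_2d(np.asarray(covariates, dtype=float))
    if c.shape[0] != len(y):
        c = c.T
    x = np.column_stack([c, np.ones(len(y))])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("collinear covariates")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> StatResult:
    """Partial Pearson correlation of x and y controlling for covariates.

    Computed as the correlation of the two covariate-adjusted residual
    vectors; the t statistic uses df = n - 2 - n_covariates and the 95% CI
    comes from the Fisher-z normal approximation at the same df.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    n_cov = 0
    if covariates is not None and np.size(covariates) > 0:
        c = np.atleast_2d(np.asarray(covariates, float))
        n_cov = c.shape[1] if c.shape[0] == n else c.shape[0]
    if n <= n_cov + 2:
        raise ValueError("too few observations for the requested covariates")
    rx = _residualize(x, covariates)
    ry = _residualize(y, covariates)
    denom = np.linalg.norm(rx) * np.linalg.norm(ry)
    if denom < 1e-30:
        raise ValueError("zero-variance residuals; correlation undefined")
    r = float(rx @ ry / denom)
    df = n - 2 - n_cov
    r_ = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r_ * np.sqrt(df / (1.0 - r_**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    # Fisher-z interval with effective sample size n - n_cov
    se_z = 1.0 / np.sqrt(max(n - n_cov - 3, 1))
    zc = stats.norm.ppf(0.975)
    lo, hi = np.tanh(np.arctanh(r_) + np.array([-zc, zc]) * se_z)
    return StatResult(
        estimate=r, ci_low=float(lo), ci_high=float(hi),
        statistic=float(t), p_value=p, df=df, n=n,
    )


def bootstrap_ci(
    statistic,
    data: np.ndarray | pd.DataFrame,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI resampling subjects (rows) with replacement.

    ``statistic`` is called on the row-resampled data. Resamples on which
    the statistic is undefined (raises or returns NaN) are redrawn, up to
    ten times the requested number of resamples.
    """
    n = len(data)
    if n < 10:
        raise ValueError("need at least 10 subjects to bootstrap")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    values = np.empty(n_boot)
    got, attempts = 0, 0
    is_frame = isinstance(data, pd.DataFrame)
    while got < n_boot:
        if attempts >= 10 * n_boot:
            raise RuntimeError("statistic undefined on too many resamples")
        attempts += 1
        idx = rng.integers(0, n, size=n)
        sample = data.iloc[idx] if is_frame else np.asarray(data)[idx]
        try:
            v = float(statistic(sample))
        except (ValueError, ZeroDivisionError, FloatingPointError):
            continue
        if np.isnan(v):
            continue
        values[got] = v
        got += 1
    alpha = (1.0 - level) / 2.0
    return (
        float(np.quantile(values, alpha)),
        float(np.quantile(values, 1.0 - alpha)),
    )


def roi_age_map(
    z_syncs: np.ndarray,
    age: np.ndarray,
    covariates: np.ndarray | None = None,
    alpha: float = 0.05,
    uncorrected_p: float = 0.001,
) -> pd.DataFrame:
    """Per-ROI partial correlation between synchrony (Fisher z) and age.

    ``z_syncs`` is ``(n_subjects, n_roi)``. Returns one row per ROI with the
    partial r, t, p, and two significance flags: uncorrected
    (p < ``uncorrected_p``) and Bonferroni (p < ``alpha`` / n_roi).
    """
    z = np.asarray(z_syncs, dtype=float)
    age = np.asarray(age, dtype=float)
    n, m = z.shape
    if np.isnan(z).any() or np.isnan(age).any():
        raise ValueError("complete rows required (missing values present)")
    r_age = _residualize(age, covariates)
    n_cov = 0 if covariates is None or np.size(covariates) == 0 else (
        np.atleast_2d(covariates).shape[1]
        if np.atleast_2d(covariates).shape[0] == n
        else np.atleast_2d(covariates).shape[0]
    )
    df = n - 2 - n_cov
    rz = np.column_stack([_residualize(z[:, j], covariates) for j in range(m)])
    num = rz.T @ r_age
    denom = np.linalg.norm(rz, axis=0) * np.linalg.norm(r_age)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.clip(num / denom, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    bonf = bonferroni_alpha(alpha, m)
    return pd.DataFrame(
        {
            "roi": np.arange(m),
            "partial_r": r,
            "t": t,
            "p": p,
            "sig_uncorrected": p < uncorrected_p,
            "sig_bonferroni": p < bonf,
        }
    )


def group_contrast_map(
    z_syncs: np.ndarray,
    group: np.ndarray,
    covariates: np.ndarray | None = None,
    alpha: float = 0.05,
    uncorrected_p: float = 0.001,
) -> pd.DataFrame:
    """Covariate-adjusted two-group contrast per ROI.

    Fits ``z ~ group + covariates`` by OLS for each ROI and reports the
    group coefficient's estimate, t, and p (the standard realization of a
    covariate-adjusted two-sample t test). ``group`` is binary (0/1).
    """
    z = np.asarray(z_syncs, dtype=float)
    g = np.asarray(group, dtype=float)
    n, m = z.shape
    counts = [np.sum(g == v) for v in (0.0, 1.0)]
    if min(counts) < 3:
        raise ValueError("each group needs at least 3 subjects")
    cols = [g]
    if covariates is not None and np.size(covariates) > 0:
        c = np.atleast_2d(np.asarray(covariates, float))
        if c.shape[0] != n:
            c = c.T
        cols.append(c)
    x = np.column_stack([*cols, np.ones(n)])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("collinear design in group contrast")
    df = n - x.shape[1]
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ z  # (p, m)
    resid = z - x @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * xtx_inv[0, 0])
    t = beta[0] / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    bonf = bonferroni_alpha(alpha, m)
    return pd.DataFrame(
        {
            "roi": np.arange(m),
            "estimate": beta[0],
            "se": se,
            "t": t,
            "p": p,
            "sig_uncorrected": p < uncorrected_p,
            "sig_bonferroni": p < bonf,
        }
    )


def split_age_groups(
    ages: np.ndarray, young_max: float = 50.0, old_min: float = 65.0
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of younger (< ``young_max``) and older (> ``old_min``)
    subjects; the middle band is excluded. Defaults follow the convention
    of contrasting adults under 50 with adults over 65."""
    ages = np.asarray(ages, dtype=float)
    return np.flatnonzero(ages < young_max), np.flatnonzero(ages > old_min)


class CognitionModel:
    """OLS model predicting a cognitive score from age, synchronization,
    their interaction, and covariates.

    Age and synchronization are mean-centred before the interaction is
    formed, so main effects are interpretable at the sample mean; the
    interaction t is unaffected by centring. Rows with missing values in
    any used column are dropped (listwise deletion).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        score: str,
        age_col: str = "age",
        sync_col: str = "sync_score",
        covariate_cols: tuple[str, ...] = ("education",),
    ) -> None:
        cols = [score, age_col, sync_col, *covariate_cols]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise KeyError(f"missing columns: {missing}")
        d = data[cols].dropna()
        n_pred = 3 + len(covariate_cols)
        if len(d) <= n_pred + 2:
            raise ValueError("too few complete rows for the model")
        self.score = score
        self.n_dropped = len(data) - len(d)
        age_c = d[age_col] - d[age_col].mean()
        sync_c = d[sync_col] - d[sync_col].mean()
        design = pd.DataFrame(
            {
                "age": age_c,
                "sync": sync_c,
                "age_x_sync": age_c * sync_c,
            },
            index=d.index,
        )
        for c in covariate_cols:
            design[c] = d[c]
        exog = sm.add_constant(design)
        if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
            raise ValueError("collinear predictors in cognition model")
        self._endog = d[score]
        self._exog = exog

    def fit(self) -> "CognitionResults":
        res = sm.OLS(self._endog, self._exog).fit()
        return CognitionResults(res, score=self.score, n_dropped=self.n_dropped)


@dataclass
class CognitionResults:
    """Fitted cognition regression: unstandardized coefficients with SE, t,
    p, 95% CI, and model R^2."""

    _res: object
    score: str
    n_dropped: int = 0

    @property
    def params(self) -> pd.Series:
        return self._res.params

    @property
    def rsquared(self) -> float:
        return float(self._res.rsquared)

    @property
    def nobs(self) -> int:
        return int(self._res.nobs)

    def conf_int(self) -> pd.DataFrame:
        return self._res.conf_int()

    def coefficient_table(self) -> pd.DataFrame:
        ci = self._res.conf_int()
        return pd.DataFrame(
            {
                "beta": self._res.params,
                "ci_low": ci[0],
                "ci_high": ci[1],
                "se": self._res.bse,
                "t": self._res.tvalues,
                "p": self._res.pvalues,
            }
        )

    def summary(self) -> str:
        head = (
            f"Cognition regression: {self.score}\n"
            f"  n = {self.nobs} (dropped {self.n_dropped}), "
            f"R^2 = {self.rsquared:.3f}\n"
        )
        return head + self.coefficient_table().to_string(float_format="%.4g")


def cognition_regression(
    data: pd.DataFrame,
    score: str,
    covariate_cols: tuple[str, ...] = ("education",),
    **kwargs,
) -> CognitionResults:
    """Fit the cognition model (see :class:`CognitionModel`).

    For RT outcomes include the companion RT measure among
    ``covariate_cols`` (mean when modelling ISD and vice versa) so that any
    synchrony effect is unique to the modelled measure.
    """
    return CognitionModel(
        data, score=score, covariate_cols=covariate_cols, **kwargs
    ).fit()


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m for m simultaneous tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m
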
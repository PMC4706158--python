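"""Multi-subject group decomposition into shared maps, shared timecourses,
and per-subject loading values.

A naturalistic stimulus imposes a common timecourse on every viewer, so the
multi-subject decomposition is implemented as spatial ICA on the
subject-average series followed by a per-subject rank-1 projection: each
subject's loading on a component is the scalar least-squares fit of their
(demeaned) data onto the component's timecourse x map outer product. This
reproduces the (timecourse, map, subject-mode) output contract of a
tensorial group ICA while staying directly testable against simulated
ground truth.

The model order can be estimated by maximizing the Laplace-approximated
evidence of a probabilistic PCA model (Minka's criterion) on the
subject-average data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import skew
from sklearn.decomposition import FastICA
from sklearn.metrics import silhouette_score

from .bold import BoldRun

__all__ = [
    "ComponentSet",
    "GroupICA",
    "estimate_model_order",
    "select_components",
    "match_templates",
    "component_correlation_clusters",
    "stimulus_correlation",
    "detect_loading_outliers",
]

logger = logging.getLogger(__name__)


@dataclass
class ComponentSet:
    """Group decomposition result.

    Attributes
    ----------
    maps
        ``(n_components, n_voxels)`` spatial maps, z-scaled (zero mean, unit
        SD over voxels) and sign-fixed to nonnegative skewness.
    timecourses
        ``(T, n_components)`` shared timecourses, unit variance per column.
    loadings
        ``(n_subjects, n_components)`` subject modes: how strongly each
        subject expresses each spatiotemporal component.
    component_labels
        Optional template-matched names.
    """

    maps: np.ndarray
    timecourses: np.ndarray
    loadings: np.ndarray
    component_labels: list[str] | None = None
    explained_variance: np.ndarray | None = None
    converged: bool = True
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        k = self.maps.shape[0]
        if self.timecourses.shape[1] != k or self.loadings.shape[1] != k:
            raise ValueError("maps/timecourses/loadings component counts differ")
        if self.component_labels is not None and len(self.component_labels) != k:
            raise ValueError("one label per component required")

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.loadings.shape[0]

    def summary(self) -> str:
        lines = [
            "Group decomposition",
            f"  components: {self.n_components}   subjects: {self.n_subjects}",
            f"  converged: {self.converged}",
            "  comp  median_loading  expl_var  label",
        ]
        med = np.median(self.loadings, axis=0)
        ev = (
            self.explained_variance
            if self.explained_variance is not None
            else np.full(self.n_components, np.nan)
        )
        labels = self.component_labels or [""] * self.n_components
        for i in range(self.n_components):
            lines.append(f"  {i:4d}  {med[i]:14.4f}  {ev[i]:8.4f}  {labels[i]}")
        return "\n".join(lines)


def _subject_average(runs: list[BoldRun]) -> tuple[np.ndarray, list[np.ndarray]]:
    """Demean each subject's series; average scale-normalized copies.

    Per-subject global-SD normalization makes the average (hence maps and
    timecourses) invariant to rescaling any single subject's data, while the
    returned raw demeaned matrices keep amplitude for loading estimation.
    """
    shapes = {(r.n_timepoints, r.n_voxels) for r in runs}
    if len(shapes) != 1:
        raise ValueError("all runs must share frame count and voxel grid")
    demeaned = []
    avg = None
    for r in runs:
        ts = r.timeseries()
        ts = ts - ts.mean(axis=0)
        demeaned.append(ts)
        sd = ts.std()
        if sd < 1e-12:
            raise ValueError(f"run {r.subject_id!r} has zero variance")
        avg = ts / sd if avg is None else avg + ts / sd
    return avg / len(runs), demeaned


def estimate_model_order(data: np.ndarray, max_order: int | None = None) -> int:
    """Model order maximizing the Laplace-approximated PPCA evidence.

    ``data`` is a ``(T, V)`` matrix (typically the subject average); the V
    voxels are treated as observations of a T-dimensional variable.
    Implements Minka's Laplace approximation to the marginal likelihood of
    a probabilistic PCA model with k retained directions.
    """
    data = np.asarray(data, dtype=float)
    n_t, n_vox = data.shape
    x = data - data.mean(axis=1, keepdims=True)
    if float((x**2).sum()) < 1e-12:
        raise ValueError("zero-variance data; model order undefined")
    n, d = n_vox, n_t  # observations, dimension
    # full eigenvalue spectrum of the (d x d) covariance over voxels
    spectrum = np.zeros(d)
    sv = np.linalg.svd(x, compute_uv=False)
    spectrum[: len(sv)] = sv**2 / n
    kmax = d - 1
    if max_order is not None:
        kmax = min(kmax, int(max_order))
    if kmax < 1:
        raise ValueError("not enough data for order estimation")

    best_k, best_ll = 1, -np.inf
    for k in range(1, kmax + 1):
        ll = _laplace_evidence(spectrum, k, n)
        if ll > best_ll:
            best_ll, best_k = ll, k
    return best_k


def _laplace_evidence(spectrum: np.ndarray, rank: int, n: int) -> float:
    """Minka's Laplace-approximated log evidence of PPCA at a given rank."""
    d = len(spectrum)
    eps = 1e-15
    if spectrum[rank - 1] < eps:
        return -np.inf
    from scipy.special import gammaln

    pu = -rank * np.log(2.0)
    for i in range(1, rank + 1):
        pu += gammaln((d - i + 1) / 2.0) - np.log(np.pi) * (d - i + 1) / 2.0
    pl = -np.sum(np.log(spectrum[:rank])) * n / 2.0
    v = max(eps, np.sum(spectrum[rank:]) / (d - rank))
    pv = -np.log(v) * n * (d - rank) / 2.0
    m = d * rank - rank * (rank + 1) / 2.0
    pp = np.log(2.0 * np.pi) * (m + rank) / 2.0
    filled = spectrum.copy()
    filled[rank:] = v
    pa = 0.0
    for i in range(rank):
        gaps = (spectrum[i] - spectrum[i + 1 :]) * (
            1.0 / filled[i + 1 :] - 1.0 / filled[i]
        )
        pa += np.sum(np.log(np.maximum(gaps, eps))) + (d - 1 - i) * np.log(n)
    return pu + pl + pv + pp - pa / 2.0 - rank * np.log(n) / 2.0


@dataclass
class GroupICA:
    """Group spatial-ICA model over a cohort of BOLD runs.

    Parameters
    ----------
    runs
        Subject runs on a common grid with equal frame counts.
    n_components
        Number of components, or ``"auto"`` to maximize the
        Laplace-approximated PPCA evidence.
    n_restarts
        Seeded FastICA restarts; the solution with the highest negentropy
        objective is kept.
    """

    runs: list[BoldRun]
    n_components: int | str = "auto"
    n_restarts: int = 5
    max_iter: int = 500
    tol: float = 1e-5
    seed: int = 0

    def fit(self) -> ComponentSet:
        avg, demeaned = _subject_average(self.runs)
        n_t, n_vox = avg.shape
        if self.n_components == "auto":
            k = estimate_model_order(avg, max_order=min(n_t, n_vox) // 2)
            logger.info("estimated model order: %d", k)
        else:
            k = int(self.n_components)
        if not 1 <= k < min(n_t, n_vox):
            raise ValueError(f"n_components={k} out of range for data {avg.shape}")

        x = avg - avg.mean(axis=0)  # centre voxel series over time as well
        best = None
        ss = np.random.SeedSequence([self.seed, 0x1CA])
        for child in ss.spawn(max(1, self.n_restarts)):
            rs = int(child.generate_state(1)[0] % 2**31)
            ica = FastICA(
                n_components=k,
                fun="logcosh",
                algorithm="parallel",
                whiten="unit-variance",
                max_iter=self.max_iter,
                tol=self.tol,
                random_state=rs,
            )
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                sources = ica.fit_transform(x.T)  # (V, k) spatial sources
            converged = not any(
                "did not converge" in str(c.message) for c in caught
            )
            obj = _negentropy(sources)
            if best is None or obj > best[0]:
                best = (obj, sources, ica.mixing_.copy(), converged)
        _, sources, mixing, converged = best
        if not converged:
            logger.warning("FastICA did not converge; returning best iterate")

        maps = sources.T  # (k, V)
        tcs = mixing  # (T, k)
        # sign convention: nonnegative map skewness
        sgn = np.where(skew(maps, axis=1) < 0, -1.0, 1.0)
        maps = maps * sgn[:, None]
        tcs = tcs * sgn[None, :]
        # z-scale maps; push scale into timecourses, then normalize those too
        map_sd = maps.std(axis=1)
        maps = (maps - maps.mean(axis=1, keepdims=True)) / map_sd[:, None]
        tcs = tcs * map_sd[None, :]
        tc_sd = tcs.std(axis=0, ddof=0)
        comp_var = tc_sd**2  # variance explained per component in avg data
        tcs = tcs / tc_sd[None, :]
        order = np.argsort(comp_var)[::-1]
        maps, tcs, comp_var = maps[order], tcs[:, order], comp_var[order]

        loadings = _rank1_loadings(demeaned, tcs, maps)
        return ComponentSet(
            maps=maps,
            timecourses=tcs,
            loadings=loadings,
            explained_variance=comp_var / max((x**2).mean(), 1e-30),
            converged=converged,
            subject_ids=[r.subject_id for r in self.runs],
        )


def _negentropy(sources: np.ndarray) -> float:
    """Sum over components of the logcosh negentropy approximation."""
    s = (sources - sources.mean(axis=0)) / np.maximum(sources.std(axis=0), 1e-12)
    g = np.log(np.cosh(s)).mean(axis=0)
    g0 = 0.374567207491438  # E[log cosh Z], Z standard normal
    return float(np.sum((g - g0) ** 2))


def _rank1_loadings(
    demeaned: list[np.ndarray], tcs: np.ndarray, maps: np.ndarray
) -> np.ndarray:
    """Scalar least-squares fit of each subject's data onto tc_i x map_i."""
    n_sub, k = len(demeaned), maps.shape[0]
    loadings = np.empty((n_sub, k))
    denom = (tcs**2).sum(axis=0) * (maps**2).sum(axis=1)  # ||M_i||_F^2
    for s, ts in enumerate(demeaned):
        # <X, tc_i map_i^T> = tc_i^T X map_i
        num = np.einsum("ti,tv,iv->i", tcs, ts, maps, optimize=True)
        loadings[s] = num / denom
    return loadings


def fit_group_decomposition(
    runs: list[BoldRun], n_components: int | str = "auto", **kwargs
) -> ComponentSet:
    """Functional wrapper around :class:`GroupICA`."""
    return GroupICA(runs=runs, n_components=n_components, **kwargs).fit()


def select_components(cs: ComponentSet, k: int = 10) -> ComponentSet:
    """Keep the k most strongly expressed components.

    Strength is the median loading across subjects; the default k = 10
    matches the convention of analysing the ten most expressed networks.
    Ties keep the original component order (stable sort).
    """
    if k > cs.n_components:
        raise ValueError(f"k={k} exceeds {cs.n_components} components")
    med = np.median(cs.loadings, axis=0)
    order = np.argsort(-med, kind="stable")[:k]
    return replace(
        cs,
        maps=cs.maps[order],
        timecourses=cs.timecourses[:, order],
        loadings=cs.loadings[:, order],
        component_labels=(
            [cs.component_labels[i] for i in order] if cs.component_labels else None
        ),
        explained_variance=(
            cs.explained_variance[order] if cs.explained_variance is not None else None
        ),
    )


def match_templates(
    maps: np.ndarray,
    templates: np.ndarray,
    template_names: list[str],
    r_min: float = 0.25,
) -> list[str]:
    """Label each component map with its most spatially correlated template.

    A component whose best match falls below ``r_min`` is labelled
    ``"unmatched"``.
    """
    templates = np.asarray(templates, dtype=float)
    if templates.size == 0 or len(template_names) == 0:
        raise ValueError("template set is empty")
    if templates.shape[1] != maps.shape[1]:
        raise ValueError("template grid does not match component map grid")
    labels = []
    for m in maps:
        rs = np.array([_pearson(m, t) for t in templates])
        best = int(np.argmax(rs))
        labels.append(template_names[best] if rs[best] >= r_min else "unmatched")
    return labels


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom < 1e-30:
        return 0.0
    return float(a @ b / denom)


def component_correlation_clusters(
    timecourses: np.ndarray, max_clusters: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise timecourse correlations plus a cluster assignment.

    Average-linkage hierarchical clustering on distance 1 - r, cut at the
    number of clusters maximizing the silhouette. Constant timecourses are
    rejected (their correlation is undefined).
    """
    tcs = np.asarray(timecourses, dtype=float)
    k = tcs.shape[1]
    if k < 1:
        raise ValueError("need at least one component")
    if np.any(tcs.std(axis=0) < 1e-12):
        raise ValueError("constant timecourse: correlation undefined")
    if k == 1:
        return np.ones((1, 1)), np.zeros(1, dtype=int)
    corr = np.corrcoef(tcs.T)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    if k == 2:
        assign = np.array([0, 0]) if corr[0, 1] > 0 else np.array([0, 1])
        return corr, assign
    z = linkage(squareform(dist, checks=False), method="average")
    best_assign, best_sil = np.zeros(k, dtype=int), -np.inf
    for n_clust in range(2, min(max_clusters, k - 1) + 1):
        assign = fcluster(z, t=n_clust, criterion="maxclust") - 1
        if len(np.unique(assign)) < 2:
            continue
        sil = silhouette_score(dist, assign, metric="precomputed")
        if sil > best_sil:
            best_sil, best_assign = sil, assign
    return corr, best_assign


def stimulus_correlation(timecourses: np.ndarray, regressor: np.ndarray) -> np.ndarray:
    """Pearson correlation of each component timecourse with a stimulus
    regressor (e.g. talking on/off convolved with the HRF)."""
    tcs = np.asarray(timecourses, dtype=float)
    reg = np.asarray(regressor, dtype=float)
    if len(reg) != tcs.shape[0]:
        raise ValueError("regressor length does not match timecourses")
    if reg.std() < 1e-12:
        raise ValueError("zero-variance stimulus regressor")
    return np.array([_pearson(tcs[:, i], reg) for i in range(tcs.shape[1])])


def detect_loading_outliers(loadings: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Subjects whose loading on any component is > k sample-SDs from that
    component's mean (two-sided); k = 3 is the conventional rule."""
    lo = np.asarray(loadings, dtype=float)
    if lo.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    sd = lo.std(axis=0, ddof=1)
    keep = sd > 0  # zero-variance components carry no outlier information
    if not keep.any():
        return np.array([], dtype=int)
    z = np.abs(lo[:, keep] - lo[:, keep].mean(axis=0)) / sd[keep]
    return np.flatnonzero((z > k).any(axis=1))
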
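"""Individual-to-group correspondence in time and space.

Temporal synchrony is the Pearson correlation between one subject's
component (or ROI) timecourse and the group-average timecourse — computed
leave-one-out, so a subject is never correlated with a mean containing
their own data. Spatial correspondence is the correlation of a subject's
dual-regression map with the group component map. The per-subject
synchronization score is the arithmetic mean of the subject's temporal
correlations across the selected components.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bold import BoldRun, Parcellation

__all__ = [
    "temporal_synchrony",
    "leave_one_out_mean",
    "roi_timecourses",
    "roi_isc",
    "fisher_z",
    "spatial_correspondence",
    "synchronization_score",
    "component_synchrony_table",
]

#: |r| clip applied before arctanh so Fisher z stays finite
R_CLIP = 1.0 - 1e-7


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 samples")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-30 or nb < 1e-30:
        raise ValueError("zero-variance input; correlation undefined")
    return float(a @ b / (na * nb))


def temporal_synchrony(subject_tc: np.ndarray, group_tc: np.ndarray) -> float:
    """Pearson correlation of a subject timecourse with the group timecourse."""
    return _pearson(subject_tc, group_tc)


def leave_one_out_mean(tcs: np.ndarray, subject: int) -> np.ndarray:
    """Mean over all subjects' rows except ``subject``.

    Satisfies ``mean_all == ((n - 1) * loo_k + row_k) / n`` exactly.
    """
    tcs = np.asarray(tcs, dtype=float)
    n = tcs.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for a leave-one-out mean")
    if not 0 <= subject < n:
        raise IndexError(f"subject {subject} out of range")
    return (tcs.sum(axis=0) - tcs[subject]) / (n - 1)


def roi_timecourses(run: BoldRun, parcellation: Parcellation) -> tuple[np.ndarray, np.ndarray]:
    """Mean in-mask timecourse per ROI.

    Returns ``(roi_ids, tcs)`` with ``tcs`` of shape ``(n_roi, T)``. ROIs
    with no voxels inside the run's mask are dropped with a warning.
    """
    if parcellation.labels.shape != run.grid_shape:
        raise ValueError("parcellation grid does not match run grid")
    labels = parcellation.labels[run.mask]
    ts = run.timeseries()  # (T, V)
    kept_ids, tcs = [], []
    import warnings

    for roi in parcellation.roi_ids:
        member = labels == roi
        if not member.any():
            warnings.warn(f"ROI {roi} has no in-mask voxels; dropped", stacklevel=2)
            continue
        kept_ids.append(int(roi))
        tcs.append(ts[:, member].mean(axis=1))
    return np.array(kept_ids), np.array(tcs)


def roi_isc(all_roi_tcs: np.ndarray) -> np.ndarray:
    """Leave-one-out intersubject correlation per subject and ROI.

    ``all_roi_tcs`` has shape ``(n_subjects, n_roi, T)``; entry ``[k, j]``
    of the result is the correlation of subject k's ROI-j series with the
    mean ROI-j series of all other subjects. Undefined correlations
    (zero-variance series) are recorded as NaN.
    """
    x = np.asarray(all_roi_tcs, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected (subjects, rois, time) array")
    n_sub = x.shape[0]
    if n_sub < 3:
        raise ValueError("need at least 3 subjects")
    total = x.sum(axis=0)  # (roi, T)
    out = np.empty(x.shape[:2])
    for k in range(n_sub):
        loo = (total - x[k]) / (n_sub - 1)
        a = x[k] - x[k].mean(axis=1, keepdims=True)
        b = loo - loo.mean(axis=1, keepdims=True)
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (a * b).sum(axis=1) / (na * nb)
        r[(na < 1e-30) | (nb < 1e-30)] = np.nan
        out[k] = r
    return out


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher r-to-z transform, arctanh(r), with |r| clipped below 1."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0 + 1e-12):
        raise ValueError("|r| > 1 is not a correlation")
    z = np.arctanh(np.clip(arr, -R_CLIP, R_CLIP))
    return float(z) if np.isscalar(r) or arr.ndim == 0 else z


def spatial_correspondence(
    subject_map: np.ndarray, group_map: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Pearson correlation of a subject map with the group map over in-mask
    voxels."""
    sm = np.asarray(subject_map, float).ravel()
    gm = np.asarray(group_map, float).ravel()
    if mask is not None:
        m = np.asarray(mask, bool).ravel()
        if not m.any():
            raise ValueError("mask is empty")
        sm, gm = sm[m], gm[m]
    return _pearson(sm, gm)


def synchronization_score(per_component_r: np.ndarray) -> float:
    """Arithmetic mean of a subject's per-component temporal correlations.

    Missing values are rejected rather than silently skipped: the score is
    only comparable across subjects when every selected component
    contributes.
    """
    r = np.asarray(per_component_r, dtype=float)
    if r.size == 0:
        raise ValueError("no component correlations supplied")
    if np.isnan(r).any():
        raise ValueError("missing component correlation; cannot form score")
    return float(r.mean())


def component_synchrony_table(
    subject_timecourses: list[np.ndarray],
    subject_maps: list[np.ndarray] | None = None,
    group_maps: np.ndarray | None = None,
    subject_ids: list[str] | None = None,
    leave_one_out: bool = True,
) -> pd.DataFrame:
    """Per-subject, per-component synchrony table with the mean score.

    ``subject_timecourses`` holds each subject's stage-1 dual-regression
    timecourses ``(T, k)``. Temporal synchrony for subject s, component i is
    the correlation of their timecourse with the (leave-one-out) mean of
    everyone else's; with ``leave_one_out=False`` the self-inclusive group
    mean is used instead. If subject maps and group maps are given, spatial
    correspondence per component is added.
    """
    stack = np.stack(subject_timecourses)  # (S, T, k)
    n_sub, _, k = stack.shape
    if subject_ids is None:
        subject_ids = [f"sub-{s:03d}" for s in range(n_sub)]
    rows = []
    per_comp = stack.transpose(0, 2, 1)  # (S, k, T)
    for s in range(n_sub):
        row: dict[str, object] = {"subject_id": subject_ids[s]}
        rs = np.empty(k)
        for i in range(k):
            group = (
                leave_one_out_mean(per_comp[:, i, :], s)
                if leave_one_out
                else per_comp[:, i, :].mean(axis=0)
            )
            rs[i] = temporal_synchrony(per_comp[s, i], group)
            row[f"temporal_r_{i}"] = rs[i]
            row[f"temporal_z_{i}"] = fisher_z(rs[i])
        if subject_maps is not None and group_maps is not None:
            for i in range(k):
                row[f"spatial_r_{i}"] = spatial_correspondence(
                    subject_maps[s][i], group_maps[i]
                )
        row["sync_score"] = synchronization_score(rs)
        rows.append(row)
    return pd.DataFrame(rows)
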
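"""Dual regression: back-projection of group maps to subject space.

Stage 1 (spatial regression): for every frame, the subject's voxel vector
is regressed on all group spatial maps simultaneously (plus an intercept);
the per-frame coefficients form participant-specific component timecourses.
Stage 2 (temporal regression): those timecourses are variance-normalized
and used as a per-voxel temporal design; the coefficients form
participant-specific spatial maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bold import BoldRun

__all__ = [
    "SubjectSpatioTemporal",
    "spatial_regression",
    "temporal_regression",
    "dual_regress",
]

#: condition number above which a design is treated as rank-deficient
MAX_CONDITION = 1e8


@dataclass
class SubjectSpatioTemporal:
    """Participant-specific timecourses (stage 1) and maps (stage 2)."""

    timecourses: np.ndarray  # (T, k)
    maps: np.ndarray  # (k, V)
    subject_id: str = ""


def _design(columns: np.ndarray) -> np.ndarray:
    """Append an intercept column and check conditioning."""
    x = np.column_stack([columns, np.ones(columns.shape[0])])
    cond = np.linalg.cond(x)
    if not np.isfinite(cond) or cond > MAX_CONDITION:
        raise ValueError(
            f"rank-deficient regression design (condition number {cond:.3g})"
        )
    return x


def spatial_regression(run: BoldRun, group_maps: np.ndarray) -> np.ndarray:
    """Stage 1: OLS of each frame's voxel vector on the group maps.

    Returns the ``(T, k)`` participant-specific timecourses.
    """
    group_maps = np.asarray(group_maps, dtype=float)
    ts = run.timeseries()  # (T, V)
    if group_maps.shape[1] != ts.shape[1]:
        raise ValueError("group map grid does not match run voxel count")
    x = _design(group_maps.T)  # (V, k+1)
    beta, *_ = np.linalg.lstsq(x, ts.T, rcond=None)  # (k+1, T)
    return beta[:-1].T.copy()


def temporal_regression(run: BoldRun, subject_timecourses: np.ndarray) -> np.ndarray:
    """Stage 2: per-voxel OLS on variance-normalized subject timecourses.

    Returns the ``(k, V)`` participant-specific spatial maps.
    """
    tcs = np.asarray(subject_timecourses, dtype=float)
    ts = run.timeseries()
    if tcs.shape[0] != ts.shape[0]:
        raise ValueError("timecourse length does not match run")
    sd = tcs.std(axis=0, ddof=1)
    if np.any(sd < 1e-12):
        raise ValueError("constant timecourse column cannot be variance-normalized")
    x = _design(tcs / sd)
    beta, *_ = np.linalg.lstsq(x, ts, rcond=None)  # (k+1, V)
    return beta[:-1].copy()


def dual_regress(run: BoldRun, group_maps: np.ndarray) -> SubjectSpatioTemporal:
    """Both stages in order: group maps -> subject timecourses -> subject maps."""
    tcs = spatial_regression(run, group_maps)
    maps = temporal_regression(run, tcs)
    return SubjectSpatioTemporal(timecourses=tcs, maps=maps, subject_id=run.subject_id)
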
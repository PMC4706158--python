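"""In-memory containers for single-subject BOLD runs and parcellations."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["BoldRun", "Parcellation"]


@dataclass
class BoldRun:
    """One subject's 4D BOLD series.

    Attributes
    ----------
    data
        Array of shape ``(X, Y, Z, T)``.
    tr_s
        Repetition time in seconds.
    mask
        Boolean brain mask of shape ``(X, Y, Z)``; analysis operates on
        in-mask voxels only.
    subject_id
        Subject identifier.
    affine
        4x4 voxel-to-world NIfTI affine.
    voxel_mm
        Voxel edge lengths (mm) along each spatial axis, derived from the
        affine if not given.
    """

    data: np.ndarray
    tr_s: float
    mask: np.ndarray | None = None
    subject_id: str = ""
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    voxel_mm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(
                f"BOLD data must be 4D (X, Y, Z, T); got {self.data.ndim}D"
            )
        if self.data.shape[-1] < 2:
            raise ValueError("BOLD run needs at least 2 frames")
        if np.isnan(self.data).any():
            raise ValueError("BOLD data contain missing values")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape does not match spatial grid")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if self.voxel_mm is None:
            self.voxel_mm = tuple(
                float(v) for v in np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def timeseries(self) -> np.ndarray:
        """Return the in-mask data as a ``(T, V)`` matrix (frames x voxels)."""
        return self.data[self.mask].T.copy()

    def with_timeseries(self, ts: np.ndarray) -> "BoldRun":
        """Return a copy with in-mask voxel series replaced by ``ts`` (T x V)."""
        ts = np.asarray(ts, dtype=float)
        if ts.shape != (self.n_timepoints, self.n_voxels):
            raise ValueError(
                f"expected shape {(self.n_timepoints, self.n_voxels)}, got {ts.shape}"
            )
        data = self.data.copy()
        data[self.mask] = ts.T
        return replace(self, data=data)


@dataclass
class Parcellation:
    """Integer-labelled volume partitioning voxels into ROIs (0 = background)."""

    labels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("parcellation labels must be integer")
        if self.labels.ndim != 3:
            raise ValueError("parcellation must be a 3D label volume")
        if (self.labels < 0).any():
            raise ValueError("parcellation labels must be nonnegative")

    @property
    def roi_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def roi_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}
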
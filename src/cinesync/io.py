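"""Readers and writers for NIfTI runs, parcellations, and TSV tables.

Conventions: voxel indices are 0-based internally; world coordinates go
through the NIfTI affine; all volumes are written on the input grid (the
pipeline never resamples). Tables are TSV, UTF-8, '.' decimal.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .bold import BoldRun, Parcellation

__all__ = [
    "read_bold",
    "write_bold",
    "read_parcellation",
    "write_parcellation",
    "read_subject_table",
    "read_events",
    "write_component_maps",
    "paint_roi_values",
    "write_roi_map",
    "write_tsv",
]

logger = logging.getLogger(__name__)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_bold(path: str | Path, subject_id: str | None = None) -> BoldRun:
    """Load a 4D NIfTI run.

    The repetition time comes from a JSON sidecar (key ``RepetitionTime``,
    seconds) when one exists next to the image — the sidecar wins over the
    header and the override is logged — otherwise from the header's fourth
    pixdim. A missing or nonpositive TR is rejected.
    """
    path = Path(path)
    img = nib.load(path)
    if img.ndim != 4:
        raise ValueError(f"{path.name}: expected a 4D image, got {img.ndim}D")
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "RepetitionTime" in meta:
            tr_side = float(meta["RepetitionTime"])
            if tr > 0 and abs(tr_side - tr) > 1e-6:
                logger.info(
                    "%s: sidecar TR %.4f s overrides header TR %.4f s",
                    path.name, tr_side, tr,
                )
            tr = tr_side
    if tr <= 0:
        raise ValueError(f"{path.name}: repetition time missing from header and sidecar")
    data = np.asarray(img.get_fdata(), dtype=float)
    return BoldRun(
        data=data,
        tr_s=tr,
        subject_id=subject_id or path.name.split(".")[0],
        affine=np.asarray(img.affine),
    )


def write_bold(run: BoldRun, path: str | Path) -> None:
    """Write a run as float32 NIfTI-1 with the TR in the header and sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(run.data.astype(np.float32), run.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = run.tr_s
    img.header.set_zooms(zooms)
    nib.save(img, path)
    _sidecar_path(path).write_text(json.dumps({"RepetitionTime": run.tr_s}))


def read_parcellation(path: str | Path) -> Parcellation:
    """Load an integer-labelled 3D parcellation volume (0 = background)."""
    img = nib.load(Path(path))
    if img.ndim != 3:
        raise ValueError(f"parcellation must be 3D, got {img.ndim}D")
    labels = np.rint(np.asarray(img.get_fdata())).astype(int)
    return Parcellation(labels=labels, affine=np.asarray(img.affine))


def write_parcellation(parc: Parcellation, path: str | Path) -> None:
    nib.save(
        nib.Nifti1Image(parc.labels.astype(np.int32), parc.affine), Path(path)
    )


def read_subject_table(path: str | Path) -> pd.DataFrame:
    """Load the subject covariate TSV.

    Requires ``subject_id``, ``age``, and ``education`` columns and unique
    subject ids; row order is preserved. A ``rt_trials`` column, when
    present, holds paths (relative to the table) to per-subject trial TSVs
    with an ``rt_s`` column, which are loaded into numpy arrays.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    for col in ("subject_id", "age", "education"):
        if col not in table.columns:
            raise ValueError(f"subject table is missing required column '{col}'")
    dupes = table["subject_id"][table["subject_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate subject_id: {sorted(set(dupes))}")
    if "rt_trials" in table.columns and table["rt_trials"].dtype == object:
        trials = []
        for p in table["rt_trials"]:
            if pd.isna(p):
                trials.append(None)
                continue
            tp = path.parent / str(p)
            trials.append(pd.read_csv(tp, sep="\t")["rt_s"].to_numpy())
        table["rt_trials"] = trials
    return table


def read_events(path: str | Path) -> list[tuple[float, float]]:
    """Load a stimulus event TSV with ``onset`` and ``duration`` columns
    (seconds). Overlapping events are accepted; their boxcars sum."""
    table = pd.read_csv(Path(path), sep="\t")
    for col in ("onset", "duration"):
        if col not in table.columns:
            raise ValueError(f"event file is missing required column '{col}'")
    if (table["duration"] < 0).any():
        bad = table.index[table["duration"] < 0].tolist()
        raise ValueError(f"negative event duration at rows {bad}")
    if (table["onset"] < 0).any():
        bad = table.index[table["onset"] < 0].tolist()
        raise ValueError(f"negative event onset at rows {bad}")
    return list(zip(table["onset"].astype(float), table["duration"].astype(float)))


def write_component_maps(
    maps: np.ndarray,
    grid_shape: tuple[int, int, int],
    affine: np.ndarray,
    path: str | Path,
) -> None:
    """Write component maps as one 4D NIfTI, component axis last."""
    vol = maps.T.reshape(*grid_shape, maps.shape[0]).astype(np.float32)
    nib.save(nib.Nifti1Image(vol, affine), Path(path))


def paint_roi_values(
    parc: Parcellation,
    roi_ids: np.ndarray,
    values: np.ndarray,
    background: float = 0.0,
) -> np.ndarray:
    """Paint one scalar per ROI onto the parcellation grid.

    Returns a float volume with each ROI's voxels set to its value;
    background (label 0) and unlisted ROIs get ``background``. Useful for
    writing per-ROI r/t/significance statistics as NIfTI overlays.
    """
    roi_ids = np.asarray(roi_ids)
    values = np.asarray(values, dtype=float)
    if roi_ids.shape != values.shape:
        raise ValueError("one value per roi_id required")
    vol = np.full(parc.labels.shape, background, dtype=float)
    for roi, val in zip(roi_ids, values):
        vol[parc.labels == roi] = val
    return vol


def write_roi_map(
    parc: Parcellation,
    roi_ids: np.ndarray,
    values: np.ndarray,
    path: str | Path,
) -> None:
    """Write per-ROI values painted onto the parcellation as a 3D NIfTI."""
    vol = paint_roi_values(parc, roi_ids, values)
    nib.save(nib.Nifti1Image(vol.astype(np.float32), parc.affine), Path(path))


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(Path(path), sep="\t", index=False, lineterminator="\n")
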
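"""Temporal preprocessing and motion/spike quality control.

These are the analysis-relevant steps applied to already spatially-aligned
runs: spike (motion artifact) detection and interpolation, run-level spike
percentage and subject exclusion, high-pass filtering on a discrete-cosine
drift basis, Gaussian spatial smoothing, grand-mean intensity scaling, and
RMS volume-to-volume displacement from rigid-body motion parameters.

Spike detection is a wavelet-flavoured surrogate: for runs whose length is
a multiple of ``2**level`` a stationary (undecimated) wavelet transform
(Daubechies-4) is taken per voxel and time points whose detail coefficients
exceed ``k`` times a MAD-based scale at any level are flagged; other run
lengths fall back to a robust second-difference detector with the same
MAD thresholding. Both flag frame x voxel samples, which is all the
downstream spike-percentage metric and exclusion rule consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pywt
from scipy import ndimage

from .bold import BoldRun

__all__ = [
    "QCReport",
    "detect_spikes",
    "despike",
    "spike_percentage",
    "exclude_outliers_above",
    "highpass_filter",
    "smooth_gaussian",
    "grand_mean_scale",
    "rms_displacement",
    "qc_cohort",
]

#: factor converting a median absolute deviation to a Gaussian SD
MAD_TO_SD = 1.4826
#: assumed head radius (mm) for converting rotations to arc displacement
HEAD_RADIUS_MM = 50.0


@dataclass
class QCReport:
    subject_id: str
    spike_percentage: float
    rms_displacement_mm: float | None = None
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.spike_percentage <= 100.0:
            raise ValueError("spike_percentage must lie in [0, 100]")


def _mad_scale(x: np.ndarray, axis: int = 0) -> np.ndarray:
    med = np.median(x, axis=axis, keepdims=True)
    return MAD_TO_SD * np.median(np.abs(x - med), axis=axis)


def detect_spikes(run: BoldRun, threshold_k: float = 5.0) -> np.ndarray:
    """Flag voxel-frames carrying spike artifacts.

    Returns a boolean ``(T, V)`` mask over in-mask voxels. ``threshold_k``
    multiplies the per-voxel MAD-based robust scale.
    """
    if threshold_k <= 0:
        raise ValueError("threshold_k must be positive")
    ts = run.timeseries()
    n_t = ts.shape[0]
    if n_t < 8:
        raise ValueError("run too short for spike detection (< 8 frames)")

    flags = _detect_spikes_derivative(ts, threshold_k)
    level = min(4, pywt.swt_max_level(n_t))
    if level >= 1 and n_t % (2**level) == 0:
        # wavelet chains catch prolonged events the frame-local detector
        # misses; the union keeps exact-frame sensitivity for spikes
        flags |= _detect_spikes_swt(ts, threshold_k, level)
    return flags


def _detect_spikes_swt(ts: np.ndarray, k: float, level: int) -> np.ndarray:
    x = ts - ts.mean(axis=0)
    coeffs = pywt.swt(x, "db4", level=level, axis=0, trim_approx=True, norm=True)
    flags = np.zeros(ts.shape, dtype=bool)
    for detail in coeffs[1:]:  # detail bands, coarse to fine
        scale = np.maximum(_mad_scale(detail, axis=0), 1e-12)
        flags |= np.abs(detail) > k * scale
    return flags


def _detect_spikes_derivative(ts: np.ndarray, k: float) -> np.ndarray:
    # deviation of each sample from the midpoint of its temporal neighbours;
    # isolated spikes stand out, smooth trends cancel
    x = ts
    score = np.empty_like(x)
    score[1:-1] = np.abs(x[1:-1] - 0.5 * (x[:-2] + x[2:]))
    score[0] = np.abs(x[0] - x[1])
    score[-1] = np.abs(x[-1] - x[-2])
    scale = np.maximum(_mad_scale(score, axis=0), 1e-12)
    return score > k * scale


def despike(run: BoldRun, spike_mask: np.ndarray) -> BoldRun:
    """Replace flagged samples by temporal interpolation between clean frames.

    Frame count is preserved; unflagged samples are untouched. A voxel with
    every frame flagged is left unchanged with a warning.
    """
    ts = run.timeseries()
    spike_mask = np.asarray(spike_mask, dtype=bool)
    if spike_mask.shape != ts.shape:
        raise ValueError(
            f"spike mask shape {spike_mask.shape} does not match run {ts.shape}"
        )
    if not spike_mask.any():
        return run.with_timeseries(ts)
    frames = np.arange(ts.shape[0])
    out = ts.copy()
    n_dead = 0
    for v in np.flatnonzero(spike_mask.any(axis=0)):
        good = ~spike_mask[:, v]
        if not good.any():
            n_dead += 1
            continue
        out[~good, v] = np.interp(frames[~good], frames[good], ts[good, v])
    if n_dead:
        warnings.warn(
            f"{n_dead} voxel(s) had every frame flagged; left unchanged",
            stacklevel=2,
        )
    return run.with_timeseries(out)


def spike_percentage(spike_mask: np.ndarray) -> float:
    """Mean over frames of the percentage of voxels flagged in that frame."""
    spike_mask = np.asarray(spike_mask, dtype=bool)
    if spike_mask.size == 0:
        raise ValueError("empty spike mask")
    return float(100.0 * spike_mask.mean(axis=1).mean())


def exclude_outliers_above(values: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Indices of subjects whose value exceeds mean + k * sample SD.

    The default k = 3 is the conventional high-motion exclusion rule.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 subjects")
    sd = values.std(ddof=1)
    if sd == 0:
        return np.array([], dtype=int)
    return np.flatnonzero(values > values.mean() + k * sd)


def _dct_drift_basis(n_t: int, tr_s: float, cutoff_s: float) -> np.ndarray:
    """Drift basis: constant, straight line, and discrete cosines spanning
    fluctuations with period > cutoff_s. The explicit linear term mirrors a
    running-line detrend, which removes straight lines exactly."""
    order = int(np.floor(2.0 * n_t * tr_s / cutoff_s))
    t = (np.arange(n_t) + 0.5) / n_t
    cols = [np.ones(n_t), t - t.mean()]
    for j in range(1, order + 1):
        cols.append(np.cos(np.pi * j * t))
    return np.column_stack(cols)


def highpass_filter(run: BoldRun, cutoff_s: float = 100.0) -> BoldRun:
    """Remove the mean and fluctuations slower than ``cutoff_s`` seconds.

    Implemented as residualization against a discrete-cosine drift basis —
    the standard explicit equivalent of a Gaussian-weighted running-line
    detrend at the same cutoff.
    """
    if cutoff_s <= 2 * run.tr_s:
        raise ValueError("cutoff_s must exceed twice the repetition time")
    ts = run.timeseries()
    basis = _dct_drift_basis(ts.shape[0], run.tr_s, cutoff_s)
    beta, *_ = np.linalg.lstsq(basis, ts, rcond=None)
    return run.with_timeseries(ts - basis @ beta)


def smooth_gaussian(
    run: BoldRun, fwhm_mm: float = 8.0, voxel_mm: tuple[float, float, float] | None = None
) -> BoldRun:
    """Per-frame 3D Gaussian smoothing, sigma = FWHM / (2 sqrt(2 ln 2)) per axis.

    Outside-mask voxels carry no weight: the kernel is renormalized inside
    the mask (smooth(data * mask) / smooth(mask)).
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    voxel_mm = voxel_mm or run.voxel_mm
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = [sigma_mm / v for v in voxel_mm]
    mask = run.mask.astype(float)
    weight = ndimage.gaussian_filter(mask, sigma=sigma_vox, mode="constant")
    data = run.data.copy()
    for t in range(run.n_timepoints):
        frame = ndimage.gaussian_filter(
            run.data[..., t] * mask, sigma=sigma_vox, mode="constant"
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = np.where(weight > 1e-12, frame / np.maximum(weight, 1e-12), 0.0)
        data[..., t] = np.where(run.mask, sm, run.data[..., t])
    return replace(run, data=data)


def grand_mean_scale(run: BoldRun, target: float = 10000.0) -> BoldRun:
    """Scale the whole 4D series so the in-mask grand mean equals ``target``."""
    ts = run.timeseries()
    gm = ts.mean()
    if abs(gm) < 1e-12:
        raise ValueError("grand mean is zero; cannot scale")
    return run.with_timeseries(ts * (target / gm))


def rms_displacement(motion_params: np.ndarray, head_radius_mm: float = HEAD_RADIUS_MM) -> float:
    """RMS volume-to-volume displacement from ``(T, 6)`` rigid-body parameters.

    Columns are three translations (mm) and three rotations (radians);
    rotations are converted to arc displacement at ``head_radius_mm``.
    """
    p = np.asarray(motion_params, dtype=float)
    if p.ndim != 2 or p.shape[1] != 6:
        raise ValueError("motion parameters must have shape (T, 6)")
    if p.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    d = np.diff(p, axis=0)
    d[:, 3:] *= head_radius_mm
    step = np.linalg.norm(d, axis=1)
    return float(np.sqrt(np.mean(step**2)))


def qc_cohort(
    runs: list[BoldRun],
    threshold_k: float = 5.0,
    exclusion_k: float = 3.0,
    motion_params: list[np.ndarray] | None = None,
) -> tuple[list[QCReport], list[np.ndarray]]:
    """Run spike QC over a cohort and apply the mean + k SD exclusion rule.

    Returns per-subject reports and the spike masks (for despiking).
    """
    masks = [detect_spikes(run, threshold_k) for run in runs]
    pct = np.array([spike_percentage(m) for m in masks])
    excluded = set()
    if len(runs) >= 3:
        excluded = set(exclude_outliers_above(pct, k=exclusion_k).tolist())
    reports = []
    for i, run in enumerate(runs):
        rms = None
        if motion_params is not None:
            rms = rms_displacement(motion_params[i])
        reports.append(
            QCReport(
                subject_id=run.subject_id,
                spike_percentage=float(pct[i]),
                rms_displacement_mm=rms,
                excluded=i in excluded,
                exclusion_reason="spike_percentage" if i in excluded else "",
            )
        )
    return reports, masks
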
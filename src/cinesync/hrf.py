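"""Canonical hemodynamic response function and stimulus-event regressors.

The BOLD response to a brief neural event is modelled with the canonical
double-gamma impulse response: a gamma density peaking ~5-6 s after the
event minus a smaller, later gamma capturing the post-stimulus undershoot.
Stimulus event lists (onset, duration in seconds) are turned into network
regressors by convolving a boxcar with this kernel on an oversampled time
grid and resampling at the repetition time (TR).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as _gamma_dist

__all__ = ["double_gamma_hrf", "event_regressor"]

#: shape parameters of the canonical double-gamma response (unit rate, s^-1):
#: response gamma peaks at (PEAK_SHAPE-1) = 5 s, undershoot at 15 s,
#: undershoot amplitude 1/6 of the peak.
PEAK_SHAPE = 6.0
UNDERSHOOT_SHAPE = 16.0
UNDERSHOOT_RATIO = 1.0 / 6.0
HRF_DURATION_S = 32.0


def double_gamma_hrf(t: np.ndarray) -> np.ndarray:
    """Sample the canonical double-gamma HRF at times ``t`` (seconds).

    The kernel is scaled so its maximum on a dense grid equals 1; values at
    negative times are 0 (causality).
    """
    t = np.asarray(t, dtype=float)
    h = _double_gamma_raw(t)
    dense = _double_gamma_raw(np.linspace(0.0, HRF_DURATION_S, 4097))
    return h / dense.max()


def _double_gamma_raw(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    out = _gamma_dist.pdf(t, PEAK_SHAPE) - UNDERSHOOT_RATIO * _gamma_dist.pdf(
        t, UNDERSHOOT_SHAPE
    )
    return np.where(t < 0, 0.0, out)


def event_regressor(
    events: list[tuple[float, float]],
    tr_s: float,
    n_timepoints: int,
    oversampling: int = 16,
) -> np.ndarray:
    """Boxcar-convolve stimulus events with the canonical HRF.

    Parameters
    ----------
    events
        ``(onset_s, duration_s)`` pairs. Overlapping events sum (their
        boxcars add). Each event must lie entirely within the run.
    tr_s
        Repetition time in seconds.
    n_timepoints
        Number of frames in the run; output has this length.
    oversampling
        Microtime resolution: the boxcar and HRF are sampled at
        ``tr_s / oversampling`` before convolution.

    Returns
    -------
    numpy.ndarray
        The stimulus regressor sampled at frame acquisition times
        ``0, tr_s, 2*tr_s, ...``.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    if n_timepoints <= 0:
        raise ValueError("n_timepoints must be positive")
    run_length_s = tr_s * n_timepoints
    dt = tr_s / oversampling
    n_fine = n_timepoints * oversampling
    boxcar = np.zeros(n_fine)
    for onset, duration in events:
        if onset < 0:
            raise ValueError(f"event onset {onset} s is negative")
        if duration < 0:
            raise ValueError(f"event duration {duration} s is negative")
        if onset + duration > run_length_s + 1e-9:
            raise ValueError(
                f"event ({onset} s + {duration} s) extends beyond the "
                f"{run_length_s:.2f} s run"
            )
        i0 = int(np.floor(onset / dt))
        i1 = max(i0 + 1, int(np.ceil((onset + duration) / dt)))
        boxcar[i0 : min(i1, n_fine)] += 1.0
    if not events:
        return np.zeros(n_timepoints)
    kernel = double_gamma_hrf(np.arange(0.0, HRF_DURATION_S + dt / 2, dt))
    convolved = np.convolve(boxcar, kernel)[:n_fine]
    return convolved[::oversampling].copy()
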
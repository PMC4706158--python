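"""Synthetic naturalistic-BOLD cohort generator with retained ground truth.

The generator emulates the data model assumed by a multi-subject (tensor
style) decomposition of movie-watching fMRI: every subject shares the same
network spatial maps and the same stimulus-locked network timecourses, and
differs only in a scalar coupling per network (how strongly that subject
expresses the shared spatiotemporal pattern), plus nuisance structure —
temporally autocorrelated noise, slow scanner drift, and motion-spike
artifacts whose rate may increase with age. Coupling declines linearly with
standardized age, planting the age -> synchrony effect the downstream
analysis is designed to detect. Cognitive scores (fluid/crystallized style)
and speeded-choice reaction-time trials are generated with planted age,
synchrony, and age x synchrony effects.

Everything is driven by a single integer seed through independent
``numpy.random.SeedSequence`` substreams, so identical (config, seed) pairs
reproduce every artifact bit-exactly regardless of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .bold import BoldRun
from .hrf import event_regressor

__all__ = [
    "SimulationConfig",
    "RTConfig",
    "GroundTruth",
    "generate_event_timecourse",
    "generate_network_maps",
    "simulate_truth",
    "generate_subject_bold",
    "generate_cognitive_scores",
    "simulate_cohort",
]

# stream tags for SeedSequence spawning (stable across versions)
_STREAM_TRUTH = 0
_STREAM_BOLD = 1
_STREAM_SCORES = 2

#: additive baseline of the simulated scanner signal (arbitrary units)
BASELINE = 100.0

# alias: stimulus events -> HRF-convolved regressor
generate_event_timecourse = event_regressor


@dataclass
class RTConfig:
    """Speeded choice reaction-time task generator settings.

    ``mean_base``/``isd_base`` are the population intercepts of the
    per-subject RT mean and intraindividual SD (seconds); the ``*_age_slope``
    terms are per standardized-age unit. A small fraction of trials are
    replaced by extreme attentional-lapse outliers ``outlier_scale`` ISDs
    above the subject's mean, so the 3-SD trial-trimming rule has work to do.
    """

    n_trials: int = 66
    mean_base: float = 0.55
    mean_age_slope: float = 0.08
    isd_base: float = 0.10
    isd_age_slope: float = 0.03
    trial_outlier_rate: float = 0.02
    outlier_scale: float = 6.0


def _default_cognitive_effects() -> dict[str, tuple[float, float, float, float]]:
    # score -> (age slope /yr, synchrony slope, age x synchrony slope, noise SD)
    # Scales chosen to mirror typical aging-cohort effect sizes: fluid ability
    # declines with age and interacts positively with synchrony in later life;
    # crystallized ability rises slightly with age and is synchrony-blind.
    return {
        "fluid": (-0.23, 1.9, 0.55, 4.0),
        "crystallized": (0.08, 5.6, 0.0, 5.0),
    }


@dataclass
class SimulationConfig:
    """Cohort simulation settings; defaults define the package's reference
    desk-scale study conditions."""

    n_subjects: int = 24
    n_timepoints: int = 200
    tr_s: float = 2.47
    grid_shape: tuple[int, int, int] = (16, 16, 12)
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 4.44)
    n_networks: int = 3
    age_range_years: tuple[float, float] = (18.0, 88.0)
    coupling_intercept: float = 1.0
    coupling_age_slope: float = -0.3
    coupling_noise_sd: float = 0.15
    noise_sd: float = 1.0
    ar1_coef: float = 0.3
    drift_amplitude: float = 1.0
    spike_rate_per_frame: float = 0.01
    spike_rate_age_slope: float = 0.005
    spike_voxel_fraction: float = 0.5
    cognitive_effects: dict[str, tuple[float, float, float, float]] = field(
        default_factory=_default_cognitive_effects
    )
    rt: RTConfig = field(default_factory=RTConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_timepoints <= 0 or self.n_networks <= 0:
            raise ValueError("counts must be positive")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be three positive voxel counts")
        if not 0.0 <= self.spike_rate_per_frame <= 1.0:
            raise ValueError("spike_rate_per_frame must be a probability")
        if not 0.0 <= self.ar1_coef < 1.0:
            raise ValueError("ar1_coef must lie in [0, 1)")
        if self.noise_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("noise_sd and drift_amplitude must be nonnegative")
        if self.age_range_years[0] > self.age_range_years[1]:
            raise ValueError("age_range_years must be (min, max)")


@dataclass
class GroundTruth:
    """Planted quantities retained for recovery testing."""

    maps: np.ndarray  # network x voxel
    timecourses: np.ndarray  # time x network, unit variance
    coupling: np.ndarray  # subject x network, >= 0
    ages: np.ndarray  # years
    education: np.ndarray  # ordinal levels
    sync_true: np.ndarray  # subject latent synchrony in (0, 1)
    spike_frames: list[np.ndarray]  # per-subject spiked frame indices
    grid_shape: tuple[int, int, int]
    cognitive_coefficients: dict[str, tuple[float, float, float, float]]

    def __post_init__(self) -> None:
        n_net, n_vox = self.maps.shape
        if self.timecourses.shape[1] != n_net:
            raise ValueError("timecourses/maps network counts differ")
        if self.coupling.shape != (len(self.ages), n_net):
            raise ValueError("coupling shape inconsistent with ages/networks")
        if (self.coupling < 0).any():
            raise ValueError("coupling must be nonnegative")
        if int(np.prod(self.grid_shape)) != n_vox:
            raise ValueError("grid_shape inconsistent with map voxel count")

    @property
    def n_subjects(self) -> int:
        return len(self.ages)


def generate_network_maps(
    grid_shape: tuple[int, int, int], n_networks: int, seed: int
) -> np.ndarray:
    """Smooth, compact, nonnegative-peaked network maps on a voxel grid.

    Each network is a 3D Gaussian blob (unit peak) centred at points chosen
    by farthest-point sampling so that pairwise spatial correlations stay
    below |r| = 0.3. Returns a ``(n_networks, n_voxels)`` matrix.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    grid = np.asarray(grid_shape, int)
    n_vox = int(grid.prod())
    if n_networks > n_vox // 8:
        raise ValueError(
            f"{n_networks} networks do not fit a {tuple(grid_shape)} grid"
        )
    rng = np.random.default_rng(seed)
    coords = np.stack(
        np.meshgrid(*[np.arange(s) for s in grid], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    sigma = np.maximum(grid / 10.0, 1.0)

    for _attempt in range(20):
        # farthest-point sampling of blob centres, away from the grid edge;
        # centres snap to voxels so every blob attains its unit peak exactly
        lo, hi = 0.2 * grid, 0.8 * grid
        centres = [np.round(rng.uniform(lo, hi))]
        while len(centres) < n_networks:
            cand = np.round(rng.uniform(lo, hi, size=(64, 3)))
            d = np.min(
                np.linalg.norm(cand[:, None, :] - np.array(centres)[None], axis=-1),
                axis=1,
            )
            centres.append(cand[np.argmax(d)])
        maps = np.empty((n_networks, n_vox))
        for i, c in enumerate(centres):
            z2 = (((coords - c) / sigma) ** 2).sum(axis=1)
            maps[i] = np.exp(-0.5 * z2)
        if n_networks == 1:
            return maps
        r = np.corrcoef(maps)
        if np.max(np.abs(r[np.triu_indices(n_networks, 1)])) < 0.3:
            return maps
    raise RuntimeError(
        "could not place networks with pairwise |r| < 0.3; grid too small"
    )


def _shared_timecourses(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Stimulus-locked network timecourses: random on/off scene blocks
    convolved with the canonical HRF, z-scored per network."""
    run_s = config.n_timepoints * config.tr_s
    tcs = np.empty((config.n_timepoints, config.n_networks))
    for i in range(config.n_networks):
        events = []
        t = float(rng.uniform(0, 10.0))
        while t < run_s - 1.0:
            dur = float(np.clip(rng.exponential(8.0), 1.0, 30.0))
            dur = min(dur, run_s - t)
            events.append((t, dur))
            t += dur + float(np.clip(rng.exponential(8.0), 2.0, 40.0))
        tc = generate_event_timecourse(events, config.tr_s, config.n_timepoints)
        sd = tc.std()
        if sd < 1e-12:  # degenerate draw; fall back to smooth noise
            tc = rng.standard_normal(config.n_timepoints)
            sd = tc.std()
        tcs[:, i] = (tc - tc.mean()) / sd
    return tcs


def simulate_truth(config: SimulationConfig) -> GroundTruth:
    """Draw the cohort-level ground truth: maps, shared timecourses, ages,
    education, and per-subject network couplings."""
    ss = np.random.SeedSequence([config.seed, _STREAM_TRUTH])
    rng = np.random.default_rng(ss)
    maps = generate_network_maps(
        config.grid_shape, config.n_networks, seed=int(ss.generate_state(1)[0] % 2**31)
    )
    tcs = _shared_timecourses(config, rng)
    lo, hi = config.age_range_years
    ages = rng.uniform(lo, hi, size=config.n_subjects)
    sd = ages.std()
    age_z = (ages - ages.mean()) / (sd if sd > 0 else 1.0)
    education = rng.integers(1, 6, size=config.n_subjects)
    coupling = (
        config.coupling_intercept
        + config.coupling_age_slope * age_z[:, None]
        + config.coupling_noise_sd
        * rng.standard_normal((config.n_subjects, config.n_networks))
    )
    coupling = np.clip(coupling, 0.0, None)
    # latent synchrony: expected correlation of a coupled signal with the
    # shared timecourse at unit effective noise, averaged over networks
    sync_true = np.mean(coupling / np.sqrt(coupling**2 + 1.0), axis=1)
    return GroundTruth(
        maps=maps,
        timecourses=tcs,
        coupling=coupling,
        ages=ages,
        education=education,
        sync_true=sync_true,
        spike_frames=[np.array([], dtype=int) for _ in range(config.n_subjects)],
        grid_shape=tuple(config.grid_shape),
        cognitive_coefficients=dict(config.cognitive_effects),
    )


def generate_subject_bold(
    truth: GroundTruth, config: SimulationConfig, subject_index: int
) -> BoldRun:
    """Simulate one subject's 4D run from the shared truth.

    data = baseline + sum_i coupling[k, i] * (timecourse_i x map_i)
           + AR(1) noise + slow cosine drift + recorded spike artifacts.

    Spike frame indices are written back into ``truth.spike_frames``.
    """
    k = int(subject_index)
    if not 0 <= k < truth.n_subjects:
        raise IndexError(f"subject_index {k} out of range")
    n_t, n_vox = config.n_timepoints, int(np.prod(config.grid_shape))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_BOLD, k]))

    signal = truth.timecourses @ (truth.coupling[k][:, None] * truth.maps)

    noise = np.zeros((n_t, n_vox))
    if config.noise_sd > 0:
        w = rng.standard_normal((n_t, n_vox))
        innov_sd = config.noise_sd * np.sqrt(1.0 - config.ar1_coef**2)
        noise = lfilter([1.0], [1.0, -config.ar1_coef], innov_sd * w, axis=0)

    drift = np.zeros((n_t, n_vox))
    if config.drift_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi, size=n_vox)
        t = np.arange(n_t) / n_t
        drift = config.drift_amplitude * np.cos(2 * np.pi * t[:, None] + phase[None, :])

    data = BASELINE + signal + noise + drift

    ages = truth.ages
    sd = ages.std()
    age_z = (ages[k] - ages.mean()) / (sd if sd > 0 else 1.0)
    p_spike = float(
        np.clip(
            config.spike_rate_per_frame + config.spike_rate_age_slope * age_z, 0.0, 1.0
        )
    )
    spike_frames = np.flatnonzero(rng.random(n_t) < p_spike)
    for frame in spike_frames:
        n_hit = max(1, int(round(config.spike_voxel_fraction * n_vox)))
        vox = rng.choice(n_vox, size=n_hit, replace=False)
        magnitude = rng.uniform(8.0, 20.0, size=n_hit) * max(config.noise_sd, 1e-3)
        data[frame, vox] += rng.choice([-1.0, 1.0], size=n_hit) * magnitude
    truth.spike_frames[k] = spike_frames

    affine = np.diag([*config.voxel_mm, 1.0])
    return BoldRun(
        data=data.T.reshape(*config.grid_shape, n_t),
        tr_s=config.tr_s,
        subject_id=f"sub-{k:03d}",
        affine=affine,
        voxel_mm=tuple(config.voxel_mm),
    )


def generate_cognitive_scores(truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """Cognitive scores and RT trials with planted age/synchrony effects.

    Each score in ``config.cognitive_effects`` follows

        score = b_age * age_c + b_sync * sync_c + b_int * age_c * sync_c + eps

    with sample-centred age (years) and latent synchrony, matching the
    centring convention of the downstream regression so planted and fitted
    coefficients share a scale. RT trials are drawn Normal(mean_k, isd_k)
    per subject with occasional extreme lapse outliers; trial lists are
    returned in the ``rt_trials`` column as numpy arrays.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_SCORES]))
    age_c = truth.ages - truth.ages.mean()
    sync_c = truth.sync_true - truth.sync_true.mean()
    n = truth.n_subjects
    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{k:03d}" for k in range(n)],
            "age": truth.ages,
            "education": truth.education,
        }
    )
    reserved = {"subject_id", "age", "education", "rt_trials", "rt_mean", "rt_isd"}
    for name, effects in config.cognitive_effects.items():
        if name in reserved or not name.isidentifier():
            raise ValueError(f"invalid cognitive score name {name!r}")
        if len(effects) != 4:
            raise ValueError(
                f"cognitive effect '{name}' must be "
                "(age_slope, sync_slope, interaction_slope, noise_sd)"
            )
        b_age, b_sync, b_int, noise_sd = effects
        table[name] = (
            b_age * age_c
            + b_sync * sync_c
            + b_int * age_c * sync_c
            + noise_sd * rng.standard_normal(n)
        )

    rt = config.rt
    sd = truth.ages.std()
    age_z = age_c / (sd if sd > 0 else 1.0)
    rt_trials = []
    for k in range(n):
        mean_k = max(rt.mean_base + rt.mean_age_slope * age_z[k], 0.15)
        isd_k = max(rt.isd_base + rt.isd_age_slope * age_z[k], 0.0)
        trials = mean_k + isd_k * rng.standard_normal(rt.n_trials)
        lapse = rng.random(rt.n_trials) < rt.trial_outlier_rate
        trials[lapse] = mean_k + rt.outlier_scale * max(isd_k, 0.05) * (
            1.0 + rng.random(lapse.sum())
        )
        rt_trials.append(np.clip(trials, 0.05, None))
    table["rt_trials"] = rt_trials
    return table


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[BoldRun], GroundTruth, pd.DataFrame]:
    """Generate the full cohort: BOLD runs, ground truth, covariate table."""
    truth = simulate_truth(config)
    runs = [generate_subject_bold(truth, config, k) for k in range(config.n_subjects)]
    table = generate_cognitive_scores(truth, config)
    return runs, truth, table
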
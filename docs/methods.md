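# Methods

## Data model and generator

The simulator emulates the generative structure that a multi-subject
(tensor-style) decomposition of movie-watching fMRI assumes. Subject *k*'s
run on a small 3D grid is

    X_k(t, v) = B + Σ_i c_ki · t_i(t) · m_i(v) + ε_k(t, v) + d_k(t, v) + spikes

- `B = 100` — constant scanner baseline (arbitrary units).
- `m_i` — network maps: unit-peak 3D Gaussian blobs (σ = grid/10 voxels,
  minimum 1) placed by farthest-point sampling with centres snapped to
  voxels; placement is retried until all pairwise spatial correlations are
  |r| < 0.3. This is the simplest compact, non-Gaussian-amplitude map that
  spatial ICA can separate.
- `t_i` — shared stimulus-locked timecourses: random on/off "scene" blocks
  (exponential on/off durations, mean 8 s, clipped to [1, 30] s and
  [2, 40] s) convolved with the canonical double-gamma HRF and z-scored.
  The HRF uses the standard shape (response gamma peaking 5 s after onset,
  undershoot gamma at 15 s, undershoot ratio 1/6, 32 s support), sampled on
  a 16× oversampled grid before decimation to the TR.
- `c_ki` — coupling: `intercept + slope · age_z + N(0, coupling_noise_sd)`,
  clipped at 0, with age standardized within the sample. Defaults
  (intercept 1.0, slope −0.3, noise 0.15) plant a strong cohort-level
  decline of stimulus coupling with age across all networks.
- `ε_k` — AR(1) noise per voxel (ρ = 0.3, stationary SD `noise_sd` = 1.0),
  spatially independent. Spatial noise correlation is deliberately omitted:
  it is the simplest structure that still exercises every estimator.
- `d_k` — slow drift: one cosine cycle over the run with an independent
  random phase per voxel, amplitude 1.0.
- spikes — with per-frame probability 0.01 (+0.005 per age SD), half of the
  voxels in the frame receive additive offsets of 8–20 × `noise_sd` with
  random sign; spiked frame indices are recorded in the ground truth.

Ages are uniform on 18–88 years; education is an ordinal 1–5 level drawn
independently of coupling (it enters the analysis only as a covariate).
TR defaults to 2.47 s. The default desk-scale cohort is 24 subjects,
200 frames, 16×16×12 voxels.

Latent synchrony is defined as `sync_k = mean_i c_ki / sqrt(c_ki² + 1)` —
the expected correlation of a coupled signal with the shared timecourse at
unit effective noise. Cognitive scores follow

    score = β_age·age_c + β_sync·sync_c + β_int·age_c·sync_c + N(0, σ)

with *sample-centred* age and synchrony, so planted coefficients live on
the same scale as the (centred) fitted ones. Defaults mirror typical
aging-cohort effect sizes: fluid-style score (β_age −0.23 per year,
β_int +0.55, σ = 4) and crystallized-style score (β_age +0.08, no
interaction, σ = 5). RT trials are Normal(mean_k, isd_k) per subject
(66 trials; mean 0.55 s + 0.08 s per age SD; ISD 0.10 s + 0.03 s per age
SD) with 2% extreme lapse outliers ≥ 6 ISDs above the mean, which the 3-SD
trimming rule is designed to remove.

Determinism: every artifact derives from `numpy.random.SeedSequence`
substreams of a single integer seed, so identical (config, seed) pairs
reproduce all outputs bit-exactly regardless of generation order.

What the generator does **not** emulate: anatomy and registration error,
physiological (cardiac/respiratory) noise, spatially correlated noise,
multi-echo acquisition, and hemodynamic variability across subjects.
Passing recovery tests therefore show the estimators are correct under the
assumed generative model, not that real data meet those assumptions.

## Preprocessing and QC

- **Spike detection** is a surrogate for published wavelet-despiking tools,
  which is sufficient because only the frame×voxel flags, the run-level
  spike percentage, and the exclusion rule feed the analysis. Two
  detectors are unioned per voxel: (1) a robust frame-local score
  `|x_t − (x_{t−1}+x_{t+1})/2|` thresholded at k × MAD-based scale
  (exact-frame sensitivity for isolated spikes), and (2) for run lengths
  divisible by `2^level` (level ≤ 4), stationary Daubechies-4 wavelet
  detail coefficients thresholded at k × MAD per band (chains of outlying
  coefficients catch prolonged events). Default k = 5 keeps the false-flag
  rate on clean AR(1) data well under 1%.
- **Despiking** replaces flagged samples by linear temporal interpolation
  between clean neighbours (nearest clean value at the run edges); frame
  count is preserved. A voxel with every frame flagged is left unchanged
  with a warning.
- **Spike percentage** = mean over frames of the percent of voxels flagged;
  subjects above mean + 3 sample-SD across the cohort are excluded. Note
  the rule needs n ≥ 11 to be able to flag a single extreme subject, since
  the largest attainable z with one outlier is (n−1)/√n.
- **High-pass (100 s)** is residualization on a drift basis: constant,
  linear term, and discrete cosines with periods longer than the cutoff —
  the explicit equivalent of a Gaussian-weighted running-line detrend (the
  linear term makes straight-line removal exact; the equivalence to the
  running-line filter is approximate near the cutoff).
- **Smoothing**: per-frame 3D Gaussian, σ = FWHM/(2√(2 ln 2)) per axis in
  mm, with the kernel renormalized inside the brain mask so that
  out-of-mask voxels carry no weight.
- **Motion**: RMS volume-to-volume displacement from rigid-body parameters,
  rotations converted to arc length at a 50 mm head radius (the common
  convention).

## Group decomposition

Because a movie imposes a shared timecourse, the full trilinear tensor
decomposition is replaced by an equivalent two-step estimator with the same
output contract (maps, shared timecourses, subject loadings):

1. Each subject's series is demeaned per voxel and divided by its global
   SD; the subject-average matrix is decomposed by spatial FastICA
   (fixed-point logcosh contrast, symmetric decorrelation, tolerance 1e-5,
   max 500 iterations). Five seeded restarts are run by default and the
   solution with the highest summed logcosh-negentropy objective is kept;
   non-convergence returns the best iterate and is flagged.
   Global-SD normalization makes maps and timecourses exactly invariant to
   rescaling any single subject's data.
2. Subject loadings are the scalar least-squares fit of each subject's
   (un-normalized, demeaned) data onto each component's timecourse⊗map
   outer product, so loadings scale linearly with the subject's data.

Maps are z-scaled and sign-fixed to nonnegative skewness; timecourses have
unit variance; components are ordered by explained variance. Loadings are
signed (the nonnegative-skew map convention resolves the sign
indeterminacy). Model order, when requested, maximizes Minka's
Laplace-approximated PPCA evidence computed from the eigenspectrum of the
subject-average time×time covariance (voxels as observations).

Component selection keeps the k (default 10) components with the highest
median loading across subjects, ties stable by original order. Template
matching labels each map by its most correlated template, with a minimum
correlation of 0.25 (below which a component is "unmatched"). Timecourse
clustering uses average-linkage hierarchical clustering on distance 1 − r,
cut at the silhouette-maximizing number of clusters (2-component edge case:
one cluster if r > 0, else two); this concrete choice stands in for
otherwise unspecified neighbor-based groupings.

## Dual regression and synchrony

Both regression stages include an explicit intercept (equivalent to
demeaning, but explicit). Stage-2 timecourses are variance-normalized with
the n−1 sample SD. Rank-deficient designs are rejected with the condition
number (threshold 1e8).

Temporal synchrony always uses the leave-one-out group mean — the subject
being scored is never part of the reference — at both the component level
(stage-1 dual-regression timecourses) and the ROI level (parcellation mean
timecourses); a flag allows the self-inclusive mean for comparison. The
identity `mean_all = ((n−1)·loo_k + row_k)/n` holds exactly and is tested.
Correlations are Fisher-z transformed with |r| clipped at 1 − 1e−7.
Undefined correlations (zero variance) propagate as missing; a subject with
any missing selected-component correlation has no synchronization score
(explicit error rather than silent skipping).

## Inference

- **RT trimming** is single-pass (not iterated): trials beyond 3 SDs of the
  subject's own mean are removed once, then mean and intraindividual SD are
  recomputed on the survivors.
- **Partial correlation** is the Pearson correlation of OLS residuals
  against the covariates (+intercept); t-based p with df = n − 2 − #cov;
  the CI is the Fisher-z normal approximation. A percentile bootstrap over
  subjects (default 1000 resamples, seeded) is available for any statistic;
  undefined resamples are redrawn up to a 10× budget.
- **ROI age maps** report per-ROI partial r, t, and p with two flags:
  uncorrected (p < 0.001 by default) and Bonferroni (p < α/m, m = ROI
  count).
- **Group contrasts** (younger < 50 vs older > 65 years, middle band
  excluded) fit `z ~ group + covariates` per ROI and report the group
  coefficient — the standard realization of a covariate-adjusted two-sample
  t test. When used in the pipeline, each subject's synchrony should be
  computed against their own group's leave-one-out mean first.
- **Cognition models** regress a score on mean-centred age, mean-centred
  synchronization, their product, education, and — for RT outcomes — the
  companion RT measure as a covariate. Centring stabilizes main-effect
  interpretation and leaves the interaction t unchanged (tested). Missing
  data are handled by listwise deletion per model. Education enters as a
  single ordinal covariate.

## Validation experiment sizes

The standing experiments (shared by the test suite and
`scripts/acceptance.py`) use desk-scale problem sizes chosen to make each
property measurable in seconds to minutes:

- oracle equivalence: 50 random instances, 25 frames × 40 voxels × 3
  components, n = 20 subjects; agreement required at 1e-8.
- decomposition recovery: 20 subjects, 200 frames, 10×10×8 grid, 3
  networks, noise SD 0.3 with drift and spikes disabled (the estimator is
  tested in isolation; drift removal is the high-pass filter's job and is
  tested separately, since filtering also removes genuine slow stimulus
  power from the reference timecourses).
- age→synchrony detection: 100 cohorts of 60 subjects × 300 frames on an
  8×8×6 grid with the full nuisance structure and despike + high-pass
  preprocessing, 2 ICA restarts per cohort.
- interaction recovery: 100 cohorts of 200 subjects (covariates only).
- null calibration: 200 null cohorts, 60 subjects × 100 ROIs.
- bootstrap coverage: 500 simulations, n = 100, true r = 0.5, 1000
  resamples each.

## Known limitations

- The decomposition assumes one shared timecourse per network; it does not
  model subject-specific temporal lags or hemodynamic variability.
- The high-pass filter attenuates genuine stimulus power at periods beyond
  the cutoff, which slightly lowers timecourse-recovery correlations on
  strongly low-frequency stimuli.
- The spike detector is calibrated for isolated and short-chain artifacts;
  slow spin-history-like artifacts longer than the coarsest wavelet band
  are treated as drift.
- The Laplace model-order estimator assumes isotropic residual noise and
  will overestimate the order under strong temporally structured noise
  (e.g. unremoved drift); run it on filtered data.
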
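# Methods

## Stimulus model

Each configuration block is 56 volumes at TR 2.1 s (117.6 s). The three
main configurations run an ascending 20-state progression (50→1000 ms in
50 ms steps, one state per TR), a 16.8 s baseline, the descending
progression, and a second 16.8 s baseline. Baseline states use 2000 ms
durations and/or 2100 ms periods (the configuration's fixed parameter is
kept fixed, so the constant-duration baseline is 50 ms / 2100 ms). The
gaps configuration runs four 10-state progressions that co-vary duration
and period — (50→500 ms, 950→500 ms), (50→500, 550→1000), (500→50,
500→950), (500→50, 1000→550) — separated by 6.3 s baselines and ending
with a 14.7 s baseline. A run concatenates the four blocks (470.4 s); all
24 block orders exist.

Event times live on a 50 ms grid (the display's 20 frames/s update) and
are computed in integer ticks, so all schedule arithmetic is exact. Within
a state, events repeat at the state's period. Because periods are not
generally divisors of the TR, the timing state advances at the event onset
nearest each nominal TR boundary. This rule bounds the deviation of every
realized change time by half the current period and accumulates no
systematic drift; the exact alignment rule used in the original experiment
is not documented, so nearest-onset alignment is this package's choice.
Both nominal and realized change times are stored, and all analyses use
the realized (presented) event times.

## Response models and units

Per-event amplitudes are as given in the README. Design choices where the
formulation was open:

- **Frequency scaling.** The compressive exponent enters as a per-event
  multiplier F^(exp_freq−1) (F = 1/period). Summed over one second this
  makes the response ∝ F^exp_freq, which uniquely reproduces the defining
  behaviour (10× at exponent 1, flat at exponent 0). The constant and
  linear-monotonic families fix exp_freq = 1, so their accumulated
  responses grow linearly with event frequency, and the linear family's
  duration term accumulates into an occupancy (mean-luminance) response.
- **Log-scale models** take the natural log of both axes of the chosen
  timing space; preferences and extents are then in log-units. In
  vectorized fitting, axis values are floored at 0.025 (half the event
  grid) before the log so that zero inter-event intervals stay finite; the
  scalar API raises instead.
- **Extents** are reported as Gaussian standard deviations (σ), not FWHM.
- **Temporal-frequency control model.** The display luminance is a binary
  on/off trace at 20 Hz. Power spectra are plain discrete Fourier
  transforms without taper. The per-TR variant scores one 42-sample window
  per volume; the per-event variant scores the one-period window ending at
  each event offset (window length = that event's period, the natural
  cycle), optionally frequency-scaled.

## Hemodynamic forward model

Neural impulses at event offsets are convolved with a difference-of-gammas
HRF (peak delay 6 s, undershoot delay 16 s, dispersions 1 s, undershoot
ratio 1/6 — conventional defaults; the source protocol fits subject-specific
HRFs with an unpublished parameterization). The convolved series is
averaged within each TR window, because volume acquisition integrates over
the TR, and demeaned. Predictions are scored by squared Pearson correlation
(variance explained, VE), which absorbs gain and offset; zero-variance
series score 0. A simplified subject-level HRF fit is provided: a grid
search over peak delay (4–8 s in 0.5 s steps) and undershoot ratio at fixed
neural parameters, maximizing summed VE over well-fit sites, after which
neural models are re-fit. Because every progression is presented in both
directions, a mis-set HRF delay biases extents but not preferred timings;
this symmetry is verified in the tests.

## Fitting

Coarse-to-fine: an exhaustive deterministic grid search (ties broken by
first grid entry) followed by Nelder–Mead simplex refinement from the top
3 grid points (max 200 iterations, parameter tolerance 1e-4). Grid
densities per family: dense lattices for families with ≤ 4 parameters
(preferences 0.025–1.2 s in 25 ms steps for the 1-D model, 12 log-spaced
extents 0.05–3 s, exponents in 0.1 steps); the 2-D families use coarser
lattices (preferences 0.05–1.15 s in 0.1 s steps, 6 extent levels with
ordered major/minor pairs, 4 orientations, exponents in 0.2 steps) that
refinement then polishes — the full dense cross for the 6-parameter
anisotropic family would exceed 10^8 combinations. Preference grids extend
beyond the presented 0.05–1.0 s range so that out-of-range optima exist;
sites whose fitted preferred duration or period falls outside the range,
or whose full-fit VE is below 0.10, are flagged excluded. Anisotropic fits
are canonicalized to σ_maj ≥ σ_min (swapping rotates θ by π/2; θ reported
in [0, π)).

Grid predictions are linear in per-event impulse heights, so each event
contributes a fixed HRF-convolved, TR-averaged regressor; predictions for
the whole grid are a single matrix product shared across sites, which is
what makes the study-scale simulations below cheap.

Cross-validation fits on the odd-run average and scores on the even-run
average and vice versa; the reported cv VE is their mean. Model comparison
averages cv VE per map (or subject) over sites whose best model reaches
20% cv VE, then runs paired t-tests of the best model against each other.
Comparison uses grid-level fits (no simplex polish): rankings are
insensitive to sub-grid refinement and this keeps 25-model-by-2000-site
comparisons to minutes. An empirical null converts VE to a chance
probability as the proportion of noise-only ("white-matter-like") site
fits at or above the observed VE.

## Synthetic data

The generators emulate the study conditions: full forward-modelled
timecourses per run with additive white Gaussian noise (AR(1) optional as
a stress test), averaged over runs and over the odd/even split. Defaults:
4 runs (a desk-scale stand-in for the original 24; only the averaged-data
signal-to-noise matters for the analyses, and it is set directly by the
calibration below). Predictions are normalized to unit standard deviation,
so expected VE after averaging R runs is 1/(1 + noise_sd²/R);
`calibrate_noise_sd` inverts this, and the default target VE 0.3 matches
the fitted VE regime reported for cortical data. Map strips place sites
uniformly along a 20 mm coordinate with preferred duration following
a + b·ln(x + 1 mm) (or a linear law) spanning 0.1–0.9 s; preferred period
is the duration plus a positive offset ~ N(0.10 s, 0.05 s) truncated at
zero, echoing the observed coupling of duration and period preferences
without targeting any reported mean. Major extents grow linearly with
preferred duration (default), follow a V shape around 0.5 s, or stay
constant; aspect ratio 2 with a diagonal (π/4) orientation. Everything is
reproducible from the seed.

What the generators do *not* emulate: 2-D cortical geometry, spatially
correlated (draining-vein) noise, physiological confounds, attention, and
adaptation beyond the design's counterbalancing. Passing tests therefore
demonstrate correctness and statistical calibration of the pipeline, not
empirical claims about cortex.

## Topography and between-map statistics

Map position is d_low/(d_low + d_high) × mean map length. Preferences are
binned every 2 mm; bins whose represented surface is below one functional
voxel (1.77 mm²; 2 mm² optionally, the 7T point-spread bound) are
excluded. Progressions are fit as value = a + b·ln(distance + ε) with
ε = half the bin width (admits the 0 mm bin; the original offset is
unstated), bootstrapping bins with replacement (default 1000 resamples);
the median slope/intercept is reported with 2.5/97.5 percentile CIs. The
log regressor is averaged within bins exactly like the response, so
noiseless maps are recovered without binning bias. Significance of
progressions uses Pearson correlations on raw sites (not bins) with
degrees of freedom divided by the surface-upsampling factor and
Benjamini–Hochberg FDR across all map × subject tests; split-half
repeatability correlates odd- and even-run preferences the same way.

The extent GLM splits sites at 0.5 s (the middle of the presented range),
repeatedly subsamples the larger side to balance counts (1000
permutations), fits extent ~ preferred duration + |preference − 0.5| +
constant, and averages t statistics across permutations; p values use the
fixed balanced n with upsampling correction. ROI definition sweeps VE
thresholds, counts connected components on the supplied adjacency graph,
and thresholds at the bottom of the widest interval with a stable cluster
count (the knee).

Map summaries average fit properties over non-excluded sites (circular
mean with period π for orientation; IQR as the 75th − 25th percentile).
Between-map comparisons are main-effects-only ANOVAs (hemisphere, map,
subject) with Type-II sums of squares for unbalanced designs; when the
hemisphere effect is not significant (p ≥ 0.05) the model is refit without
it. Map differences are localized with population marginal means (95% CIs
from the fit covariance over a balanced grid of the other factors) and
Tukey-style HSD pairwise tests via the studentized range.

## Problem sizes and numerical choices

Study-scale checks in the tests and acceptance script use: 100 sites for
parameter recovery; 20 maps × 20 sites per generating family (5 families)
for model selection; 200 maps × 60 sites for bootstrap-coverage
calibration; 2 × 10³ noise sites for the empirical null. These sizes give
stable rates while keeping the whole suite to a few minutes. Ties in the
grid are impossible to observe in float scoring but are defined
deterministically; cv VE may be stored raw and floored at 0 only for
reporting; all stochastic steps take explicit seeds, and fitting itself is
fully deterministic.

## Known limitations

- Parameter recovery at the realistic noise level (median fitted VE ≈ 0.3
  on run-averaged data) is information-limited for the 6-parameter
  anisotropic model: the likelihood has a ridge along the major axis
  (duration and period preferences trade off, especially for diagonal
  orientations), and the frequency exponent is weakly identified for
  narrowly duration-tuned sites, whose responses in the frequency-sweeping
  constant-duration configuration are suppressed. Refinement started at
  the true parameters does no better, so this is a property of the
  stimulus/SNR, not the optimizer. Median absolute errors at that SNR are
  ~0.1 s for preferences and ~0.3 for the exponent; split-half
  repeatability of preferences in the original cortical data is similarly
  modest.
- The temporal-frequency model's per-event window length (one period) is a
  design choice; other windows would change its (poor) fit quantitatively.
- Border distances are supplied inputs; no geodesic computation on meshes.
- ANOVA marginal means assume the main-effects model; interactions are
  deliberately not modelled.
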
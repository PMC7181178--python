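# timingprf

Timing-selective population receptive field (pRF) modelling of fMRI
responses to visual event timing.

Human association cortex contains topographic maps of *visual event timing*:
neural populations tuned to the duration of a repeating visual event (onset
to offset) and to its period (onset to next onset). Because fMRI is slow,
this selectivity cannot be read off single responses; it is estimated by
forward modelling. A stimulus presents repeating events whose duration
and/or period sweep 50–1000 ms in 50 ms steps under four configurations that
decorrelate duration, period, luminance and event frequency ("constant
luminance", "constant duration", "constant period", "gaps"; 117.6 s blocks,
470.4 s runs). A candidate neural response function is evaluated at every
event offset, scaled for sub-additive temporal summation, convolved with a
hemodynamic response function, and compared with the measured timecourse of
each recording site.

The best-supported response function is a 2-D anisotropic Gaussian over
(duration, period):

    X = (d − d_pref)·cosθ − (p − p_pref)·sinθ
    Y = (d − d_pref)·sinθ + (p − p_pref)·cosθ
    A(d, p) = exp(−½ [(Y/σ_maj)² + (X/σ_min)²]) · F^(exp_freq − 1),  F = 1/p

where (d_pref, p_pref) are the preferred duration and period, σ_maj/σ_min
the extents along the major/minor axes, θ the major-axis orientation, and
exp_freq ∈ [0,1] the compressive frequency exponent: the per-second summed
response is ∝ F^exp_freq, so it is 10× larger at 10 events/s than at
1 event/s when exp_freq = 1 and identical when exp_freq = 0. The package
also implements the competing model families (constant, linear and
compressive monotonic; 1-D duration-tuned; isotropic 2-D; temporal-frequency
tuned), three equivalent timing parameterizations (duration/period,
duration/inter-event-interval, period/occupancy) and log/linear axes.

On top of the fitting core the package provides: split-half cross-validated
model comparison, exclusion rules and an empirical null from noise-only
sites, synthetic data generators (timing-selective sites, 1-D cortical map
strips, white-matter-like noise sites), within-map topography statistics
(distance binning, bootstrap log-progression fits, upsampling-corrected
correlations with FDR, split-half repeatability, a balanced-bootstrap
extent GLM, threshold-sweep ROI clustering) and between-map summaries with
main-effects ANOVAs and Tukey-style comparisons.

No measured cortical dataset ships with the package; all analyses run on
synthetic data with known ground truth, which is what the test suite and
the acceptance script exercise.

## Worked example

Fit the anisotropic timing model to a simulated 40-site cortical map strip
and recover its duration progression:

```python
import numpy as np
from timingprf import (ModelSpec, TimingPRF, make_run, simulate_map, simulate_sites,
                       calibrate_noise_sd, timecourse_matrix, distance_along_map, bin_and_fit)

run = make_run()                      # one 470.4 s run, four configurations
smap = simulate_map(n_sites=40, seed=7, jitter_sd=0.05,
                    noise_sd=calibrate_noise_sd(0.5, 4), n_runs=4)
est = TimingPRF(spec=ModelSpec("tuned_2d_anisotropic"), schedule=run)
data = simulate_sites(smap.truth, run, design=est._design())
est.fit(timecourse_matrix(data["full"]))
print(f"median VE: {np.median(est.ve_):.3f}, excluded: {est.excluded_.sum()}/40")

g = smap.geometry.assign(
    coordinate_mm=distance_along_map(smap.geometry.d_low_mm, smap.geometry.d_high_mm, 20.0),
    preferred_duration=est.derived_.preferred_duration,
    preferred_period=est.derived_.preferred_period,
)[~est.excluded_]
bins, fits = bin_and_fit(g, n_boot=1000, seed=0, upsampling=4.0)
pf = fits["preferred_duration"]
print(f"duration progression slope: {pf.slope:.3f} s per log-mm "
      f"(95% CI {pf.slope_ci[0]:.3f}..{pf.slope_ci[1]:.3f}; generating {smap.slope:.3f})")
```

Output:

```
median VE: 0.511, excluded: 8/40
duration progression slope: 0.250 s per log-mm (95% CI 0.160..0.283; generating 0.263)
```

The median variance explained matches the calibrated noise level (target
0.5); 8 sites whose fitted preferences left the presented 0.05–1.0 s range
(or fit below 10% VE) are excluded; and the bootstrap confidence interval
of the recovered logarithmic progression slope covers the generating slope.

A `timingprf` command-line tool wraps the same functionality
(`timingprf simulate schedule|map|noise`, `timingprf fit`,
`timingprf compare`, `timingprf run-all`).

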
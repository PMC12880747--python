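# Methods

This note documents the models, the synthetic-data generator, and the
numerical and design choices behind `sceneenc`.

## The analysis in one paragraph

Each voxel's response to a scene image is modeled as a linear function
of stimulus features: a 300-feature static Gabor-wavelet pyramid
("2D" model), and two scene-surface models built from ground-truth
depth and surface-normal maps — a 27-feature whole-image model
(3D-global) and a 108-feature per-quadrant model (3D-quadrant).  Models
are fit voxelwise with ridge regression under nested run-wise
cross-validation, evaluated as the Pearson correlation between
predictions and held-out trials (averaged over folds, then over ROI
voxels), and compared by variance partitioning of a
concatenated-feature model.  Group significance comes from permutation
tests on the fold-averaged statistic; noise ceilings come from repeated
stimulus presentations.

## Feature models

### Gabor-wavelet pyramid (300 features)

Five spatial-frequency levels at 0, 2, 4, 8 and 16 cycles/image.  The
published description of this model family fixes the frequency and
orientation sets and the principle that higher frequencies tile the
image with smaller tiles, but not the exact tiling that yields 300
features.  Our default: the zero-frequency level is a 2x2 grid of
Gaussian local-luminance features (4 features), and the non-zero levels
use grids of 2, 3, 5 and 6 tiles per side with 4 orientations
(0/45/90/135 degrees), giving 4 + 4*(4+9+25+36) = 300.  The grid sizes
are configurable; this default is our documented stand-in, chosen for
monotone grid growth and the exact count.

Each non-zero-frequency feature is the quadrature energy
`sqrt(even^2 + odd^2)` of windowed inner products with an even/odd
Gabor pair (Gaussian envelope sigma = tile/4, wavelength =
image_extent/frequency, kernels forced exactly zero-mean and L2
normalized), passed through `log(1+E)` — a standard compressive
nonlinearity for energy models; raw magnitude is available by
configuration.  Energy features are non-negative pre-z-scoring and
invariant to contrast inversion.  Images are luminance in [0, 1]; the
per-image mean is *not* removed, because the zero-frequency channel is
meant to carry it.

### Scene-surface models (27 / 108 features)

Pixels are binned jointly by Euclidean distance and surface direction.

* **Distance**: 3 bins whose 2 interior edges are the pooled 1/3 and
  2/3 quantiles of all valid depths across the stimulus set (fit once
  per set, not per image; a seeded uniform subsample caps the pixel
  count).  Each bin is therefore roughly equally represented across
  images by construction.
* **Direction**: 9 total bins.  A normal is *forward* iff its angle to
  the viewing axis (+z, camera frame: x right, y up, z toward viewer)
  is at most 45 degrees; otherwise the azimuth of its (x, y) projection
  falls into one of eight 45-degree sectors centered on the compass
  directions (up = +y).  The bin names fix the partition but not its
  boundaries; the 45-degree cone and equal sectors are the symmetric,
  least-informative choice and are configurable in principle via the
  classifier.  Ties at exactly 45 degrees go to forward; azimuth sector
  boundaries are closed on the counterclockwise side (enforced with a
  1e-12-sector epsilon so exact boundary angles are stable under
  floating point).

The global model is the 27-vector of joint-bin proportions over all
valid pixels.  The quadrant model splits the image at floor(H/2),
floor(W/2) (boundary row/column to the bottom/right quadrant) and
computes the same 27 proportions **per quadrant**, normalized per
quadrant rather than per image, so quadrant features are insensitive to
valid-pixel imbalance across quadrants.  (Per-image normalization is a
plausible alternative; per-quadrant was chosen and is a documented
divergence risk.)  Invalid pixels — the synthetic analogue of
depth-sensor holes and missing sky — are excluded from numerator and
denominator everywhere; an all-invalid quadrant yields a flagged zero
block.  A weighted average of quadrant blocks by valid-pixel counts
reproduces the global vector exactly, which the tests assert.

## Stimulus selection

Feature RDMs use cosine distance between raw (pre-z-scoring) feature
rows — selection precedes model fitting, so z-scoring state does not
exist yet.  "RDM correlation" is Pearson over the strictly-upper
triangle (Spearman by option).  The search:

1. **Prefilter** — rank pool images by the variance of mean valid depth
   across the four quadrants, keep the top fraction (default 50%).
2. **Initial phase** — best of `n_iters` random subsets by the
   3D-global vs 3D-quadrant RDM correlation.
3. **Greedy phase** — one pass over the selected slots in fixed order;
   for each, sample candidates without replacement from the unselected
   pool (default 1000), accept the best strict improvement
   (keep-current wins ties).  The objective trace is non-increasing by
   construction and is asserted on every run.  Multiple passes are
   available behind a flag.

The Gabor-vs-3D RDM correlations are monitored and reported but never
optimized.

## Encoding models

* Voxel TR timeseries are z-scored within run; trials are epoched at
  stimulus onset (12 TRs at TR 0.8 s) and averaged over the 2.4-4.8 s
  window (samples at t = 2.4, 3.2, 4.0, 4.8 s).
* Ridge penalties: 0 plus 12 values uniform in log10 on [1e-2, 1e5],
  endpoints inclusive (an endpoints-exclusive reading would differ;
  inclusive was chosen and documented).
* Outer folds: 9, assigned by dealing each task's ordered runs
  round-robin, so each fold holds out 4 of 36 runs (two per task) in
  the task-collapsed design, or 2 of 18 runs in single-task mode.
* Inner folds: 10, split **by run** (never by trial) to avoid leakage
  between temporally adjacent trials of a run.  The inner selection
  statistic is squared Pearson correlation of inner held-out
  predictions (a 1 - SSE/SST variant is available by config); the
  penalty maximizing the mean inner score wins, ties to the smaller
  penalty.  If a training set has fewer runs than inner folds, the
  inner fold count is reduced with a warning.
* The solver is SVD-based; at lambda = 0 it returns the minimum-norm
  least-squares solution, well defined when features outnumber trials.
* Performance is Pearson r between predictions and held-out data per
  fold, averaged across folds first and across ROI voxels second.  The
  averaging order is part of the definition and regression-tested.

## Variance partitioning and inference

With `R2 := sign(r) * r^2` (sign-preserving squaring, so
negative-performance voxels do not inflate components — the variance
transform was an open choice and this is ours):

    unique_A = R2_AB - R2_B,  unique_B = R2_AB - R2_A,
    shared   = R2_A + R2_B - R2_AB

with no clamping.  The combined model AB concatenates the two z-scored
feature sets and is fit with a single penalty selected by the same
nested CV (a per-set penalty would be a banded model, which is out of
scope).  A practical consequence, visible in the validation
experiments: adding a useless second feature set costs a little
held-out performance, so the "wrong" model's unique component tends to
be slightly *negative*, consistently across subjects.  Inferentially we
therefore treat "evidence for unique information" as a two-tailed
p < alpha **with a positive group mean**, matching how starred effects
in this analysis family are reported.

Permutation inference shuffles each outer fold's held-out trials
relative to the predictions — one shuffle per fold per permutation,
shared across all voxels of the ROI and across models, preserving
inter-voxel correlation and the coherence of partition components under
the null.  Per permutation this yields a fold-then-voxel-averaged ROI
value per subject; the group test compares the observed across-subject
one-sample t to the null t distribution built from matching permutation
columns: `p = 2 * min(#{null >= obs}+1, #{null <= obs}+1) / (n_perm+1)`,
capped at 1, with no symmetry assumption.  Degenerate zero
between-subject variance maps to t = +/-inf rather than 0.

Noise ceilings: per voxel, `sigma2_noise` is the mean over stimuli of
the sample variance across repeats; `sigma2_signal = max(0, total -
noise)`; `ncsnr = sigma_signal/sigma_noise`; `NC = ncsnr^2 / (ncsnr^2 +
1/m)` with m = 1 because predictions here are single-trial, not
repeat-averaged.  Significance permutes stimulus labels (2000 draws by
default).  Rescaling divides correlations by sqrt(NC) and variance
components by NC.

ROI selection ranks candidate voxels by localizer statistic (ties to
the lower index), removes exclusion masks first, optionally requires a
significant noise ceiling, caps at 200 voxels and drops ROIs under 75.
Robustness utilities re-run the analysis over ten 3-TR sliding windows
(a 12-TR epoch admits exactly 10) and over cumulative voxel counts.

## The synthetic-data generator

Scenes are piecewise-planar "indoor" layouts: each spec lists planes
with a direction label, a rectangular image region (every pixel covered
exactly once, validated), a near/far distance range interpolated
linearly along the direction the plane recedes, and a texture band.
Non-frontoparallel normals are tipped toward the viewer by a tilt
below 45 degrees, preserving their direction label under
classification.  Luminance is Lambertian-style shading from a fixed
light direction (correlating image intensity with geometry, as in real
scenes) plus band-limited noise texture.  Geometry (depth, normals, and
the invalid-pixel mask emulating sensor holes; default 5% invalid)
depends only on the spec; the per-call seed drives texture alone, so
identical specs rendered with different seeds give identical surface
features but different Gabor features.

Trial responses: for each voxel, amplitude = (z-scored features of its
population's model) . weights + N(0, noise_sd).  Random weights are
rescaled so the realized signal SD over the stimulus set equals
`weight_scale` exactly, making analytic signal fractions available to
tests.  The amplitude is injected through a raised-cosine temporal
profile centered at 3.6 s (half-width 2.4 s), normalized to mean 1 over
the 2.4-4.8 s window, with independent TR noise of the same SD across
the epoch; there is no hemodynamic convolution because the analysis
consumes window-averaged epoched data, and the profile gives
sliding-window analyses a peak to find.  The window-averaged noise
variance is `noise_sd^2 * (1 + 1/4)` at the default window, inverted by
`noise_sd_for_signal_fraction` when a target noise ceiling is
requested.

Defaults mirror the emulated design: 36 runs alternating two tasks, TR
0.8 s, 12-TR epochs, 300 stimuli.  The per-stimulus repeat count was
not published beyond "fewer than ~5"; the default is 3 (and 300 x 3 =
900 trials divide evenly into 36 runs of 25), configurable.  Localizer
statistics are N(effect, 1) for signal populations vs N(0, 1) for null.

What the generator does **not** emulate: hemodynamic dynamics and their
variability, temporal autocorrelation of noise, spatial voxel
correlation, eye movements, attention/task effects, photorealistic
image statistics.  Passing tests therefore demonstrate that the
analysis chain recovers structure it is designed for under its own
assumptions — not that it would behave identically on real fMRI data.

## Validation experiments and problem sizes

* **Parameter recovery** (`validation.run_parameter_recovery`): 8
  subjects per replicate, each with 100 Gabor-coded and 100
  3D-global-coded voxels at noise ceiling 0.2; 300 stimuli at 64x64,
  36 runs, 3 repeats, 500 permutations; 10 replicates sharing one
  rendered stimulus set.  Success = significantly positive unique
  variance for each ROI's coding model and not for the other model.
* **Calibration**: 200 all-null replicates (8 subjects, 9 folds, 25
  test trials, 20 voxels, 500 permutations); rejection rate at
  alpha = 0.05 should sit in the binomial 95% band.
* **Noise-ceiling recovery**: signal fraction 0.5, 300 stimuli x 3
  repeats; the estimate should land within 0.05 of 0.5.
* Stimulus-selection improvement is demonstrated on 40-60-image pools
  with 12-20 targets; the production-scale search (300 of ~679k
  images) is the same code at larger settings.

These sizes were chosen so the full suite and the acceptance script
each run comfortably on a single CPU.

## Known limitations

* The exact 300-feature Gabor tiling and the original quadrant
  normalization are stand-ins for undocumented details (see above).
* The combined model uses one shared ridge penalty; banded ridge might
  recover slightly different partitions.
* Permutations shuffle each fold independently; jointly shuffling all
  test trials is a plausible alternative reading.
* The selection search's initial "plateau" stopping rule is replaced by
  a fixed iteration count.
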
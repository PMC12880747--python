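# sceneenc

Voxelwise encoding-model analysis comparing a **2D Gabor-wavelet
baseline model** against **3D scene-surface models** in simulated
scene-responsive cortex — the full chain of feature extraction,
RDM-based stimulus-set decorrelation, nested cross-validated ridge
regression, variance partitioning, permutation inference and noise
ceilings, driven end-to-end by a synthetic scene/fMRI generator so that
every stage is testable against known ground truth.

## Who this is for

Researchers who want to (a) run or scrutinize this model-comparison
analysis without access to the original fMRI data, (b) validate its
statistical behavior (type-I error, parameter recovery, noise-ceiling
estimation) on simulated cohorts, or (c) reuse the individual pieces —
the Gabor pyramid, surface-bin features, the greedy RDM decorrelation
search, or the nested-CV ridge machinery.

## The models and the statistic

For each voxel *v* and stimulus *s*, the response (window-averaged
2.4–4.8 s post-onset) is modeled as

    y_v(s) = x(s) · w_v + ε,

where `x(s)` is one of three z-scored feature vectors:

* **Gabor** — 300 quadrature-energy features of a static Gabor-wavelet
  pyramid: 5 spatial frequencies (0, 2, 4, 8, 16 cycles/image) × 4
  orientations (0°, 45°, 90°, 135°) on frequency-dependent tile grids;
* **3D-global** — 27 proportions of image pixels over 3 distance bins
  (pooled-quantile edges) × 9 surface-direction bins (forward + 8
  compass directions of the surface normal);
* **3D-quadrant** — the same 27 proportions per image quadrant
  (108 features, per-quadrant normalized).

Weights are fit by ridge regression, `ŵ = argmin ‖y − Xw‖² + λ‖w‖²`,
with λ chosen from a 13-value grid (0 and 12 log-spaced values in
[10⁻², 10⁵]) by 10 inner run-wise folds nested in 9 outer folds.
Performance is the Pearson *r* between predictions and held-out data,
averaged over folds and then over ROI voxels.  Model comparison uses
variance partitioning with sign-preserving R² = sign(r)·r²:

    unique_A = R²_AB − R²_B,   unique_B = R²_AB − R²_A,
    shared   = R²_A + R²_B − R²_AB,

and group significance comes from permutation tests that shuffle each
fold's held-out trials, rebuild the ROI statistic, and compare the
across-subject t to its permutation null.  See `docs/methods.md` for
every convention and default.

## Worked example

Simulate a small cohort of 4 subjects, each with 40 voxels coded by the
Gabor model and 40 coded by the 3D-global model, and run the whole
pipeline:

```python
from sceneenc.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    out_dir="demo", seed=1, n_images=30,
    design={"n_runs": 6, "repeats_per_stimulus": 2},
    ridge={"n_outer_folds": 3, "n_inner_folds": 3},
    inference={"n_subjects": 4, "n_perm": 500, "roi_min": 1},
    populations=[
        {"n_voxels": 40, "label": "gabor-coded", "noise_sd": 1.5},
        {"n_voxels": 40, "label": "3d-global-coded", "noise_sd": 1.5},
    ],
)
out = run_pipeline(cfg)  # writes stimuli/, features/, encoding/, report.csv ...
```

Mean cross-validated *r* per ROI and model (`report.csv`, averaged over
subjects) from this exact run:

```
roi              model
3d-global-coded  3d-global            0.287
                 gabor                0.174
gabor-coded      3d-global            0.129
                 gabor                0.242
```

Each simulated population is predicted best by its own generating model
(0.287 vs 0.174 in the 3D-coded ROI; 0.242 vs 0.129 in the Gabor-coded
ROI), with nonzero cross-model performance reflecting the natural
covariation between image texture and scene geometry.  The accompanying
`group_pvalues.json` puts every model's performance above its
permutation null at the minimum attainable p = 2/(500+1) ≈ 0.004 for
this strong-signal demo.

The CLI mirrors the library (`sceneenc run -c config.yaml`, plus
per-stage subcommands `synth`, `features-gabor`, `features-3d`,
`select-stimuli`, `encode`, `partition`, `infer`, `report`, `sweep`,
`windows`).

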
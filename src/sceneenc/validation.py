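"""Ground-truth validation experiments for the full analysis chain.

These experiments run the package end-to-end on synthetic cohorts whose
generative structure is known, and ask whether the analysis recovers
it:

* **Parameter recovery** — a cohort of subjects with one voxel
  population coded by the Gabor model and one coded by the 3D-global
  model, at a realistic noise ceiling.  The variance-partitioning group
  test should find significant unique-Gabor (and non-significant
  unique-3D) variance in the Gabor-coded ROI, and the reverse in the
  3D-coded ROI.
* **Permutation calibration** — with no signal anywhere, the group
  permutation test should reject at its nominal rate.
* **Noise-ceiling recovery** — the repeat-based noise-ceiling estimator
  should recover a known simulated signal-variance fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import encoding as enc
from . import inference as inf
from .gabor import GaborBankSpec, build_gabor_bank, gabor_feature_matrix
from .surface import fit_distance_bins, surface_feature_matrix
from .synth import (
    DesignSpec,
    VoxelPopulationSpec,
    generate_stimulus_set,
    noise_sd_for_signal_fraction,
    simulate_voxel_responses,
)

__all__ = [
    "RecoveryOutcome",
    "parameter_recovery_replicate",
    "run_parameter_recovery",
    "calibration_rejection_rate",
    "noise_ceiling_recovery",
    "stimulus_selection_experiment",
]


def _pearson_columns(a, b):
    return enc._pearson_columns(a, b)


def _roi_partition_observed_and_null(results, roi_idx, a, b, n_perm, seed):
    """Observed ROI-mean partition components and their permutation nulls.

    The same per-fold shuffle is applied to all three models (A, B and
    the concatenated AB share held-out trials), so the null components
    remain algebraically coherent.
    """
    ab = f"{a}+{b}"
    part = inf.variance_partition(
        results[a].voxel_r[roi_idx],
        results[b].voxel_r[roi_idx],
        results[ab].voxel_r[roi_idx],
        model_a=a,
        model_b=b,
    )
    observed = {
        f"unique_{a}": float(part.unique_a.mean()),
        f"unique_{b}": float(part.unique_b.mean()),
        "shared": float(part.shared.mean()),
        f"r_{a}": float(results[a].voxel_r[roi_idx].mean()),
        f"r_{b}": float(results[b].voxel_r[roi_idx].mean()),
    }
    null_r = inf.permutation_null_r(
        {m: results[m] for m in (a, b, ab)}, roi_idx, n_perm=n_perm, seed=seed
    )
    R2a, R2b, R2ab = (inf.signed_r2(null_r[m]) for m in (a, b, ab))
    nulls = {
        f"unique_{a}": (R2ab - R2b).mean(axis=1),
        f"unique_{b}": (R2ab - R2a).mean(axis=1),
        "shared": (R2a + R2b - R2ab).mean(axis=1),
        f"r_{a}": null_r[a].mean(axis=1),
        f"r_{b}": null_r[b].mean(axis=1),
    }
    return observed, nulls


@dataclass
class RecoveryOutcome:
    """Group p-values for one parameter-recovery replicate."""

    p_values: dict[str, float]  # "<roi>:<component>" -> p
    success: bool
    roi_means: dict[str, float]


def parameter_recovery_replicate(
    seed: int,
    n_subjects: int = 8,
    n_voxels_per_roi: int = 100,
    n_images: int = 300,
    noise_ceiling_target: float = 0.2,
    n_perm: int = 500,
    n_runs: int = 36,
    repeats_per_stimulus: int = 3,
    resolution=(64, 64),
    alpha: float = 0.05,
    stimulus_seed: int | None = None,
    features=None,
) -> RecoveryOutcome:
    """One full parameter-recovery run of the analysis chain.

    Simulates a cohort in which every subject has ``n_voxels_per_roi``
    Gabor-coded voxels (the "scene ROI") and the same number of
    3D-global-coded voxels (the control ROI), all at the target noise
    ceiling.  All subjects share the stimulus set and trial schedule (as
    in the emulated experiment); their weights and noise are
    independent.  Success requires significant unique variance for the
    coding model and non-significant unique variance for the other
    model, in both ROIs.

    ``features`` may carry precomputed ``(gabor_fm, global_fm)`` for the
    same ``stimulus_seed`` to amortize rendering across replicates.
    """
    design = DesignSpec(n_runs=n_runs, repeats_per_stimulus=repeats_per_stimulus)
    if features is None:
        stimset = generate_stimulus_set(
            n_images, seed=stimulus_seed if stimulus_seed is not None else seed,
            resolution=resolution,
        )
        bank = build_gabor_bank(GaborBankSpec(), resolution=resolution)
        fm_gabor = gabor_feature_matrix(stimset, bank)
        bins = fit_distance_bins(stimset, seed=0)
        fm_global = surface_feature_matrix(stimset, bins, "global")
    else:
        fm_gabor, fm_global = features
    feats = {"gabor": fm_gabor, "3d-global": fm_global}

    noise_sd = noise_sd_for_signal_fraction(noise_ceiling_target, 1.0, design)
    pops = []
    for s in range(n_subjects):
        pops.append(
            VoxelPopulationSpec(
                n_voxels=n_voxels_per_roi, label="gabor-coded",
                weight_scale=1.0, noise_sd=noise_sd, weight_seed=seed * 1009 + 2 * s,
            )
        )
        pops.append(
            VoxelPopulationSpec(
                n_voxels=n_voxels_per_roi, label="3d-global-coded",
                weight_scale=1.0, noise_sd=noise_sd, weight_seed=seed * 1009 + 2 * s + 1,
            )
        )
    trials = simulate_voxel_responses(feats, pops, design, seed=seed)
    ds = enc.preprocess_trials(trials)
    plan = enc.make_folds(ds.run_id, ds.task_label)
    cfg = enc.RidgeConfig()

    Xg = feats["gabor"].zscored[trials.stimulus_idx]
    X3 = feats["3d-global"].zscored[trials.stimulus_idx]
    model_X = {"gabor": Xg, "3d-global": X3, "gabor+3d-global": np.hstack([Xg, X3])}
    results = {
        name: enc.nested_cv_predict(X, ds.y, plan, cfg, run_labels=ds.run_id,
                                    model_name=name)
        for name, X in model_X.items()
    }

    # Per-subject voxel blocks: [gabor ROI s0][3d ROI s0][gabor ROI s1]...
    per_subj = 2 * n_voxels_per_roi
    roi_blocks = {"gabor-coded": [], "3d-global-coded": []}
    for s in range(n_subjects):
        base = s * per_subj
        roi_blocks["gabor-coded"].append(np.arange(base, base + n_voxels_per_roi))
        roi_blocks["3d-global-coded"].append(
            np.arange(base + n_voxels_per_roi, base + per_subj)
        )

    p_values: dict[str, float] = {}
    roi_means: dict[str, float] = {}
    for roi_label, blocks in roi_blocks.items():
        obs_by_comp: dict[str, list[float]] = {}
        null_by_comp: dict[str, list[np.ndarray]] = {}
        for s, block in enumerate(blocks):
            observed, nulls = _roi_partition_observed_and_null(
                results, block, "gabor", "3d-global", n_perm, seed=seed * 31 + s
            )
            for comp, v in observed.items():
                obs_by_comp.setdefault(comp, []).append(v)
                null_by_comp.setdefault(comp, []).append(nulls[comp])
        for comp in obs_by_comp:
            p = inf.group_permutation_test(
                np.asarray(obs_by_comp[comp]), np.vstack(null_by_comp[comp])
            )
            p_values[f"{roi_label}:{comp}"] = p
            roi_means[f"{roi_label}:{comp}"] = float(np.mean(obs_by_comp[comp]))

    # "Significant" here means significant in the positive direction (the
    # two-tailed p below alpha with a positive group mean): evidence *for*
    # unique information.  A reliably negative unique component (the cost
    # of carrying a second model's useless features) is not evidence for
    # that model.
    def sig_pos(key: str) -> bool:
        return p_values[key] < alpha and roi_means[key] > 0

    success = (
        sig_pos("gabor-coded:unique_gabor")
        and not sig_pos("gabor-coded:unique_3d-global")
        and sig_pos("3d-global-coded:unique_3d-global")
        and not sig_pos("3d-global-coded:unique_gabor")
    )
    return RecoveryOutcome(p_values=p_values, success=success, roi_means=roi_means)


def run_parameter_recovery(n_replicates: int = 10, seed: int = 0, **kwargs):
    """Run several seeded recovery replicates; returns (outcomes, n_success).

    The stimulus set and feature matrices are rendered once and shared
    across replicates (replicates differ in weights, noise and trial
    schedules).
    """
    resolution = kwargs.pop("resolution", (64, 64))
    n_images = kwargs.get("n_images", 300)
    stimulus_seed = seed * 7 + 1
    stimset = generate_stimulus_set(n_images, seed=stimulus_seed, resolution=resolution)
    bank = build_gabor_bank(GaborBankSpec(), resolution=resolution)
    fm_gabor = gabor_feature_matrix(stimset, bank)
    bins = fit_distance_bins(stimset, seed=0)
    fm_global = surface_feature_matrix(stimset, bins, "global")
    outcomes = []
    for rep in range(n_replicates):
        outcomes.append(
            parameter_recovery_replicate(
                seed=seed * 100003 + rep + 1,
                stimulus_seed=stimulus_seed,
                features=(fm_gabor, fm_global),
                **kwargs,
            )
        )
    return outcomes, sum(o.success for o in outcomes)


def _null_encoding_result(rng, n_folds=9, n_test=25, n_voxels=20, name="null"):
    """EncodingResult whose predictions and data are independent noise."""
    preds, actuals, test_idx, fold_r = [], [], [], []
    t0 = 0
    for _ in range(n_folds):
        p = rng.standard_normal((n_test, n_voxels))
        a = rng.standard_normal((n_test, n_voxels))
        preds.append(p)
        actuals.append(a)
        test_idx.append(np.arange(t0, t0 + n_test))
        fold_r.append(_pearson_columns(p, a))
        t0 += n_test
    fold_r = np.asarray(fold_r)
    return enc.EncodingResult(
        model_name=name,
        voxel_r=fold_r.mean(axis=0),
        fold_r=fold_r,
        lambdas=np.zeros((n_folds, n_voxels)),
        fold_test_idx=test_idx,
        fold_predictions=preds,
        fold_actuals=actuals,
    )


def calibration_rejection_rate(
    n_replicates: int = 200,
    n_subjects: int = 8,
    n_perm: int = 500,
    n_folds: int = 9,
    n_test: int = 25,
    n_voxels: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error rate of the ROI group permutation test under the null.

    Each replicate draws, for every subject, fold-wise predictions and
    held-out data that are independent noise, computes the observed
    fold-then-voxel-averaged ROI performance, builds its permutation
    null, and applies the group test.  Returns the fraction of
    replicates rejecting at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    voxels = np.arange(n_voxels)
    for rep in range(n_replicates):
        observed = np.empty(n_subjects)
        nulls = np.empty((n_subjects, n_perm))
        for s in range(n_subjects):
            res = _null_encoding_result(rng, n_folds, n_test, n_voxels)
            observed[s] = float(res.voxel_r.mean())
            nulls[s] = inf.permutation_null_roi(
                res, voxels, n_perm=n_perm,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        p = inf.group_permutation_test(observed, nulls)
        rejections += p < alpha
    return rejections / n_replicates


def noise_ceiling_recovery(
    seed: int,
    signal_fraction: float = 0.5,
    n_stimuli: int = 300,
    repeats: int = 3,
    n_voxels: int = 1,
    n_runs: int = 36,
) -> tuple[np.ndarray, float]:
    """Estimate the noise ceiling of voxels with a known signal fraction.

    Returns ``(estimated_nc_per_voxel, analytic_nc)`` where the analytic
    value equals the simulated signal-variance fraction.
    """
    rng = np.random.default_rng(seed)
    design = DesignSpec(n_runs=n_runs, repeats_per_stimulus=repeats)
    feats = {"gabor": rng.standard_normal((n_stimuli, 30))}
    noise_sd = noise_sd_for_signal_fraction(signal_fraction, 1.0, design)
    pops = [
        VoxelPopulationSpec(
            n_voxels=n_voxels, label="gabor-coded", weight_scale=1.0,
            noise_sd=noise_sd, weight_seed=seed + 1,
        )
    ]
    trials = simulate_voxel_responses(feats, pops, design, seed=seed)
    ds = enc.epoch_and_average(trials)
    nc = inf.noise_ceiling(ds.y, ds.stimulus_idx, n_perm=200, seed=seed)
    return nc.nc, signal_fraction


def stimulus_selection_experiment(
    n_pool: int = 60,
    n_target: int = 20,
    n_initial_iters: int = 30,
    candidates_per_image: int = 20,
    seed: int = 0,
    resolution=(64, 64),
):
    """Initial + greedy stimulus selection on a heterogeneous synthetic pool.

    Returns ``(initial_objective, final_objective)`` for the 3D-global
    vs 3D-quadrant RDM-correlation objective.
    """
    from . import rdm as rdm_mod

    stimset = generate_stimulus_set(n_pool, seed=seed, resolution=resolution)
    bins = fit_distance_bins(stimset, seed=0)
    fm_g = surface_feature_matrix(stimset, bins, "global")
    fm_q = surface_feature_matrix(stimset, bins, "quadrant")
    rdm_a = rdm_mod.compute_rdm(fm_g)
    rdm_b = rdm_mod.compute_rdm(fm_q)
    kept = rdm_mod.prefilter_pool(stimset, keep_fraction=0.8)
    state = rdm_mod.initial_random_search(
        rdm_a, rdm_b, n_target, n_initial_iters, seed=seed, pool_indices=kept
    )
    initial = state.objective
    state = rdm_mod.greedy_replacement(
        state, rdm_a, rdm_b, candidates_per_image=candidates_per_image, seed=seed + 1
    )
    return initial, state.objective
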
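"""Preprocessing, ridge solver, fold construction and nested CV."""

import numpy as np
import pytest

from sceneenc.encoding import (
    EncodingResult,
    RidgeConfig,
    default_lambda_grid,
    epoch_and_average,
    make_folds,
    nested_cv_predict,
    prediction_performance,
    ridge_solve,
    zscore_within_run,
)
from sceneenc.synth import DesignSpec, TrialTable


def test_default_lambda_grid():
    grid = default_lambda_grid()
    assert len(grid) == 13
    assert grid[0] == 0.0
    assert grid[1] == pytest.approx(1e-2)
    assert grid[-1] == pytest.approx(1e5)
    assert np.all(np.diff(grid) > 0)


# -- within-run z-scoring ----------------------------------------------------


def test_zscore_within_run_matches_per_run_loop():
    rng = np.random.default_rng(0)
    ts = rng.standard_normal((40, 3)) * 5 + 2
    runs = np.repeat([0, 1, 2, 3], 10)
    z = zscore_within_run(ts, runs)
    for r in range(4):
        seg = ts[runs == r]
        expect = (seg - seg.mean(axis=0)) / seg.std(axis=0)
        assert np.allclose(z[runs == r], expect, atol=1e-12)
        assert np.allclose(z[runs == r].mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(z[runs == r].std(axis=0), 1.0, atol=1e-10)


def test_zscore_constant_run_zeros_with_warning():
    ts = np.ones((10, 2))
    with pytest.warns(UserWarning, match="constant"):
        z = zscore_within_run(ts, np.repeat([0, 1], 5))
    assert np.allclose(z, 0.0)


# -- epoch averaging ---------------------------------------------------------


def _trial_table(responses, design=None):
    n_trials = responses.shape[0]
    design = design or DesignSpec(n_runs=2, repeats_per_stimulus=1)
    return TrialTable(
        responses=responses,
        run_id=np.repeat([0, 1], n_trials // 2),
        task_label=np.asarray(["scene"] * n_trials),
        stimulus_idx=np.arange(n_trials),
        stimulus_id=np.asarray([f"s{i}" for i in range(n_trials)]),
        design=design,
        voxel_labels=np.asarray(["null"] * responses.shape[2]),
    )


def test_epoch_average_constant_and_ramp():
    const = np.full((2, 12, 1), 3.25)
    assert np.allclose(epoch_and_average(_trial_table(const)).y, 3.25)
    ramp = np.tile(np.arange(12.0)[None, :, None], (2, 1, 1))
    # TR 0.8: samples 3..6 fall in [2.4, 4.8]; mean(3,4,5,6) = 4.5
    assert np.allclose(epoch_and_average(_trial_table(ramp)).y, 4.5)


def test_epoch_window_outside_epoch_errors():
    tt = _trial_table(np.zeros((2, 12, 1)))
    with pytest.raises(ValueError, match="outside the trial epoch"):
        epoch_and_average(tt, window=(8.0, 12.0))


# -- ridge solver ------------------------------------------------------------


def test_ridge_lambda_zero_equals_least_squares():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((20, 5))
    y = rng.standard_normal(20)
    w = ridge_solve(X, y, 0.0)
    w_ls, *_ = np.linalg.lstsq(X, y, rcond=None)
    assert np.allclose(w, w_ls, atol=1e-8)


def test_ridge_huge_lambda_shrinks_to_zero():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((20, 5))
    y = rng.standard_normal(20)
    assert np.linalg.norm(ridge_solve(X, y, 1e12)) < 1e-9


def test_ridge_matches_gradient_minimizer():
    from scipy.optimize import minimize

    rng = np.random.default_rng(3)
    X = rng.standard_normal((30, 8))
    y = rng.standard_normal(30)
    lam = 2.5
    w = ridge_solve(X, y, lam)
    res = minimize(
        lambda v: np.sum((y - X @ v) ** 2) + lam * np.sum(v**2),
        np.zeros(8),
        jac=lambda v: -2 * X.T @ (y - X @ v) + 2 * lam * v,
        method="L-BFGS-B",
        options=dict(maxiter=5000, ftol=1e-18, gtol=1e-14),
    )
    assert np.allclose(w, res.x, atol=1e-6)


def test_ridge_minimum_norm_on_rank_deficiency():
    rng = np.random.default_rng(4)
    X = rng.standard_normal((5, 10))  # p > n
    y = rng.standard_normal(5)
    w = ridge_solve(X, y, 0.0)
    assert np.allclose(X @ w, y, atol=1e-8)
    assert np.allclose(w, np.linalg.pinv(X) @ y, atol=1e-8)


def test_ridge_rejects_bad_inputs():
    with pytest.raises(ValueError):
        ridge_solve(np.ones((3, 2)), np.array([1.0, np.nan, 0.0]), 1.0)
    with pytest.raises(ValueError):
        ridge_solve(np.ones((3, 2)), np.ones(3), -1.0)


# -- fold plans --------------------------------------------------------------


def _design_labels(n_runs=36, trials_per_run=5):
    run = np.repeat(np.arange(n_runs), trials_per_run)
    task = np.asarray(["scene" if r % 2 == 0 else "dot" for r in run])
    return run, task


def test_collapsed_folds_balance_tasks():
    run, task = _design_labels()
    plan = make_folds(run, task, n_folds=9)
    assert len(plan.fold_runs) == 9
    for fold_runs in plan.fold_runs:
        assert len(fold_runs) == 4
        fold_tasks = [task[run == r][0] for r in fold_runs]
        assert sorted(fold_tasks) == ["dot", "dot", "scene", "scene"]
    # Folds partition all runs.
    assert sorted(np.concatenate(plan.fold_runs)) == list(range(36))
    assert plan.included.all()


def test_single_task_folds():
    run, task = _design_labels()
    plan = make_folds(run, task, n_folds=9, mode="single-task", task="scene")
    for fold_runs in plan.fold_runs:
        assert len(fold_runs) == 2
    excluded = plan.trial_fold < 0
    assert np.array_equal(excluded, task == "dot")


def test_indivisible_runs_rejected():
    run, task = _design_labels(n_runs=20)
    with pytest.raises(ValueError, match="divisible"):
        make_folds(run, task, n_folds=9)


# -- nested CV ---------------------------------------------------------------


def _nested_setup(n_runs=8, trials_per_run=10, n_feat=6, n_vox=3, seed=0):
    rng = np.random.default_rng(seed)
    n_trials = n_runs * trials_per_run
    run = np.repeat(np.arange(n_runs), trials_per_run)
    task = np.asarray(["scene" if r % 2 == 0 else "dot" for r in run])
    X = rng.standard_normal((n_trials, n_feat))
    X = (X - X.mean(0)) / X.std(0)
    plan = make_folds(run, task, n_folds=4)
    cfg = RidgeConfig(n_outer_folds=4, n_inner_folds=3)
    return X, run, plan, cfg, rng


def test_noiseless_fit_selects_zero_lambda_and_recovers():
    X, run, plan, cfg, rng = _nested_setup()
    W = rng.standard_normal((X.shape[1], 3))
    Y = X @ W
    res = nested_cv_predict(X, Y, plan, cfg, run_labels=run)
    assert np.all(res.lambdas == 0.0)
    assert np.all(res.voxel_r > 0.999)
    # Refit weights at the chosen penalty recover ground truth.
    w_hat = ridge_solve(X, Y, 0.0)
    for v in range(3):
        c = np.corrcoef(w_hat[:, v], W[:, v])[0, 1]
        assert c > 0.999


def test_pure_noise_performance_near_zero():
    X, run, plan, cfg, rng = _nested_setup(n_runs=8, trials_per_run=25, n_vox=40)
    Y = rng.standard_normal((X.shape[0], 40))
    res = nested_cv_predict(X, Y, plan, cfg, run_labels=run)
    assert abs(res.voxel_r.mean()) < 0.05
    assert np.all(np.abs(res.voxel_r) <= 1.0)


def test_degenerate_target_ties_resolve_to_smallest_lambda():
    X, run, plan, cfg, _ = _nested_setup()
    Y = np.zeros((X.shape[0], 2))  # all inner scores tie at 0
    res = nested_cv_predict(X, Y, plan, cfg, run_labels=run)
    assert np.all(res.lambdas == 0.0)


def test_predictions_cover_every_trial_once():
    X, run, plan, cfg, rng = _nested_setup()
    Y = rng.standard_normal((X.shape[0], 2))
    res = nested_cv_predict(X, Y, plan, cfg, run_labels=run)
    covered = np.concatenate(res.fold_test_idx)
    assert sorted(covered) == list(range(X.shape[0]))
    assert len(covered) == len(set(covered))


def test_performance_invariant_to_feature_order():
    X, run, plan, cfg, rng = _nested_setup()
    Y = X @ rng.standard_normal((X.shape[1], 2)) + 0.5 * rng.standard_normal(
        (X.shape[0], 2)
    )
    res1 = nested_cv_predict(X, Y, plan, cfg, run_labels=run)
    perm = rng.permutation(X.shape[1])
    res2 = nested_cv_predict(X[:, perm], Y, plan, cfg, run_labels=run)
    assert np.allclose(res1.voxel_r, res2.voxel_r, atol=1e-8)


def test_inner_fold_reduction_warns():
    X, run, plan, cfg, rng = _nested_setup()
    cfg = RidgeConfig(n_outer_folds=4, n_inner_folds=10)  # only 6 training runs
    Y = rng.standard_normal((X.shape[0], 2))
    with pytest.warns(UserWarning, match="reducing inner folds"):
        nested_cv_predict(X, Y, plan, cfg, run_labels=run)


# -- performance summaries ---------------------------------------------------


def _result_from_folds(preds, actuals):
    from sceneenc.encoding import _pearson_columns

    fold_r = np.asarray([_pearson_columns(p, a) for p, a in zip(preds, actuals)])
    t0 = 0
    idx = []
    for p in preds:
        idx.append(np.arange(t0, t0 + p.shape[0]))
        t0 += p.shape[0]
    return EncodingResult(
        model_name="m",
        voxel_r=fold_r.mean(axis=0),
        fold_r=fold_r,
        lambdas=np.zeros_like(fold_r),
        fold_test_idx=idx,
        fold_predictions=list(preds),
        fold_actuals=list(actuals),
    )


def test_prediction_performance_limits_and_averaging_order():
    rng = np.random.default_rng(5)
    actuals = [rng.standard_normal((10, 2)) for _ in range(3)]
    perfect = _result_from_folds([a.copy() for a in actuals], actuals)
    assert prediction_performance(perfect) == pytest.approx(1.0)
    flipped = _result_from_folds([-a for a in actuals], actuals)
    assert prediction_performance(flipped) == pytest.approx(-1.0)
    # Oracle: per-fold correlation loop, folds averaged before voxels.
    preds = [rng.standard_normal((10, 2)) for _ in range(3)]
    res = _result_from_folds(preds, actuals)
    per_voxel = []
    for v in range(2):
        rs = [np.corrcoef(p[:, v], a[:, v])[0, 1] for p, a in zip(preds, actuals)]
        per_voxel.append(np.mean(rs))
    assert prediction_performance(res) == pytest.approx(np.mean(per_voxel), abs=1e-12)
    assert np.allclose(res.voxel_r, per_voxel, atol=1e-12)
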
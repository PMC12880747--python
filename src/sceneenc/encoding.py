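"""Voxelwise encoding models: nested cross-validated ridge regression.

The analysis fits, per voxel, a linear mapping from z-scored stimulus
features to window-averaged trial responses.  Runs are partitioned into
9 outer cross-validation folds (4 of 36 runs held out per fold, two
from each task, in the task-collapsed design).  Within each outer
fold's training runs, 10 inner run-wise folds select the ridge penalty
from a 13-value grid (0 plus 12 values log-spaced from 1e-2 to 1e5) by
maximizing mean inner held-out r-squared; ties go to the smaller
penalty.  The selected penalty is refit on all training trials and used
to predict the held-out trials.

Prediction performance is the Pearson correlation between predictions
and held-out data, computed per fold and averaged across folds first,
then across voxels when summarizing an ROI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .synth import TrialTable

__all__ = [
    "RidgeConfig",
    "FoldPlan",
    "EncodingResult",
    "VoxelDataset",
    "default_lambda_grid",
    "zscore_within_run",
    "epoch_and_average",
    "preprocess_trials",
    "ridge_solve",
    "make_folds",
    "nested_cv_predict",
    "prediction_performance",
]


def default_lambda_grid() -> np.ndarray:
    """13 ridge penalties: 0 plus 12 log-spaced values in [1e-2, 1e5]."""
    return np.concatenate(([0.0], np.logspace(-2.0, 5.0, 12)))


@dataclass(frozen=True)
class RidgeConfig:
    lambda_grid: tuple[float, ...] = tuple(default_lambda_grid())
    n_outer_folds: int = 9
    n_inner_folds: int = 10
    inner_metric: str = "r2_corr"  # squared Pearson r; "r2_ss" -> 1 - SSE/SST

    def __post_init__(self):
        grid = np.asarray(self.lambda_grid)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("lambda grid must be sorted strictly ascending")
        if np.any(grid < 0):
            raise ValueError("lambda values must be >= 0")
        if self.inner_metric not in ("r2_corr", "r2_ss"):
            raise ValueError("inner_metric must be 'r2_corr' or 'r2_ss'")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def zscore_within_run(timeseries: np.ndarray, run_labels: np.ndarray) -> np.ndarray:
    """Z-score each voxel's timeseries within each run.

    ``timeseries`` is (n_timepoints, n_voxels).  Constant segments are
    set to zero with a warning.
    """
    ts = np.asarray(timeseries, dtype=float)
    runs = np.asarray(run_labels)
    out = np.empty_like(ts)
    warned = False
    for r in np.unique(runs):
        sel = runs == r
        if sel.sum() < 2:
            raise ValueError(f"run {r!r} has fewer than 2 timepoints")
        seg = ts[sel]
        mu = seg.mean(axis=0)
        sd = seg.std(axis=0)
        const = sd <= 1e-12
        if const.any() and not warned:
            warnings.warn("constant voxel timeseries within a run set to zeros", stacklevel=2)
            warned = True
        sd = np.where(const, 1.0, sd)
        z = (seg - mu) / sd
        z[:, const] = 0.0
        out[sel] = z
    return out


@dataclass
class VoxelDataset:
    """Window-averaged trial responses ready for model fitting."""

    y: np.ndarray  # (n_trials, n_voxels)
    run_id: np.ndarray
    task_label: np.ndarray
    stimulus_idx: np.ndarray
    stimulus_id: np.ndarray


def epoch_and_average(
    trials: TrialTable, window: tuple[float, float] = (2.4, 4.8)
) -> VoxelDataset:
    """Average each trial's TR samples inside the analysis window.

    TR samples whose onset-relative time t satisfies ``window[0] <= t <=
    window[1]`` are averaged (4 samples at TR 0.8 for the default
    2.4-4.8 s window).
    """
    design = trials.design
    t_max = (design.epoch_len_trs - 1) * design.tr
    if window[0] < -1e-9 or window[1] > t_max + 1e-9 or window[1] < window[0]:
        raise ValueError(
            f"window {window} lies outside the trial epoch [0, {t_max:g}] s"
        )
    idx = design.window_tr_indices(window)
    if len(idx) == 0:
        raise ValueError(f"no TR samples fall inside window {window}")
    y = trials.responses[:, idx, :].mean(axis=1)
    return VoxelDataset(
        y=y,
        run_id=trials.run_id,
        task_label=trials.task_label,
        stimulus_idx=trials.stimulus_idx,
        stimulus_id=trials.stimulus_id,
    )


def preprocess_trials(
    trials: TrialTable,
    window: tuple[float, float] = (2.4, 4.8),
    zscore: bool = True,
) -> VoxelDataset:
    """Within-run z-scoring of the TR timeseries, then window averaging."""
    if not zscore:
        return epoch_and_average(trials, window)
    n_trials, n_trs, n_vox = trials.responses.shape
    flat = trials.responses.reshape(n_trials * n_trs, n_vox)
    run_per_tr = np.repeat(trials.run_id, n_trs)
    zflat = zscore_within_run(flat, run_per_tr)
    ztrials = TrialTable(
        responses=zflat.reshape(n_trials, n_trs, n_vox),
        run_id=trials.run_id,
        task_label=trials.task_label,
        stimulus_idx=trials.stimulus_idx,
        stimulus_id=trials.stimulus_id,
        design=trials.design,
        voxel_labels=trials.voxel_labels,
        true_weights=trials.true_weights,
        true_signal_sd=trials.true_signal_sd,
    )
    return epoch_and_average(ztrials, window)


# ---------------------------------------------------------------------------
# Ridge solver
# ---------------------------------------------------------------------------


def _filter_factors(s: np.ndarray, lam: float, rcond: float = 1e-10) -> np.ndarray:
    """Singular-value shrinkage factors d such that w = V diag(d) U' y."""
    if lam == 0:
        cutoff = rcond * (s.max() if s.size else 0.0)
        return np.where(s > cutoff, 1.0 / np.where(s > cutoff, s, 1.0), 0.0)
    return s / (s**2 + lam)


def ridge_solve(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Ridge weights via SVD: argmin ||y - Xw||^2 + lam ||w||^2.

    ``lam == 0`` returns the minimum-norm least-squares solution (well
    defined under rank deficiency).  ``y`` may be 1-D or (n, n_targets).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in ridge inputs")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    d = _filter_factors(s, lam)
    uy = U.T @ y
    if y.ndim == 1:
        return Vt.T @ (d * uy)
    return Vt.T @ (d[:, None] * uy)


# ---------------------------------------------------------------------------
# Fold construction
# ---------------------------------------------------------------------------


@dataclass
class FoldPlan:
    """Run-derived outer-fold assignment per trial.

    ``trial_fold`` is -1 for trials excluded by the mode (e.g. the other
    task in single-task mode).
    """

    trial_fold: np.ndarray
    fold_runs: list[np.ndarray]
    n_folds: int
    mode: str

    @property
    def included(self) -> np.ndarray:
        return self.trial_fold >= 0


def make_folds(
    run_labels: np.ndarray,
    task_labels: np.ndarray,
    n_folds: int = 9,
    mode: str = "collapsed",
    task: str | None = None,
) -> FoldPlan:
    """Deterministic run-to-fold assignment.

    In ``collapsed`` mode each task's runs are ordered and dealt
    round-robin across folds, so every fold holds out the same number of
    runs from each task (4 of 36 runs per fold, two per task, at the
    default design).  In ``single-task`` mode only runs of ``task`` are
    used (2 of 18 runs held out per fold at the default design).
    """
    run_labels = np.asarray(run_labels)
    task_labels = np.asarray(task_labels)
    if mode not in ("collapsed", "single-task"):
        raise ValueError("mode must be 'collapsed' or 'single-task'")
    run_task = {}
    for r, t in zip(run_labels, task_labels):
        prev = run_task.setdefault(r, t)
        if prev != t:
            raise ValueError(f"run {r!r} has inconsistent task labels")
    tasks = sorted(set(run_task.values()))
    if mode == "single-task":
        if task is None:
            raise ValueError("single-task mode requires the task argument")
        if task not in tasks:
            raise ValueError(f"unknown task {task!r}")
        tasks = [task]
    run_fold = {}
    for t in tasks:
        t_runs = sorted(r for r, rt in run_task.items() if rt == t)
        if len(t_runs) % n_folds != 0:
            raise ValueError(
                f"{len(t_runs)} runs of task {t!r} are not divisible into {n_folds} folds"
            )
        for i, r in enumerate(t_runs):
            run_fold[r] = i % n_folds
    # Runs of excluded tasks (single-task mode) are absent from run_fold,
    # so their trials get fold -1.
    trial_fold = np.array([run_fold.get(r, -1) for r in run_labels])
    fold_runs = [
        np.array(sorted(r for r, f in run_fold.items() if f == k)) for k in range(n_folds)
    ]
    return FoldPlan(trial_fold=trial_fold, fold_runs=fold_runs, n_folds=n_folds, mode=mode)


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------


@dataclass
class EncodingResult:
    """Per-voxel cross-validated encoding performance for one model."""

    model_name: str
    voxel_r: np.ndarray  # (n_voxels,) mean over folds
    fold_r: np.ndarray  # (n_folds, n_voxels)
    lambdas: np.ndarray  # (n_folds, n_voxels) chosen penalty
    fold_test_idx: list[np.ndarray] = field(repr=False, default_factory=list)
    fold_predictions: list[np.ndarray] = field(repr=False, default_factory=list)
    fold_actuals: list[np.ndarray] = field(repr=False, default_factory=list)

    @property
    def n_folds(self) -> int:
        return self.fold_r.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.fold_r.shape[1]


def _pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r between two (n, V) arrays (0 where degenerate)."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    na = np.linalg.norm(ac, axis=0)
    nb = np.linalg.norm(bc, axis=0)
    denom = na * nb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac * bc).sum(axis=0) / denom
    return np.where(denom > 0, r, 0.0)


def _inner_score(pred: np.ndarray, actual: np.ndarray, metric: str) -> np.ndarray:
    if metric == "r2_corr":
        return _pearson_columns(pred, actual) ** 2
    sst = ((actual - actual.mean(axis=0)) ** 2).sum(axis=0)
    sse = ((actual - pred) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - sse / sst
    return np.where(sst > 0, r2, 0.0)


def _deal_runs(runs: np.ndarray, n_folds: int) -> list[np.ndarray]:
    return [runs[k::n_folds] for k in range(n_folds)]


def nested_cv_predict(
    X: np.ndarray,
    Y: np.ndarray,
    plan: FoldPlan,
    cfg: RidgeConfig = RidgeConfig(),
    run_labels: np.ndarray | None = None,
    model_name: str = "model",
) -> EncodingResult:
    """Fit and evaluate one encoding model under the nested-CV protocol.

    ``X`` is (n_trials, n_features) of z-scored features aligned to the
    trials; ``Y`` is (n_trials, n_voxels).  ``run_labels`` (per trial)
    defaults to the plan's implied runs and is used to split training
    runs into inner folds, so no inner split ever separates trials of
    one run.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if run_labels is None:
        raise ValueError("run_labels are required to build inner folds")
    run_labels = np.asarray(run_labels)
    grid = np.asarray(cfg.lambda_grid)
    n_vox = Y.shape[1]
    n_folds = plan.n_folds

    fold_r = np.zeros((n_folds, n_vox))
    lambdas = np.zeros((n_folds, n_vox))
    fold_test_idx, fold_preds, fold_actuals = [], [], []

    covered = np.zeros(X.shape[0], dtype=bool)
    for f in range(n_folds):
        test = np.nonzero(plan.trial_fold == f)[0]
        train = np.nonzero((plan.trial_fold >= 0) & (plan.trial_fold != f))[0]
        if test.size == 0 or train.size == 0:
            raise ValueError(f"fold {f} has empty train or test set")
        covered[test] = True

        train_runs = np.unique(run_labels[train])
        n_inner = cfg.n_inner_folds
        if len(train_runs) < n_inner:
            warnings.warn(
                f"only {len(train_runs)} training runs: reducing inner folds "
                f"from {n_inner}",
                stacklevel=2,
            )
            n_inner = len(train_runs)
        inner_folds = _deal_runs(train_runs, n_inner)

        score_sum = np.zeros((len(grid), n_vox))
        for inner_runs in inner_folds:
            is_inner_test = np.isin(run_labels[train], inner_runs)
            itrain = train[~is_inner_test]
            itest = train[is_inner_test]
            U, s, Vt = np.linalg.svd(X[itrain], full_matrices=False)
            uy = U.T @ Y[itrain]
            proj = X[itest] @ Vt.T
            for li, lam in enumerate(grid):
                d = _filter_factors(s, lam)
                pred = proj @ (d[:, None] * uy)
                score_sum[li] += _inner_score(pred, Y[itest], cfg.inner_metric)
        mean_score = score_sum / len(inner_folds)
        best = np.argmax(mean_score, axis=0)  # first max -> smaller lambda on ties
        lambdas[f] = grid[best]

        U, s, Vt = np.linalg.svd(X[train], full_matrices=False)
        uy = U.T @ Y[train]
        proj = X[test] @ Vt.T
        pred = np.empty((test.size, n_vox))
        for li in np.unique(best):
            sel = best == li
            d = _filter_factors(s, grid[li])
            pred[:, sel] = proj @ (d[:, None] * uy[:, sel])
        actual = Y[test]
        fold_r[f] = _pearson_columns(pred, actual)
        fold_test_idx.append(test)
        fold_preds.append(pred)
        fold_actuals.append(actual)

    if not np.array_equal(covered, plan.included):
        raise AssertionError("folds do not cover every included trial exactly once")

    return EncodingResult(
        model_name=model_name,
        voxel_r=fold_r.mean(axis=0),
        fold_r=fold_r,
        lambdas=lambdas,
        fold_test_idx=fold_test_idx,
        fold_predictions=fold_preds,
        fold_actuals=fold_actuals,
    )


def prediction_performance(result: EncodingResult, voxel_idx=None) -> float:
    """ROI-level performance: fold-mean r per voxel, then mean over voxels.

    The averaging order (folds first, then voxels) is part of the
    analysis definition and preserved exactly.
    """
    r = result.voxel_r if voxel_idx is None else result.voxel_r[np.asarray(voxel_idx)]
    return float(r.mean())
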
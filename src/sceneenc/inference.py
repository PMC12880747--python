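"""Variance partitioning, permutation inference, noise ceilings, ROIs.

Variance partitioning decomposes the cross-validated performance of a
combined (concatenated-feature) model AB into components unique to A,
unique to B, and shared, using sign-preserving squared correlations
R^2 := sign(r) * r^2:

    unique_A = R2_AB - R2_B
    unique_B = R2_AB - R2_A
    shared   = R2_A + R2_B - R2_AB

Group inference shuffles each outer fold's held-out data relative to
the predictions (the same shuffle for every voxel of an ROI, preserving
inter-voxel correlation), rebuilds the fold-then-voxel-averaged
statistic per permutation and per subject, and compares the observed
across-subject t-statistic to the null t distribution without assuming
symmetry.

Noise ceilings follow the repeat-based signal/noise variance split
appropriate when stimuli have only a few exact repeats: per voxel,
sigma2_noise is the mean over stimuli of the sample variance across
repeats, sigma2_signal = max(0, total - noise), ncsnr =
sigma_signal/sigma_noise and NC = ncsnr^2 / (ncsnr^2 + 1/m) with m the
number of trials averaged per prediction target (m = 1 here: the
analysis predicts single trials).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .encoding import EncodingResult

__all__ = [
    "PartitionResult",
    "NoiseCeiling",
    "ROISpec",
    "variance_partition",
    "signed_r2",
    "permutation_null_r",
    "permutation_null_roi",
    "group_permutation_test",
    "noise_ceiling",
    "rescale_by_nc",
    "select_roi_voxels",
    "sliding_window",
    "voxel_count_sweep",
    "bh_fdr",
]


def signed_r2(r: np.ndarray) -> np.ndarray:
    """Sign-preserving squared correlation: sign(r) * r**2."""
    r = np.asarray(r, dtype=float)
    return np.sign(r) * r**2


@dataclass
class PartitionResult:
    """Per-voxel unique/shared variance components for one model pair."""

    unique_a: np.ndarray
    unique_b: np.ndarray
    shared: np.ndarray
    model_a: str = "A"
    model_b: str = "B"

    @property
    def r2_combined(self) -> np.ndarray:
        return self.unique_a + self.unique_b + self.shared


def variance_partition(r_a, r_b, r_ab, model_a="A", model_b="B") -> PartitionResult:
    """Partition combined-model performance into unique and shared parts.

    Inputs are per-voxel fold-mean correlations for model A, model B and
    the concatenated model AB, on identical voxels.  Components are not
    clamped: negative values are meaningful and preserved.
    """
    r_a, r_b, r_ab = (np.asarray(x, dtype=float) for x in (r_a, r_b, r_ab))
    if not (r_a.shape == r_b.shape == r_ab.shape):
        raise ValueError("per-voxel inputs must have identical shapes")
    R2a, R2b, R2ab = signed_r2(r_a), signed_r2(r_b), signed_r2(r_ab)
    return PartitionResult(
        unique_a=R2ab - R2b,
        unique_b=R2ab - R2a,
        shared=R2a + R2b - R2ab,
        model_a=model_a,
        model_b=model_b,
    )


# ---------------------------------------------------------------------------
# Permutation inference
# ---------------------------------------------------------------------------


def _normalize_columns(a: np.ndarray) -> np.ndarray:
    c = a - a.mean(axis=0)
    n = np.linalg.norm(c, axis=0)
    n = np.where(n > 0, n, np.inf)
    return c / n


def _fold_permutations(rng, n_perm, n_trials, identity_first=False):
    perms = np.empty((n_perm, n_trials), dtype=np.intp)
    start = 0
    if identity_first:
        perms[0] = np.arange(n_trials)
        start = 1
    for p in range(start, n_perm):
        perms[p] = rng.permutation(n_trials)
    return perms


def permutation_null_r(
    results: dict[str, EncodingResult],
    voxel_idx,
    n_perm: int = 10000,
    seed: int = 0,
    identity_first: bool = False,
    chunk: int = 64,
) -> dict[str, np.ndarray]:
    """Null distribution of per-voxel fold-mean r under test-set shuffles.

    Each permutation draws one trial-order shuffle per outer fold and
    applies it identically across all ROI voxels *and all models* (the
    models share the same held-out trials, so consistent shuffles keep
    the partition components coherent under the null).  Returns, per
    model, an (n_perm, n_voxels) array of fold-mean correlations.

    With ``identity_first`` the first "permutation" is the identity and
    reproduces the observed values exactly.
    """
    voxel_idx = np.asarray(voxel_idx)
    models = list(results)
    first = results[models[0]]
    n_folds = first.n_folds
    for m in models[1:]:
        if results[m].n_folds != n_folds:
            raise ValueError("all models must share the fold structure")
        for f in range(n_folds):
            if not np.array_equal(results[m].fold_test_idx[f], first.fold_test_idx[f]):
                raise ValueError("models were fit on different held-out trials")

    rng = np.random.default_rng(seed)
    null = {m: np.zeros((n_perm, len(voxel_idx))) for m in models}
    for f in range(n_folds):
        n_t = first.fold_test_idx[f].size
        perms = _fold_permutations(rng, n_perm, n_t, identity_first=identity_first)
        # Normalized actuals are permutation-invariant in their scaling.
        a_norm = _normalize_columns(first.fold_actuals[f][:, voxel_idx])
        p_norms = {
            m: _normalize_columns(results[m].fold_predictions[f][:, voxel_idx])
            for m in models
        }
        for c0 in range(0, n_perm, chunk):
            pc = perms[c0 : c0 + chunk]
            a_perm = a_norm[pc]  # (chunk, n_t, V)
            for m in models:
                null[m][c0 : c0 + chunk] += np.einsum(
                    "ptv,tv->pv", a_perm, p_norms[m], optimize=True
                )
    for m in models:
        null[m] /= n_folds
    return null


def permutation_null_roi(
    result: EncodingResult,
    voxel_idx,
    n_perm: int = 10000,
    seed: int = 0,
    identity_first: bool = False,
) -> np.ndarray:
    """ROI-mean null values (one scalar per permutation) for one model."""
    null = permutation_null_r(
        {result.model_name: result}, voxel_idx, n_perm=n_perm, seed=seed,
        identity_first=identity_first,
    )[result.model_name]
    return null.mean(axis=1)


def group_permutation_test(observed: np.ndarray, nulls: np.ndarray) -> float:
    """Two-tailed group-level permutation p-value on a one-sample t.

    ``observed`` holds one value per subject; ``nulls`` is (n_subjects,
    n_perm), the i-th column being the i-th permutation's value for each
    subject.  The observed t (across subjects, against 0) is compared to
    the null t distribution built from matching permutation columns:
    p = 2 * min(#{null >= obs} + 1, #{null <= obs} + 1) / (n_perm + 1),
    capped at 1, without assuming a symmetric null.
    """
    observed = np.asarray(observed, dtype=float)
    nulls = np.asarray(nulls, dtype=float)
    if observed.ndim != 1 or observed.size < 2:
        raise ValueError("need at least 2 subjects")
    if nulls.ndim != 2 or nulls.shape[0] != observed.size:
        raise ValueError("nulls must be (n_subjects, n_perm) matching observed")

    def tstat(x, axis=0):
        n = x.shape[axis]
        mu = x.mean(axis=axis)
        sd = x.std(axis=axis, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mu / (sd / np.sqrt(n))
        # Zero between-subject variance: t is +/-inf (or 0 for a zero mean).
        return np.where(sd > 0, t, np.sign(mu) * np.inf)

    t_obs = tstat(observed)
    t_null = tstat(nulls, axis=0)
    n_perm = t_null.size
    ge = int(np.sum(t_null >= t_obs)) + 1
    le = int(np.sum(t_null <= t_obs)) + 1
    return float(min(1.0, 2.0 * min(ge, le) / (n_perm + 1)))


# ---------------------------------------------------------------------------
# Noise ceilings
# ---------------------------------------------------------------------------


@dataclass
class NoiseCeiling:
    nc: np.ndarray  # (n_voxels,) fraction in [0, 1]
    p: np.ndarray  # (n_voxels,) permutation p-value
    ncsnr: np.ndarray = None
    n_perm: int = 0


def _nc_from_labels(y: np.ndarray, labels: np.ndarray, m: float) -> np.ndarray:
    """Noise-ceiling fractions for one labeling of trials to stimuli."""
    n_trials, n_vox = y.shape
    order = np.argsort(labels, kind="stable")
    sorted_labels = labels[order]
    uniq, starts, counts = np.unique(sorted_labels, return_index=True, return_counts=True)
    if np.all(counts == counts[0]) and counts[0] >= 2:
        grouped = y[order].reshape(len(uniq), counts[0], n_vox)
        noise_var = grouped.var(axis=1, ddof=1).mean(axis=0)
    else:
        rep = counts >= 2
        if not rep.any():
            raise ValueError("no stimulus has >= 2 repeats")
        vars_ = [
            y[order[s : s + c]].var(axis=0, ddof=1)
            for s, c, ok in zip(starts, counts, rep)
            if ok
        ]
        noise_var = np.mean(vars_, axis=0)
    total_var = y.var(axis=0, ddof=1)
    signal_var = np.maximum(0.0, total_var - noise_var)
    with np.errstate(invalid="ignore", divide="ignore"):
        ncsnr2 = np.where(noise_var > 0, signal_var / noise_var, np.inf)
        nc = ncsnr2 / (ncsnr2 + 1.0 / m)
    nc = np.where(np.isfinite(nc), nc, 1.0)
    return nc, np.sqrt(ncsnr2)


def noise_ceiling(
    y: np.ndarray,
    stimulus_idx: np.ndarray,
    n_perm: int = 2000,
    seed: int = 0,
    m: float = 1.0,
) -> NoiseCeiling:
    """Repeat-based noise ceiling with permutation significance.

    ``y`` is (n_trials, n_voxels) of window-averaged responses;
    ``stimulus_idx`` labels which stimulus each trial showed.
    Significance permutes the stimulus labels across trials ``n_perm``
    times; p = (#{NC_perm >= NC_obs} + 1) / (n_perm + 1).
    """
    y = np.asarray(y, dtype=float)
    labels = np.asarray(stimulus_idx)
    nc_obs, ncsnr = _nc_from_labels(y, labels, m)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(y.shape[1])
    for _ in range(n_perm):
        perm_labels = rng.permutation(labels)
        nc_p, _ = _nc_from_labels(y, perm_labels, m)
        exceed += nc_p >= nc_obs
    p = (exceed + 1.0) / (n_perm + 1.0)
    return NoiseCeiling(nc=nc_obs, p=p, ncsnr=ncsnr, n_perm=n_perm)


def rescale_by_nc(values: np.ndarray, nc: np.ndarray, kind: str = "r") -> np.ndarray:
    """Rescale performance by the noise ceiling.

    Correlations (``kind='r'``) divide by sqrt(NC); variance components
    (``kind='variance'``) divide by NC.  Voxels must have NC > 0
    (non-significant-NC voxels are excluded upstream).
    """
    values = np.asarray(values, dtype=float)
    nc = np.asarray(nc, dtype=float)
    if np.any(nc <= 0):
        raise ValueError("noise ceiling must be > 0 for all included voxels")
    if kind == "r":
        return values / np.sqrt(nc)
    if kind == "variance":
        return values / nc
    raise ValueError("kind must be 'r' or 'variance'")


# ---------------------------------------------------------------------------
# ROI selection and robustness analyses
# ---------------------------------------------------------------------------


@dataclass
class ROISpec:
    name: str
    voxel_idx: np.ndarray
    localizer_stats: np.ndarray
    n_candidates: int = 0
    n_excluded: int = 0


def select_roi_voxels(
    localizer_stats: np.ndarray,
    candidate_mask: np.ndarray,
    exclusion_masks: list[np.ndarray] | None = None,
    cap: int = 200,
    minimum: int = 75,
    nc_p: np.ndarray | None = None,
    nc_alpha: float = 0.05,
    name: str = "ROI",
) -> ROISpec | None:
    """Select up to ``cap`` voxels by localizer strength.

    Exclusion masks (e.g. retinotopic regions) are removed first; an
    optional noise-ceiling significance filter then applies; remaining
    candidates are ranked by statistic descending (ties broken by lower
    voxel index) and capped.  Returns ``None`` if fewer than ``minimum``
    voxels survive.
    """
    stats = np.asarray(localizer_stats, dtype=float)
    keep = np.asarray(candidate_mask, dtype=bool).copy()
    n_candidates = int(keep.sum())
    if exclusion_masks:
        for mask in exclusion_masks:
            keep &= ~np.asarray(mask, dtype=bool)
    if nc_p is not None:
        keep &= np.asarray(nc_p) < nc_alpha
    n_excluded = n_candidates - int(keep.sum())
    idx = np.nonzero(keep)[0]
    order = idx[np.argsort(-stats[idx], kind="stable")]
    selected = order[:cap]
    if selected.size < minimum:
        return None
    return ROISpec(
        name=name,
        voxel_idx=selected,
        localizer_stats=stats[selected],
        n_candidates=n_candidates,
        n_excluded=n_excluded,
    )


def sliding_window(
    trials,
    analysis_fn,
    window_len_trs: int = 3,
    n_windows: int = 10,
    zscore: bool = True,
):
    """Re-run an analysis across sliding TR windows.

    Windows of ``window_len_trs`` TRs start at TR 0, 1, ..., stride 1.
    Each window's TR average replaces the default epoch average and
    ``analysis_fn(dataset, window_index)`` is called on the result; the
    per-window return values are collected in a list.
    """
    from .encoding import preprocess_trials

    design = trials.design
    if design.epoch_len_trs < n_windows + window_len_trs - 1:
        raise ValueError(
            f"epoch of {design.epoch_len_trs} TRs is too short for "
            f"{n_windows} windows of {window_len_trs} TRs"
        )
    results = []
    for k in range(n_windows):
        t0 = k * design.tr
        t1 = (k + window_len_trs - 1) * design.tr
        ds = preprocess_trials(trials, window=(t0, t1), zscore=zscore)
        results.append(analysis_fn(ds, k))
    return results


def voxel_count_sweep(values: np.ndarray, order: np.ndarray | None = None,
                      n_grid: np.ndarray | None = None) -> np.ndarray:
    """Cumulative ROI means as a function of included voxel count.

    ``values`` is (n_voxels,) or (n_voxels, k) of per-voxel results
    already ranked by localizer statistic, or ranked here via ``order``.
    Returns the running mean over the top-N voxels for each N in
    ``n_grid`` (default 1..n_voxels).
    """
    values = np.asarray(values, dtype=float)
    if order is not None:
        values = values[np.asarray(order)]
    counts = np.arange(1, values.shape[0] + 1)
    cums = np.cumsum(values, axis=0)
    if values.ndim == 1:
        curve = cums / counts
    else:
        curve = cums / counts[:, None]
    if n_grid is not None:
        curve = curve[np.asarray(n_grid) - 1]
    return curve


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject
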
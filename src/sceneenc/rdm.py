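"""RDM construction and decorrelating stimulus selection.

The stimulus-selection procedure picks a subset of a large image pool
whose 3D-global and 3D-quadrant feature RDMs are as weakly correlated
as possible: a prefilter keeps images with heterogeneous quadrant
depths, an iterated random search finds a good starting subset, and a
single greedy pass replaces each selected image with the best of a
batch of random candidates (keeping the incumbent on ties), so the
objective trace is non-increasing by construction.

RDMs use the cosine distance between raw (pre z-scoring) feature rows;
the "RDM correlation" objective is the Pearson correlation of the
strictly-upper-triangle entries (Spearman available by option).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from .features import FeatureMatrix
from .synth import StimulusSet

__all__ = [
    "RDM",
    "SelectionState",
    "compute_rdm",
    "rdm_correlation",
    "prefilter_pool",
    "quadrant_depth_variance",
    "initial_random_search",
    "greedy_replacement",
]


@dataclass
class RDM:
    """n x n representational dissimilarity matrix."""

    values: np.ndarray
    metric: str = "cosine"

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset(self, idx) -> "RDM":
        idx = np.asarray(idx)
        return RDM(values=self.values[np.ix_(idx, idx)], metric=self.metric)


def compute_rdm(features, metric: str = "cosine") -> RDM:
    """RDM of a feature matrix (raw rows, not z-scored columns)."""
    if isinstance(features, FeatureMatrix):
        values = features.values
        ids = features.stimulus_ids
    else:
        values = np.asarray(features, dtype=float)
        ids = [str(i) for i in range(values.shape[0])]
    if values.shape[0] < 2:
        raise ValueError("need at least 2 stimuli for an RDM")
    if metric == "cosine":
        norms = np.linalg.norm(values, axis=1)
        zero = np.nonzero(norms == 0)[0]
        if zero.size:
            raise ValueError(
                f"cosine RDM undefined for all-zero feature row(s): {ids[zero[0]]}"
            )
    d = squareform(pdist(values, metric=metric))
    np.fill_diagonal(d, 0.0)
    return RDM(values=d, metric=metric)


def _upper(values: np.ndarray) -> np.ndarray:
    i, j = np.triu_indices(values.shape[0], k=1)
    return values[i, j]


def rdm_correlation(a: RDM, b: RDM, method: str = "pearson") -> float:
    """Correlation of two RDMs over their strictly-upper triangles."""
    if a.n != b.n:
        raise ValueError("RDMs must have the same size")
    ua, ub = _upper(a.values), _upper(b.values)
    if np.ptp(ua) == 0 or np.ptp(ub) == 0:
        raise ValueError("RDM correlation undefined: constant upper triangle")
    if method == "pearson":
        return float(np.corrcoef(ua, ub)[0, 1])
    if method == "spearman":
        return float(spearmanr(ua, ub).statistic)
    raise ValueError("method must be 'pearson' or 'spearman'")


def quadrant_depth_variance(sample) -> float:
    """Variance of the mean valid depth across the 4 image quadrants."""
    h, w = sample.resolution
    h2, w2 = h // 2, w // 2
    means = []
    for rs, cs in [
        (slice(0, h2), slice(0, w2)),
        (slice(0, h2), slice(w2, w)),
        (slice(h2, h), slice(0, w2)),
        (slice(h2, h), slice(w2, w)),
    ]:
        valid = sample.valid_mask[rs, cs]
        means.append(sample.depth[rs, cs][valid].mean() if valid.any() else 0.0)
    return float(np.var(means))


def prefilter_pool(pool_set: StimulusSet, keep_fraction: float = 0.5) -> np.ndarray:
    """Rank pool images by descending quadrant-depth heterogeneity.

    Returns the indices of the retained top fraction, in rank order
    (ties broken by lower index).
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    scores = np.array([quadrant_depth_variance(s) for s in pool_set.samples])
    order = np.argsort(-scores, kind="stable")
    n_keep = max(2, int(round(keep_fraction * len(pool_set))))
    return order[:n_keep]


@dataclass
class SelectionState:
    """Current stimulus subset and the objective trace that produced it."""

    selected: np.ndarray
    objective: float
    trace: list[float] = field(default_factory=list)
    pool_indices: np.ndarray | None = None

    def __post_init__(self):
        self.selected = np.asarray(self.selected)
        if len(np.unique(self.selected)) != len(self.selected):
            raise ValueError("selected indices must be unique")


def _subset_objective(rdm_a: RDM, rdm_b: RDM, idx, method: str) -> float:
    return rdm_correlation(rdm_a.subset(idx), rdm_b.subset(idx), method=method)


def initial_random_search(
    rdm_a: RDM,
    rdm_b: RDM,
    n_target: int,
    n_iters: int,
    seed: int = 0,
    pool_indices=None,
    method: str = "pearson",
) -> SelectionState:
    """Best-of-``n_iters`` random subsets by RDM-correlation objective."""
    pool = np.arange(rdm_a.n) if pool_indices is None else np.asarray(pool_indices)
    if len(pool) < n_target:
        raise ValueError(f"pool of {len(pool)} is smaller than target {n_target}")
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    rng = np.random.default_rng(seed)
    best_idx = None
    best_obj = np.inf
    for _ in range(n_iters):
        idx = rng.choice(pool, size=n_target, replace=False)
        obj = _subset_objective(rdm_a, rdm_b, idx, method)
        if obj < best_obj:
            best_obj = obj
            best_idx = idx
    return SelectionState(
        selected=np.sort(best_idx),
        objective=float(best_obj),
        trace=[float(best_obj)],
        pool_indices=pool,
    )


def greedy_replacement(
    state: SelectionState,
    rdm_a: RDM,
    rdm_b: RDM,
    candidates_per_image: int = 1000,
    seed: int = 0,
    n_passes: int = 1,
    method: str = "pearson",
) -> SelectionState:
    """Greedy slot-wise replacement pass(es) over the selected subset.

    For each selected image in fixed order, ``candidates_per_image``
    replacement images are sampled without replacement from the
    unselected pool; the swap (or keeping the incumbent, which wins
    ties) with the lowest RDM correlation is accepted.  The objective
    trace is therefore non-increasing.
    """
    pool = state.pool_indices if state.pool_indices is not None else np.arange(rdm_a.n)
    rng = np.random.default_rng(seed)
    selected = np.array(state.selected, copy=True)
    objective = state.objective
    trace = list(state.trace)
    for _ in range(n_passes):
        for slot in range(len(selected)):
            unselected = np.setdiff1d(pool, selected)
            if len(unselected) == 0:
                warnings.warn("pool exhausted: no replacement candidates", stacklevel=2)
                trace.append(objective)
                continue
            k = min(candidates_per_image, len(unselected))
            if k < candidates_per_image:
                warnings.warn(
                    f"only {k} replacement candidates available "
                    f"(requested {candidates_per_image})",
                    stacklevel=2,
                )
            cands = rng.choice(unselected, size=k, replace=False)
            best_obj = objective
            best_cand = None
            trial = selected.copy()
            for cand in cands:
                trial[slot] = cand
                obj = _subset_objective(rdm_a, rdm_b, trial, method)
                if obj < best_obj:  # strict: incumbent wins ties
                    best_obj = obj
                    best_cand = cand
            if best_cand is not None:
                selected[slot] = best_cand
                objective = best_obj
            trace.append(objective)
    assert all(t2 <= t1 + 1e-12 for t1, t2 in zip(trace, trace[1:])), (
        "objective trace must be non-increasing"
    )
    return SelectionState(
        selected=selected, objective=float(objective), trace=trace, pool_indices=pool
    )
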
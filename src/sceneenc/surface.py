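"""3D scene-surface feature models from depth and surface-normal maps.

Pixels are binned by Euclidean distance (3 bins whose edges are pooled
quantiles over the stimulus set, so each bin is roughly equally
represented across images) and by surface direction (9 bins: forward
plus the 8 compass directions of the image plane).  The *3D-global*
model is the 27-vector of joint-bin pixel proportions over the whole
image; the *3D-quadrant* model computes the same 27 proportions within
each image quadrant (108 features), normalized per quadrant.

Invalid pixels (depth-sensor holes) are excluded from both numerator
and denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix
from .synth import DIRECTION_LABELS, SceneSample, StimulusSet

__all__ = [
    "DistanceBins",
    "SurfaceFeatureVector",
    "fit_distance_bins",
    "classify_normal",
    "classify_normals",
    "surface_features_global",
    "surface_features_quadrant",
    "surface_feature_matrix",
]

_COS45 = np.cos(np.pi / 4.0)
# Azimuth sector index (0 = right, counterclockwise in 45-degree steps)
# -> canonical direction-label index in DIRECTION_LABELS.
_SECTOR_TO_LABEL = np.array([4, 6, 1, 5, 3, 7, 2, 8])


@dataclass(frozen=True)
class DistanceBins:
    """Distance binning fit on a stimulus set (not per image).

    ``edges`` are the two interior thresholds (meters) splitting depths
    into 3 bins at the pooled 1/3 and 2/3 quantiles.
    """

    edges: tuple[float, ...]
    n_pixels_used: int = 0

    def __post_init__(self):
        e = np.asarray(self.edges)
        if e.ndim != 1 or len(e) < 1 or np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges) + 1

    def assign(self, depth: np.ndarray) -> np.ndarray:
        return np.digitize(np.asarray(depth), self.edges)


def fit_distance_bins(
    stimulus_set: StimulusSet,
    n_bins: int = 3,
    max_pixels_sampled: int = 1_000_000,
    seed: int = 0,
) -> DistanceBins:
    """Fit pooled-quantile distance bins over all valid pixels of a set."""
    depths = np.concatenate(
        [s.depth[s.valid_mask].ravel() for s in stimulus_set.samples]
    )
    if depths.size == 0:
        raise ValueError("no valid depth pixels in the stimulus set")
    if depths.size > max_pixels_sampled:
        rng = np.random.default_rng(seed)
        depths = rng.choice(depths, size=max_pixels_sampled, replace=False)
    qs = np.arange(1, n_bins) / n_bins
    edges = np.quantile(depths, qs)
    if depths.min() == depths.max() or (len(edges) > 1 and np.any(np.diff(edges) <= 0)):
        raise ValueError("constant depth: cannot fit distinct distance bins")
    return DistanceBins(edges=tuple(float(e) for e in edges), n_pixels_used=int(depths.size))


def classify_normals(normals: np.ndarray, tol: float = 1e-3) -> np.ndarray:
    """Vectorized direction-bin classification of unit normals.

    ``normals`` has shape (..., 3) in camera coordinates (x right, y up,
    z toward viewer).  A normal is *forward* iff its angle to +z is at
    most 45 degrees (ties go to forward); otherwise it is assigned by
    the azimuth of (x, y) into eight 45-degree sectors centered on the
    compass directions, with sector boundaries closed on the
    counterclockwise side.
    """
    v = np.asarray(normals, dtype=float)
    norms = np.linalg.norm(v, axis=-1)
    if np.any(norms < 1e-9):
        raise ValueError("zero-length normal vector")
    if np.any(np.abs(norms - 1.0) > tol):
        raise ValueError("normals must be unit length within tolerance")
    unit = v / norms[..., None]
    forward = unit[..., 2] >= _COS45 - 1e-12
    az = np.degrees(np.arctan2(unit[..., 1], unit[..., 0]))  # (-180, 180]
    # Boundaries closed on the counterclockwise side; the tiny epsilon
    # keeps exact boundary angles on their sector despite rounding.
    sector = np.ceil((az - 22.5) / 45.0 - 1e-12).astype(int) % 8
    out = _SECTOR_TO_LABEL[sector]
    out = np.where(forward, 0, out)
    return out


def classify_normal(v) -> int:
    """Direction-bin index (into ``DIRECTION_LABELS``) of one unit vector."""
    return int(classify_normals(np.asarray(v, dtype=float)))


@dataclass
class SurfaceFeatureVector:
    """Proportions per (distance bin x direction bin [x quadrant])."""

    values: np.ndarray
    variant: str  # "global" | "quadrant"
    empty_quadrants: tuple[int, ...] = field(default_factory=tuple)


def _joint_histogram(depth, normals, valid, bins: DistanceBins) -> np.ndarray:
    """Counts over the (n_dist x 9) joint bins for the valid pixels given."""
    d = bins.assign(depth[valid])
    dirs = classify_normals(normals[valid])
    joint = d * len(DIRECTION_LABELS) + dirs
    return np.bincount(joint, minlength=bins.n_bins * len(DIRECTION_LABELS)).astype(float)


def surface_features_global(sample: SceneSample, bins: DistanceBins) -> SurfaceFeatureVector:
    """27 whole-image proportions over (distance x direction) bins."""
    valid = sample.valid_mask
    if not valid.any():
        raise ValueError("sample has no valid pixels")
    counts = _joint_histogram(sample.depth, sample.normals, valid, bins)
    return SurfaceFeatureVector(values=counts / counts.sum(), variant="global")


def _quadrant_slices(h, w):
    h2, w2 = h // 2, w // 2
    # Fixed order: top-left, top-right, bottom-left, bottom-right.  With
    # odd dimensions the boundary row/column goes to the bottom/right.
    return [
        (slice(0, h2), slice(0, w2)),
        (slice(0, h2), slice(w2, w)),
        (slice(h2, h), slice(0, w2)),
        (slice(h2, h), slice(w2, w)),
    ]


def surface_features_quadrant(sample: SceneSample, bins: DistanceBins) -> SurfaceFeatureVector:
    """108 per-quadrant proportions, each quadrant normalized separately.

    Quadrants with no valid pixels yield a zero block and are flagged in
    ``empty_quadrants``.
    """
    h, w = sample.resolution
    blocks = []
    empty = []
    for q, (rs, cs) in enumerate(_quadrant_slices(h, w)):
        valid = sample.valid_mask[rs, cs]
        if not valid.any():
            empty.append(q)
            blocks.append(np.zeros(bins.n_bins * len(DIRECTION_LABELS)))
            continue
        counts = _joint_histogram(sample.depth[rs, cs], sample.normals[rs, cs], valid, bins)
        blocks.append(counts / counts.sum())
    if len(empty) == 4:
        raise ValueError("sample has no valid pixels")
    return SurfaceFeatureVector(
        values=np.concatenate(blocks), variant="quadrant", empty_quadrants=tuple(empty)
    )


def _global_labels(bins: DistanceBins) -> list[str]:
    return [
        f"d{i}_dir{lbl}" for i in range(bins.n_bins) for lbl in DIRECTION_LABELS
    ]


def surface_feature_matrix(
    stimulus_set: StimulusSet, bins: DistanceBins, variant: str = "global"
) -> FeatureMatrix:
    """Surface feature matrix for a stimulus set (rows in id order)."""
    if variant not in ("global", "quadrant"):
        raise ValueError("variant must be 'global' or 'quadrant'")
    rows = []
    any_empty = False
    for sample in stimulus_set.samples:
        if variant == "global":
            fv = surface_features_global(sample, bins)
        else:
            fv = surface_features_quadrant(sample, bins)
            any_empty = any_empty or bool(fv.empty_quadrants)
        rows.append(fv.values)
    if any_empty:
        warnings.warn("some quadrants had no valid pixels (zero feature blocks)", stacklevel=2)
    if variant == "global":
        labels = _global_labels(bins)
        name = "3d-global"
    else:
        labels = [f"q{q}_{lbl}" for q in range(4) for lbl in _global_labels(bins)]
        name = "3d-quadrant"
    fm = FeatureMatrix(
        values=np.asarray(rows),
        model_name=name,
        feature_labels=labels,
        stimulus_ids=list(stimulus_set.stimulus_ids),
    )
    fm.zscored
    return fm
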
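"""Synthetic scenes and synthetic fMRI responses.

This module generates everything the downstream analysis needs without
external data:

* planar indoor-style scenes with ground-truth per-pixel Euclidean
  distance maps and camera-frame surface-normal maps (standing in for
  RGB-D captures of real interiors);
* trial-level voxel responses that are, by construction, linear in a
  chosen feature model plus Gaussian noise, epoched at the TR level so
  that window-averaging, noise ceilings and sliding-window analyses can
  all be exercised against known ground truth;
* per-voxel localizer statistics for ROI selection.

Camera frame convention (used everywhere in the package): x to the
right, y up, z toward the viewer.  Depth is Euclidean distance in
meters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SceneSpecError",
    "PlaneSpec",
    "SceneSpec",
    "SceneSample",
    "StimulusSet",
    "VoxelPopulationSpec",
    "DesignSpec",
    "TrialTable",
    "generate_scene",
    "generate_stimulus_set",
    "default_spec_sampler",
    "simulate_voxel_responses",
    "simulate_localizer_stats",
    "trial_profile",
    "window_noise_variance",
    "noise_sd_for_signal_fraction",
]


class SceneSpecError(ValueError):
    """Raised for invalid scene specifications (overlap / coverage / depth)."""


#: The nine surface-direction labels, in canonical order.  Index 0 is the
#: frontoparallel ("forward") direction; the remainder are the eight
#: compass directions of the image plane (up = +y).
DIRECTION_LABELS = (
    "forward",
    "upward",
    "downward",
    "leftward",
    "rightward",
    "up-left",
    "up-right",
    "down-left",
    "down-right",
)

_S = np.sqrt(0.5)
#: In-image-plane base vector for each direction label (before the
#: toward-viewer tilt applied to non-forward planes).
_BASE_NORMALS = {
    "forward": np.array([0.0, 0.0, 1.0]),
    "upward": np.array([0.0, 1.0, 0.0]),
    "downward": np.array([0.0, -1.0, 0.0]),
    "leftward": np.array([-1.0, 0.0, 0.0]),
    "rightward": np.array([1.0, 0.0, 0.0]),
    "up-left": np.array([-_S, _S, 0.0]),
    "up-right": np.array([_S, _S, 0.0]),
    "down-left": np.array([-_S, -_S, 0.0]),
    "down-right": np.array([_S, -_S, 0.0]),
}

# Depth-gradient direction in image coordinates (d_row, d_col): the depth
# of a slanted plane increases linearly along this direction.  A floor
# ("upward") recedes toward the top of the image; a right wall
# ("leftward", i.e. facing left toward the viewer) recedes toward the
# image center from the right, etc.  Frontoparallel planes are constant.
_DEPTH_GRADIENTS = {
    "forward": (0.0, 0.0),
    "upward": (-1.0, 0.0),
    "downward": (1.0, 0.0),
    "leftward": (0.0, -1.0),
    "rightward": (0.0, 1.0),
    "up-left": (-_S, _S),
    "up-right": (-_S, -_S),
    "down-left": (_S, _S),
    "down-right": (_S, -_S),
}

_LIGHT_DIR = np.array([0.35, 0.75, 0.56])
_LIGHT_DIR = _LIGHT_DIR / np.linalg.norm(_LIGHT_DIR)


@dataclass(frozen=True)
class PlaneSpec:
    """One planar surface of a scene.

    ``region`` is the fractional image rectangle (row0, row1, col0, col1)
    covered by the plane; ``depth_range`` gives (near, far) Euclidean
    distance in meters, interpolated linearly along the direction the
    plane recedes; ``tilt_deg`` tips non-frontoparallel normals toward
    the viewer (must stay below 45 degrees so the direction label is
    preserved under classification).
    """

    direction: str
    region: tuple[float, float, float, float]
    depth_range: tuple[float, float]
    texture_sf: float = 4.0
    texture_contrast: float = 0.15
    tilt_deg: float = 20.0

    def __post_init__(self):
        if self.direction not in _BASE_NORMALS:
            raise SceneSpecError(f"unknown surface direction {self.direction!r}")
        r0, r1, c0, c1 = self.region
        if not (0 <= r0 < r1 <= 1 and 0 <= c0 < c1 <= 1):
            raise SceneSpecError(f"invalid plane region {self.region}")
        if min(self.depth_range) <= 0:
            raise SceneSpecError("plane distances must be strictly positive")
        if self.direction != "forward" and not (0 <= self.tilt_deg < 45):
            raise SceneSpecError("tilt_deg must be in [0, 45) to preserve direction")

    @property
    def normal(self) -> np.ndarray:
        base = _BASE_NORMALS[self.direction]
        if self.direction == "forward":
            return base.copy()
        t = np.deg2rad(self.tilt_deg)
        n = base * np.cos(t) + np.array([0.0, 0.0, 1.0]) * np.sin(t)
        return n / np.linalg.norm(n)


@dataclass(frozen=True)
class SceneSpec:
    """Full specification of one synthetic scene.

    Every pixel must be covered by exactly one plane.  ``mask_seed``
    drives the (spec-determined) invalid-pixel mask, which emulates
    depth-sensor holes; the per-call seed of :func:`generate_scene`
    drives only the luminance texture, so two scenes rendered from the
    same spec share depth, normals and validity exactly.
    """

    resolution: tuple[int, int] = (64, 64)
    planes: tuple[PlaneSpec, ...] = ()
    lighting_gradient: float = 0.12
    invalid_fraction: float = 0.05
    mask_seed: int = 0

    def __post_init__(self):
        h, w = self.resolution
        if h < 32 or w < 32:
            raise SceneSpecError("resolution must be at least 32x32")
        if not self.planes:
            raise SceneSpecError("scene needs at least one plane")
        if not (0 <= self.invalid_fraction < 1):
            raise SceneSpecError("invalid_fraction must be in [0, 1)")


@dataclass
class SceneSample:
    """Rendered scene: luminance image plus ground-truth geometry."""

    image: np.ndarray  # (H, W) luminance in [0, 1]
    depth: np.ndarray  # (H, W) Euclidean distance, meters
    normals: np.ndarray  # (H, W, 3) unit vectors, camera frame
    valid_mask: np.ndarray  # (H, W) bool

    @property
    def resolution(self) -> tuple[int, int]:
        return self.image.shape


@dataclass
class StimulusSet:
    samples: list[SceneSample]
    stimulus_ids: list[str]

    def __post_init__(self):
        if len(self.samples) != len(self.stimulus_ids):
            raise ValueError("samples and stimulus_ids must have equal length")
        if len(set(self.stimulus_ids)) != len(self.stimulus_ids):
            raise ValueError("stimulus ids must be unique")
        if self.samples:
            res = self.samples[0].resolution
            if any(s.resolution != res for s in self.samples):
                raise ValueError("all samples must share one resolution")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def resolution(self) -> tuple[int, int]:
        return self.samples[0].resolution

    def images(self) -> np.ndarray:
        return np.stack([s.image for s in self.samples])

    def subset(self, idx) -> "StimulusSet":
        idx = list(np.asarray(idx))
        return StimulusSet(
            samples=[self.samples[i] for i in idx],
            stimulus_ids=[self.stimulus_ids[i] for i in idx],
        )


def _region_to_pixels(region, resolution):
    h, w = resolution
    r0, r1, c0, c1 = region
    return (
        int(round(r0 * h)),
        int(round(r1 * h)),
        int(round(c0 * w)),
        int(round(c1 * w)),
    )


def _bandpass_noise(rng, resolution, sf):
    """Unit-variance noise band-limited around ``sf`` cycles/image."""
    h, w = resolution
    white = rng.standard_normal((h, w))
    fy = np.fft.fftfreq(h) * h
    fx = np.fft.fftfreq(w) * w
    r = np.hypot(fy[:, None], fx[None, :])
    bw = sf / 3.0 + 0.75
    filt = np.exp(-0.5 * ((r - sf) / bw) ** 2)
    shaped = np.real(np.fft.ifft2(np.fft.fft2(white) * filt))
    sd = shaped.std()
    if sd <= 0:
        return np.zeros((h, w))
    return shaped / sd


def generate_scene(spec: SceneSpec, seed: int) -> SceneSample:
    """Render one scene from its specification.

    Deterministic given ``(spec, seed)``.  Geometry (depth, normals,
    valid mask) depends only on the spec; ``seed`` randomizes texture.
    """
    h, w = spec.resolution
    coverage = np.zeros((h, w), dtype=int)
    depth = np.zeros((h, w))
    normals = np.zeros((h, w, 3))
    image = np.full((h, w), 0.5)

    rng = np.random.default_rng(seed)
    rows = np.arange(h)[:, None] + 0.5
    cols = np.arange(w)[None, :] + 0.5

    for plane in spec.planes:
        r0, r1, c0, c1 = _region_to_pixels(plane.region, spec.resolution)
        if r1 <= r0 or c1 <= c0:
            raise SceneSpecError("plane region collapses to zero pixels")
        sl = (slice(r0, r1), slice(c0, c1))
        coverage[sl] += 1

        # Depth: linear along the plane's recession direction.
        d_near, d_far = plane.depth_range
        g_r, g_c = _DEPTH_GRADIENTS[plane.direction]
        if g_r == 0 and g_c == 0:
            u = np.zeros((r1 - r0, c1 - c0))
            d_far = d_near = 0.5 * (d_near + d_far)
        else:
            proj = g_r * rows[r0:r1] + g_c * cols[:, c0:c1]
            lo, hi = proj.min(), proj.max()
            u = (proj - lo) / (hi - lo) if hi > lo else np.zeros_like(proj)
        depth[sl] = d_near + (d_far - d_near) * u
        normals[sl] = plane.normal

        # Luminance: Lambertian-style base shading + band-limited texture.
        shade = 0.5 + spec.lighting_gradient * float(plane.normal @ _LIGHT_DIR)
        tex = _bandpass_noise(rng, (h, w), plane.texture_sf)
        image[sl] = shade + plane.texture_contrast * tex[sl]

    if np.any(coverage == 0):
        raise SceneSpecError("scene planes leave uncovered pixels")
    if np.any(coverage > 1):
        raise SceneSpecError("scene planes overlap")
    if np.any(depth <= 0):
        raise SceneSpecError("non-positive depth generated")

    mask_rng = np.random.default_rng(spec.mask_seed)
    valid = mask_rng.random((h, w)) >= spec.invalid_fraction

    return SceneSample(
        image=np.clip(image, 0.0, 1.0),
        depth=depth,
        normals=normals,
        valid_mask=valid,
    )


def _split(rng, lo=0.35, hi=0.65):
    return float(rng.uniform(lo, hi))


def default_spec_sampler(rng: np.random.Generator, resolution=(64, 64)) -> SceneSpec:
    """Sample a randomized indoor-style scene layout.

    Layouts mix floors, ceilings, side walls, back walls and slanted
    surfaces with randomized split positions, depth ranges and texture
    bands, so that both surface features and Gabor features vary
    non-degenerately across a sampled set.
    """

    def depth_range():
        near = float(rng.uniform(0.5, 2.0))
        return (near, near + float(rng.uniform(1.0, 6.0)))

    def tex():
        return dict(
            texture_sf=float(rng.choice([2.0, 4.0, 8.0, 16.0])),
            texture_contrast=float(rng.uniform(0.05, 0.25)),
        )

    tilt = float(rng.uniform(8.0, 35.0))
    layout = int(rng.integers(0, 4))
    planes: list[PlaneSpec] = []
    if layout == 0:  # back wall above a floor
        s = _split(rng)
        planes = [
            PlaneSpec("forward", (0.0, s, 0.0, 1.0), depth_range(), **tex()),
            PlaneSpec("upward", (s, 1.0, 0.0, 1.0), depth_range(), tilt_deg=tilt, **tex()),
        ]
    elif layout == 1:  # floor + side wall + back wall
        s = _split(rng)
        c = _split(rng)
        side = "rightward" if rng.random() < 0.5 else "leftward"
        if side == "rightward":  # wall on the left faces right
            wall_region, back_region = (0.0, s, 0.0, c), (0.0, s, c, 1.0)
        else:
            wall_region, back_region = (0.0, s, c, 1.0), (0.0, s, 0.0, c)
        planes = [
            PlaneSpec(side, wall_region, depth_range(), tilt_deg=tilt, **tex()),
            PlaneSpec("forward", back_region, depth_range(), **tex()),
            PlaneSpec("upward", (s, 1.0, 0.0, 1.0), depth_range(), tilt_deg=tilt, **tex()),
        ]
    elif layout == 2:  # corridor: ceiling, two walls around a back wall, floor
        a = _split(rng, 0.15, 0.3)
        b = _split(rng, 0.7, 0.85)
        c0 = _split(rng, 0.2, 0.4)
        c1 = _split(rng, 0.6, 0.8)
        planes = [
            PlaneSpec("downward", (0.0, a, 0.0, 1.0), depth_range(), tilt_deg=tilt, **tex()),
            PlaneSpec("rightward", (a, b, 0.0, c0), depth_range(), tilt_deg=tilt, **tex()),
            PlaneSpec("forward", (a, b, c0, c1), depth_range(), **tex()),
            PlaneSpec("leftward", (a, b, c1, 1.0), depth_range(), tilt_deg=tilt, **tex()),
            PlaneSpec("upward", (b, 1.0, 0.0, 1.0), depth_range(), tilt_deg=tilt, **tex()),
        ]
    else:  # two slanted surfaces meeting at a vertical seam
        c = _split(rng)
        d0, d1 = rng.permutation(["up-right", "up-left"])
        planes = [
            PlaneSpec(str(d0), (0.0, 1.0, 0.0, c), depth_range(), tilt_deg=tilt, **tex()),
            PlaneSpec(str(d1), (0.0, 1.0, c, 1.0), depth_range(), tilt_deg=tilt, **tex()),
        ]
    return SceneSpec(
        resolution=resolution,
        planes=tuple(planes),
        lighting_gradient=float(rng.uniform(0.05, 0.2)),
        invalid_fraction=0.05,
        mask_seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_stimulus_set(
    n: int,
    spec_sampler=None,
    seed: int = 0,
    resolution=(64, 64),
) -> StimulusSet:
    """Generate ``n`` scenes with randomized layouts.

    ``spec_sampler(rng)`` must return a :class:`SceneSpec`; the default
    sampler randomizes layout, depth ranges and textures so feature
    variance across images is non-degenerate.
    """
    if n < 2:
        raise ValueError("a stimulus set needs at least 2 images")
    rng = np.random.default_rng(seed)
    if spec_sampler is None:
        def spec_sampler(r):  # noqa: ANN001
            return default_spec_sampler(r, resolution=resolution)
    samples = []
    for _ in range(n):
        spec = spec_sampler(rng)
        tex_seed = int(rng.integers(0, 2**31 - 1))
        samples.append(generate_scene(spec, seed=tex_seed))
    ids = [f"stim{i:04d}" for i in range(n)]
    first = samples[0]
    if all(
        np.array_equal(s.depth, first.depth) and np.array_equal(s.normals, first.normals)
        for s in samples[1:]
    ):
        warnings.warn(
            "spec sampler produced identical geometry for every image; "
            "3D features will be degenerate",
            stacklevel=2,
        )
    return StimulusSet(samples=samples, stimulus_ids=ids)


# ---------------------------------------------------------------------------
# Voxel response simulation
# ---------------------------------------------------------------------------

POPULATION_LABELS = ("gabor-coded", "3d-global-coded", "3d-quadrant-coded", "mixed", "null")
_POP_MODEL = {
    "gabor-coded": ("gabor",),
    "3d-global-coded": ("3d-global",),
    "3d-quadrant-coded": ("3d-quadrant",),
    "mixed": ("gabor", "3d-global"),
    "null": (),
}


@dataclass(frozen=True)
class VoxelPopulationSpec:
    """A homogeneous population of simulated voxels.

    ``weight_scale`` is the standard deviation of the stimulus-driven
    trial amplitude (the simulator rescales random weights so that the
    realized signal SD over the stimulus set equals it exactly);
    ``noise_sd`` is the SD of the additive Gaussian trial noise.
    """

    n_voxels: int
    label: str
    weight_scale: float = 1.0
    noise_sd: float = 1.0
    weight_seed: int = 0

    def __post_init__(self):
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        if self.label not in POPULATION_LABELS:
            raise ValueError(f"unknown population label {self.label!r}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass(frozen=True)
class DesignSpec:
    """Run/task/trial structure of the simulated experiment.

    Defaults follow the emulated study design: 36 runs alternating
    between two tasks, TR 0.8 s, 12-TR trial epochs, and each stimulus
    repeated 3 times overall.
    """

    n_runs: int = 36
    task_labels: tuple[str, str] = ("scene", "dot")
    repeats_per_stimulus: int = 3
    tr: float = 0.8
    epoch_len_trs: int = 12

    def __post_init__(self):
        if self.n_runs < 2 or self.n_runs % 2 != 0:
            raise ValueError("n_runs must be an even count >= 2")
        if self.repeats_per_stimulus < 1:
            raise ValueError("repeats_per_stimulus must be >= 1")
        if self.tr <= 0 or self.epoch_len_trs < 1:
            raise ValueError("invalid TR / epoch length")

    @property
    def tr_times(self) -> np.ndarray:
        return np.arange(self.epoch_len_trs) * self.tr

    def window_tr_indices(self, window=(2.4, 4.8)) -> np.ndarray:
        t = self.tr_times
        idx = np.nonzero((t >= window[0] - 1e-9) & (t <= window[1] + 1e-9))[0]
        return idx


@dataclass
class TrialTable:
    """Trial-level TR-resolved voxel responses with labels and ground truth."""

    responses: np.ndarray  # (n_trials, epoch_len_trs, n_voxels)
    run_id: np.ndarray  # (n_trials,)
    task_label: np.ndarray  # (n_trials,) str
    stimulus_idx: np.ndarray  # (n_trials,) int row into the stimulus set
    stimulus_id: np.ndarray  # (n_trials,) str
    design: DesignSpec
    voxel_labels: np.ndarray  # (n_voxels,) population label per voxel
    true_weights: dict[str, np.ndarray] = field(default_factory=dict)
    true_signal_sd: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.responses.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.responses.shape[2]


def trial_profile(design: DesignSpec, center: float = 3.6, half_width: float = 2.4) -> np.ndarray:
    """Smooth temporal profile of the injected trial amplitude.

    A raised cosine centered inside the 2.4-4.8 s analysis window,
    normalized so its mean over the window TRs is exactly 1 (the
    window-averaged response of a noiseless trial then equals the trial
    amplitude).
    """
    t = design.tr_times
    p = np.where(
        np.abs(t - center) <= half_width,
        0.5 * (1.0 + np.cos(np.pi * (t - center) / half_width)),
        0.0,
    )
    widx = design.window_tr_indices()
    if len(widx) == 0 or p[widx].mean() <= 0:
        raise ValueError("trial profile does not cover the analysis window")
    return p / p[widx].mean()


def window_noise_variance(noise_sd: float, design: DesignSpec, window=(2.4, 4.8)) -> float:
    """Variance of the window-averaged noise for a given trial ``noise_sd``.

    Trial-amplitude noise passes through the (window-mean-1) profile
    unchanged; independent TR noise of the same SD is averaged over the
    window samples.
    """
    n_win = len(design.window_tr_indices(window))
    return noise_sd**2 * (1.0 + 1.0 / n_win)


def noise_sd_for_signal_fraction(
    fraction: float, signal_sd: float, design: DesignSpec, window=(2.4, 4.8)
) -> float:
    """Trial noise SD giving a target signal-variance fraction.

    Solves ``signal_sd**2 / (signal_sd**2 + window_noise_variance) ==
    fraction`` for the window-averaged responses.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n_win = len(design.window_tr_indices(window))
    target_var = signal_sd**2 * (1.0 - fraction) / fraction
    return float(np.sqrt(target_var / (1.0 + 1.0 / n_win)))


def _population_weights(pop, features_by_model, rng):
    """Per-model weights for one population, rescaled so the realized
    signal SD over the stimulus set equals ``weight_scale``."""
    models = _POP_MODEL[pop.label]
    weights = {}
    if not models:
        return weights, np.zeros(pop.n_voxels)
    share = pop.weight_scale / np.sqrt(len(models))
    for model in models:
        if model not in features_by_model:
            raise ValueError(f"population {pop.label!r} needs features for model {model!r}")
        z = features_by_model[model]
        w = rng.standard_normal((z.shape[1], pop.n_voxels))
        sig = z @ w
        sd = sig.std(axis=0)
        sd[sd <= 0] = 1.0
        weights[model] = w * (share / sd)
    total_sd = np.sqrt(
        sum((features_by_model[m] @ weights[m]).var(axis=0) for m in models)
    )
    return weights, total_sd


def simulate_voxel_responses(
    features_by_model: dict[str, np.ndarray],
    populations: list[VoxelPopulationSpec],
    design: DesignSpec,
    seed: int,
    stimulus_ids: list[str] | None = None,
) -> TrialTable:
    """Simulate a full session of trial-level voxel responses.

    ``features_by_model`` maps model names to z-scored (stimuli x
    features) arrays or :class:`~sceneenc.features.FeatureMatrix`
    objects, all row-aligned to the same stimulus set.  For each voxel,
    the trial amplitude is ``features . weights + N(0, noise_sd)``; the
    amplitude is injected into the epoch with a fixed smooth temporal
    profile peaking inside the 2.4-4.8 s window, with independent
    Gaussian TR noise (same SD) elsewhere in the epoch.
    """
    feats = {}
    for name, f in features_by_model.items():
        feats[name] = f.zscored if hasattr(f, "zscored") else np.asarray(f, dtype=float)
    n_stimuli = {f.shape[0] for f in feats.values()}
    if len(n_stimuli) != 1:
        raise ValueError("feature matrices have mismatched row counts")
    n_stim = n_stimuli.pop()
    if stimulus_ids is None:
        stimulus_ids = [f"stim{i:04d}" for i in range(n_stim)]
    if len(stimulus_ids) != n_stim:
        raise ValueError("stimulus_ids length does not match feature rows")

    n_trials = n_stim * design.repeats_per_stimulus
    if n_trials % design.n_runs != 0:
        raise ValueError(
            f"{n_stim} stimuli x {design.repeats_per_stimulus} repeats does not divide "
            f"evenly into {design.n_runs} runs"
        )
    trials_per_run = n_trials // design.n_runs

    rng = np.random.default_rng(seed)
    order = rng.permutation(np.repeat(np.arange(n_stim), design.repeats_per_stimulus))
    run_id = np.repeat(np.arange(design.n_runs), trials_per_run)
    task_label = np.asarray([design.task_labels[r % 2] for r in run_id])

    n_vox = sum(p.n_voxels for p in populations)
    voxel_labels = np.concatenate([[p.label] * p.n_voxels for p in populations])

    # Per-stimulus signal amplitude per voxel.
    signal = np.zeros((n_stim, n_vox))
    true_weights = {m: np.zeros((n_vox, f.shape[1])) for m, f in feats.items()}
    true_signal_sd = np.zeros(n_vox)
    v0 = 0
    for pop in populations:
        v1 = v0 + pop.n_voxels
        wrng = np.random.default_rng(pop.weight_seed)
        weights, total_sd = _population_weights(pop, feats, wrng)
        for model, w in weights.items():
            signal[:, v0:v1] += feats[model] @ w
            true_weights[model][v0:v1] = w.T
        true_signal_sd[v0:v1] = total_sd
        v0 = v1

    noise_sd = np.concatenate([np.full(p.n_voxels, p.noise_sd) for p in populations])
    amplitude = signal[order] + rng.standard_normal((n_trials, n_vox)) * noise_sd
    profile = trial_profile(design)
    responses = amplitude[:, None, :] * profile[None, :, None]
    responses += rng.standard_normal(responses.shape) * noise_sd

    return TrialTable(
        responses=responses,
        run_id=run_id,
        task_label=task_label,
        stimulus_idx=order,
        stimulus_id=np.asarray([stimulus_ids[i] for i in order]),
        design=design,
        voxel_labels=voxel_labels,
        true_weights=true_weights,
        true_signal_sd=true_signal_sd,
    )


def simulate_localizer_stats(
    populations: list[VoxelPopulationSpec],
    seed: int,
    effect_size: float = 3.0,
) -> np.ndarray:
    """Per-voxel localizer statistic (e.g. a scenes > objects contrast t).

    Signal-carrying populations draw from ``N(effect_size, 1)``; null
    populations from ``N(0, 1)``.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for pop in populations:
        mu = 0.0 if pop.label == "null" else effect_size
        parts.append(rng.standard_normal(pop.n_voxels) + mu)
    return np.concatenate(parts)
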
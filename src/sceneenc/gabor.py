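"""Static Gabor-wavelet pyramid feature model.

The default bank has exactly 300 features built from 5 spatial
frequencies (0, 2, 4, 8 and 16 cycles/image).  The zero-frequency level
is a 2x2 grid of Gaussian local-luminance features; each non-zero
frequency f is tiled by a grid of quadrature Gabor pairs at 4
orientations (0, 45, 90, 135 degrees), with higher frequencies on
smaller tiles (grids of 2, 3, 5 and 6 tiles per side for 2, 4, 8 and 16
cpi): 4 + 4*(4 + 9 + 25 + 36) = 300.

Each feature is the quadrature energy sqrt(even^2 + odd^2) of the
windowed inner products, passed through a compressive log(1 + E)
nonlinearity by default.  Energy features are phase-invariant and
non-negative before z-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix
from .synth import StimulusSet

__all__ = [
    "GaborBankSpec",
    "GaborWavelet",
    "GaborBank",
    "build_gabor_bank",
    "extract_gabor_features",
    "gabor_feature_matrix",
]


@dataclass(frozen=True)
class GaborBankSpec:
    """Configuration of the Gabor pyramid.

    ``grid_sizes[i]`` is the tile-grid edge count for
    ``spatial_frequencies[i]``; the zero-frequency level contributes
    ``grid**2`` Gaussian features, every other level ``4 * grid**2``
    quadrature-energy features (one per orientation).
    """

    spatial_frequencies: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0, 16.0)
    orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    grid_sizes: tuple[int, ...] = (2, 2, 3, 5, 6)
    envelope_ratio: float = 0.25
    nonlinearity: str = "log"  # "log" -> log(1 + E), "magnitude" -> E

    def __post_init__(self):
        if len(self.grid_sizes) != len(self.spatial_frequencies):
            raise ValueError("grid_sizes must align with spatial_frequencies")
        if any(g < 1 for g in self.grid_sizes):
            raise ValueError("grid sizes must be >= 1")
        if self.nonlinearity not in ("log", "magnitude"):
            raise ValueError("nonlinearity must be 'log' or 'magnitude'")
        if self.envelope_ratio <= 0:
            raise ValueError("envelope_ratio must be > 0")

    @property
    def n_features(self) -> int:
        total = 0
        for f, g in zip(self.spatial_frequencies, self.grid_sizes):
            total += g * g if f == 0 else len(self.orientations) * g * g
        return total


@dataclass
class GaborWavelet:
    """One positioned wavelet: a quadrature pair of windowed kernels.

    Kernels are stored on a local patch with image-slice bounds, L2
    normalized, and (for non-zero frequencies) exactly zero-mean.
    """

    frequency: float
    orientation: float
    center: tuple[float, float]  # (row, col) in pixels
    sigma: float
    even: np.ndarray
    odd: np.ndarray
    y0: int
    y1: int
    x0: int
    x1: int
    label: str


@dataclass
class GaborBank:
    wavelets: list[GaborWavelet]
    resolution: tuple[int, int]
    spec: GaborBankSpec = field(default_factory=GaborBankSpec)

    def __len__(self) -> int:
        return len(self.wavelets)

    @property
    def feature_labels(self) -> list[str]:
        return [w.label for w in self.wavelets]


def _make_kernel(h, w, cy, cx, sigma, freq_cpi, theta_deg, resolution):
    """Even/odd kernel patch for one wavelet, plus its slice bounds."""
    H, W = resolution
    half = max(2, int(np.ceil(2.5 * sigma)))
    y0, y1 = max(0, int(np.floor(cy)) - half), min(H, int(np.floor(cy)) + half + 1)
    x0, x1 = max(0, int(np.floor(cx)) - half), min(W, int(np.floor(cx)) + half + 1)
    yy = np.arange(y0, y1)[:, None] + 0.5 - cy
    xx = np.arange(x0, x1)[None, :] + 0.5 - cx
    gauss = np.exp(-(yy**2 + xx**2) / (2.0 * sigma**2))
    if freq_cpi == 0:
        even = gauss / np.linalg.norm(gauss)
        odd = np.zeros_like(gauss)
        return even, odd, y0, y1, x0, x1
    theta = np.deg2rad(theta_deg)
    # Spatial wavelength in pixels; phase advances along the orientation
    # direction (x to the right, y downward in array coordinates, so use
    # -yy for image "up").
    lam = W / freq_cpi
    phase = 2.0 * np.pi * (xx * np.cos(theta) + (-yy) * np.sin(theta)) / lam
    even = gauss * np.cos(phase)
    odd = gauss * np.sin(phase)
    # Enforce exactly zero-mean kernels (project out the envelope's DC).
    even = even - (even.sum() / gauss.sum()) * gauss
    odd = odd - (odd.sum() / gauss.sum()) * gauss
    even /= np.linalg.norm(even)
    odd /= np.linalg.norm(odd)
    return even, odd, y0, y1, x0, x1


def build_gabor_bank(spec: GaborBankSpec, resolution=(64, 64)) -> GaborBank:
    """Construct the positioned wavelets of a Gabor pyramid.

    Tile centers lie on a uniform ``grid x grid`` lattice per frequency
    level; the Gaussian envelope is ``envelope_ratio`` times the tile
    size.
    """
    H, W = resolution
    wavelets: list[GaborWavelet] = []
    for freq, grid in zip(spec.spatial_frequencies, spec.grid_sizes):
        tile_h, tile_w = H / grid, W / grid
        if tile_h < 1 or tile_w < 1:
            raise ValueError(
                f"grid of {grid} implies sub-pixel tiles at resolution {resolution}"
            )
        sigma = spec.envelope_ratio * min(tile_h, tile_w)
        oris = (0.0,) if freq == 0 else spec.orientations
        for iy in range(grid):
            for ix in range(grid):
                cy = (iy + 0.5) * tile_h
                cx = (ix + 0.5) * tile_w
                for ori in oris:
                    even, odd, y0, y1, x0, x1 = _make_kernel(
                        H, W, cy, cx, sigma, freq, ori, resolution
                    )
                    wavelets.append(
                        GaborWavelet(
                            frequency=freq,
                            orientation=ori,
                            center=(cy, cx),
                            sigma=sigma,
                            even=even,
                            odd=odd,
                            y0=y0,
                            y1=y1,
                            x0=x0,
                            x1=x1,
                            label=f"sf{freq:g}_ori{ori:g}_x{ix}_y{iy}",
                        )
                    )
    if len(wavelets) != spec.n_features:
        raise AssertionError("bank size does not match the spec's implied count")
    return GaborBank(wavelets=wavelets, resolution=(H, W), spec=spec)


def _apply_nonlinearity(energy: np.ndarray, kind: str) -> np.ndarray:
    return np.log1p(energy) if kind == "log" else energy


def extract_gabor_features(image: np.ndarray, bank: GaborBank) -> np.ndarray:
    """Feature vector for a single grayscale image."""
    image = np.asarray(image, dtype=float)
    if image.shape != bank.resolution:
        raise ValueError(
            f"image shape {image.shape} does not match bank resolution {bank.resolution}"
        )
    out = np.empty(len(bank))
    for k, wv in enumerate(bank.wavelets):
        patch = image[wv.y0 : wv.y1, wv.x0 : wv.x1]
        e = float((patch * wv.even).sum())
        o = float((patch * wv.odd).sum())
        out[k] = np.hypot(e, o)
    return _apply_nonlinearity(out, bank.spec.nonlinearity)


def gabor_feature_matrix(stimulus_set: StimulusSet, bank: GaborBank) -> FeatureMatrix:
    """Feature matrix for a stimulus set (rows ordered by stimulus ids)."""
    if len(stimulus_set) == 0:
        raise ValueError("empty stimulus set")
    images = stimulus_set.images()
    n = images.shape[0]
    values = np.empty((n, len(bank)))
    for k, wv in enumerate(bank.wavelets):
        patches = images[:, wv.y0 : wv.y1, wv.x0 : wv.x1]
        e = np.tensordot(patches, wv.even, axes=([1, 2], [0, 1]))
        o = np.tensordot(patches, wv.odd, axes=([1, 2], [0, 1]))
        values[:, k] = np.hypot(e, o)
    values = _apply_nonlinearity(values, bank.spec.nonlinearity)
    fm = FeatureMatrix(
        values=values,
        model_name="gabor",
        feature_labels=bank.feature_labels,
        stimulus_ids=list(stimulus_set.stimulus_ids),
    )
    fm.zscored  # materialize z-scoring state
    return fm
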
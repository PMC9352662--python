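"""Synthetic environmental stressor layers on the global grid.

Real pipelines of this kind summarise hundreds of raster layers (climate,
land cover, human footprint, dams, power plants, ...) over species ranges.
Here the layers are generated: some spatially autocorrelated fields (smoothed
white noise), some pure white noise, and some count-like point layers that
play the role of dam / power-plant counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import GridSpec

LAYER_KINDS = ("autocorrelated", "noise", "count-like")


@dataclass
class StressorLayer:
    """A named value grid on the shared GridSpec.

    ``values`` is a float array of shape ``grid.shape``; missing cells are
    NaN.  ``kind`` records how the layer was built: smoothed random field,
    white noise, or a non-negative integer count surface.
    """

    name: str
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.kind == "count-like":
            finite = self.values[np.isfinite(self.values)]
            if np.any(finite < 0) or np.any(finite != np.round(finite)):
                raise ValueError("count-like layer must hold non-negative integers")


def _smooth_field(rng: np.random.Generator, grid: GridSpec, sigma: float) -> np.ndarray:
    field = rng.standard_normal(grid.shape)
    # wrap in longitude (the world is periodic east-west), reflect in latitude
    field = ndimage.gaussian_filter(field, sigma=sigma, mode=("reflect", "wrap"))
    return (field - field.mean()) / field.std()


def generate_stressor_layers(
    grid: GridSpec,
    n_causal: int,
    n_noise: int,
    seed: int,
    smoothing_sigma: float = 6.0,
    missing_fraction: float = 0.0,
) -> list[StressorLayer]:
    """Generate ``n_causal`` autocorrelated plus ``n_noise`` white-noise layers.

    Causal layers (named ``causal_00`` ...) are smoothed seeded white noise,
    standardised to zero mean / unit variance; noise layers (``noise_00`` ...)
    are unsmoothed standard normal fields.  Identical seeds give bit-identical
    layers.  ``missing_fraction`` pokes NaN holes to exercise the
    missing-data path downstream.
    """
    if n_causal < 1:
        raise ValueError("n_causal must be >= 1")
    if n_noise < 0:
        raise ValueError("n_noise must be >= 0")
    rng = np.random.default_rng(seed)
    layers: list[StressorLayer] = []
    for i in range(n_causal):
        values = _smooth_field(rng, grid, smoothing_sigma)
        layers.append(StressorLayer(f"causal_{i:02d}", values, "autocorrelated"))
    for i in range(n_noise):
        values = rng.standard_normal(grid.shape)
        layers.append(StressorLayer(f"noise_{i:02d}", values, "noise"))
    if missing_fraction > 0:
        for layer in layers:
            holes = rng.random(grid.shape) < missing_fraction
            layer.values[holes] = np.nan
    return layers


def generate_count_layers(
    grid: GridSpec,
    seed: int,
    names: tuple[str, ...] = ("dams", "power_plants"),
    mean_rate: float = 0.03,
) -> list[StressorLayer]:
    """Sparse Poisson point-count layers (dam / power-plant analogues)."""
    rng = np.random.default_rng(seed)
    layers = []
    for name in names:
        # hotspot structure: rate varies smoothly so counts cluster
        log_rate = _smooth_field(rng, grid, sigma=8.0)
        rate = mean_rate * np.exp(log_rate)
        counts = rng.poisson(rate).astype(float)
        layers.append(StressorLayer(name, counts, "count-like"))
    return layers


def lag1_autocorrelation(values: np.ndarray) -> float:
    """Moran-style lag-1 spatial autocorrelation on a grid.

    Correlation between each cell and its rook-adjacent neighbours (computed
    as the average of the row-wise and column-wise lag-1 Pearson
    correlations, ignoring NaN).  ~0 for white noise, -> 1 for smooth fields.
    """
    v = np.asarray(values, dtype=float)

    def _corr(a: np.ndarray, b: np.ndarray) -> float:
        ok = np.isfinite(a) & np.isfinite(b)
        a, b = a[ok], b[ok]
        a = a - a.mean()
        b = b - b.mean()
        return float((a * b).sum() / np.sqrt((a**2).sum() * (b**2).sum()))

    horiz = _corr(v[:, :-1].ravel(), v[:, 1:].ravel())
    vert = _corr(v[:-1, :].ravel(), v[1:, :].ravel())
    return 0.5 * (horiz + vert)
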
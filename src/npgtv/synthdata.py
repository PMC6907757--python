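"""Synthetic grayscale phantoms and the additive white Gaussian noise model.

The observation model is ``u0 = u + z`` with ``z`` i.i.d. zero-mean Gaussian.
Noise levels are quoted on the familiar 8-bit gray scale (e.g. sigma = 25
means a standard deviation of 25 gray levels out of 255); images are carried
internally as float arrays in [0, 1], so the noise standard deviation applied
to the pixels is ``sigma / 255``.

Phantoms replace the usual copyrighted benchmark photographs: piecewise
constant images (cartoon-like, the ideal total-variation target), smooth
ramps, and band-limited textures. All generators are seeded and
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NoiseModel", "make_phantom", "add_awgn", "validate_image"]

PHANTOM_KINDS = ("piecewise", "ramp", "texture")


@dataclass(frozen=True)
class NoiseModel:
    """Additive white Gaussian noise, parameterized on the 8-bit scale.

    Parameters
    ----------
    sigma : float
        Noise standard deviation in gray levels (0-255 scale). Internally
        divided by 255 to match unit-range intensities.
    seed : int
        Seed for the pseudo-random generator. Mandatory: every stochastic
        operation in this package must be replayable.
    """

    sigma: float
    seed: int

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"noise sigma must be >= 0, got {self.sigma}")
        if not isinstance(self.seed, (int, np.integer)):
            raise TypeError("seed must be an integer (unseeded noise is rejected)")

    @property
    def sigma_unit(self) -> float:
        """Noise standard deviation on the [0, 1] intensity scale."""
        return float(self.sigma) / 255.0


def validate_image(image: np.ndarray) -> np.ndarray:
    """Check that *image* is a finite 2-D array with values in [0, 1]."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale array, got ndim={arr.ndim}")
    if arr.shape[0] <= 0 or arr.shape[1] <= 0:
        raise ValueError(f"image dimensions must be positive, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("image intensities must lie in [0, 1]")
    return arr


def make_phantom(kind: str, m: int, l: int, num_regions: int = 4, seed: int = 0) -> np.ndarray:
    """Generate a clean m-by-l phantom with intensities in [0, 1].

    Kinds
    -----
    ``piecewise``
        Voronoi tessellation of ``num_regions`` seed points, each cell filled
        with a distinct constant gray level — the cartoon model for which
        total-variation regularization is exact. ``num_regions = 1`` gives a
        constant image.
    ``ramp``
        A smooth diagonal intensity ramp (zero-measure level sets, high TV).
    ``texture``
        A band-limited pseudo-random texture built from a few random
        sinusoids, emulating repetitive fine structure that non-local
        methods are designed to preserve.

    Deterministic for a fixed ``seed``.
    """
    if kind not in PHANTOM_KINDS:
        raise ValueError(f"unknown phantom kind {kind!r}; choose from {PHANTOM_KINDS}")
    if m < 8 or l < 8:
        raise ValueError(f"phantom dimensions must be >= 8, got {m}x{l}")
    if num_regions < 1:
        raise ValueError(f"num_regions must be >= 1, got {num_regions}")

    rng = np.random.default_rng(seed)
    rows, cols = np.mgrid[0:m, 0:l]

    if kind == "piecewise":
        if num_regions == 1:
            return np.full((m, l), 0.5)
        # Voronoi cells of random centers, distinct evenly spaced gray levels.
        centers = np.column_stack(
            [rng.uniform(0, m, size=num_regions), rng.uniform(0, l, size=num_regions)]
        )
        d2 = (rows[..., None] - centers[:, 0]) ** 2 + (cols[..., None] - centers[:, 1]) ** 2
        labels = np.argmin(d2, axis=-1)
        levels = np.linspace(0.1, 0.9, num_regions)
        rng.shuffle(levels)
        return levels[labels]

    if kind == "ramp":
        ramp = (rows / max(m - 1, 1) + cols / max(l - 1, 1)) / 2.0
        return 0.1 + 0.8 * ramp

    # texture: sum of a few random plane waves, rescaled into [0.1, 0.9]
    field = np.zeros((m, l))
    for _ in range(max(num_regions, 3)):
        freq = rng.uniform(0.05, 0.25, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        field += amp * np.sin(2 * np.pi * (freq[0] * rows + freq[1] * cols) + phase)
    lo, hi = field.min(), field.max()
    if hi - lo < 1e-12:
        return np.full((m, l), 0.5)
    return 0.1 + 0.8 * (field - lo) / (hi - lo)


def add_awgn(image: np.ndarray, noise: NoiseModel) -> np.ndarray:
    """Contaminate *image* with seeded additive white Gaussian noise.

    Returns ``clip(image + z, 0, 1)`` with ``z ~ N(0, (sigma/255)^2)`` i.i.d.
    per pixel. Identical ``(image, noise)`` inputs give bit-identical output.
    """
    arr = validate_image(image)
    if noise.sigma == 0:
        return arr.copy()
    rng = np.random.default_rng(noise.seed)
    z = rng.normal(0.0, noise.sigma_unit, size=arr.shape)
    return np.clip(arr + z, 0.0, 1.0)
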
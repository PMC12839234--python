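"""Poisson–Gaussian forward corruption model and frame-averaging levels.

The observation model for a clean image x is

    y_p = (1/α) · Poisson(α · f(x)_p) + ε_p,    ε_p ~ N(0, σ²)

where α > 0 is the photon-to-digital gain, σ ≥ 0 the readout noise
standard deviation on the [0, 1] intensity scale, and f(x) = h ∗ x an
optional point-spread-function blur (identity by default, the usual
assumption for pre-calibrated fluorescence systems).  "Noise level" L
follows the frame-averaging convention of real paired-acquisition
benchmarks: an observation at level L is the mean of L independent
captures, so larger L means *less* noise (variance shrinks by 1/L).

Closed-form first two moments of an un-clipped observation:

    E[y_p]   = f(x)_p
    Var[y_p] = f(x)_p / α + σ²
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve2d

from .phantoms import check_image

DEFAULT_ALPHA = 80.0
DEFAULT_SIGMA = 0.02
NOISE_LEVELS = (1, 2, 4, 8, 16)


@dataclass(frozen=True)
class NoiseParams:
    """Parameters of the forward corruption model."""

    alpha: float = DEFAULT_ALPHA
    sigma: float = DEFAULT_SIGMA
    psf: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha (photon gain) must be positive")
        if self.sigma < 0:
            raise ValueError("sigma (readout std) must be non-negative")
        if self.psf is not None:
            _validate_psf(self.psf)


def _validate_psf(psf: np.ndarray) -> None:
    psf = np.asarray(psf)
    if psf.ndim != 2 or psf.shape[0] != psf.shape[1]:
        raise ValueError("psf must be a square 2D kernel")
    if psf.shape[0] % 2 == 0:
        raise ValueError("psf size must be odd")
    if psf.min() < 0:
        raise ValueError("psf entries must be non-negative")
    if abs(float(psf.sum()) - 1.0) > 1e-9:
        raise ValueError("psf entries must sum to 1")


def apply_forward(clean: np.ndarray, psf: np.ndarray | None = None) -> np.ndarray:
    """f(x) = h ∗ x with zero padding; the identity when no PSF is given."""
    clean = check_image(clean)
    if psf is None:
        return clean.copy()
    _validate_psf(psf)
    out = convolve2d(clean, psf, mode="same", boundary="fill", fillvalue=0.0)
    return np.clip(out, 0.0, 1.0)


def add_poisson_gaussian(
    clean: np.ndarray,
    params: NoiseParams = NoiseParams(),
    seed: int = 0,
    clip: bool = True,
) -> np.ndarray:
    """One noisy capture of ``clean``; deterministic per seed.

    ``clip=False`` returns the raw (possibly out-of-range) observation,
    which is what moment checks must use — clipping biases both moments.
    """
    fx = apply_forward(clean, params.psf)
    rng = np.random.default_rng(seed)
    shot = rng.poisson(params.alpha * fx) / params.alpha
    noisy = shot + rng.normal(0.0, params.sigma, size=fx.shape) if params.sigma > 0 else shot
    return np.clip(noisy, 0.0, 1.0) if clip else noisy


def simulate_level(
    clean: np.ndarray,
    params: NoiseParams = NoiseParams(),
    level: int = 1,
    seed: int = 0,
    clip: bool = True,
) -> np.ndarray:
    """Average of ``level`` independent captures (frame-averaging convention).

    Frame i uses sub-seed ``seed + i``, so level 1 reproduces the single
    capture ``add_poisson_gaussian(clean, params, seed)`` exactly.
    """
    if level < 1:
        raise ValueError("level must be a positive integer")
    acc = np.zeros_like(np.asarray(clean, dtype=np.float64))
    for i in range(level):
        acc += add_poisson_gaussian(clean, params, seed=seed + i, clip=clip)
    mean = acc / level
    return np.clip(mean, 0.0, 1.0) if clip else mean


def noise_moments(clean_value: float, params: NoiseParams) -> tuple[float, float]:
    """Closed-form (mean, variance) of an un-clipped single capture at a
    pixel with clean intensity ``clean_value`` (identity PSF)."""
    if not 0.0 <= clean_value <= 1.0:
        raise ValueError("clean_value must lie in [0, 1]")
    return clean_value, clean_value / params.alpha + params.sigma**2
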
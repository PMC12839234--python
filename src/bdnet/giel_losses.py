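"""Gradient-information-enhanced training objective.

The hybrid loss combines four terms::

    L_total = λ1·L1 + λ2·L2 + λ3·(1 − SSIM) + λg·L_grad

where ``L_grad`` penalises the mean absolute difference between the Sobel
gradient maps of the prediction and the target in both directions.  All
terms use per-pixel MEAN reductions so that the published λ values remain
meaningful at any image size (a sum convention differs only by the constant
pixel count, absorbable into the weights).

Every term is exposed both as a plain value and as ``*_and_grad`` returning
the analytic gradient with respect to the prediction; the training loop
consumes the latter.  Inputs may be single images ``(H, W)`` or batches
``(N, 1, H, W)``; losses average over the batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn.ops import (
    correlate2d_replicate,
    correlate2d_replicate_adjoint,
    correlate2d_valid_separable,
    correlate2d_valid_separable_adjoint,
)

SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float32)
SOBEL_Y = SOBEL_X.T.copy()

# 11-tap Gaussian window, σ = 1.5, the MATLAB-consistent SSIM window
_SSIM_SIGMA = 1.5
_SSIM_RADIUS = 5
_SSIM_C1 = 0.01**2  # (0.01·R)², data range R = 1
_SSIM_C2 = 0.03**2


def _gaussian_window(sigma: float = _SSIM_SIGMA, radius: int = _SSIM_RADIUS) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return (k / k.sum()).astype(np.float64)

_GWIN = _gaussian_window()


@dataclass(frozen=True)
class LossWeights:
    """Mixing coefficients of the hybrid objective."""

    lambda1: float = 1.0  # L1 (mean absolute error)
    lambda2: float = 0.1  # L2 (mean squared error)
    lambda3: float = 0.2  # structural dissimilarity, 1 − SSIM
    lambdag: float = 0.2  # Sobel gradient-consistency term

    def __post_init__(self) -> None:
        if min(self.lambda1, self.lambda2, self.lambda3, self.lambdag) < 0:
            raise ValueError("loss weights must be non-negative")


#: Ablation presets: which terms participate in each studied variant.
ABLATION_PRESETS: dict[str, LossWeights] = {
    "l1": LossWeights(1.0, 0.0, 0.0, 0.0),
    "l2": LossWeights(0.0, 1.0, 0.0, 0.0),
    "l1_ssim": LossWeights(1.0, 0.0, 0.2, 0.0),
    "l1_l2_ssim": LossWeights(1.0, 0.1, 0.2, 0.0),
    "l1_l2_ssim_grad": LossWeights(1.0, 0.1, 0.2, 0.2),
}


def _check_pair(pred: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # float32 inputs (the training path) stay float32; float64 is preserved
    # so that finite-difference verification is not precision-limited
    dtype = np.result_type(np.asarray(pred).dtype, np.float32)
    pred = np.asarray(pred, dtype=dtype)
    target = np.asarray(target, dtype=dtype)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return pred, target


def sobel_gradients(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Horizontal and vertical Sobel gradient maps (replicate padding).

    Replicate padding is used so that a constant image has exactly zero
    response everywhere, including the border.
    """
    image = np.asarray(image, dtype=np.result_type(np.asarray(image).dtype, np.float32))
    if image.shape[-1] < 3 or image.shape[-2] < 3:
        raise ValueError("image must be at least 3×3 for Sobel filtering")
    gx = correlate2d_replicate(image, SOBEL_X)
    gy = correlate2d_replicate(image, SOBEL_Y)
    return gx, gy


def l1_loss(pred: np.ndarray, target: np.ndarray) -> float:
    pred, target = _check_pair(pred, target)
    return float(np.mean(np.abs(pred - target)))


def l1_loss_and_grad(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    pred, target = _check_pair(pred, target)
    d = pred - target
    return float(np.mean(np.abs(d))), np.sign(d) / d.size


def l2_loss(pred: np.ndarray, target: np.ndarray) -> float:
    pred, target = _check_pair(pred, target)
    return float(np.mean((pred - target) ** 2))


def l2_loss_and_grad(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    pred, target = _check_pair(pred, target)
    d = pred - target
    return float(np.mean(d**2)), 2.0 * d / d.size


def gradient_loss(pred: np.ndarray, target: np.ndarray) -> float:
    return gradient_loss_and_grad(pred, target)[0]


def gradient_loss_and_grad(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean |∆gx| + mean |∆gy| between prediction and target Sobel maps."""
    pred, target = _check_pair(pred, target)
    gxp, gyp = sobel_gradients(pred)
    gxt, gyt = sobel_gradients(target)
    dx = gxp - gxt
    dy = gyp - gyt
    value = float(np.mean(np.abs(dx)) + np.mean(np.abs(dy)))
    grad = correlate2d_replicate_adjoint(np.sign(dx) / dx.size, SOBEL_X)
    grad += correlate2d_replicate_adjoint(np.sign(dy) / dy.size, SOBEL_Y)
    return value, grad


def _ssim_maps(pred: np.ndarray, target: np.ndarray):
    """Filtered moment maps and the SSIM map on the valid (cropped) grid."""
    x = pred.astype(np.float64)
    y = target.astype(np.float64)
    ux = correlate2d_valid_separable(x, _GWIN)
    uy = correlate2d_valid_separable(y, _GWIN)
    uxx = correlate2d_valid_separable(x * x, _GWIN)
    uyy = correlate2d_valid_separable(y * y, _GWIN)
    uxy = correlate2d_valid_separable(x * y, _GWIN)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    a1 = 2.0 * ux * uy + _SSIM_C1
    a2 = 2.0 * vxy + _SSIM_C2
    b1 = ux * ux + uy * uy + _SSIM_C1
    b2 = vx + vy + _SSIM_C2
    s = (a1 * a2) / (b1 * b2)
    return x, y, ux, uy, a1, a2, b1, b2, s


def ssim(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean structural similarity, 11×11 Gaussian window σ = 1.5, data range 1.

    Matches the MATLAB-style convention: moment maps are computed where the
    window fits entirely inside the image, then averaged.
    """
    pred, target = _check_pair(pred, target)
    win = 2 * _SSIM_RADIUS + 1
    if pred.shape[-1] < win or pred.shape[-2] < win:
        raise ValueError(f"image must be at least {win}×{win} for SSIM")
    return float(_ssim_maps(pred, target)[-1].mean())


def ssim_loss(pred: np.ndarray, target: np.ndarray) -> float:
    return 1.0 - ssim(pred, target)


def ssim_loss_and_grad(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    pred, target = _check_pair(pred, target)
    win = 2 * _SSIM_RADIUS + 1
    if pred.shape[-1] < win or pred.shape[-2] < win:
        raise ValueError(f"image must be at least {win}×{win} for SSIM")
    x, y, ux, uy, a1, a2, b1, b2, s = _ssim_maps(pred, target)
    m = s.size
    h, w = pred.shape[-2], pred.shape[-1]
    # dL/dS = -1/m for L = 1 - mean(S); chain through the five moment maps
    dS = np.full_like(s, -1.0 / m)
    inv_d = 1.0 / (b1 * b2)
    dA1 = dS * a2 * inv_d
    dA2 = dS * a1 * inv_d
    dB1 = -dS * s / b1
    dB2 = -dS * s / b2
    # a1 = 2 ux uy + C1; a2 = 2(uxy - ux uy) + C2; b1 = ux²+uy²+C1; b2 = (uxx-ux²)+(uyy-uy²)+C2
    dux = 2.0 * uy * dA1 - 2.0 * uy * dA2 + 2.0 * ux * dB1 - 2.0 * ux * dB2
    duxx = dB2
    duxy = 2.0 * dA2
    grad = correlate2d_valid_separable_adjoint(dux, _GWIN, h, w)
    grad += 2.0 * x * correlate2d_valid_separable_adjoint(duxx, _GWIN, h, w)
    grad += y * correlate2d_valid_separable_adjoint(duxy, _GWIN, h, w)
    value = 1.0 - float(s.mean())
    return value, grad.astype(pred.dtype)


def total_loss(pred: np.ndarray, target: np.ndarray,
               weights: LossWeights = LossWeights()) -> float:
    return total_loss_and_grad(pred, target, weights)[0]


def total_loss_and_grad(
    pred: np.ndarray, target: np.ndarray, weights: LossWeights = LossWeights()
) -> tuple[float, np.ndarray]:
    """λ1·L1 + λ2·L2 + λ3·(1−SSIM) + λg·L_grad; terms with zero weight are
    skipped entirely (enabling the loss-ablation variants)."""
    pred, target = _check_pair(pred, target)
    total = 0.0
    grad = np.zeros_like(pred, dtype=np.float64)
    if weights.lambda1 > 0:
        v, g = l1_loss_and_grad(pred, target)
        total += weights.lambda1 * v
        grad += weights.lambda1 * g
    if weights.lambda2 > 0:
        v, g = l2_loss_and_grad(pred, target)
        total += weights.lambda2 * v
        grad += weights.lambda2 * g
    if weights.lambda3 > 0:
        v, g = ssim_loss_and_grad(pred, target)
        total += weights.lambda3 * v
        grad += weights.lambda3 * g
    if weights.lambdag > 0:
        v, g = gradient_loss_and_grad(pred, target)
        total += weights.lambdag * v
        grad += weights.lambdag * g
    return float(total), grad.astype(pred.dtype)
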
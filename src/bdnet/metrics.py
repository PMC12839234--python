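"""Evaluation protocol: PSNR, RMSE and SSIM on [0, 1] data, optional
learned-perceptual distance, and an informational throughput probe."""

from __future__ import annotations

import math
import time
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .giel_losses import ssim as _ssim


@dataclass
class MetricsReport:
    """Per-image or set-averaged quality metrics.

    ``psnr`` is +inf for identical images (serialized as the string
    ``"inf"``); ``lpips`` is ``None`` when no perceptual backbone is
    available.
    """

    psnr: float
    rmse: float
    ssim: float
    lpips: float | None = None
    n_images: int = 1

    def to_dict(self) -> dict:
        return {
            "psnr": "inf" if math.isinf(self.psnr) else self.psnr,
            "rmse": self.rmse,
            "ssim": self.ssim,
            "lpips": self.lpips,
            "n_images": self.n_images,
        }


def _check(pred: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    return pred, ref


def rmse(pred: np.ndarray, ref: np.ndarray) -> float:
    """Root-mean-square per-pixel reconstruction error."""
    pred, ref = _check(pred, ref)
    return float(np.sqrt(np.mean((pred - ref) ** 2)))


def psnr(pred: np.ndarray, ref: np.ndarray) -> float:
    """10·log10(1/MSE) dB with data range 1; +inf for identical images."""
    pred, ref = _check(pred, ref)
    mse = float(np.mean((pred - ref) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(1.0 / mse)


def ssim_metric(pred: np.ndarray, ref: np.ndarray) -> float:
    """Structural similarity; shares the loss module's implementation."""
    return _ssim(pred, ref)


def lpips_optional(
    pred: np.ndarray,
    ref: np.ndarray,
    backbone: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> float | None:
    """Learned perceptual distance, if a pretrained backbone is supplied.

    The backbone receives two ``(3, H, W)`` arrays in [0, 1] (grayscale
    replicated across three channels, matching the convention for
    single-channel micrographs).  Without a backbone the metric is simply
    unavailable and ``None`` is returned — the rest of the report is
    unaffected.
    """
    pred, ref = _check(pred, ref)
    if backbone is None:
        return None

    def to3(a: np.ndarray) -> np.ndarray:
        if a.ndim == 2:
            return np.repeat(a[None], 3, axis=0)
        if a.ndim == 3 and a.shape[0] == 1:
            return np.repeat(a, 3, axis=0)
        if a.ndim == 3 and a.shape[0] == 3:
            return a
        raise ValueError(f"cannot interpret shape {a.shape} as an image")

    return float(backbone(to3(pred), to3(ref)))


def compute_report(
    pred: np.ndarray,
    ref: np.ndarray,
    backbone: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> MetricsReport:
    return MetricsReport(
        psnr=psnr(pred, ref),
        rmse=rmse(pred, ref),
        ssim=ssim_metric(pred, ref),
        lpips=lpips_optional(pred, ref, backbone),
        n_images=1,
    )


def average_reports(reports: Sequence[MetricsReport]) -> MetricsReport:
    """Arithmetic per-image mean; lpips averaged only if present everywhere."""
    if not reports:
        raise ValueError("cannot average an empty list of reports")
    lp = [r.lpips for r in reports]
    return MetricsReport(
        psnr=float(np.mean([r.psnr for r in reports])),
        rmse=float(np.mean([r.rmse for r in reports])),
        ssim=float(np.mean([r.ssim for r in reports])),
        lpips=float(np.mean(lp)) if all(v is not None for v in lp) else None,
        n_images=sum(r.n_images for r in reports),
    )


def timing_report(
    network,
    image_size: tuple[int, int] = (512, 512),
    n_warmup: int = 50,
    n_runs: int = 500,
    seed: int = 0,
) -> float:
    """Frames per second of single-image inference on the current hardware.

    Informational only — the number depends entirely on the machine it runs
    on and is never part of any quality claim.  Warm-up passes are excluded
    from the average.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if n_warmup < 0:
        raise ValueError("n_warmup must be >= 0")
    rng = np.random.default_rng(seed)
    x = rng.random((1, 1, *image_size), dtype=np.float32)
    network.eval()
    for _ in range(n_warmup):
        network.forward(x)
    start = time.perf_counter()
    for _ in range(n_runs):
        network.forward(x)
    elapsed = time.perf_counter() - start
    return n_runs / elapsed
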
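"""Supervised training loop, evaluation, and single-image inference.

The objective is the empirical risk (1/N) Σ L(F_θ(y_i), x_i) over paired
noisy/clean images, minimised with AdamW under a step learning-rate
schedule and global gradient-norm clipping.  Default protocol values are
the config defaults: lr 1e-3 decayed ×0.2 every 1500 iterations, weight
decay 1e-4, β = (0.9, 0.999), batch size 30, clip norm 1.0, seeds
{2025, 2026, 2027}, flips-only augmentation applied on the fly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from ._nn import AdamW, StepLR, clip_grad_norm
from .bdnet_arch import BDNet
from .giel_losses import LossWeights, total_loss_and_grad
from .metrics import MetricsReport, average_reports, compute_report
from .phantoms import PairedSample, apply_flip

DEFAULT_SEEDS = (2025, 2026, 2027)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    step_size: int = 1500  # StepLR period, in iterations
    decay_factor: float = 0.2
    batch_size: int = 30
    max_iterations: int = 2500
    clip_norm: float = 1.0
    seed: int = DEFAULT_SEEDS[0]
    split: tuple[float, float, float] = (0.7, 0.1, 0.2)
    val_interval: int = 100

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.decay_factor <= 0:
            raise ValueError("rates and factors must be positive")
        if self.decay_factor >= 1:
            raise ValueError("decay_factor must be < 1")
        if self.batch_size < 1 or self.max_iterations < 1 or self.step_size < 1:
            raise ValueError("batch_size, max_iterations and step_size must be >= 1")


@dataclass
class TrainingHistory:
    """Per-iteration traces and periodic validation reports."""

    losses: list[float] = field(default_factory=list)
    lrs: list[float] = field(default_factory=list)
    grad_norms: list[float] = field(default_factory=list)  # pre-clip global norms
    val_iterations: list[int] = field(default_factory=list)
    val_reports: list[MetricsReport] = field(default_factory=list)
    best_val_psnr: float = -np.inf
    best_iteration: int = -1


def _stack_batch(pairs: list[PairedSample], rng: np.random.Generator):
    noisy = np.empty((len(pairs), 1) + pairs[0].noisy.shape, dtype=np.float32)
    clean = np.empty_like(noisy)
    for i, pair in enumerate(pairs):
        flipped = apply_flip(pair, int(rng.integers(0, 4)))
        noisy[i, 0] = flipped.noisy
        clean[i, 0] = flipped.clean
    return noisy, clean


def train(
    network: BDNet,
    train_pairs: list[PairedSample],
    val_pairs: list[PairedSample] | None = None,
    config: TrainConfig = TrainConfig(),
    weights: LossWeights = LossWeights(),
) -> tuple[BDNet, TrainingHistory]:
    """Optimise ``network`` in place; returns it with the best-validation
    checkpoint restored (when a validation set is given) and the history."""
    if not train_pairs:
        raise ValueError("training set must not be empty")
    shapes = {p.noisy.shape for p in train_pairs}
    if len(shapes) != 1:
        raise ValueError(f"all training pairs must share one shape, got {shapes}")
    rng = np.random.default_rng(config.seed)
    optimizer = AdamW(
        network.parameters(),
        lr=config.learning_rate,
        betas=config.betas,
        weight_decay=config.weight_decay,
    )
    scheduler = StepLR(optimizer, config.step_size, config.decay_factor)
    history = TrainingHistory()
    best_state: dict | None = None

    n = len(train_pairs)
    order = rng.permutation(n)
    cursor = 0
    network.train()
    for iteration in range(config.max_iterations):
        batch_idx = []
        while len(batch_idx) < config.batch_size:
            if cursor == n:
                order = rng.permutation(n)
                cursor = 0
            batch_idx.append(int(order[cursor]))
            cursor += 1
        noisy, clean = _stack_batch([train_pairs[i] for i in batch_idx], rng)

        lr = scheduler.set_iteration(iteration)
        pred = network.forward(noisy)
        loss, grad = total_loss_and_grad(pred, clean, weights)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged: non-finite loss {loss!r} at iteration {iteration}"
            )
        network.zero_grad()
        network.backward(grad)
        history.grad_norms.append(clip_grad_norm(network.parameters(), config.clip_norm))
        optimizer.step()
        history.losses.append(loss)
        history.lrs.append(lr)

        last = iteration == config.max_iterations - 1
        if val_pairs and ((iteration + 1) % config.val_interval == 0 or last):
            report = evaluate(network, val_pairs)
            network.train()
            history.val_iterations.append(iteration + 1)
            history.val_reports.append(report)
            if report.psnr > history.best_val_psnr:
                history.best_val_psnr = report.psnr
                history.best_iteration = iteration + 1
                best_state = copy.deepcopy(network.state_dict())

    if best_state is not None:
        network.load_state_dict(best_state)
    network.eval()
    return network, history


def denoise_image(network: BDNet, noisy: np.ndarray) -> np.ndarray:
    """Denoise one image of any size ≥ 8×8: reflect-pad to a multiple of the
    network's downsampling factor, forward in inference mode, crop back."""
    noisy = np.asarray(noisy, dtype=np.float32)
    if noisy.ndim != 2:
        raise ValueError("denoise_image expects a single 2D image")
    h, w = noisy.shape
    f = network.spec.downsample_factor
    ph = (-h) % f
    pw = (-w) % f
    x = np.pad(noisy, ((0, ph), (0, pw)), mode="reflect") if (ph or pw) else noisy
    network.eval()
    out = network.forward(x[None, None])[0, 0]
    return np.clip(out[:h, :w], 0.0, 1.0)


def evaluate(network: BDNet, pairs: list[PairedSample], backbone=None) -> MetricsReport:
    """Denoise every pair and average the per-image metric reports."""
    if not pairs:
        raise ValueError("evaluation set must not be empty")
    reports = [
        compute_report(denoise_image(network, p.noisy), p.clean, backbone) for p in pairs
    ]
    return average_reports(reports)
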
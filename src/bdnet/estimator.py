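"""scikit-learn style estimator wrapping the denoiser end to end.

``BDNetDenoiser`` follows the estimator protocol (``get_params`` /
``set_params`` / ``fit`` / ``transform``), so it composes with sklearn
pipelines and model selection.  ``X`` is a stack of noisy images of shape
``(n_images, H, W)`` in [0, 1]; ``y`` is the matching stack of clean
references.  ``transform`` (alias ``predict``) denoises a stack of any
image size ≥ 8×8.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .bdnet_arch import NetworkSpec, build_network, count_parameters
from .giel_losses import LossWeights
from .phantoms import PairedSample
from .training import TrainConfig, denoise_image, evaluate, train


class BDNetDenoiser(TransformerMixin, BaseEstimator):
    """Supervised image denoiser (encoder–decoder CNN with bottleneck CBAM,
    trained with the gradient-information-enhanced hybrid loss).

    Parameters
    ----------
    attention:
        "none" | "channel" | "spatial" | "full" — which bottleneck
        attention sublayers to build.
    lambda1, lambda2, lambda3, lambdag:
        Weights of the L1, L2, (1 − SSIM) and Sobel-gradient loss terms.
    learning_rate, weight_decay, step_size, decay_factor, batch_size,
    max_iterations, clip_norm, val_interval:
        Optimiser protocol (AdamW + StepLR + gradient clipping).
    val_fraction:
        Fraction of the training stack held out for checkpoint selection
        (best validation PSNR); 0 disables validation.
    random_state:
        Seeds initialization, data order and augmentation.

    Attributes
    ----------
    network_ : the trained network
    history_ : per-iteration losses, learning rates, validation reports
    n_parameters_ : learnable parameter count
    """

    def __init__(
        self,
        attention: str = "full",
        lambda1: float = 1.0,
        lambda2: float = 0.1,
        lambda3: float = 0.2,
        lambdag: float = 0.2,
        learning_rate: float = 1e-3,
        weight_decay: float = 1e-4,
        step_size: int = 1500,
        decay_factor: float = 0.2,
        batch_size: int = 30,
        max_iterations: int = 2500,
        clip_norm: float = 1.0,
        val_fraction: float = 0.1,
        val_interval: int = 100,
        random_state: int = 2025,
    ):
        self.attention = attention
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.lambda3 = lambda3
        self.lambdag = lambdag
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.step_size = step_size
        self.decay_factor = decay_factor
        self.batch_size = batch_size
        self.max_iterations = max_iterations
        self.clip_norm = clip_norm
        self.val_fraction = val_fraction
        self.val_interval = val_interval
        self.random_state = random_state

    def _loss_weights(self) -> LossWeights:
        return LossWeights(self.lambda1, self.lambda2, self.lambda3, self.lambdag)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            step_size=self.step_size,
            decay_factor=self.decay_factor,
            batch_size=self.batch_size,
            max_iterations=self.max_iterations,
            clip_norm=self.clip_norm,
            seed=self.random_state,
            val_interval=self.val_interval,
        )

    @staticmethod
    def _check_stack(X: np.ndarray, name: str) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError(f"{name} must have shape (n_images, H, W), got {X.shape}")
        if X.min() < 0 or X.max() > 1:
            raise ValueError(f"{name} values must lie in [0, 1]")
        return X

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BDNetDenoiser":
        X = self._check_stack(X, "X")
        y = self._check_stack(y, "y")
        if X.shape != y.shape:
            raise ValueError(f"X and y must match, got {X.shape} vs {y.shape}")
        pairs = [PairedSample(noisy, clean) for noisy, clean in zip(X, y)]
        n_val = int(round(self.val_fraction * len(pairs)))
        rng = np.random.default_rng(self.random_state)
        order = rng.permutation(len(pairs))
        val_pairs = [pairs[i] for i in order[:n_val]]
        train_pairs = [pairs[i] for i in order[n_val:]]
        spec = NetworkSpec(attention=self.attention)
        network = build_network(spec, seed=self.random_state)
        self.network_, self.history_ = train(
            network, train_pairs, val_pairs, self._train_config(), self._loss_weights()
        )
        self.n_parameters_ = count_parameters(self.network_)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self)
        X = self._check_stack(X, "X")
        return np.stack([denoise_image(self.network_, img) for img in X])

    predict = transform

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        """Mean PSNR (dB) of the denoised images against the references."""
        check_is_fitted(self)
        X = self._check_stack(X, "X")
        y = self._check_stack(y, "y")
        pairs = [PairedSample(noisy, clean) for noisy, clean in zip(X, y)]
        return evaluate(self.network_, pairs).psnr
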
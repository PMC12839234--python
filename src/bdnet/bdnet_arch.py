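"""Lightweight encoder–bottleneck–decoder denoiser with bottleneck CBAM.

The network maps a single-channel image in [0, 1] to a denoised image of
the same size.  Four encoder blocks (Conv 3×3 → BatchNorm → ReLU, strides
2, 2, 1, 1) take the input from 1 to 256 channels while downsampling by 4;
a convolutional block attention module (CBAM: channel attention then
spatial attention) re-weights the bottleneck features; the decoder restores
resolution with a 3×3 convolution and two stride-2 transposed convolutions,
and a final convolution produces the residual-corrected output.  Three skip
connections carry raw texture (three 3×3 convs on the input), and early
encoder features (1×1 channel-matching convs) into the decoder by
element-wise addition.

For a 512×512 input the stage sizes are::

    input   512×512×1
    enc1    256×256×32     enc2  128×128×64
    enc3    128×128×128    enc4  128×128×256
    CBAM    128×128×256
    conv5   128×128×128  (+ skip3: 1×1 conv of enc2)
    tconv1  256×256×64   (+ skip2: 1×1 conv of enc1)
    tconv2  512×512×32
    conv6   512×512×1    (+ skip1: 3×3 conv chain on the input)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import BatchNorm2d, Conv2d, ConvTranspose2d, Module, Parameter, ReLU, Sequential

_ATTENTION_VARIANTS = ("none", "channel", "spatial", "full")


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters; the defaults define the reference architecture."""

    encoder_channels: tuple[int, ...] = (32, 64, 128, 256)
    encoder_strides: tuple[int, ...] = (2, 2, 1, 1)
    encoder_kernel: int = 3
    cbam_reduction: int = 16
    cbam_spatial_kernel: int = 7
    decoder_channels: tuple[int, ...] = (128, 64, 32)
    output_channels: int = 1
    final_kernel: int = 3  # the reference description is ambiguous (1×1 vs 3×3)
    attention: str = "full"  # none | channel | spatial | full

    def __post_init__(self) -> None:
        if len(self.encoder_channels) != len(self.encoder_strides):
            raise ValueError("encoder_channels and encoder_strides must align")
        if any(c <= 0 for c in self.encoder_channels + self.decoder_channels):
            raise ValueError("channel counts must be positive")
        if self.attention not in _ATTENTION_VARIANTS:
            raise ValueError(f"attention must be one of {_ATTENTION_VARIANTS}")
        bottleneck = self.encoder_channels[-1]
        if self.attention in ("channel", "full") and bottleneck % self.cbam_reduction:
            raise ValueError(
                f"cbam_reduction {self.cbam_reduction} must divide the bottleneck "
                f"channel count {bottleneck}"
            )
        if self.final_kernel not in (1, 3):
            raise ValueError("final_kernel must be 1 or 3")
        stride_product = int(np.prod(self.encoder_strides))
        if stride_product != 4:
            raise ValueError("encoder must downsample by exactly 4 (two stride-2 stages)")

    @property
    def downsample_factor(self) -> int:
        return int(np.prod(self.encoder_strides))


class ChannelAttention(Module):
    """Squeeze both global average- and max-pooled vectors through a shared
    bottleneck MLP (C → C/r → C, no bias) and gate channels with a sigmoid."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        if channels % reduction:
            raise ValueError("reduction ratio must divide the channel count")
        hidden = channels // reduction
        bound1 = np.sqrt(6.0 / channels)
        bound2 = np.sqrt(6.0 / hidden)
        self.w1 = Parameter(rng.uniform(-bound1, bound1, size=(hidden, channels)))
        self.w2 = Parameter(rng.uniform(-bound2, bound2, size=(channels, hidden)))
        self._cache: tuple | None = None

    def weights(self, x: np.ndarray) -> np.ndarray:
        """Per-channel gates in (0, 1), shape (N, C); caches for backward."""
        n, c, h, w = x.shape
        avg = x.mean(axis=(2, 3))
        flat = x.reshape(n, c, -1)
        arg = flat.argmax(axis=2)
        mx = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]
        h_avg = avg @ self.w1.data.T
        h_max = mx @ self.w1.data.T
        a = np.maximum(h_avg, 0.0) @ self.w2.data.T + np.maximum(h_max, 0.0) @ self.w2.data.T
        s = 1.0 / (1.0 + np.exp(-a))
        if self.training:
            self._cache = (x, avg, mx, h_avg, h_max, arg, s)
        return s.astype(np.float32, copy=False)

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.weights(x)
        return x * s[:, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, avg, mx, h_avg, h_max, arg, s = self._cache
        n, c, h, w = x.shape
        dx = grad * s[:, :, None, None]
        ds = (grad * x).sum(axis=(2, 3))
        da = ds * s * (1.0 - s)
        # two pooled branches through the shared MLP
        dh_avg = (da @ self.w2.data) * (h_avg > 0)
        dh_max = (da @ self.w2.data) * (h_max > 0)
        self.w2.grad += da.T @ (np.maximum(h_avg, 0.0) + np.maximum(h_max, 0.0))
        self.w1.grad += dh_avg.T @ avg + dh_max.T @ mx
        davg = dh_avg @ self.w1.data
        dmx = dh_max @ self.w1.data
        dx += (davg / (h * w))[:, :, None, None]
        dflat = np.zeros((n, c, h * w), dtype=grad.dtype)
        np.put_along_axis(dflat, arg[:, :, None], dmx[:, :, None], axis=2)
        dx += dflat.reshape(n, c, h, w)
        return dx


class SpatialAttention(Module):
    """Concatenate the channel-wise mean and max maps, convolve (k×k, default
    7×7), and gate every spatial location with a sigmoid."""

    def __init__(self, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("spatial attention kernel must be odd")
        self.conv = Conv2d(2, 1, kernel, stride=1, padding=kernel // 2, bias=True, rng=rng)
        self._cache: tuple | None = None

    def weights(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel gates in (0, 1), shape (N, 1, H, W); caches for backward."""
        n, c, h, w = x.shape
        avg = x.mean(axis=1, keepdims=True)
        arg = x.argmax(axis=1)
        mx = np.take_along_axis(x, arg[:, None, :, :], axis=1)
        a = self.conv(np.concatenate([avg, mx], axis=1))
        s = 1.0 / (1.0 + np.exp(-a))
        if self.training:
            self._cache = (x, arg, s)
        return s.astype(np.float32, copy=False)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x * self.weights(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, arg, s = self._cache
        n, c, h, w = x.shape
        dx = grad * s
        ds = (grad * x).sum(axis=1, keepdims=True)
        da = ds * s * (1.0 - s)
        dcat = self.conv.backward(da)
        dx += dcat[:, :1] / c
        dmax = np.zeros_like(x)
        np.put_along_axis(dmax, arg[:, None, :, :], dcat[:, 1:2], axis=1)
        dx += dmax
        return dx


class CBAM(Module):
    def __init__(self, channels: int, reduction: int, spatial_kernel: int, variant: str,
                 rng: np.random.Generator):
        super().__init__()
        self.variant = variant
        self.channel = (
            ChannelAttention(channels, reduction, rng) if variant in ("channel", "full") else None
        )
        self.spatial = (
            SpatialAttention(spatial_kernel, rng) if variant in ("spatial", "full") else None
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.channel is not None:
            x = self.channel(x)
        if self.spatial is not None:
            x = self.spatial(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.spatial is not None:
            grad = self.spatial.backward(grad)
        if self.channel is not None:
            grad = self.channel.backward(grad)
        return grad


def _conv_block(cin: int, cout: int, k: int, stride: int, rng: np.random.Generator) -> Sequential:
    return Sequential(
        Conv2d(cin, cout, k, stride=stride, padding=k // 2, rng=rng),
        BatchNorm2d(cout),
        ReLU(),
    )


def _tconv_block(cin: int, cout: int, rng: np.random.Generator) -> Sequential:
    return Sequential(
        ConvTranspose2d(cin, cout, 3, stride=2, padding=1, output_padding=1, rng=rng),
        BatchNorm2d(cout),
        ReLU(),
    )


class BDNet(Module):
    """The denoiser.  In eval mode the output is clamped to [0, 1]; in
    training mode the raw linear output is returned so the loss sees
    gradients everywhere (the clamp is the deployment-time range guarantee)."""

    def __init__(self, spec: NetworkSpec | None = None, seed: int = 0):
        super().__init__()
        spec = spec or NetworkSpec()
        self.spec = spec
        rng = np.random.default_rng(seed)
        c1, c2, c3, c4 = spec.encoder_channels
        s1, s2, s3, s4 = spec.encoder_strides
        k = spec.encoder_kernel
        d1, d2, d3 = spec.decoder_channels
        self.enc1 = _conv_block(1, c1, k, s1, rng)
        self.enc2 = _conv_block(c1, c2, k, s2, rng)
        self.enc3 = _conv_block(c2, c3, k, s3, rng)
        self.enc4 = _conv_block(c3, c4, k, s4, rng)
        self.cbam = CBAM(c4, spec.cbam_reduction, spec.cbam_spatial_kernel, spec.attention, rng)
        self.conv5 = _conv_block(c4, d1, k, 1, rng)
        self.tconv1 = _tconv_block(d1, d2, rng)
        self.tconv2 = _tconv_block(d2, d3, rng)
        fk = spec.final_kernel
        self.conv6 = Conv2d(d3, spec.output_channels, fk, stride=1, padding=fk // 2, rng=rng)
        self.skip1 = Sequential(
            Conv2d(1, 1, 3, stride=1, padding=1, rng=rng),
            Conv2d(1, 1, 3, stride=1, padding=1, rng=rng),
            Conv2d(1, 1, 3, stride=1, padding=1, rng=rng),
        )
        self.skip2 = Conv2d(c1, d2, 1, rng=rng)
        self.skip3 = Conv2d(c2, d1, 1, rng=rng)
        self._init_identity_residual()

    def _init_identity_residual(self) -> None:
        """Start as the identity mapping: the raw-texture skip chain is a
        delta-kernel identity and the final conv is zero, so the untrained
        network reproduces its input and optimisation learns the denoising
        correction (zero-init residual branch; the final conv's weight
        gradient is nonzero, so the main path engages from step one)."""
        for conv in self.skip1.layers:
            conv.weight.data[...] = 0.0
            conv.weight.data[0, 0, conv.kernel_size // 2, conv.kernel_size // 2] = 1.0
            conv.bias.data[...] = 0.0
        self.conv6.weight.data[...] = 0.0
        self.conv6.bias.data[...] = 0.0

    # ------------------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected (N, 1, H, W) input, got {x.shape}")
        f = self.spec.downsample_factor
        if x.shape[2] % f or x.shape[3] % f:
            raise ValueError(
                f"spatial dims {x.shape[2:]} must be divisible by {f}; "
                "use denoise_image() for automatic padding"
            )
        x = np.ascontiguousarray(x, dtype=np.float32)
        f1 = self.enc1(x)
        f2 = self.enc2(f1)
        f3 = self.enc3(f2)
        f4 = self.enc4(f3)
        fc = self.cbam(f4)
        d = self.conv5(fc) + self.skip3(f2)
        d = self.tconv1(d) + self.skip2(f1)
        d = self.tconv2(d)
        out = self.conv6(d) + self.skip1(x)
        if not self.training:
            out = np.clip(out, 0.0, 1.0)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dx = self.skip1.backward(grad)
        d = self.conv6.backward(grad)
        d = self.tconv2.backward(d)
        df1 = self.skip2.backward(d)
        d = self.tconv1.backward(d)
        df2 = self.skip3.backward(d)
        d = self.conv5.backward(d)
        d = self.cbam.backward(d)
        d = self.enc4.backward(d)
        d = self.enc3.backward(d)
        d = self.enc2.backward(d + df2)
        d = self.enc1.backward(d + df1)
        return dx + d

    # ------------------------------------------------------------------
    def shape_ledger(self, height: int = 512, width: int = 512) -> list[dict]:
        """Per-stage (input size, output size, channels) table for a square
        input, mirroring the published implementation table."""
        if height != width:
            raise ValueError("the ledger is defined for square inputs")
        c1, c2, c3, c4 = self.spec.encoder_channels
        d1, d2, d3 = self.spec.decoder_channels
        s = height
        rows = []

        def row(name, size_in, size_out, channels):
            rows.append(
                {"layer": name, "in_size": size_in, "out_size": size_out, "channels": channels}
            )

        row("Conv Layer 1", s, s // 2, c1)
        row("Conv Layer 2", s // 2, s // 4, c2)
        row("Conv Layer 3", s // 4, s // 4, c3)
        row("Conv Layer 4", s // 4, s // 4, c4)
        row("CBAM Layer", s // 4, s // 4, c4)
        row("Conv Layer 5", s // 4, s // 4, d1)
        row("TransConv Layer 1", s // 4, s // 2, d2)
        row("TransConv Layer 2", s // 2, s, d3)
        row("Conv Layer 6", s, s, self.spec.output_channels)
        row("Skip connection 1", s, s, 1)
        row("Skip connection 2", s // 2, s // 2, d2)
        row("Skip connection 3", s // 4, s // 4, d1)
        return rows


def build_network(spec: NetworkSpec | None = None, seed: int = 0) -> BDNet:
    """Construct the denoiser with deterministic, seeded initialization."""
    return BDNet(spec, seed=seed)


def channel_attention(features: np.ndarray, module: ChannelAttention) -> np.ndarray:
    """Per-channel gate vector for a (N, C, H, W) feature map."""
    return module.weights(np.asarray(features, dtype=np.float32))


def spatial_attention(features: np.ndarray, module: SpatialAttention) -> np.ndarray:
    """Per-pixel gate map for a (N, C, H, W) feature map."""
    return module.weights(np.asarray(features, dtype=np.float32))


def count_parameters(network: Module) -> int:
    """Number of learnable scalars (BatchNorm running statistics excluded)."""
    return sum(p.data.size for p in network.parameters())


def serialized_size_mb(network: Module) -> float:
    """Float-32 state-dict size in MB: serialized entries × 4 / 1024²."""
    entries = sum(v.size for v in network.state_dict().values())
    return entries * 4 / 1024**2


def parameter_ledger(network: Module) -> list[tuple[str, tuple[int, ...], int]]:
    """(name, shape, size) for every serialized array, in schema order."""
    return [(name, v.shape, v.size) for name, v in network.state_dict().items()]


def save_weights(network: Module, path) -> None:
    """Serialize the float-32 state dict (stable layer-name schema) to .npz."""
    state = network.state_dict()
    assert all(v.dtype == np.float32 for v in state.values())
    with open(path, "wb") as fh:
        np.savez(fh, **state)


def load_weights(network: Module, path) -> None:
    with np.load(path) as data:
        network.load_state_dict({k: data[k] for k in data.files})
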
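"""Neural-network layers with hand-written forward/backward passes.

The contract mirrors the usual framework semantics (Kaiming-uniform conv
init, BatchNorm with momentum-0.1 running statistics, biased variance for
normalisation) so that the denoiser's serialized state and behaviour are
what a practitioner would expect from the standard tooling.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .ops import col2im, conv_out_size, im2col

_F32 = np.float32


class Parameter:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=_F32)
        self.grad = np.zeros_like(self.data)


class Module:
    """Base class: named parameters/buffers, train/eval mode, state dict."""

    def __init__(self) -> None:
        self.training = True

    # -- registry ---------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix + name + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield from value.named_buffers(prefix + name + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{name}.{i}.")
        for name in getattr(self, "_buffer_names", ()):
            yield prefix + name, getattr(self, name)

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def train(self) -> None:
        self._set_mode(True)

    def eval(self) -> None:
        self._set_mode(False)

    def _set_mode(self, training: bool) -> None:
        self.training = training
        for value in vars(self).values():
            if isinstance(value, Module):
                value._set_mode(training)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item._set_mode(training)

    # -- serialization ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffer_owners = {}
        for name, _ in self.named_buffers():
            owner, attr = self._resolve(name)
            buffer_owners[name] = (owner, attr)
        expected = set(params) | set(buffer_owners)
        missing = expected - set(state)
        extra = set(state) - expected
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in params.items():
            if state[name].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data[...] = state[name]
        for name, (owner, attr) in buffer_owners.items():
            getattr(owner, attr)[...] = state[name]

    def _resolve(self, dotted: str) -> tuple["Module", str]:
        obj: Module | list = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            obj = obj[int(part)] if isinstance(obj, (list, tuple)) else getattr(obj, part)
        return obj, parts[-1]

    # -- interface ---------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _kaiming_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    # ReLU Kaiming-uniform bound sqrt(6/fan_in)
    bound = math.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(_F32)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(
            _kaiming_uniform(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in)
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.kernel_size, self.stride, self.padding
        col = im2col(x, k, s, p)
        wmat = self.weight.data.reshape(self.out_channels, -1)
        out = col @ wmat.T
        if self.bias is not None:
            out += self.bias.data
        ho, wo = conv_out_size(h, k, s, p), conv_out_size(w, k, s, p)
        if self.training:
            self._cache = (col, x.shape)
        return np.ascontiguousarray(
            out.reshape(n, ho, wo, self.out_channels).transpose(0, 3, 1, 2)
        )

    def backward(self, grad: np.ndarray) -> np.ndarray:
        col, x_shape = self._cache
        n, co, ho, wo = grad.shape
        gmat = np.ascontiguousarray(grad.transpose(0, 2, 3, 1).reshape(-1, co))
        wmat = self.weight.data.reshape(co, -1)
        self.weight.grad += (gmat.T @ col).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += gmat.sum(axis=0)
        dcol = gmat @ wmat
        return col2im(dcol, x_shape, self.kernel_size, self.stride, self.padding)


class ConvTranspose2d(Module):
    """Transposed convolution == adjoint of a strided convolution.

    With kernel 3, stride 2, padding 1 and output_padding 1 this exactly
    doubles the spatial size, the upsampling step of the decoder.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 2,
        padding: int = 1,
        output_padding: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.output_padding = output_padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(
            _kaiming_uniform(rng, (in_channels, out_channels, kernel_size, kernel_size), fan_in)
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self._cache: np.ndarray | None = None

    def out_size(self, size: int) -> int:
        return (size - 1) * self.stride - 2 * self.padding + self.kernel_size + self.output_padding

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, ci, h, w = x.shape
        k, s, p = self.kernel_size, self.stride, self.padding
        ho, wo = self.out_size(h), self.out_size(w)
        # sanity: the adjoint convolution must map (ho, wo) back to (h, w)
        assert conv_out_size(ho, k, s, p) == h and conv_out_size(wo, k, s, p) == w
        xmat = np.ascontiguousarray(x.transpose(0, 2, 3, 1).reshape(-1, ci))
        wmat = self.weight.data.reshape(ci, -1)  # (ci, co*k*k)
        col = xmat @ wmat
        out = col2im(col, (n, self.out_channels, ho, wo), k, s, p)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        if self.training:
            self._cache = xmat
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xmat = self._cache
        n, co, ho, wo = grad.shape
        k, s, p = self.kernel_size, self.stride, self.padding
        gcol = im2col(grad, k, s, p)  # (n*h*w, co*k*k)
        self.weight.grad += (xmat.T @ gcol).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        wmat = self.weight.data.reshape(self.in_channels, -1)
        dx = gcol @ wmat.T  # (n*h*w, ci)
        h = conv_out_size(ho, k, s, p)
        w = conv_out_size(wo, k, s, p)
        return np.ascontiguousarray(dx.reshape(n, h, w, self.in_channels).transpose(0, 3, 1, 2))


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=_F32)
        self.running_var = np.ones(num_features, dtype=_F32)
        self._buffer_names = ("running_mean", "running_var")
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            axes = (0, 2, 3)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var * m / max(m - 1, 1)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        out = xhat * self.weight.data[None, :, None, None] + self.bias.data[None, :, None, None]
        if self.training:
            self._cache = (xhat, inv_std)
        return out.astype(_F32, copy=False)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        axes = (0, 2, 3)
        self.weight.grad += (grad * xhat).sum(axis=axes)
        self.bias.grad += grad.sum(axis=axes)
        g = grad * self.weight.data[None, :, None, None]
        gsum = g.sum(axis=axes, keepdims=True)
        gx_sum = (g * xhat).sum(axis=axes, keepdims=True)
        dx = (g - gsum / m - xhat * gx_sum / m) * inv_std[None, :, None, None]
        return dx.astype(_F32, copy=False)


class ReLU(Module):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = list(modules)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
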
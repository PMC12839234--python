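"""Low-level array primitives: im2col/col2im lowering and 2D correlations.

Layout convention: activations are ``(N, C, H, W)`` float32.  ``im2col``
produces patch matrices of shape ``(N*Ho*Wo, C*k*k)`` so a convolution is a
single GEMM against a ``(C_out, C*k*k)`` weight matrix; ``col2im`` is its
exact adjoint and doubles as the forward pass of transposed convolution.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def conv_out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """Extract k×k patches as rows.

    Returns an array of shape ``(N*Ho*Wo, C*k*k)`` whose row ordering is
    (n, ho, wo) C-contiguous and whose column ordering is (c, ki, kj).
    """
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    # win: (N, C, Ho, Wo, k, k) -> (N, Ho, Wo, C, k, k)
    ho, wo = win.shape[2], win.shape[3]
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(col)


def col2im(
    col: np.ndarray,
    x_shape: tuple[int, int, int, int],
    k: int,
    stride: int,
    pad: int,
) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patch rows back onto the grid."""
    n, c, h, w = x_shape
    ho = conv_out_size(h, k, stride, pad)
    wo = conv_out_size(w, k, stride, pad)
    cols = col.reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    out = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=col.dtype)
    for ki in range(k):
        for kj in range(k):
            out[:, :, ki : ki + stride * ho : stride, kj : kj + stride * wo : stride] += cols[
                :, :, ki, kj
            ]
    if pad:
        out = out[:, :, pad : pad + h, pad : pad + w]
    return out


def correlate2d_replicate(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """'Same'-size 2D correlation with replicate (edge) padding.

    ``x`` may carry arbitrary leading axes; the kernel is applied over the
    trailing two.  Vectorised as a sum of shifted slices (k*k terms).
    """
    k = kernel.shape[0]
    pad = k // 2
    h, w = x.shape[-2], x.shape[-1]
    xp = np.pad(x, [(0, 0)] * (x.ndim - 2) + [(pad, pad), (pad, pad)], mode="edge")
    out = np.zeros_like(x, dtype=np.result_type(x, kernel))
    for i in range(k):
        for j in range(k):
            kij = kernel[i, j]
            if kij != 0:
                out += kij * xp[..., i : i + h, j : j + w]
    return out


def correlate2d_replicate_adjoint(g: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`correlate2d_replicate` for gradient propagation."""
    k = kernel.shape[0]
    pad = k // 2
    h, w = g.shape[-2], g.shape[-1]
    gp = np.zeros(g.shape[:-2] + (h + 2 * pad, w + 2 * pad), dtype=g.dtype)
    for i in range(k):
        for j in range(k):
            kij = kernel[i, j]
            if kij != 0:
                gp[..., i : i + h, j : j + w] += kij * g
    # fold the replicate-padding contributions back onto the edges
    gp[..., pad, :] += gp[..., :pad, :].sum(axis=-2)
    gp[..., h + pad - 1, :] += gp[..., h + pad :, :].sum(axis=-2)
    core = gp[..., pad : pad + h, :]
    core[..., pad] += gp[..., pad : pad + h, :pad].sum(axis=-1)
    core[..., w + pad - 1] += gp[..., pad : pad + h, w + pad :].sum(axis=-1)
    return np.ascontiguousarray(core[..., pad : pad + w])


def correlate2d_valid_separable(x: np.ndarray, k1d: np.ndarray) -> np.ndarray:
    """Valid-mode correlation with a separable symmetric kernel ``k1d ⊗ k1d``."""
    r = len(k1d)
    win = sliding_window_view(x, r, axis=-1)
    x2 = np.tensordot(win, k1d, axes=([-1], [0]))
    win = sliding_window_view(x2, r, axis=-2)
    # sliding over axis -2 appends the window axis at the end
    return np.tensordot(win, k1d, axes=([-1], [0]))


def correlate2d_valid_separable_adjoint(g: np.ndarray, k1d: np.ndarray, h: int, w: int) -> np.ndarray:
    """Adjoint of the valid separable correlation: zero-embed + full correlation."""
    r = len(k1d)
    pad = r - 1
    gp = np.pad(g, [(0, 0)] * (g.ndim - 2) + [(pad, pad), (pad, pad)])
    out = correlate2d_valid_separable(gp, k1d[::-1])
    assert out.shape[-2:] == (h, w)
    return out
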
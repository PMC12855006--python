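"""2-D convolution primitives (im2col based) and their autograd wrappers.

Only what the image VAE requires: square kernels, symmetric padding, a single
stride. Weight layout follows the (out_channels, in_channels, kh, kw)
convention; the transposed convolution reuses the convolution's input-gradient
routine for its forward pass.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .autograd import Tensor

__all__ = ["conv2d", "conv_transpose2d"]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, Ho*Wo) patch matrix."""
    n, c, h, w = x.shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s0, s1, s2, s3 = xp.strides
    win = as_strided(
        xp,
        shape=(n, c, k, k, ho, wo),
        strides=(s0, s1, s2, s3, stride * s2, stride * s3),
        writeable=False,
    )
    return np.ascontiguousarray(win).reshape(n, c * k * k, ho * wo)


def _col2im(cols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    """Scatter-add inverse of :func:`_im2col`."""
    n, c, h, w = x_shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    cols = cols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        hi = i + stride * ho
        for j in range(k):
            wj = j + stride * wo
            xp[:, :, i:hi:stride, j:wj:stride] += cols[:, :, i, j]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


def _conv_fwd(x, w, stride, pad):
    n = x.shape[0]
    co, ci, k, _ = w.shape
    ho = (x.shape[2] + 2 * pad - k) // stride + 1
    wo = (x.shape[3] + 2 * pad - k) // stride + 1
    cols = _im2col(x, k, stride, pad)
    out = w.reshape(co, -1) @ cols  # (N, Co, Ho*Wo) by broadcasting over N
    return out.reshape(n, co, ho, wo)


def _conv_dx(dy, w, stride, pad, x_shape):
    n = dy.shape[0]
    co, ci, k, _ = w.shape
    cols = w.reshape(co, -1).T @ dy.reshape(n, co, -1)
    return _col2im(cols, x_shape, k, stride, pad)


def _conv_dw(x, dy, stride, pad, w_shape):
    n = x.shape[0]
    co, ci, k, _ = w_shape
    cols = _im2col(x, k, stride, pad)  # (N, Ci*k*k, L)
    dyf = dy.reshape(n, co, -1)  # (N, Co, L)
    dw = np.einsum("ncl,nkl->ck", dyf, cols)
    return dw.reshape(w_shape)


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 2, pad: int = 1) -> Tensor:
    out_data = _conv_fwd(x.data, w.data, stride, pad)
    out_data += b.data.reshape(1, -1, 1, 1)
    out = Tensor(out_data, x.requires_grad or w.requires_grad or b.requires_grad,
                 (x, w, b))

    def _bw(g):
        if x.requires_grad:
            x._accum(_conv_dx(g, w.data, stride, pad, x.data.shape))
        if w.requires_grad:
            w._accum(_conv_dw(x.data, g, stride, pad, w.data.shape))
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    out._backward = _bw
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 2,
                     pad: int = 1) -> Tensor:
    """Transposed convolution; ``w`` has shape (in_channels, out_channels, k, k).

    Forward pass is the input-gradient of the equivalent convolution, so the
    output side is ``(H - 1) * stride - 2 * pad + k``.
    """
    cin, cout, k, _ = w.data.shape
    n, _, h, wd = x.data.shape
    ho = (h - 1) * stride - 2 * pad + k
    wo = (wd - 1) * stride - 2 * pad + k
    out_data = _conv_dx(x.data, w.data, stride, pad, (n, cout, ho, wo))
    out_data += b.data.reshape(1, -1, 1, 1)
    out = Tensor(out_data, x.requires_grad or w.requires_grad or b.requires_grad,
                 (x, w, b))

    def _bw(g):
        if x.requires_grad:
            x._accum(_conv_fwd(g, w.data, stride, pad))
        if w.requires_grad:
            w._accum(_conv_dw(g, x.data, stride, pad, w.data.shape))
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    out._backward = _bw
    return out
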
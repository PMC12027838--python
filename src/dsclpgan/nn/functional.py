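"""Network-level differentiable operations: convolution, upsampling,
log-softmax and the DC-centered log-magnitude spectrum used by the
frequency-domain critic."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["conv2d", "upsample_nearest", "log_softmax", "spectral_logmag"]


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols.reshape(n, c * kh * kw, ho * wo), ho, wo


def _col2im(cols: np.ndarray, x_shape, kh, kw, stride, pad, ho, wo) -> np.ndarray:
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[:, :, i, j]
    if pad:
        out = out[:, :, pad : pad + h, pad : pad + w]
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """2-D cross-correlation; x (N,C,H,W), weight (F,C,kh,kw), bias (F,)."""
    n = x.data.shape[0]
    f, c, kh, kw = weight.data.shape
    if x.data.shape[1] != c:
        raise ValueError(f"conv2d channel mismatch: input {x.data.shape[1]}, weight {c}")
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)
    wmat = weight.data.reshape(f, -1)
    out_data = (wmat @ cols).reshape(n, f, ho, wo) + bias.data.reshape(1, f, 1, 1)
    x_shape = x.data.shape

    def backward(g):
        gmat = g.reshape(n, f, ho * wo)
        gw = np.einsum("nfl,nkl->fk", gmat, cols).reshape(weight.data.shape)
        gb = g.sum(axis=(0, 2, 3))
        gcols = np.einsum("fk,nfl->nkl", wmat, gmat)
        gx = _col2im(gcols, x_shape, kh, kw, stride, pad, ho, wo)
        return (gx, gw, gb)

    return Tensor._make(out_data, (x, weight, bias), backward)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    n, c, h, w = x.data.shape
    out_data = x.data.repeat(factor, axis=2).repeat(factor, axis=3)

    def backward(g):
        return (g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5)),)

    return Tensor._make(out_data, (x,), backward)


def log_softmax(x: Tensor, axis: int = 1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    shifted = x.data - m
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse

    def backward(g):
        return (g - np.exp(out_data) * g.sum(axis=axis, keepdims=True),)

    return Tensor._make(out_data, (x,), backward)


def spectral_logmag(x: Tensor, eps: float = 1e-12) -> Tensor:
    """DC-centered log-compressed magnitude spectrum, log(1 + |F(x)|).

    Operates on the trailing two axes with the unnormalized DFT convention.
    Differentiable with respect to the (real) input pixels.
    """
    fx = np.fft.fft2(x.data, axes=(-2, -1))
    mag = np.abs(fx)
    out_data = np.fft.fftshift(np.log1p(mag), axes=(-2, -1))

    def backward(g):
        g_log = np.fft.ifftshift(g, axes=(-2, -1))
        g_mag = g_log / (1.0 + mag)
        # adjoint of x -> |fft2(x)| for real x
        u = g_mag * np.conj(fx) / (mag + eps)
        gx = np.real(np.fft.fft2(u, axes=(-2, -1)))
        return (gx,)

    return Tensor._make(out_data, (x,), backward)
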
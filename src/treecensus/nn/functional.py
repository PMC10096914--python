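"""Structured differentiable ops: convolution, pooling, upsampling, batch norm.

All ops take NCHW arrays. Only stride-1 convolutions are provided; spatial
down/up-sampling is done by max pooling and nearest-neighbour upsampling,
which is all the U-Net variants here require.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autodiff import Tensor, as_tensor

__all__ = ["conv2d", "maxpool2x2", "upsample2x", "batchnorm2d", "concat_channels"]


def _corr2d(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """Batched stride-1 cross-correlation. x (N,C,H,W), w (F,C,kh,kw)."""
    n, c, _, _ = x.shape
    f, _, kh, kw = w.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # (N,C,Ho,Wo,kh,kw)
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    out = cols @ w.reshape(f, -1).T
    return np.ascontiguousarray(out.reshape(n, ho, wo, f).transpose(0, 3, 1, 2))


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, pad: int = 0) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation) with zero padding."""
    x = as_tensor(x)
    f, cin, kh, kw = weight.data.shape
    if x.data.shape[1] != cin:
        raise ValueError(f"conv2d: expected {cin} input channels, got {x.data.shape[1]}")
    y = _corr2d(x.data, weight.data, pad)
    if bias is not None:
        y += bias.data.reshape(1, f, 1, 1)
    parents = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor(y, parents=parents)

    def backward(g, x=x, weight=weight, bias=bias, pad=pad):
        if x.requires_grad:
            # full correlation with the spatially flipped, channel-swapped kernel
            w_flip = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            x.accumulate(_corr2d(g, np.ascontiguousarray(w_flip), weight.data.shape[2] - 1 - pad))
        if weight.requires_grad:
            # dW[f,c,i,j] = sum_{n,h,w} x_pad[n,c,h+i,w+j] g[n,f,h,w];
            # one matmul-backed einsum per kernel tap
            f_, c_, kh, kw = weight.data.shape
            xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
            ho, wo = g.shape[2], g.shape[3]
            dw = np.empty_like(weight.data)
            for i in range(kh):
                for j in range(kw):
                    xs = xp[:, :, i:i + ho, j:j + wo]
                    dw[:, :, i, j] = np.einsum("nchw,nfhw->fc", xs, g, optimize=True)
            weight.accumulate(dw)
        if bias is not None and bias.requires_grad:
            bias.accumulate(g.sum(axis=(0, 2, 3)))

    out._backward = backward if out.requires_grad else None
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; ties share the gradient equally."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dimensions")
    v = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    y = v.max(axis=(3, 5))
    out = Tensor(y, parents=(x,))

    def backward(g, x=x, v=v, y=y):
        if x.requires_grad:
            mask = (v == y[:, :, :, None, :, None]).astype(x.data.dtype)
            mask /= mask.sum(axis=(3, 5), keepdims=True)
            gv = mask * g[:, :, :, None, :, None]
            x.accumulate(gv.reshape(x.data.shape))

    out._backward = backward if out.requires_grad else None
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    x = as_tensor(x)
    y = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    out = Tensor(y, parents=(x,))

    def backward(g, x=x):
        if x.requires_grad:
            n, c, h2, w2 = g.shape
            x.accumulate(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    out._backward = backward if out.requires_grad else None
    return out


def concat_channels(tensors: list[Tensor]) -> Tensor:
    """Concatenate NCHW tensors along the channel axis."""
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=1), parents=tuple(tensors))
    splits = np.cumsum([t.data.shape[1] for t in tensors])[:-1]

    def backward(g, tensors=tensors, splits=splits):
        for t, piece in zip(tensors, np.split(g, splits, axis=1)):
            if t.requires_grad:
                t.accumulate(piece)

    out._backward = backward if out.requires_grad else None
    return out


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalisation over (N, H, W).

    In training mode the batch statistics are used and the running
    statistics updated in place; in eval mode the frozen running
    statistics are used (the transform is then a pure affine map).
    """
    x = as_tensor(x)
    c = x.data.shape[1]
    gshape = (1, c, 1, 1)
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        unbiased = var * (m / max(m - 1, 1))
        running_var *= 1.0 - momentum
        running_var += momentum * unbiased
        inv_std = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mu.reshape(gshape)) * inv_std.reshape(gshape)
        y = gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape)
        out = Tensor(y, parents=(x, gamma, beta))

        def backward(g, x=x, gamma=gamma, beta=beta, xhat=xhat, inv_std=inv_std, m=m, gshape=gshape):
            if gamma.requires_grad:
                gamma.accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta.accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dxhat = g * gamma.data.reshape(gshape)
                s1 = dxhat.sum(axis=(0, 2, 3)).reshape(gshape)
                s2 = (dxhat * xhat).sum(axis=(0, 2, 3)).reshape(gshape)
                dx = (dxhat - s1 / m - xhat * s2 / m) * inv_std.reshape(gshape)
                x.accumulate(dx)

        out._backward = backward if out.requires_grad else None
        return out

    inv_std = 1.0 / np.sqrt(running_var + eps)
    scale = (gamma.data * inv_std).reshape(gshape)
    y = (x.data - running_mean.reshape(gshape)) * scale + beta.data.reshape(gshape)
    out = Tensor(y, parents=(x, gamma, beta))
    xhat_eval = (x.data - running_mean.reshape(gshape)) * inv_std.reshape(gshape)

    def backward(g, x=x, gamma=gamma, beta=beta, scale=scale, xhat=xhat_eval):
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x.accumulate(g * scale)

    out._backward = backward if out.requires_grad else None
    return out
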
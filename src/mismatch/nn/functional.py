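"""Spatial primitives: N-d convolution, 2x max-pooling, 2x nearest upsampling.

All convolutions are stride 1 with "same" zero padding, so every block in
the package preserves spatial shape by construction.  Dilation enlarges the
kernel footprint to ``d*(k-1)+1`` without extra parameters.  Both 2-D
(N, C, H, W) and 3-D (N, C, D, H, W) inputs are supported by the same code
path.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = ["conv_nd", "max_pool", "upsample_nearest"]


def _same_pad(kernel: tuple[int, ...], dilation: int) -> list[tuple[int, int]]:
    pads = []
    for k in kernel:
        if k % 2 == 0:
            raise ValueError(f"kernel size must be odd, got {k}")
        span = dilation * (k - 1)
        pads.append((span // 2, span // 2))
    return pads


def conv_nd(x: Tensor, weight: Tensor, bias: Tensor | None = None,
            dilation: int = 1) -> Tensor:
    """Cross-correlate ``x`` (N, C, *S) with ``weight`` (O, C, *K).

    Stride 1, same padding; output shape (N, O, *S).
    """
    kernel = weight.shape[2:]
    nd = len(kernel)
    if x.ndim != nd + 2:
        raise ValueError(f"input rank {x.ndim} does not match {nd}-d kernel")
    if x.shape[1] != weight.shape[1]:
        raise ValueError(
            f"channel mismatch: input has {x.shape[1]}, kernel expects {weight.shape[1]}")
    spatial = x.shape[2:]
    pads = _same_pad(kernel, dilation)
    xp = np.pad(x.data, [(0, 0), (0, 0)] + pads)

    eff = tuple(dilation * (k - 1) + 1 for k in kernel)
    # windows: (N, C, *S, *K_eff) -> subsample dilated taps -> (N, C, *S, *K)
    win = sliding_window_view(xp, eff, axis=tuple(range(2, 2 + nd)))
    sub = (slice(None),) * (2 + nd) + (slice(None, None, dilation),) * nd
    win = win[sub]

    kernel_axes_win = tuple(range(2 + nd, 2 + 2 * nd))
    kernel_axes_w = tuple(range(2, 2 + nd))
    # out[n, *s, o] = sum_{c, *k} win[n, c, *s, *k] * w[o, c, *k]
    out_data = np.tensordot(win, weight.data,
                            axes=((1,) + kernel_axes_win, (1,) + kernel_axes_w))
    out_data = np.moveaxis(out_data, -1, 1)
    if bias is not None:
        out_data = out_data + bias.data.reshape((1, -1) + (1,) * nd)

    parents = [t for t in (x, weight, bias) if t is not None and t.requires_grad]
    out = Tensor(out_data, requires_grad=bool(parents), parents=parents)

    def backward(g):
        # g: (N, O, *S)
        if weight.requires_grad:
            spatial_axes = tuple(range(2, 2 + nd))
            # dW[o, c, *k] = sum_{n, *s} g[n, o, *s] * win[n, c, *s, *k]
            gw = np.tensordot(g, win, axes=((0,) + spatial_axes,
                                            (0,) + spatial_axes))
            weight._accumulate(gw)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0,) + tuple(range(2, 2 + nd))))
        if x.requires_grad:
            # t[n, *s, c, *k] = sum_o g[n, o, *s] * w[o, c, *k]
            t = np.tensordot(g, weight.data, axes=((1,), (0,)))
            t = np.moveaxis(t, nd + 1, 1)  # (N, C, *S, *K)
            gxp = np.zeros_like(xp)
            for kk in product(*(range(k) for k in kernel)):
                sl = tuple(slice(kk[d] * dilation, kk[d] * dilation + spatial[d])
                           for d in range(nd))
                gxp[(slice(None), slice(None)) + sl] += t[
                    (slice(None), slice(None)) + (slice(None),) * nd + kk]
            crop = tuple(slice(p[0], p[0] + s) for p, s in zip(pads, spatial))
            x._accumulate(gxp[(slice(None), slice(None)) + crop])

    out._backward = backward if parents else None
    return out


def max_pool(x: Tensor, factor: int = 2) -> Tensor:
    """Non-overlapping max pooling by ``factor`` along every spatial axis."""
    nd = x.ndim - 2
    spatial = x.shape[2:]
    if any(s % factor for s in spatial):
        raise ValueError(f"spatial dims {spatial} not divisible by {factor}")
    blocked_shape = x.shape[:2] + sum(
        ((s // factor, factor) for s in spatial), ())
    blocked = x.data.reshape(blocked_shape)
    # move the window axes (3, 5, ...) to the end and flatten them
    window_axes = tuple(3 + 2 * i for i in range(nd))
    moved = np.moveaxis(blocked, window_axes, tuple(range(-nd, 0)))
    lead_shape = moved.shape[:-nd]
    flat = moved.reshape(lead_shape + (factor ** nd,))
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    out = Tensor(out_data, requires_grad=x.requires_grad,
                 parents=[x] if x.requires_grad else ())

    def backward(g):
        gflat = np.zeros(lead_shape + (factor ** nd,))
        np.put_along_axis(gflat, arg[..., None], g[..., None], axis=-1)
        gmoved = gflat.reshape(moved.shape)
        gblocked = np.moveaxis(gmoved, tuple(range(-nd, 0)), window_axes)
        x._accumulate(gblocked.reshape(x.shape))

    out._backward = backward if x.requires_grad else None
    return out


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    """Repeat every spatial element ``factor`` times along each axis."""
    nd = x.ndim - 2
    data = x.data
    for axis in range(2, 2 + nd):
        data = np.repeat(data, factor, axis=axis)
    out = Tensor(data, requires_grad=x.requires_grad,
                 parents=[x] if x.requires_grad else ())

    def backward(g):
        blocked_shape = x.shape[:2] + sum(
            ((s, factor) for s in x.shape[2:]), ())
        gb = g.reshape(blocked_shape)
        window_axes = tuple(3 + 2 * i for i in range(nd))
        x._accumulate(gb.sum(axis=window_axes))

    out._backward = backward if x.requires_grad else None
    return out
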
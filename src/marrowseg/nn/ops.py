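"""Differentiable 3-D building blocks on top of autograd's numpy wrapper.

Every function here takes and returns arrays that may be autograd boxes, so
whole networks can be expressed as pure functions of a parameter dict and
differentiated with ``autograd.grad``.  Feature tensors are ``(C, D, H, W)``
(channels first, spatial axes in the package's ``(z, y, x)`` order).

Convolutions use a shift-and-add formulation: for a k^3 kernel the output is
a sum of k^3 channel-mixing matmuls over shifted views of the padded input.
At the small kernel sizes used here this is considerably faster (and far
lighter on memory) than an im2col gather, and its reverse pass reduces to
slice-scatter additions.
"""

from __future__ import annotations

import autograd.numpy as np
import numpy as onp
from autograd.extend import defvjp, primitive
from autograd.tracer import isbox

__all__ = [
    "detach",
    "pad3d",
    "pad_to",
    "conv3d",
    "instance_norm",
    "relu",
    "sigmoid",
    "upsample2",
    "trilinear_resize",
    "softmax_all",
    "softmax_channels",
    "he_init",
]


def detach(x):
    """Strip autograd tracing boxes, returning the underlying ndarray/value."""
    while isbox(x):
        x = x._value
    return x


def pad3d(x, p: int):
    """Zero-pad the three spatial axes of ``(C, D, H, W)`` by ``p`` on each side."""
    if p == 0:
        return x
    C = x.shape[0]
    D, H, W = x.shape[1:]
    zd = np.zeros((C, p, H, W))
    x = np.concatenate([zd, x, zd], axis=1)
    zh = np.zeros((C, D + 2 * p, p, W))
    x = np.concatenate([zh, x, zh], axis=2)
    zw = np.zeros((C, D + 2 * p, H + 2 * p, p))
    x = np.concatenate([zw, x, zw], axis=3)
    return x


def pad_to(x, corner, full_shape):
    """Embed a 3-D block ``x`` into a zero volume of ``full_shape`` at ``corner``.

    Differentiable with respect to ``x``; ``corner`` is a plain integer triple.
    """
    out = x
    for ax in range(3):
        lo = int(corner[ax])
        hi = full_shape[ax] - lo - x.shape[ax]
        if lo < 0 or hi < 0:
            raise ValueError(
                f"block of shape {x.shape} at corner {tuple(corner)} does not fit "
                f"inside {tuple(full_shape)}"
            )
        shape_lo = list(out.shape)
        shape_lo[ax] = lo
        shape_hi = list(out.shape)
        shape_hi[ax] = hi
        out = np.concatenate([np.zeros(shape_lo), out, np.zeros(shape_hi)], axis=ax)
    return out


def _conv_geometry(x_shape, k, stride, pad):
    D, H, W = (s + 2 * pad for s in x_shape[1:])
    return (D - k) // stride + 1, (H - k) // stride + 1, (W - k) // stride + 1


def _pad_raw(x, p):
    if p == 0:
        return x
    return onp.pad(x, ((0, 0), (p, p), (p, p), (p, p)))


def conv3d(x, w, b, stride: int = 1, pad: int | None = None):
    """3-D convolution, ``x`` (Cin, D, H, W) -> (Cout, D', H', W').

    ``pad=None`` means 'same' padding for stride 1 (``(k-1)//2``).
    """
    if pad is None:
        pad = (w.shape[2] - 1) // 2
    return _conv3d(x, w, b, stride, pad)


@primitive
def _conv3d(x, w, b, stride: int, pad: int):
    """Shift-and-add 3-D convolution, registered as an autograd primitive.

    The hand-coded reverse passes (a transposed convolution for the input,
    a correlation for the weights) run on fast contiguous slices instead of
    autograd's generic gather/scatter machinery.
    """
    cout, cin, k = w.shape[0], w.shape[1], w.shape[2]
    xp = _pad_raw(x, pad)
    od, oh, ow = _conv_geometry(x.shape, k, stride, pad)
    out = onp.zeros((cout, od * oh * ow))
    for dz in range(k):
        for dy in range(k):
            for dx in range(k):
                xs = xp[
                    :,
                    dz : dz + od * stride : stride,
                    dy : dy + oh * stride : stride,
                    dx : dx + ow * stride : stride,
                ]
                out += onp.tensordot(w[:, :, dz, dy, dx], xs.reshape(cin, -1), axes=1)
    return (out + b[:, None]).reshape(cout, od, oh, ow)


def _conv3d_vjp_x(ans, x, w, b, stride, pad):
    cin, k = w.shape[1], w.shape[2]

    def vjp(g):
        od, oh, ow = g.shape[1:]
        gf = g.reshape(g.shape[0], -1)
        dxp = onp.zeros((cin,) + tuple(s + 2 * pad for s in x.shape[1:]))
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    contrib = onp.tensordot(w[:, :, dz, dy, dx].T, gf, axes=1)
                    dxp[
                        :,
                        dz : dz + od * stride : stride,
                        dy : dy + oh * stride : stride,
                        dx : dx + ow * stride : stride,
                    ] += contrib.reshape(cin, od, oh, ow)
        if pad == 0:
            return dxp
        return dxp[:, pad:-pad, pad:-pad, pad:-pad]

    return vjp


def _conv3d_vjp_w(ans, x, w, b, stride, pad):
    cin, k = w.shape[1], w.shape[2]

    def vjp(g):
        od, oh, ow = g.shape[1:]
        gf = g.reshape(g.shape[0], -1)
        xp = _pad_raw(x, pad)
        dw = onp.zeros_like(w)
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    xs = xp[
                        :,
                        dz : dz + od * stride : stride,
                        dy : dy + oh * stride : stride,
                        dx : dx + ow * stride : stride,
                    ]
                    dw[:, :, dz, dy, dx] = onp.dot(gf, xs.reshape(cin, -1).T)
        return dw

    return vjp


def _conv3d_vjp_b(ans, x, w, b, stride, pad):
    return lambda g: g.sum(axis=(1, 2, 3))


defvjp(_conv3d, _conv3d_vjp_x, _conv3d_vjp_w, _conv3d_vjp_b)


def instance_norm(x, gamma, beta, eps: float = 1e-5):
    """Per-channel normalization over the spatial axes of one sample."""
    mu = np.mean(x, axis=(1, 2, 3), keepdims=True)
    var = np.mean((x - mu) ** 2, axis=(1, 2, 3), keepdims=True)
    xn = (x - mu) / np.sqrt(var + eps)
    return gamma[:, None, None, None] * xn + beta[:, None, None, None]


def relu(x):
    return np.maximum(x, 0.0)


def sigmoid(x):
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


def upsample2(x):
    """Nearest-neighbour x2 upsampling of the spatial axes of (C, D, H, W)."""
    x = np.repeat(x, 2, axis=1)
    x = np.repeat(x, 2, axis=2)
    return np.repeat(x, 2, axis=3)


# Cached corner indices / weights for trilinear interpolation, keyed by
# (source shape, target shape).  These are plain integer/float arrays.
_TRILINEAR_CACHE: dict = {}


def _trilinear_tables(src_shape, tgt_shape):
    key = (tuple(src_shape), tuple(tgt_shape))
    if key in _TRILINEAR_CACHE:
        return _TRILINEAR_CACHE[key]
    axes = []
    for s, t in zip(src_shape, tgt_shape):
        if s == 1:
            i0 = onp.zeros(t, dtype=onp.intp)
            i1 = i0
            f = onp.zeros(t)
        else:
            # align voxel centres of the two grids
            pos = onp.linspace(0.0, s - 1.0, t)
            i0 = onp.floor(pos).astype(onp.intp)
            i0 = onp.minimum(i0, s - 2)
            i1 = i0 + 1
            f = pos - i0
        axes.append((i0, i1, f))
    (z0, z1, fz), (y0, y1, fy), (x0, x1, fx) = axes
    H, W = src_shape[1], src_shape[2]
    flats = []
    weights = []
    for zc, wz in ((z0, 1 - fz), (z1, fz)):
        for yc, wy in ((y0, 1 - fy), (y1, fy)):
            for xc, wx in ((x0, 1 - fx), (x1, fx)):
                flat = (
                    zc[:, None, None] * (H * W)
                    + yc[None, :, None] * W
                    + xc[None, None, :]
                )
                wgt = wz[:, None, None] * wy[None, :, None] * wx[None, None, :]
                flats.append(flat)
                weights.append(wgt)
    _TRILINEAR_CACHE[key] = (flats, weights)
    return flats, weights


def trilinear_resize(x, tgt_shape):
    """Trilinearly resample a single-channel 3-D grid to ``tgt_shape``."""
    src_shape = tuple(int(s) for s in x.shape)
    tgt_shape = tuple(int(s) for s in tgt_shape)
    if src_shape == tgt_shape:
        return x
    flats, weights = _trilinear_tables(src_shape, tgt_shape)
    xf = np.reshape(x, (-1,))
    out = 0.0
    for flat, wgt in zip(flats, weights):
        out = out + wgt * xf[flat]
    return out


def softmax_all(logits):
    """Softmax over *all* entries of a grid (a spatial probability map)."""
    m = np.max(logits)
    e = np.exp(logits - m)
    return e / np.sum(e)


def softmax_channels(logits):
    """Softmax over axis 0 (the class axis) of (C, ...)."""
    m = np.max(logits, axis=0, keepdims=True)
    e = np.exp(logits - m)
    return e / np.sum(e, axis=0, keepdims=True)


def he_init(rng: onp.random.Generator, shape, fan_in: int) -> onp.ndarray:
    """Kaiming-normal weight initialization for ReLU networks."""
    return rng.normal(0.0, onp.sqrt(2.0 / fan_in), size=shape)
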
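"""Differentiable 3D network operations.

All feature maps are ``(C, D, H, W)`` float32 arrays (no batch axis —
micro-batching is a loop with gradient accumulation).  Convolutions use
'same' zero padding and stride 1; they are evaluated as im2col + BLAS
matmul, chunked along the depth axis to bound the im2col buffer.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from voxsr.nn.tensor import Tensor

# im2col buffer cap, in float32 entries (64 MB)
_CHUNK_ENTRIES = 1 << 22


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0.0), parents=(x,))
    out._backward = lambda g, a=x, m=mask: a._accumulate(np.where(m, g, 0.0))
    return out


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, slope * x.data), parents=(x,))
    out._backward = lambda g, a=x, m=mask, s=slope: a._accumulate(
        np.where(m, g, s * g)
    )
    return out


# ---------------------------------------------------------------- conv3d

def _depth_chunks(depth: int, per_slice: int):
    step = max(_CHUNK_ENTRIES // max(per_slice, 1), 1)
    for d0 in range(0, depth, step):
        yield d0, min(d0 + step, depth)


def _conv3d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray | None):
    cin, D, H, W = x.shape
    cout, cin2, k, _, _ = w.shape
    assert cin == cin2, (cin, cin2)
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p))) if p else x
    wmat = w.reshape(cout, cin * k * k * k)
    y = np.empty((cout, D, H, W), dtype=np.float32)
    if k == 1:
        y[:] = np.tensordot(w[:, :, 0, 0, 0], x, axes=([1], [0]))
    else:
        win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
        # win: (cin, D, H, W, k, k, k)
        for d0, d1 in _depth_chunks(D, cin * k ** 3 * H * W):
            cols = np.ascontiguousarray(
                win[:, d0:d1].transpose(0, 4, 5, 6, 1, 2, 3)
            ).reshape(cin * k ** 3, (d1 - d0) * H * W)
            y[:, d0:d1] = (wmat @ cols).reshape(cout, d1 - d0, H, W)
    if b is not None:
        y += b[:, None, None, None]
    return y


def _conv3d_backward(x, w, gy, need_gx=True):
    cin, D, H, W = x.shape
    cout, _, k, _, _ = w.shape
    p = k // 2
    if k == 1:
        gymat = gy.reshape(cout, -1)
        gw = (gymat @ x.reshape(cin, -1).T).reshape(cout, cin, 1, 1, 1)
        gx = None
        if need_gx:
            gx = np.tensordot(w[:, :, 0, 0, 0].T, gy, axes=([1], [0]))
        return gw, gx
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p))) if p else x
    win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
    wmat = w.reshape(cout, cin * k ** 3)
    gw = np.zeros((cout, cin * k ** 3), dtype=np.float32)
    gx_pad = (
        np.zeros_like(xp) if need_gx else None
    )
    for d0, d1 in _depth_chunks(D, cin * k ** 3 * H * W):
        cols = np.ascontiguousarray(
            win[:, d0:d1].transpose(0, 4, 5, 6, 1, 2, 3)
        ).reshape(cin * k ** 3, (d1 - d0) * H * W)
        gymat = gy[:, d0:d1].reshape(cout, -1)
        gw += gymat @ cols.T
        if need_gx:
            gcols = (wmat.T @ gymat).reshape(cin, k, k, k, d1 - d0, H, W)
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        gx_pad[:, d0 + i : d1 + i, j : j + H, l : l + W] += gcols[
                            :, i, j, l
                        ]
    gx = None
    if need_gx:
        gx = gx_pad[:, p : p + D, p : p + H, p : p + W] if p else gx_pad
    return gw.reshape(w.shape), gx


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    parents = (x, weight) + ((bias,) if bias is not None else ())
    y = _conv3d_forward(x.data, weight.data, None if bias is None else bias.data)
    out = Tensor(y, parents=parents)

    def bwd(g, x=x, weight=weight, bias=bias):
        gw, gx = _conv3d_backward(x.data, weight.data, g, need_gx=x.requires_grad)
        if weight.requires_grad:
            weight._accumulate(gw)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(1, 2, 3)))
        if x.requires_grad and gx is not None:
            x._accumulate(gx)

    out._backward = bwd
    return out


# ------------------------------------------------- transposed conv (k=s=2)

def conv_transpose3d(x: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    """Stride-2, kernel-2 transposed convolution (non-overlapping upsampling).

    ``weight`` has shape (cin, cout, 2, 2, 2).
    """
    cin, D, H, W = x.shape
    _, cout, k, _, _ = weight.shape
    assert k == 2
    y6 = np.tensordot(weight.data, x.data, axes=([0], [0]))
    # y6: (cout, 2, 2, 2, D, H, W) -> (cout, D,2, H,2, W,2)
    y = np.ascontiguousarray(y6.transpose(0, 4, 1, 5, 2, 6, 3)).reshape(
        cout, 2 * D, 2 * H, 2 * W
    )
    if bias is not None:
        y += bias.data[:, None, None, None]
    parents = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor(y, parents=parents)

    def bwd(g, x=x, weight=weight, bias=bias, D=D, H=H, W=W, cout=cout):
        gb = g.reshape(cout, D, 2, H, 2, W, 2).transpose(0, 2, 4, 6, 1, 3, 5)
        # gb: (cout, 2, 2, 2, D, H, W)
        if weight.requires_grad:
            gw = np.tensordot(x.data, gb, axes=([1, 2, 3], [4, 5, 6]))
            weight._accumulate(gw)  # (cin, cout, 2, 2, 2)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(1, 2, 3)))
        if x.requires_grad:
            gx = np.tensordot(weight.data, gb, axes=([1, 2, 3, 4], [0, 1, 2, 3]))
            x._accumulate(gx)

    out._backward = bwd
    return out


# ------------------------------------------------------------ max pooling

def maxpool3d(x: Tensor) -> Tensor:
    """2x2x2 max pooling; requires even spatial dims."""
    C, D, H, W = x.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"maxpool3d needs even dims, got {(D, H, W)}")
    xr = x.data.reshape(C, D // 2, 2, H // 2, 2, W // 2, 2)
    xw = np.ascontiguousarray(xr.transpose(0, 1, 3, 5, 2, 4, 6)).reshape(
        C, D // 2, H // 2, W // 2, 8
    )
    idx = xw.argmax(axis=-1)
    y = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
    out = Tensor(y, parents=(x,))

    def bwd(g, x=x, idx=idx, C=C, D=D, H=H, W=W):
        gw = np.zeros((C, D // 2, H // 2, W // 2, 8), dtype=np.float32)
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gx = gw.reshape(C, D // 2, H // 2, W // 2, 2, 2, 2).transpose(
            0, 1, 4, 2, 5, 3, 6
        )
        x._accumulate(np.ascontiguousarray(gx).reshape(C, D, H, W))

    out._backward = bwd
    return out


# ----------------------------------------------------- pixel (un)shuffle

def pixel_unshuffle3(x: Tensor, r: int) -> Tensor:
    """(C, D, H, W) -> (C*r^3, D/r, H/r, W/r), pure rearrangement.

    Voxel ``(c, d, h, w)`` lands in channel
    ``c*r^3 + (d%r)*r^2 + (h%r)*r + (w%r)`` at ``(d//r, h//r, w//r)``.
    """
    C, D, H, W = x.shape
    if r == 1:
        return x
    if D % r or H % r or W % r:
        raise ValueError(f"dims {(D, H, W)} not divisible by r={r}")
    xr = x.data.reshape(C, D // r, r, H // r, r, W // r, r)
    y = np.ascontiguousarray(xr.transpose(0, 2, 4, 6, 1, 3, 5)).reshape(
        C * r ** 3, D // r, H // r, W // r
    )
    out = Tensor(y, parents=(x,))

    def bwd(g, x=x, C=C, D=D, H=H, W=W, r=r):
        gr = g.reshape(C, r, r, r, D // r, H // r, W // r).transpose(
            0, 4, 1, 5, 2, 6, 3
        )
        x._accumulate(np.ascontiguousarray(gr).reshape(C, D, H, W))

    out._backward = bwd
    return out


def pixel_shuffle3(x: Tensor, r: int) -> Tensor:
    """Exact inverse of :func:`pixel_unshuffle3`."""
    C, D, H, W = x.shape
    if r == 1:
        return x
    if C % r ** 3:
        raise ValueError(f"channels {C} not divisible by r^3={r ** 3}")
    c = C // r ** 3
    xr = x.data.reshape(c, r, r, r, D, H, W)
    y = np.ascontiguousarray(xr.transpose(0, 4, 1, 5, 2, 6, 3)).reshape(
        c, D * r, H * r, W * r
    )
    out = Tensor(y, parents=(x,))

    def bwd(g, x=x, c=c, D=D, H=H, W=W, r=r):
        gr = g.reshape(c, D, r, H, r, W, r).transpose(0, 2, 4, 6, 1, 3, 5)
        x._accumulate(np.ascontiguousarray(gr).reshape(c * r ** 3, D, H, W))

    out._backward = bwd
    return out


# ------------------------------------------------------- fixed filters

def correlate1d(x: Tensor, kernel: np.ndarray, axis: int) -> Tensor:
    """Correlation with a fixed (non-trainable) 1D kernel, zero padding.

    The adjoint of zero-padded correlation is zero-padded convolution,
    i.e. correlation with the reversed kernel.
    """
    kernel = np.asarray(kernel, dtype=np.float32)
    y = _corr1d(x.data, kernel, axis)
    out = Tensor(y, parents=(x,))
    out._backward = lambda g, a=x, k=kernel[::-1], ax=axis: a._accumulate(
        _corr1d(g, k, ax)
    )
    return out


def _corr1d(arr: np.ndarray, kernel: np.ndarray, axis: int) -> np.ndarray:
    k = kernel.size
    p = k // 2
    pad = [(0, 0)] * arr.ndim
    pad[axis] = (p, p)
    ap = np.pad(arr, pad)
    win = sliding_window_view(ap, k, axis=axis)
    return np.tensordot(win, kernel, axes=([-1], [0])).astype(np.float32)


def upsample_nearest(x: Tensor, factors) -> Tensor:
    """Nearest-neighbour upsampling by integer factors over the spatial axes.

    Input is (C, D, H, W); backward is the block sum (adjoint of replication).
    """
    fd, fh, fw = (int(f) for f in factors)
    y = np.repeat(np.repeat(np.repeat(x.data, fd, axis=1), fh, axis=2), fw, axis=3)
    out = Tensor(y, parents=(x,))

    def bwd(g, x=x, fd=fd, fh=fh, fw=fw):
        C, D, H, W = x.shape
        gr = g.reshape(C, D, fd, H, fh, W, fw).sum(axis=(2, 4, 6))
        x._accumulate(gr)

    out._backward = bwd
    return out


# ------------------------------------------------ inference perturbations

def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted voxel-wise dropout with a mask drawn from ``rng``."""
    if rate <= 0:
        return x
    keep = (rng.random(x.shape) >= rate).astype(np.float32) / (1.0 - rate)
    out = Tensor(x.data * keep, parents=(x,))
    out._backward = lambda g, a=x, m=keep: a._accumulate(g * m)
    return out


def gaussian_noise(x: Tensor, sd: float, rng: np.random.Generator) -> Tensor:
    """Additive Gaussian perturbation with standard deviation ``sd``."""
    if sd <= 0:
        return x
    out = Tensor(
        x.data + rng.normal(0.0, sd, x.shape).astype(np.float32), parents=(x,)
    )
    out._backward = lambda g, a=x: a._accumulate(g)
    return out


def sobel_magnitude(x: Tensor, eps: float = 1e-12) -> Tensor:
    """Differentiable 3D Sobel gradient magnitude of a (C, D, H, W) tensor.

    Separable kernels: derivative [-1, 0, 1] on the gradient axis,
    smoothing [1, 2, 1] on the other two; zero padding at the border.
    ``eps`` regularises the square root away from zero for training.
    """
    from voxsr.nn.tensor import square as _sq, sqrt as _sqrt

    deriv = np.array([-1.0, 0.0, 1.0], dtype=np.float32)
    smooth = np.array([1.0, 2.0, 1.0], dtype=np.float32)
    comps = []
    for axis in (1, 2, 3):
        g = x
        for ax in (1, 2, 3):
            g = correlate1d(g, deriv if ax == axis else smooth, ax)
        comps.append(g)
    mag2 = _sq(comps[0]) + _sq(comps[1]) + _sq(comps[2])
    return _sqrt(mag2, eps=eps)
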
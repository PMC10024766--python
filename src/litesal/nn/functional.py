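"""Structured differentiable operations: convolution, pooling, resampling.

Convolution is evaluated tap-by-tap (one GEMM per kernel element via
``np.tensordot``), which keeps memory flat compared to im2col while still
routing the arithmetic through BLAS.  Bilinear resampling and adaptive
average pooling are expressed as separable interpolation matrices, so their
backward passes are the transposed matrix products.
"""

from __future__ import annotations

import functools

import numpy as np

from .tensor import Tensor, as_tensor, build, _accum

__all__ = [
    "conv2d",
    "max_pool2d",
    "resize_bilinear",
    "adaptive_avg_pool2d",
    "global_avg_pool",
    "binary_cross_entropy",
]


def _im2col(xp: np.ndarray, kh: int, kw: int, oh: int, ow: int, s: int, d: int) -> np.ndarray:
    """Padded NCHW input -> column tensor (N, C*kh*kw, OH*OW)."""
    n, c = xp.shape[0], xp.shape[1]
    sn, sc, sh, sw = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, kh, kw, oh, ow),
        strides=(sn, sc, sh * d, sw * d, sh * s, sw * s),
        writeable=False,
    )
    return np.ascontiguousarray(win).reshape(n, c * kh * kw, oh * ow)


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
) -> Tensor:
    """2-D cross-correlation on NCHW input with OIHW weights.

    Evaluated as a single GEMM over an im2col matrix; the column matrix is
    rebuilt in the backward pass instead of being stored, which keeps the
    memory of a taped full-network pass flat.
    """
    x, w = as_tensor(x), as_tensor(w)
    n, cin, h, wd = x.shape
    cout, cin_w, kh, kw = w.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    s, p, d = int(stride), int(padding), int(dilation)
    oh = (h + 2 * p - d * (kh - 1) - 1) // s + 1
    ow = (wd + 2 * p - d * (kw - 1) - 1) // s + 1
    if oh < 1 or ow < 1:
        raise ValueError("conv2d: kernel does not fit input")
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    wm = w.data.reshape(cout, cin * kh * kw)
    pointwise = kh == kw == 1 and s == 1  # 1x1 convs need no column copy

    if pointwise:
        col = xp.reshape(n, cin, oh * ow)
    else:
        col = _im2col(xp, kh, kw, oh, ow, s, d)
    data = np.matmul(wm[None], col).reshape(n, cout, oh, ow)
    if b is not None:
        data += b.data.reshape(1, cout, 1, 1)

    parents = (x, w) if b is None else (x, w, b)
    out: Tensor = None  # type: ignore[assignment]

    def bwd():
        g = out.grad  # (n,cout,oh,ow)
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=(0, 2, 3)))
        need_x = x.requires_grad
        need_w = w.requires_grad
        if not (need_x or need_w):
            return
        gm = g.reshape(n, cout, oh * ow)
        if need_w:
            gw = np.matmul(gm, col.transpose(0, 2, 1)).sum(axis=0)
            _accum(w, gw.reshape(w.shape))
        if need_x:
            gcol = np.matmul(wm.T[None], gm)  # (n, cin*kh*kw, oh*ow)
            if pointwise:
                _accum(x, gcol.reshape(x.shape))
                return
            gcol = gcol.reshape(n, cin, kh, kw, oh, ow)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i * d : i * d + (oh - 1) * s + 1 : s,
                        j * d : j * d + (ow - 1) * s + 1 : s] += gcol[:, :, i, j]
            _accum(x, gxp[:, :, p : p + h, p : p + wd] if p else gxp)

    out = build(data, parents, bwd)
    return out


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k x k max pooling (spatial dims must divide k)."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"max_pool2d: {h}x{w} not divisible by {k}")
    oh, ow = h // k, w // k
    win = x.data.reshape(n, c, oh, k, ow, k).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, oh, ow, k * k)
    idx = win.argmax(axis=-1)
    data = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    out: Tensor = None  # type: ignore[assignment]

    def bwd():
        if not x.requires_grad:
            return
        gwin = np.zeros((n, c, oh, ow, k * k), dtype=np.float32)
        np.put_along_axis(gwin, idx[..., None], out.grad[..., None], axis=-1)
        gx = gwin.reshape(n, c, oh, ow, k, k).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        _accum(x, gx)

    out = build(np.ascontiguousarray(data), (x,), bwd)
    return out


@functools.lru_cache(maxsize=256)
def _interp_matrix(src: int, dst: int) -> np.ndarray:
    """Bilinear interpolation matrix (dst, src), align_corners=False."""
    m = np.zeros((dst, src), dtype=np.float32)
    if src == 1:
        m[:, 0] = 1.0
        return m
    pos = (np.arange(dst, dtype=np.float64) + 0.5) * src / dst - 0.5
    pos = np.clip(pos, 0.0, src - 1.0)
    i0 = np.floor(pos).astype(int)
    i1 = np.minimum(i0 + 1, src - 1)
    frac = (pos - i0).astype(np.float32)
    for r in range(dst):
        m[r, i0[r]] += 1.0 - frac[r]
        m[r, i1[r]] += frac[r]
    return m


@functools.lru_cache(maxsize=256)
def _pool_matrix(src: int, bins: int) -> np.ndarray:
    """Adaptive average-pooling matrix (bins, src)."""
    if bins > src:
        raise ValueError(f"adaptive pool: {bins} bins exceed size {src}")
    m = np.zeros((bins, src), dtype=np.float32)
    for b in range(bins):
        lo = (b * src) // bins
        hi = -(-((b + 1) * src) // bins)  # ceil
        m[b, lo:hi] = 1.0 / (hi - lo)
    return m


def _apply_separable(x: Tensor, mh: np.ndarray, mw: np.ndarray) -> Tensor:
    """out[n,c,a,b] = sum_{h,w} mh[a,h] mw[b,w] x[n,c,h,w], differentiable."""
    x = as_tensor(x)
    t = np.tensordot(x.data, mh, axes=(2, 1))  # (n,c,w,oh)
    data = np.tensordot(t, mw, axes=(2, 1))    # (n,c,oh,ow)
    out: Tensor = None  # type: ignore[assignment]

    def bwd():
        if not x.requires_grad:
            return
        g = out.grad
        t2 = np.tensordot(g, mw, axes=(3, 0))   # (n,c,oh,w)
        gx = np.tensordot(t2, mh, axes=(2, 0))  # (n,c,w,h)
        _accum(x, np.ascontiguousarray(gx.transpose(0, 1, 3, 2)))

    out = build(np.ascontiguousarray(data), (x,), bwd)
    return out


def resize_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear resample of an NCHW tensor to (oh, ow), align_corners=False."""
    oh, ow = size
    _, _, h, w = x.shape
    if (oh, ow) == (h, w):
        return x
    return _apply_separable(x, _interp_matrix(h, oh), _interp_matrix(w, ow))


def adaptive_avg_pool2d(x: Tensor, bins: tuple[int, int] | int) -> Tensor:
    if isinstance(bins, int):
        bins = (bins, bins)
    _, _, h, w = x.shape
    return _apply_separable(x, _pool_matrix(h, bins[0]), _pool_matrix(w, bins[1]))


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C) spatial mean."""
    from .tensor import tmean

    return tmean(x, axis=(2, 3), keepdims=False)


def batch_norm(
    x: Tensor,
    weight: Tensor,
    bias: Tensor,
    mean: np.ndarray,
    var: np.ndarray,
    eps: float,
    stats_from_x: bool,
) -> Tensor:
    """Channel normalization with affine transform, fused into one tape node.

    ``stats_from_x=True`` means `mean`/`var` are the batch statistics of `x`
    itself (training mode), so the backward pass includes their dependence
    on `x`; ``False`` treats them as constants (running statistics, eval).
    """
    x = as_tensor(x)
    c = x.shape[1]
    inv = (1.0 / np.sqrt(var + eps)).astype(np.float32).reshape(1, c, 1, 1)
    xhat = (x.data - mean.astype(np.float32).reshape(1, c, 1, 1)) * inv
    data = xhat * weight.data.reshape(1, c, 1, 1) + bias.data.reshape(1, c, 1, 1)
    out: Tensor = None  # type: ignore[assignment]

    def bwd():
        g = out.grad
        if bias.requires_grad:
            _accum(bias, g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            _accum(weight, (g * xhat).sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        gxhat = g * weight.data.reshape(1, c, 1, 1)
        if not stats_from_x:
            _accum(x, gxhat * inv)
            return
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        _accum(x, inv * (gxhat - s1 / m - xhat * (s2 / m)))

    out = build(data, (x, weight, bias), bwd)
    return out


def binary_cross_entropy(p: Tensor, y: np.ndarray | Tensor, eps: float = 1e-6) -> Tensor:
    """Mean BCE between a probability map and a binary target.

    Probabilities are clamped to [eps, 1-eps]; the clamp zeroes the gradient
    at saturated pixels rather than producing infinities.
    """
    from .tensor import clip, log, tmean

    p = as_tensor(p)
    yv = y.data if isinstance(y, Tensor) else np.asarray(y, dtype=np.float32)
    if p.shape != yv.shape:
        raise ValueError(f"BCE shape mismatch: {p.shape} vs {yv.shape}")
    pc = clip(p, eps, 1.0 - eps)
    loss = -(Tensor(yv) * log(pc) + Tensor(1.0 - yv) * log(1.0 - pc))
    return tmean(loss)
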
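"""Straight-line, loop-based reference implementations.

These deliberately avoid the package's vectorized tensor ops: convolutions
are quadruple loops, resampling interpolates pixel by pixel, statistics are
computed with plain Python arithmetic.  They exist so the fast paths can be
checked against an independent formulation on tiny inputs.
"""

from __future__ import annotations

import math

import numpy as np


def naive_conv2d(x, w, b=None, stride=1, padding=0, dilation=1):
    """NCHW x OIHW cross-correlation, one output element at a time."""
    n, cin, h, wd = x.shape
    cout, _, kh, kw = w.shape
    s, p, d = stride, padding, dilation
    oh = (h + 2 * p - d * (kh - 1) - 1) // s + 1
    ow = (wd + 2 * p - d * (kw - 1) - 1) // s + 1
    xp = np.zeros((n, cin, h + 2 * p, wd + 2 * p), dtype=np.float64)
    xp[:, :, p : p + h, p : p + wd] = x
    out = np.zeros((n, cout, oh, ow), dtype=np.float64)
    for ni in range(n):
        for oc in range(cout):
            for oy in range(oh):
                for ox in range(ow):
                    acc = 0.0
                    for ic in range(cin):
                        for ky in range(kh):
                            for kx in range(kw):
                                acc += (
                                    w[oc, ic, ky, kx]
                                    * xp[ni, ic, oy * s + ky * d, ox * s + kx * d]
                                )
                    out[ni, oc, oy, ox] = acc + (b[oc] if b is not None else 0.0)
    return out


def naive_batchnorm_train(x, gamma, beta, eps=1e-5):
    out = np.zeros_like(x, dtype=np.float64)
    for c in range(x.shape[1]):
        vals = x[:, c]
        mu = vals.mean()
        var = vals.var()
        out[:, c] = (vals - mu) / math.sqrt(var + eps) * gamma[c] + beta[c]
    return out


def naive_relu(x):
    return np.where(x > 0, x, 0.0)


def naive_sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def naive_bilinear_resize(x, oh, ow):
    """Per-pixel bilinear interpolation, align_corners=False, NCHW."""
    n, c, h, w = x.shape
    out = np.zeros((n, c, oh, ow), dtype=np.float64)
    for oy in range(oh):
        sy = min(max((oy + 0.5) * h / oh - 0.5, 0.0), h - 1.0)
        y0, fy = int(math.floor(sy)), sy - math.floor(sy)
        y1 = min(y0 + 1, h - 1)
        for ox in range(ow):
            sx = min(max((ox + 0.5) * w / ow - 0.5, 0.0), w - 1.0)
            x0, fx = int(math.floor(sx)), sx - math.floor(sx)
            x1 = min(x0 + 1, w - 1)
            out[:, :, oy, ox] = (
                x[:, :, y0, x0] * (1 - fy) * (1 - fx)
                + x[:, :, y0, x1] * (1 - fy) * fx
                + x[:, :, y1, x0] * fy * (1 - fx)
                + x[:, :, y1, x1] * fy * fx
            )
    return out


def naive_adaptive_avgpool(x, bh, bw):
    n, c, h, w = x.shape
    out = np.zeros((n, c, bh, bw), dtype=np.float64)
    for by in range(bh):
        y0, y1 = (by * h) // bh, -(-((by + 1) * h) // bh)
        for bx in range(bw):
            x0, x1 = (bx * w) // bw, -(-((bx + 1) * w) // bw)
            out[:, :, by, bx] = x[:, :, y0:y1, x0:x1].mean(axis=(2, 3))
    return out


def naive_maxpool2(x):
    n, c, h, w = x.shape
    out = np.zeros((n, c, h // 2, w // 2), dtype=np.float64)
    for oy in range(h // 2):
        for ox in range(w // 2):
            out[:, :, oy, ox] = x[:, :, 2 * oy : 2 * oy + 2, 2 * ox : 2 * ox + 2].max(axis=(2, 3))
    return out


def naive_weighted_fbeta(p, y, beta2=1.0, sigma=5.0, ksize=7, alpha=math.log(0.5) / 5.0):
    """Dense re-derivation of the weighted F-measure on small arrays.

    Distances, nearest-foreground indices and the Gaussian dependency
    smoothing are all computed with explicit per-pixel searches.
    """
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y).astype(bool)
    h, w = y.shape
    fg = [(i, j) for i in range(h) for j in range(w) if y[i, j]]
    assert fg, "oracle needs foreground"
    E = np.abs(p - y.astype(float))

    dist = np.zeros((h, w))
    nearest = {}
    for i in range(h):
        for j in range(w):
            if y[i, j]:
                nearest[(i, j)] = (i, j)
                continue
            best, arg = None, None
            for (fi, fj) in fg:
                d2 = (fi - i) ** 2 + (fj - j) ** 2
                if best is None or d2 < best:
                    best, arg = d2, (fi, fj)
            dist[i, j] = math.sqrt(best)
            nearest[(i, j)] = arg

    Et = E.copy()
    for i in range(h):
        for j in range(w):
            if not y[i, j]:
                Et[i, j] = E[nearest[(i, j)]]

    half = ksize // 2
    kern = np.zeros((ksize, ksize))
    for a in range(ksize):
        for b in range(ksize):
            kern[a, b] = math.exp(-((a - half) ** 2 + (b - half) ** 2) / (2 * sigma**2))
    kern /= kern.sum()

    EA = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for a in range(ksize):
                for b in range(ksize):
                    ii, jj = i + a - half, j + b - half
                    if 0 <= ii < h and 0 <= jj < w:
                        acc += kern[a, b] * Et[ii, jj]
            EA[i, j] = acc

    min_e = E.copy()
    for i in range(h):
        for j in range(w):
            if y[i, j] and EA[i, j] < E[i, j]:
                min_e[i, j] = EA[i, j]

    Ew = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            B = 1.0 if y[i, j] else 2.0 - math.exp(alpha * dist[i, j])
            Ew[i, j] = min_e[i, j] * B

    nfg = len(fg)
    tpw = nfg - sum(Ew[i, j] for (i, j) in fg)
    fpw = sum(Ew[i, j] for i in range(h) for j in range(w) if not y[i, j])
    recall = 1.0 - sum(Ew[i, j] for (i, j) in fg) / nfg
    precision = tpw / (tpw + fpw + 1e-12)
    den = beta2 * precision + recall
    return 0.0 if den <= 0 else (1 + beta2) * precision * recall / den


def naive_max_f(p, y, n_thresholds=256, beta2=0.3):
    """Exhaustive threshold sweep with per-threshold set arithmetic."""
    y = np.asarray(y).astype(bool)
    best = 0.0
    for t in np.linspace(0.0, 1.0, n_thresholds):
        pred = np.asarray(p) > t
        tp = float(np.logical_and(pred, y).sum())
        if tp == 0:
            continue
        prec = tp / pred.sum()
        rec = tp / y.sum()
        best = max(best, (1 + beta2) * prec * rec / (beta2 * prec + rec))
    return best
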
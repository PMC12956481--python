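"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine: a :class:`Tensor` wraps a float
``ndarray`` (float32 in training, float64 preserved when supplied) and
records the operations applied to it; ``Tensor.backward()``
walks the tape in reverse topological order and accumulates gradients.
Only the operations the segmentation networks need are implemented
(convolution, batch normalisation, bilinear resampling, element-wise
arithmetic, reductions, attention-style pooling).  Everything is pure
NumPy, single threaded, and bit-deterministic for fixed inputs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "sub",
    "mul",
    "neg",
    "relu",
    "sigmoid",
    "absolute",
    "log",
    "clamp",
    "mean_all",
    "sum_all",
    "reduce_mean",
    "reduce_max",
    "concat",
    "pad2d",
    "conv2d",
    "batch_norm2d",
    "avg_pool2d",
    "global_avg_pool",
    "global_max_pool",
    "upsample_bilinear",
    "deform_conv2d",
]


class Tensor:
    """A float array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float32)
        self.data = data
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    # -- conveniences -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def detach(self):
        """Cut the tape: same values, no gradient history."""
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # operator sugar used sparingly in model code
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __neg__(self):
        return neg(self)

    # -- backprop -----------------------------------------------------
    def backward(self, grad=None):
        """Accumulate gradients of a scalar (or supplied seed) into leaves."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.astype(t.data.dtype, copy=True)
    else:
        t.grad = t.grad + g


def _make(data, parents, backward):
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, _parents=tuple(parents) if req else (),
                  _backward=backward if req else None)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------
# element-wise arithmetic
# ---------------------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def neg(a):
    a = as_tensor(a)

    def backward(g):
        _accum(a, -g)

    return _make(-a.data, (a,), backward)


def sub(a, b):
    return add(a, neg(as_tensor(b)))


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.shape))
        _accum(b, _unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def relu(a):
    a = as_tensor(a)
    mask = a.data > 0

    def backward(g):
        _accum(a, g * mask)

    return _make(a.data * mask, (a,), backward)


def sigmoid(a):
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        _accum(a, g * s * (1.0 - s))

    return _make(s, (a,), backward)


def absolute(a):
    a = as_tensor(a)
    sign = np.sign(a.data)

    def backward(g):
        _accum(a, g * sign)

    return _make(np.abs(a.data), (a,), backward)


def log(a):
    a = as_tensor(a)

    def backward(g):
        _accum(a, g / a.data)

    return _make(np.log(a.data), (a,), backward)


def clamp(a, lo, hi):
    a = as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = (a.data >= lo) & (a.data <= hi)

    def backward(g):
        _accum(a, g * mask)

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------

def sum_all(a):
    a = as_tensor(a)

    def backward(g):
        _accum(a, np.broadcast_to(g, a.shape).astype(a.data.dtype))

    return _make(a.data.sum(), (a,), backward)


def mean_all(a):
    a = as_tensor(a)
    n = a.data.size

    def backward(g):
        _accum(a, np.broadcast_to(g / n, a.shape).astype(a.data.dtype))

    return _make(a.data.mean(), (a,), backward)


def reduce_mean(a, axis, keepdims=True):
    a = as_tensor(a)
    axis = tuple(np.atleast_1d(axis))
    out_data = a.data.mean(axis=axis, keepdims=keepdims)
    n = int(np.prod([a.shape[ax] for ax in axis]))

    def backward(g):
        gg = g
        if not keepdims:
            for ax in sorted(axis):
                gg = np.expand_dims(gg, ax)
        _accum(a, np.broadcast_to(gg / n, a.shape).astype(a.data.dtype))

    return _make(out_data, (a,), backward)


def reduce_max(a, axis, keepdims=True):
    """Max over one axis; ties send the gradient to the first maximiser."""
    a = as_tensor(a)
    out_data = a.data.max(axis=axis, keepdims=True)
    arg = a.data.argmax(axis=axis)
    res = out_data if keepdims else np.squeeze(out_data, axis=axis)

    def backward(g):
        gg = g if keepdims else np.expand_dims(g, axis)
        dx = np.zeros_like(a.data)
        np.put_along_axis(dx, np.expand_dims(arg, axis), gg, axis=axis)
        _accum(a, dx)

    return _make(res, (a,), backward)


def concat(tensors, axis=1):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return _make(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------
# spatial ops (all NCHW)
# ---------------------------------------------------------------------

def pad2d(a, pad_h, pad_w, value=0.0):
    a = as_tensor(a)
    out_data = np.pad(a.data, ((0, 0), (0, 0), (0, pad_h), (0, pad_w)),
                      constant_values=value)

    def backward(g):
        H, W = a.shape[2], a.shape[3]
        _accum(a, g[:, :, :H, :W])

    return _make(out_data, (a,), backward)


def _im2col(xp: np.ndarray, kh, kw, sh, sw, dh, dw, Ho, Wo):
    N, C = xp.shape[:2]
    sN, sC, sH, sW = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp,
        shape=(N, C, kh, kw, Ho, Wo),
        strides=(sN, sC, sH * dh, sW * dw, sH * sh, sW * sw),
    )


def conv2d(x, w, b=None, stride=1, padding=0, dilation=1):
    """2-D cross-correlation, NCHW input, OIHW weights."""
    x, w = as_tensor(x), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    N, C, H, W = x.shape
    Co, Ci, kh, kw = w.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight expects {Ci}")
    sh = sw = int(stride)
    ph = pw = int(padding)
    dh = dw = int(dilation)
    eff_kh = (kh - 1) * dh + 1
    eff_kw = (kw - 1) * dw + 1
    Ho = (H + 2 * ph - eff_kh) // sh + 1
    Wo = (W + 2 * pw - eff_kw) // sw + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if ph or pw else x.data
    cols = _im2col(xp, kh, kw, sh, sw, dh, dw, Ho, Wo)
    out_data = np.tensordot(w.data, cols, axes=([1, 2, 3], [1, 2, 3]))
    out_data = np.ascontiguousarray(out_data.transpose(1, 0, 2, 3))
    if b is not None:
        out_data = out_data + b.data.reshape(1, Co, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        # g: (N, Co, Ho, Wo)
        if w.requires_grad:
            dW = np.tensordot(g, cols, axes=([0, 2, 3], [0, 4, 5]))
            _accum(w, dW)
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # dcols[n,c,i,j,ho,wo] = sum_o g[n,o,ho,wo] w[o,c,i,j]
            dcols = np.tensordot(g, w.data, axes=([1], [0]))  # (N,Ho,Wo,C,kh,kw)
            dcols = dcols.transpose(0, 3, 4, 5, 1, 2)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i * dh:i * dh + (Ho - 1) * sh + 1:sh,
                        j * dw:j * dw + (Wo - 1) * sw + 1:sw] += dcols[:, :, i, j]
            if ph or pw:
                dxp = dxp[:, :, ph:ph + H, pw:pw + W]
            _accum(x, dxp)

    return _make(out_data, parents, backward)


def batch_norm2d(x, gamma, beta, running_mean, running_var, training,
                 momentum=0.1, eps=1e-5):
    """Per-channel normalisation over (N, H, W).

    ``running_mean``/``running_var`` are plain ndarrays updated in place in
    training mode (biased variance is used throughout, documented choice).
    """
    x = as_tensor(x)
    gamma, beta = as_tensor(gamma), as_tensor(beta)
    C = x.shape[1]
    gshape = (1, C, 1, 1)
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= (1 - momentum)
        running_mean += momentum * mean
        running_var *= (1 - momentum)
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(gshape)) * inv.reshape(gshape)
    out_data = gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape)

    def backward(g):
        if gamma.requires_grad:
            _accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            _accum(beta, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gi = g * gamma.data.reshape(gshape)
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                s1 = gi.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (gi * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = (gi - s1 / m - xhat * s2 / m) * inv.reshape(gshape)
            else:
                dx = gi * inv.reshape(gshape)
            _accum(x, dx.astype(x.data.dtype))

    return _make(out_data, (x, gamma, beta), backward)


def avg_pool2d(x, kernel=2, stride=2):
    x = as_tensor(x)
    N, C, H, W = x.shape
    k, s = int(kernel), int(stride)
    Ho = (H - k) // s + 1
    Wo = (W - k) // s + 1
    cols = _im2col(x.data, k, k, s, s, 1, 1, Ho, Wo)
    out_data = cols.mean(axis=(2, 3))

    def backward(g):
        dx = np.zeros_like(x.data)
        gk = g / (k * k)
        for i in range(k):
            for j in range(k):
                dx[:, :, i:i + (Ho - 1) * s + 1:s, j:j + (Wo - 1) * s + 1:s] += gk
        _accum(x, dx)

    return _make(out_data, (x,), backward)


def global_avg_pool(x):
    return reduce_mean(x, axis=(2, 3), keepdims=True)


def global_max_pool(x):
    x = as_tensor(x)
    N, C = x.shape[:2]
    flat = x.data.reshape(N, C, -1)
    arg = flat.argmax(axis=2)
    out_data = flat.max(axis=2).reshape(N, C, 1, 1)

    def backward(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, arg[..., None], g.reshape(N, C, 1), axis=2)
        _accum(x, dflat.reshape(x.shape))

    return _make(out_data, (x,), backward)


def _linear_resample_axis(n_in: int, n_out: int):
    """Index pairs and weights for half-pixel-centre bilinear resampling."""
    scale = n_in / n_out
    src = (np.arange(n_out, dtype=np.float64) + 0.5) * scale - 0.5
    i0 = np.floor(src).astype(np.int64)
    frac = src - i0
    i0c = np.clip(i0, 0, n_in - 1)
    i1c = np.clip(i0 + 1, 0, n_in - 1)
    return i0c, i1c, frac


def upsample_bilinear(x, out_hw):
    """Bilinear resize to ``out_hw`` (half-pixel centres, edges clamped)."""
    x = as_tensor(x)
    N, C, H, W = x.shape
    Ho, Wo = int(out_hw[0]), int(out_hw[1])
    if (Ho, Wo) == (H, W):
        def backward_id(g):
            _accum(x, g)
        return _make(x.data.copy(), (x,), backward_id)
    r0, r1, fr = _linear_resample_axis(H, Ho)
    c0, c1, fc = _linear_resample_axis(W, Wo)
    fr_ = fr.reshape(1, 1, Ho, 1)
    fc_ = fc.reshape(1, 1, 1, Wo)
    top = x.data[:, :, r0][:, :, :, c0] * (1 - fc_) + x.data[:, :, r0][:, :, :, c1] * fc_
    bot = x.data[:, :, r1][:, :, :, c0] * (1 - fc_) + x.data[:, :, r1][:, :, :, c1] * fc_
    out_data = top * (1 - fr_) + bot * fr_

    def backward(g):
        dx = np.zeros_like(x.data)
        rr0 = r0.reshape(Ho, 1)
        rr1 = r1.reshape(Ho, 1)
        cc0 = c0.reshape(1, Wo)
        cc1 = c1.reshape(1, Wo)
        w00 = ((1 - fr_) * (1 - fc_))[0, 0]
        w01 = ((1 - fr_) * fc_)[0, 0]
        w10 = (fr_ * (1 - fc_))[0, 0]
        w11 = (fr_ * fc_)[0, 0]
        for n in range(N):
            for ch in range(C):
                gn = g[n, ch]
                np.add.at(dx[n, ch], (rr0, cc0), gn * w00)
                np.add.at(dx[n, ch], (rr0, cc1), gn * w01)
                np.add.at(dx[n, ch], (rr1, cc0), gn * w10)
                np.add.at(dx[n, ch], (rr1, cc1), gn * w11)
        _accum(x, dx)

    return _make(out_data.astype(x.data.dtype), (x,), backward)


# ---------------------------------------------------------------------
# deformable convolution
# ---------------------------------------------------------------------

def deform_conv2d(x, offset, w, b=None, stride=1, padding=0, dilation=1):
    """Convolution whose kernel taps are displaced by learned offsets.

    ``offset`` has ``2*kh*kw`` channels per output location, ordered
    (dy, dx) per kernel tap.  Samples are taken from ``x`` by bilinear
    interpolation; positions outside the image contribute zero.  With all
    offsets zero this reproduces plain ``conv2d`` exactly (integer-grid
    bilinear sampling is exact).
    """
    x, offset, w = as_tensor(x), as_tensor(offset), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    N, C, H, W = x.shape
    Co, Ci, kh, kw = w.shape
    K = kh * kw
    if offset.shape[1] != 2 * K:
        raise ValueError("offset must have 2*kh*kw channels")
    sh = sw = int(stride)
    ph = pw = int(padding)
    dh = dw = int(dilation)
    eff_kh = (kh - 1) * dh + 1
    eff_kw = (kw - 1) * dw + 1
    Ho = (H + 2 * ph - eff_kh) // sh + 1
    Wo = (W + 2 * pw - eff_kw) // sw + 1

    base_y = (np.arange(Ho) * sh - ph).reshape(1, 1, Ho, 1)
    base_x = (np.arange(Wo) * sw - pw).reshape(1, 1, 1, Wo)
    tap_y = (np.repeat(np.arange(kh), kw) * dh).reshape(1, K, 1, 1)
    tap_x = (np.tile(np.arange(kw), kh) * dw).reshape(1, K, 1, 1)
    off = offset.data.reshape(N, K, 2, Ho, Wo)
    py = base_y + tap_y + off[:, :, 0]          # (N,K,Ho,Wo)
    px = base_x + tap_x + off[:, :, 1]

    y0 = np.floor(py).astype(np.int64)
    x0 = np.floor(px).astype(np.int64)
    fy = py - y0
    fx = px - x0

    nb = np.arange(N).reshape(N, 1, 1, 1)

    def gather(yy, xx):
        valid = (yy >= 0) & (yy < H) & (xx >= 0) & (xx < W)
        yc = np.clip(yy, 0, H - 1)
        xc = np.clip(xx, 0, W - 1)
        vals = x.data[nb, :, yc, xc]            # (N,K,Ho,Wo,C)
        return np.moveaxis(vals, -1, 1), valid  # (N,C,K,Ho,Wo)

    v00, m00 = gather(y0, x0)
    v01, m01 = gather(y0, x0 + 1)
    v10, m10 = gather(y0 + 1, x0)
    v11, m11 = gather(y0 + 1, x0 + 1)
    w00 = ((1 - fy) * (1 - fx) * m00)[:, None]
    w01 = ((1 - fy) * fx * m01)[:, None]
    w10 = (fy * (1 - fx) * m10)[:, None]
    w11 = (fy * fx * m11)[:, None]
    cols = v00 * w00 + v01 * w01 + v10 * w10 + v11 * w11  # (N,C,K,Ho,Wo)

    wk = w.data.reshape(Co, C * K)
    out_data = np.einsum("ok,nkhw->nohw", wk,
                         cols.reshape(N, C * K, Ho, Wo), optimize=True)
    if b is not None:
        out_data = out_data + b.data.reshape(1, Co, 1, 1)

    parents = [x, offset, w] + ([b] if b is not None else [])

    def backward(g):
        if w.requires_grad:
            dW = np.einsum("nohw,nkhw->ok", g,
                           cols.reshape(N, C * K, Ho, Wo), optimize=True)
            _accum(w, dW.reshape(w.shape))
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad or offset.requires_grad:
            dcols = np.einsum("nohw,ok->nkhw", g, wk, optimize=True)
            dcols = dcols.reshape(N, C, K, Ho, Wo)
            if x.requires_grad:
                dx = np.zeros_like(x.data)
                dx_hwview = dx.transpose(0, 2, 3, 1)  # channels-last view
                for yy, xx, ww in ((y0, x0, w00), (y0, x0 + 1, w01),
                                   (y0 + 1, x0, w10), (y0 + 1, x0 + 1, w11)):
                    yc = np.clip(yy, 0, H - 1)
                    xc = np.clip(xx, 0, W - 1)
                    contrib = np.moveaxis(dcols * ww, 1, -1)  # (N,K,Ho,Wo,C)
                    np.add.at(dx_hwview, (nb, yc, xc), contrib)
                _accum(x, dx)
            if offset.requires_grad:
                dfy = (dcols * (-(1 - fx)[:, None] * m00[:, None] * v00
                                - fx[:, None] * m01[:, None] * v01
                                + (1 - fx)[:, None] * m10[:, None] * v10
                                + fx[:, None] * m11[:, None] * v11)).sum(axis=1)
                dfx = (dcols * (-(1 - fy)[:, None] * m00[:, None] * v00
                                + (1 - fy)[:, None] * m01[:, None] * v01
                                - fy[:, None] * m10[:, None] * v10
                                + fy[:, None] * m11[:, None] * v11)).sum(axis=1)
                doff = np.stack([dfy, dfx], axis=2).reshape(offset.shape)
                _accum(offset, doff)

    return _make(out_data.astype(x.data.dtype), tuple(parents), backward)
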
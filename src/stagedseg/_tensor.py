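"""Minimal reverse-mode autodiff over NumPy arrays.

Implements exactly the operations the 3D encoder-decoder needs: 3D
correlation (stride 1 and 2) via im2col and BLAS matmul, kernel-2/stride-2
transposed convolution for upsampling, instance normalization, leaky ReLU,
residual addition, channel concatenation, and scalar arithmetic for loss
aggregation.  Convolution backward is expressed as another correlation
(dilate-pad-flip), so no scatter-add appears anywhere on the hot path.

Tensors carry float32 data; gradients are accumulated in float32.  The tape
is a flat list of nodes in creation order, so backward is a reverse sweep —
no explicit topological sort is needed because operations are recorded in
execution order.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np

from . import _kernels

USE_NUMBA = _kernels.HAVE_NUMBA


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "_tape")

    def __init__(self, data, requires_grad=False, parents=(), tape=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[], None]] = None
        self._parents = parents
        self._tape = tape
        if tape is not None:
            tape.append(self)

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g: np.ndarray, own: bool = False) -> None:
        """Add g to the gradient.

        ``own=True`` promises that g is freshly computed and never re-read by
        its producer, so it may be adopted without a copy.
        """
        if self.grad is None:
            arr = np.asarray(g, dtype=np.float32)
            self.grad = arr if own else arr.copy()
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse sweep over the tape from this (scalar) tensor.

        The tape is released afterwards: backward closures capture their own
        output tensor, so the graph is cyclic and would otherwise sit in
        memory until the garbage collector's generation-2 pass.
        """
        if self._tape is None:
            raise RuntimeError("backward requires a taped tensor")
        self.grad = np.ones_like(self.data)
        for node in reversed(self._tape):
            if node.grad is not None and node._backward is not None:
                node._backward()
        self.release_tape()

    def release_tape(self) -> None:
        """Break the tensor/closure reference cycles of this tensor's tape."""
        tape = self._tape
        if tape is None:
            return
        for node in tape:
            node._backward = None
            node._parents = ()
            node._tape = None
        tape.clear()


class Parameter(Tensor):
    """A learnable tensor; lives outside any tape."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)

    def zero_grad(self) -> None:
        self.grad = None


def _as_triple(v) -> tuple[int, int, int]:
    if np.isscalar(v):
        return (int(v),) * 3
    return tuple(int(x) for x in v)


# Workspace pool: im2col gathers and padded inputs are large relative to the
# weights, and reallocating them every step costs more in page faults than the
# arithmetic.  Buffers are keyed per conv layer (weight identity), which is
# safe because a layer's forward is never re-entered before its backward.
_POOL: dict = {}


def clear_buffers() -> None:
    _POOL.clear()


def _buffer(key, shape) -> np.ndarray:
    buf = _POOL.get(key)
    if buf is None or buf.shape != shape:
        buf = np.empty(shape, dtype=np.float32)
        _POOL[key] = buf
    return buf


def _padded(x: np.ndarray, pad, key) -> np.ndarray:
    if max(pad) == 0:
        return x
    n, c, d, h, w = x.shape
    shape = (n, c, d + 2 * pad[0], h + 2 * pad[1], w + 2 * pad[2])
    if key is None:
        xp = np.zeros(shape, dtype=np.float32)
    else:
        xp = _buffer((key, "pad"), shape)
        xp.fill(0.0)
    xp[:, :, pad[0] : pad[0] + d, pad[1] : pad[1] + h, pad[2] : pad[2] + w] = x
    return xp


def _weight_mat(w: np.ndarray) -> np.ndarray:
    """(O, C, kd, kh, kw) -> (O, K*C) matching the im2col layout below."""
    o, c = w.shape[:2]
    k = int(np.prod(w.shape[2:]))
    return np.ascontiguousarray(w.reshape(o, c, k).transpose(0, 2, 1)).reshape(o, k * c)


def _im2col(x: np.ndarray, kshape, stride, pad, key=None) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Gather kernel-offset slices: (N, C, D, H, W) -> (N, K, C, D', H', W').

    Built with one contiguous slice copy per kernel offset, which is far
    cheaper than a strided multi-axis gather.
    """
    kd, kh, kw = kshape
    sd, sh, sw = stride
    n, c = x.shape[:2]
    xp = _padded(x, pad, key)
    dp, hp, wp = xp.shape[2:]
    od, oh, ow = (dp - kd) // sd + 1, (hp - kh) // sh + 1, (wp - kw) // sw + 1
    shape = (n, kd * kh * kw, c, od, oh, ow)
    cols = np.empty(shape, dtype=np.float32) if key is None else _buffer((key, "cols"), shape)
    idx = 0
    for i in range(kd):
        for j in range(kh):
            for k in range(kw):
                cols[:, idx] = xp[
                    :,
                    :,
                    i : i + (od - 1) * sd + 1 : sd,
                    j : j + (oh - 1) * sh + 1 : sh,
                    k : k + (ow - 1) * sw + 1 : sw,
                ]
                idx += 1
    return cols, (od, oh, ow)


def _out_shape(x_shape, k, stride, pad):
    return tuple(
        (x_shape[2 + ax] + 2 * pad[ax] - k[ax]) // stride[ax] + 1 for ax in range(3)
    )


def _corr3d(x: np.ndarray, w: np.ndarray, stride, pad, key=None) -> tuple[np.ndarray, np.ndarray]:
    """Batched 3D cross-correlation.

    x: (N, C, D, H, W); w: (O, C, kd, kh, kw).  Returns (out, ctx) where ctx
    (the padded input with numba, the im2col matrix without) is reused for
    the weight gradient.
    """
    stride = _as_triple(stride)
    pad = _as_triple(pad)
    n, c = x.shape[:2]
    o = w.shape[0]
    if USE_NUMBA:
        xp = _padded(np.ascontiguousarray(x, dtype=np.float32), pad, key)
        od, oh, ow = _out_shape(x.shape, w.shape[2:], stride, pad)
        shape = (n, o, od, oh, ow)
        out = np.empty(shape, dtype=np.float32) if key is None else _buffer((key, "out"), shape)
        if stride == (1, 1, 1) and w.shape[2:] == (3, 3, 3):
            _kernels.corr_fwd3(xp, w, out)
        else:
            _kernels.corr_fwd(xp, w, stride[0], stride[1], stride[2], out)
        return out, xp
    cols, (od, oh, ow) = _im2col(x, w.shape[2:], stride, pad, key=key)
    wmat = _weight_mat(w)
    p = od * oh * ow
    shape = (n, o, od, oh, ow)
    out = np.empty(shape, dtype=np.float32) if key is None else _buffer((key, "out"), shape)
    flat = cols.reshape(n, -1, p)
    outflat = out.reshape(n, o, p)
    for i in range(n):
        np.matmul(wmat, flat[i], out=outflat[i])
    return out, cols


def _corr3d_weight_grad(dy: np.ndarray, ctx: np.ndarray, w_shape, stride) -> np.ndarray:
    stride = _as_triple(stride)
    dw = np.zeros(w_shape, dtype=np.float32)
    if USE_NUMBA:
        dy = np.ascontiguousarray(dy, dtype=np.float32)
        if stride == (1, 1, 1) and tuple(w_shape[2:]) == (3, 3, 3):
            _kernels.corr_dw3(ctx, dy, dw)
        else:
            _kernels.corr_dw(ctx, dy, stride[0], stride[1], stride[2], dw)
        return dw
    cols = ctx
    n, o = dy.shape[:2]
    p = int(np.prod(dy.shape[2:]))
    kc = cols.shape[1] * cols.shape[2]
    dwm = np.zeros((o, kc), dtype=np.float32)
    flat = cols.reshape(n, kc, p)
    dyf = dy.reshape(n, o, p)
    for i in range(n):
        dwm += dyf[i] @ flat[i].T
    k = int(np.prod(w_shape[2:]))
    return np.ascontiguousarray(dwm.reshape(o, k, w_shape[1]).transpose(0, 2, 1)).reshape(w_shape)


def _corr3d_input_grad(dy: np.ndarray, w: np.ndarray, x_shape, stride, pad, key=None) -> np.ndarray:
    """Gradient of _corr3d w.r.t. its input, itself expressed as a correlation."""
    stride = _as_triple(stride)
    pad = _as_triple(pad)
    n, o, od, oh, ow = dy.shape
    _, c, kd, kh, kw = w.shape
    d, h, wd = x_shape[2:]
    k = (kd, kh, kw)
    w_flip_t = np.ascontiguousarray(w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
    if stride == (1, 1, 1) and all(
        2 * pad[ax] == k[ax] - 1 or k[ax] == 1 for ax in range(3)
    ):
        # stride-1 "same"/1x1 convs: the input gradient is a plain correlation
        # of dy with the flipped kernel at complementary padding
        ig_pad = tuple(k[ax] - 1 - pad[ax] for ax in range(3))
        dx, _ = _corr3d(dy, w_flip_t, stride=1, pad=ig_pad,
                        key=(key, "ig") if key is not None else None)
        return dx
    # dilate by the stride, then pad so that a stride-1 correlation with the
    # flipped kernel yields the padded input size; the right side absorbs the
    # part of the input the window never reached
    pads = []
    for ax in range(3):
        dp = x_shape[2 + ax] + 2 * pad[ax]
        covered = (dy.shape[2 + ax] - 1) * stride[ax] + k[ax]
        pads.append((k[ax] - 1, k[ax] - 1 + (dp - covered)))
    dil_shape = (n, o) + tuple(
        (osz - 1) * s + 1 + pl + pr
        for osz, s, (pl, pr) in zip((od, oh, ow), stride, pads)
    )
    if key is None:
        dilp = np.zeros(dil_shape, dtype=np.float32)
    else:
        dilp = _buffer((key, "dil"), dil_shape)
        dilp.fill(0.0)
    dilp[
        :,
        :,
        pads[0][0] : pads[0][0] + (od - 1) * stride[0] + 1 : stride[0],
        pads[1][0] : pads[1][0] + (oh - 1) * stride[1] + 1 : stride[1],
        pads[2][0] : pads[2][0] + (ow - 1) * stride[2] + 1 : stride[2],
    ] = dy
    dxp, _ = _corr3d(dilp, w_flip_t, stride=1, pad=0, key=(key, "ig") if key is not None else None)
    return dxp[:, :, pad[0] : pad[0] + d, pad[1] : pad[1] + h, pad[2] : pad[2] + wd]


def conv3d(x: Tensor, w: Parameter, b: Parameter, stride=1, pad=1, tape=None) -> Tensor:
    tape = tape if tape is not None else x._tape
    key = id(w)
    out_data, ctx = _corr3d(x.data, w.data, stride, pad, key=key)
    out_data += b.data.reshape(1, -1, 1, 1, 1)
    out = Tensor(out_data, parents=(x, w, b), tape=tape)

    def _backward():
        dy = out.grad
        w.accumulate(_corr3d_weight_grad(dy, ctx, w.data.shape, stride), own=True)
        b.accumulate(dy.sum(axis=(0, 2, 3, 4)), own=True)
        if x.requires_grad or x._backward is not None or x._tape is not None:
            x.accumulate(_corr3d_input_grad(dy, w.data, x.data.shape, stride, pad, key=key), own=True)

    out._backward = _backward
    return out


def upconv2(x: Tensor, w: Parameter, b: Parameter, tape=None) -> Tensor:
    """Transposed convolution with kernel 2, stride 2 (non-overlapping upsampling).

    w: (C_in, O, 2, 2, 2).
    """
    tape = tape if tape is not None else x._tape
    n, c, d, h, wd = x.data.shape
    o = w.data.shape[1]
    y = np.einsum("ncdhw,coijk->nodihjwk", x.data, w.data, optimize=True)
    y = y.reshape(n, o, 2 * d, 2 * h, 2 * wd) + b.data.reshape(1, -1, 1, 1, 1)
    out = Tensor(y, parents=(x, w, b), tape=tape)

    def _backward():
        dy = out.grad.reshape(n, o, d, 2, h, 2, wd, 2)
        w.accumulate(np.einsum("ncdhw,nodihjwk->coijk", x.data, dy, optimize=True))
        b.accumulate(out.grad.sum(axis=(0, 2, 3, 4)))
        x.accumulate(np.einsum("nodihjwk,coijk->ncdhw", dy, w.data, optimize=True))

    out._backward = _backward
    return out


def instance_norm(x: Tensor, gamma: Parameter, beta: Parameter, eps=1e-5, tape=None) -> Tensor:
    """Per-sample, per-channel normalization over the spatial axes."""
    tape = tape if tape is not None else x._tape
    if USE_NUMBA:
        n, c = x.data.shape[:2]
        xd = np.ascontiguousarray(x.data, dtype=np.float32)
        y = np.empty_like(xd)
        mu = np.empty((n, c), dtype=np.float32)
        inv = np.empty((n, c), dtype=np.float32)
        _kernels.innorm_fwd(xd, gamma.data, beta.data, np.float32(eps), y, mu, inv)
        out = Tensor(y, parents=(x, gamma, beta), tape=tape)

        def _backward():
            dy = np.ascontiguousarray(out.grad, dtype=np.float32)
            dx = np.empty_like(xd)
            dgamma = np.zeros(c, dtype=np.float32)
            dbeta = np.zeros(c, dtype=np.float32)
            _kernels.innorm_bwd(xd, dy, gamma.data, mu, inv, dx, dgamma, dbeta)
            gamma.accumulate(dgamma, own=True)
            beta.accumulate(dbeta, own=True)
            x.accumulate(dx, own=True)

        out._backward = _backward
        return out

    axes = (2, 3, 4)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    g = gamma.data.reshape(1, -1, 1, 1, 1)
    out = Tensor(xhat * g + beta.data.reshape(1, -1, 1, 1, 1), parents=(x, gamma, beta), tape=tape)

    def _backward():
        dy = out.grad
        gamma.accumulate((dy * xhat).sum(axis=(0, 2, 3, 4)), own=True)
        beta.accumulate(dy.sum(axis=(0, 2, 3, 4)), own=True)
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        ) * inv
        x.accumulate(dx, own=True)

    out._backward = _backward
    return out


def leaky_relu(x: Tensor, alpha=1e-2, tape=None) -> Tensor:
    tape = tape if tape is not None else x._tape
    d = x.data
    if USE_NUMBA:
        y = np.empty_like(d)
        _kernels.leaky_fwd(np.ascontiguousarray(d), np.float32(alpha), y)
        out = Tensor(y, parents=(x,), tape=tape)

        def _backward():
            # leaky ReLU with alpha > 0 preserves sign, so the output's sign
            # recovers the branch taken without storing a mask
            dx = np.empty_like(y)
            _kernels.leaky_bwd(y, np.ascontiguousarray(out.grad), np.float32(alpha), dx)
            x.accumulate(dx, own=True)

        out._backward = _backward
        return out
    out = Tensor(np.where(d > 0, d, alpha * d), parents=(x,), tape=tape)

    def _backward():
        x.accumulate(np.where(out.data > 0, out.grad, alpha * out.grad), own=True)

    out._backward = _backward
    return out


def add(a: Tensor, b: Tensor, tape=None) -> Tensor:
    tape = tape if tape is not None else a._tape
    out = Tensor(a.data + b.data, parents=(a, b), tape=tape)

    def _backward():
        a.accumulate(out.grad)
        b.accumulate(out.grad)

    out._backward = _backward
    return out


def concat(tensors: Sequence[Tensor], axis=1, tape=None) -> Tensor:
    tape = tape if tape is not None else tensors[0]._tape
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors), tape=tape)
    sizes = [t.data.shape[axis] for t in tensors]

    def _backward():
        start = 0
        for t, s in zip(tensors, sizes):
            idx = [slice(None)] * out.grad.ndim
            idx[axis] = slice(start, start + s)
            t.accumulate(out.grad[tuple(idx)])
            start += s

    out._backward = _backward
    return out


def scale_add(terms: Sequence[tuple[float, Tensor]], tape=None) -> Tensor:
    """Weighted sum of scalar tensors (loss aggregation)."""
    tape = tape if tape is not None else terms[0][1]._tape
    val = sum(w * t.data for w, t in terms)
    out = Tensor(val, parents=tuple(t for _, t in terms), tape=tape)

    def _backward():
        for w, t in terms:
            t.accumulate(w * out.grad)

    out._backward = _backward
    return out
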
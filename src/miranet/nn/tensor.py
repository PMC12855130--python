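"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small engine — float32 tensors, a static set of operations
(affine, convolution, pooling, bilinear upsampling, softmax, concatenation)
— sufficient to express and train the instruction-guided restoration network
on a CPU.  Gradients are accumulated by closures attached to each node and
released via topological traversal from the loss.

Every operation here is exercised by numerical gradient checks in the test
suite.
"""

from __future__ import annotations

import math

import numpy as np

_F32 = np.float32


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data, dtype=_F32)
        # keep 0-d scalars 0-d (ascontiguousarray would promote them to 1-d)
        self.data = arr if arr.flags.c_contiguous else np.ascontiguousarray(arr)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            # copy: g may alias a buffer another branch still reads
            self.grad = np.array(np.broadcast_to(g, self.data.shape), dtype=_F32)
        else:
            self.grad += g

    def accumulate_owned(self, g: np.ndarray) -> None:
        """Accumulate a gradient buffer the caller guarantees is fresh."""
        if self.grad is None:
            self.grad = g
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) tensor with seed 1."""
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return add(self, mul(other, Tensor(np.array(-1.0))))

    def __matmul__(self, other):
        return matmul(self, other)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=_F32))


def _node(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.astype(_F32, copy=False)


# -- elementwise / affine ---------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def bw(g):
        a.accumulate(_unbroadcast(g, a.shape))
        b.accumulate(_unbroadcast(g, b.shape))

    return _node(a.data + b.data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def bw(g):
        a.accumulate(_unbroadcast(g * b.data, a.shape))
        b.accumulate(_unbroadcast(g * a.data, b.shape))

    return _node(a.data * b.data, (a, b), bw)


def relu(a: Tensor) -> Tensor:
    pos = a.data > 0

    def bw(g):
        a.accumulate_owned(g * pos)

    return _node(a.data * pos, (a,), bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        a.accumulate(g @ b.data.T)
        b.accumulate(a.data.T @ g)

    return _node(a.data @ b.data, (a, b), bw)


def reshape(a: Tensor, shape) -> Tensor:
    old = a.shape

    def bw(g):
        a.accumulate(g.reshape(old))

    return _node(a.data.reshape(shape), (a,), bw)


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice along ``axis`` (used to split MLP heads)."""
    idx = [slice(None)] * a.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)

    def bw(g):
        full = np.zeros_like(a.data)
        full[idx] = g
        a.accumulate(full)

    return _node(a.data[idx], (a,), bw)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, o, s in zip(tensors, offsets[:-1], sizes):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(o, o + s)
            t.accumulate(g[tuple(idx)])

    return _node(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), bw)


def mean(a: Tensor, axes: tuple[int, ...]) -> Tensor:
    count = math.prod(a.shape[i] for i in axes)
    out_data = a.data.mean(axis=axes)

    def bw(g):
        a.accumulate(np.broadcast_to(np.expand_dims(g, axes) / count, a.shape))

    return _node(out_data, (a,), bw)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        a.accumulate(y * (g - dot))

    return _node(y, (a,), bw)


# -- losses -----------------------------------------------------------------

def l1_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred.data - np.asarray(target, dtype=_F32)
    n = diff.size

    def bw(g):
        pred.accumulate(g * np.sign(diff) / n)

    return _node(np.float32(np.abs(diff).mean()), (pred,), bw)


def l2_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred.data - np.asarray(target, dtype=_F32)
    n = diff.size

    def bw(g):
        pred.accumulate(g * 2.0 * diff / n)

    return _node(np.float32((diff * diff).mean()), (pred,), bw)


def charbonnier_loss(pred: Tensor, target: np.ndarray, eps: float = 1e-3) -> Tensor:
    diff = pred.data - np.asarray(target, dtype=_F32)
    root = np.sqrt(diff * diff + eps * eps)
    n = diff.size

    def bw(g):
        pred.accumulate(g * diff / root / n)

    return _node(np.float32(root.mean()), (pred,), bw)


# -- spatial ops (NHWC) ------------------------------------------------------

def _im2col_numpy(xh: np.ndarray, Ho: int, Wo: int, kh: int, kw: int,
                  s: int) -> np.ndarray:
    N, _, _, C = xh.shape
    cols = np.empty((N, Ho, Wo, kh, kw, C), dtype=_F32)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, :, i, j] = xh[:, i:i + s * Ho:s, j:j + s * Wo:s]
    return cols


_im2col = _im2col_numpy


def _pad_hw(arr: np.ndarray, pad: int) -> np.ndarray:
    """Zero-pad the two spatial axes of an NHWC array (border fill only)."""
    n, h, w, c = arr.shape
    out = np.empty((n, h + 2 * pad, w + 2 * pad, c), dtype=_F32)
    out[:, :pad] = 0.0
    out[:, h + pad:] = 0.0
    out[:, pad:h + pad, :pad] = 0.0
    out[:, pad:h + pad, w + pad:] = 0.0
    out[:, pad:h + pad, pad:w + pad] = arr
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation of an NHWC input with (kh, kw, C_in, C_out) weights.

    Channels-last is the engine's native activation layout: the im2col gather
    and the col2im scatter then run over contiguous channel rows and the GEMM
    needs no transposes at all.
    """
    N, H, W, C = x.shape
    kh, kw, _, O = w.shape
    s = stride
    xh = _pad_hw(x.data, pad) if pad else x.data
    Hp, Wp = xh.shape[1:3]
    Ho = (Hp - kh) // s + 1
    Wo = (Wp - kw) // s + 1
    cols2 = _im2col(xh, Ho, Wo, kh, kw, s).reshape(N * Ho * Wo, kh * kw * C)
    wmat = w.data.reshape(kh * kw * C, O)
    out = cols2 @ wmat
    if b is not None:
        out += b.data
    out = out.reshape(N, Ho, Wo, O)

    def bw(g):
        gmat = g.reshape(N * Ho * Wo, O)
        w.accumulate((cols2.T @ gmat).reshape(kh, kw, C, O))
        if b is not None:
            b.accumulate(gmat.sum(axis=0))
        if not (x.requires_grad or x._parents):
            return  # input is a graph leaf: no dx needed
        if s == 1:
            # dx as correlation of g with the 180deg-rotated weights
            # (gather+GEMM is much faster than the scatter-add col2im)
            pg = kh - 1 - pad
            gpad = _pad_hw(g, pg) if pg else g
            gcols = _im2col(gpad, H, W, kh, kw, 1)
            wrot = np.ascontiguousarray(
                w.data[::-1, ::-1].transpose(0, 1, 3, 2)).reshape(kh * kw * O, C)
            dx = (gcols.reshape(N * H * W, kh * kw * O) @ wrot).reshape(N, H, W, C)
            x.accumulate_owned(dx)
            return
        dcols = (gmat @ wmat.T).reshape(N, Ho, Wo, kh, kw, C)
        dxh = np.zeros((N, Hp, Wp, C), dtype=_F32)
        for i in range(kh):
            for j in range(kw):
                dxh[:, i:i + s * Ho:s, j:j + s * Wo:s] += dcols[:, :, :, i, j]
        x.accumulate(dxh[:, pad:pad + H, pad:pad + W] if pad else dxh)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, bw)


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling over the spatial axes of an NHWC tensor."""
    N, H, W, C = x.shape
    out = x.data.reshape(N, H // 2, 2, W // 2, 2, C).mean(axis=(2, 4))

    def bw(g):
        x.accumulate(np.repeat(np.repeat(g, 2, axis=1), 2, axis=2) / 4.0)

    return _node(out, (x,), bw)


_INTERP_CACHE: dict[int, np.ndarray] = {}


def _interp_matrix(n: int) -> np.ndarray:
    """(2n, n) bilinear interpolation matrix, half-pixel convention."""
    m = _INTERP_CACHE.get(n)
    if m is None:
        m = np.zeros((2 * n, n), dtype=_F32)
        for i in range(2 * n):
            src = min(max((i + 0.5) / 2.0 - 0.5, 0.0), n - 1.0)
            i0 = int(math.floor(src))
            i1 = min(i0 + 1, n - 1)
            t = src - i0
            m[i, i0] += 1.0 - t
            m[i, i1] += t
        _INTERP_CACHE[n] = m
    return m


def upsample_bilinear2(x: Tensor) -> Tensor:
    """Exact 2x bilinear upsampling of an NHWC tensor via 1-D linear maps."""
    N, H, W, C = x.shape
    mh = _interp_matrix(H)
    mw = _interp_matrix(W)

    def apply(arr, a, bmat):  # einsum 'hH,nHWc,wW->nhwc'
        t = np.tensordot(arr, a, axes=([1], [1]))      # (N, W, C, 2H)
        t = np.tensordot(t, bmat, axes=([1], [1]))     # (N, C, 2H, 2W)
        return np.ascontiguousarray(t.transpose(0, 2, 3, 1))

    out = apply(x.data, mh, mw)

    def bw(g):
        x.accumulate(apply(g, mh.T, mw.T))

    return _node(out, (x,), bw)
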
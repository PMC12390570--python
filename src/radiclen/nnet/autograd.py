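"""Compact reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the tape in reverse topological order and
accumulates gradients.  Only the operations needed by the radicle networks are
provided: broadcasting arithmetic, matmul, the usual pointwise nonlinearities,
reductions, reshaping/indexing, 2-D convolution, bilinear resampling and
RoIAlign.  Everything is dtype-preserving so the same code runs in float32
for training and float64 in numerical tests.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "stack",
    "where_mask",
    "conv2d",
    "bilinear_resize",
    "roi_align",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        arr = np.asarray(data)
        if arr.dtype.kind in "iub":
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = tuple(_prev)

    # -- basic protocol ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __len__(self):
        return len(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    # -- graph construction helpers ---------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req, _prev=parents if req else ())
        if req:
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS (graphs can be deep for long conv towers)
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._prev if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other, self.dtype)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return as_tensor(other, self.dtype) + (-self)

    def __mul__(self, other):
        other = as_tensor(other, self.dtype)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other, self.dtype)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other, self.dtype) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other, self.dtype)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return self._make(out_data, (self, other), backward)

    # -- pointwise nonlinearities ------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        e = np.exp(-np.abs(self.data))
        out_data = np.where(self.data >= 0, 1.0 / (1.0 + e), e / (1.0 + e))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * sign)

        return self._make(np.abs(self.data), (self,), backward)

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        out_data = np.clip(self.data, lo, hi)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(out_data, (self,), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, tuple(a % self.ndim for a in axes))
            self._accum(np.broadcast_to(g, self.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- shape manipulation -------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(out_data, (self,), backward)

    def pad2d(self, pad: int):
        """Zero-pad the last two axes symmetrically by ``pad`` pixels."""
        if pad == 0:
            return self
        width = [(0, 0)] * (self.ndim - 2) + [(pad, pad), (pad, pad)]
        out_data = np.pad(self.data, width)
        sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))

        def backward(g):
            if self.requires_grad:
                self._accum(g[sl])

        return self._make(out_data, (self,), backward)


def as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if dtype is not None and arr.dtype != dtype and arr.dtype.kind == "f":
        arr = arr.astype(dtype)
    return Tensor(arr)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    req = any(t.requires_grad for t in tensors)
    out = Tensor(out_data, requires_grad=req, _prev=tuple(tensors) if req else ())
    if req:
        out._backward = backward
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        slices = np.split(g, len(tensors), axis=axis)
        for t, gs in zip(tensors, slices):
            if t.requires_grad:
                t._accum(np.squeeze(gs, axis=axis))

    req = any(t.requires_grad for t in tensors)
    out = Tensor(out_data, requires_grad=req, _prev=tuple(tensors) if req else ())
    if req:
        out._backward = backward
    return out


def where_mask(mask: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Select ``a`` where ``mask`` is true, ``b`` elsewhere (mask is constant)."""
    a = as_tensor(a)
    b = as_tensor(b)
    m = np.asarray(mask, dtype=bool)
    out_data = np.where(m, a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * m, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~m, b.shape))

    req = a.requires_grad or b.requires_grad
    out = Tensor(out_data, requires_grad=req, _prev=(a, b) if req else ())
    if req:
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int):
    """Return patches of shape (N, Hout, Wout, C*kh*kw)."""
    n, c, h, w = x.shape
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Hout, Wout, kh, kw)
    hout, wout = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, hout, wout, c * kh * kw)
    return np.ascontiguousarray(cols), hout, wout


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, square stride/padding."""
    x = as_tensor(x)
    xp = x.pad2d(padding) if padding else x
    n, c, h, w = xp.shape
    o, ci, kh, kw = weight.shape
    if ci != c:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {ci}")
    cols, hout, wout = _im2col(xp.data, kh, kw, stride)
    wmat = weight.data.reshape(o, -1)
    out_data = cols @ wmat.T  # (N, Hout, Wout, O)
    if bias is not None:
        out_data = out_data + bias.data
    out_data = out_data.transpose(0, 3, 1, 2)

    parents = [xp, weight] + ([bias] if bias is not None else [])

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1)  # (N, Hout, Wout, O)
        if weight.requires_grad:
            gw = np.tensordot(gmat, cols, axes=([0, 1, 2], [0, 1, 2]))
            weight._accum(gw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(gmat.sum(axis=(0, 1, 2)))
        if xp.requires_grad:
            gcols = gmat @ wmat  # (N, Hout, Wout, C*kh*kw)
            gcols = gcols.reshape(n, hout, wout, c, kh, kw)
            gx = np.zeros((n, c, h, w), dtype=g.dtype)
            for i in range(kh):
                hi = i + stride * hout
                for j in range(kw):
                    wj = j + stride * wout
                    gx[:, :, i:hi:stride, j:wj:stride] += gcols[
                        :, :, :, :, i, j
                    ].transpose(0, 3, 1, 2)
            xp._accum(gx)

    req = any(p.requires_grad for p in parents)
    out = Tensor(out_data, requires_grad=req, _prev=tuple(parents) if req else ())
    if req:
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# bilinear resampling
# ---------------------------------------------------------------------------

def _resize_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (align_corners=False)."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of the last two axes (align_corners=False convention).

    Implemented as two dense separable interpolation matrices so the backward
    pass is the exact transpose of the forward operator.
    """
    x = as_tensor(x)
    h, w = x.shape[-2], x.shape[-1]
    if h == out_h and w == out_w:
        return x
    rows = _resize_matrix(h, out_h, x.dtype)
    colsm = _resize_matrix(w, out_w, x.dtype)
    out_data = np.einsum("oh,...hw,pw->...op", rows, x.data, colsm, optimize=True)

    def backward(g):
        if x.requires_grad:
            gx = np.einsum("oh,...op,pw->...hw", rows, g, colsm, optimize=True)
            x._accum(gx)

    req = x.requires_grad
    out = Tensor(out_data, requires_grad=req, _prev=(x,) if req else ())
    if req:
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# RoIAlign
# ---------------------------------------------------------------------------

def roi_align(feature: Tensor, boxes: np.ndarray, out_size: int,
              stride: float = 1.0) -> Tensor:
    """RoIAlign with one bilinear sample per output bin (sampling_ratio=1).

    ``feature`` is (C, H, W) or (1, C, H, W); ``boxes`` is (K, 4) in *image*
    coordinates ``[x1, y1, x2, y2]``; ``stride`` maps image to feature
    coordinates.  Returns (K, C, out_size, out_size).
    """
    feature = as_tensor(feature)
    fdata = feature.data
    squeeze_batch = False
    if fdata.ndim == 4:
        if fdata.shape[0] != 1:
            raise ValueError("roi_align expects a single-image feature map")
        squeeze_batch = True
        fdata2 = fdata[0]
    else:
        fdata2 = fdata
    c, h, w = fdata2.shape
    boxes = np.asarray(boxes, dtype=np.float64)
    k = boxes.shape[0]
    r = out_size

    # sample-point grid in feature coordinates
    x1 = boxes[:, 0] / stride
    y1 = boxes[:, 1] / stride
    bw = np.maximum((boxes[:, 2] - boxes[:, 0]) / stride, 1e-6)
    bh = np.maximum((boxes[:, 3] - boxes[:, 1]) / stride, 1e-6)
    jj = (np.arange(r) + 0.5) / r
    sx = x1[:, None] + jj[None, :] * bw[:, None]  # (K, R)
    sy = y1[:, None] + jj[None, :] * bh[:, None]
    # bilinear interpolation indices/weights, clipped to the map
    sx = np.clip(sx - 0.5, 0.0, w - 1.0)
    sy = np.clip(sy - 0.5, 0.0, h - 1.0)
    x0 = np.floor(sx).astype(int)
    y0 = np.floor(sy).astype(int)
    x1i = np.minimum(x0 + 1, w - 1)
    y1i = np.minimum(y0 + 1, h - 1)
    fx = sx - x0
    fy = sy - y0

    # gather: out[k, c, i, j] built from four corners
    def gather(yidx, xidx):
        # yidx: (K, R) rows, xidx: (K, R) cols -> (K, C, R, R)
        return fdata2[:, yidx[:, :, None], xidx[:, None, :]].transpose(1, 0, 2, 3)

    w00 = ((1 - fy)[:, :, None] * (1 - fx)[:, None, :])[:, None]  # (K,1,R,R)
    w01 = ((1 - fy)[:, :, None] * fx[:, None, :])[:, None]
    w10 = (fy[:, :, None] * (1 - fx)[:, None, :])[:, None]
    w11 = (fy[:, :, None] * fx[:, None, :])[:, None]
    out_data = (
        w00 * gather(y0, x0)
        + w01 * gather(y0, x1i)
        + w10 * gather(y1i, x0)
        + w11 * gather(y1i, x1i)
    ).astype(fdata2.dtype)

    def backward(g):
        if not feature.requires_grad:
            return
        gx = np.zeros_like(fdata2)
        for kk in range(k):
            gk = g[kk]  # (C, R, R)
            for wgt, yy, xx in (
                (w00[kk, 0], y0[kk], x0[kk]),
                (w01[kk, 0], y0[kk], x1i[kk]),
                (w10[kk, 0], y1i[kk], x0[kk]),
                (w11[kk, 0], y1i[kk], x1i[kk]),
            ):
                contrib = gk * wgt[None]
                np.add.at(gx, (slice(None), yy[:, None], xx[None, :]), contrib)
        if squeeze_batch:
            gx = gx[None]
        feature._accum(gx)

    req = feature.requires_grad
    out = Tensor(out_data, requires_grad=req, _prev=(feature,) if req else ())
    if req:
        out._backward = backward
    return out
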
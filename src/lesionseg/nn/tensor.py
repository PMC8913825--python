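"""Reverse-mode autodiff tensor.

A ``Tensor`` wraps a float32 ``numpy`` array together with a gradient slot
and a closure that propagates the gradient to its parents.  The operation
set is exactly what the segmentation networks and losses need: broadcasted
arithmetic, matmul, conv2d (with stride and dilation, replicate padding),
2x2 transposed conv, 2x2 max pooling, nearest-neighbor upsampling, channel
concatenation/resizing and elementwise nonlinearities.

Convolutions pad with edge replication so that a spatially constant input
produces a spatially constant response (no positional leakage from a zero
border).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Run reverse-mode accumulation from this tensor."""
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = (np.ones_like(self.data) if grad is None
                     else np.asarray(grad, dtype=np.float32))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()
                # release the graph eagerly: the closure (and the forward
                # buffers it captured) and this node's gradient are no
                # longer needed once its parents have been updated
                t._backward = None
                t._parents = ()
                if t is not self:
                    t.grad = None

    def zero_grad(self) -> None:
        self.grad = None

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _wrap(other)
        out = _node(self.data + other.data, (self, other))

        def bw():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))

        def bw():
            if self.requires_grad:
                self._accumulate(-out.grad)
        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)
        out = _node(self.data * other.data, (self, other))

        def bw():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        out = _node(self.data / other.data, (self, other))

        def bw():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(
                    -out.grad * self.data / (other.data ** 2), other.data.shape))
        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return _wrap(other) / self

    def __pow__(self, p: float):
        out = _node(self.data ** p, (self,))

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad * p * self.data ** (p - 1))
        out._backward = bw
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = _wrap(other)
        out = _node(self.data @ other.data, (self, other))

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ out.grad)
        out._backward = bw
        return out

    __matmul__ = matmul

    # -- reductions / reshaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw():
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).astype(np.float32))
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out = _node(self.data.reshape(shape), (self,))

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad.reshape(old))
        out._backward = bw
        return out


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: tuple) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    out._parents = tuple(p for p in parents if p.requires_grad)
    return out


# -- elementwise nonlinearities -------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = _node(np.maximum(x.data, 0.0), (x,))

    def bw():
        if x.requires_grad:
            x._accumulate(out.grad * (x.data > 0))
    out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    d = x.data
    # numerically stable logistic
    s = np.empty_like(d)
    pos = d >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
    ed = np.exp(d[~pos])
    s[~pos] = ed / (1.0 + ed)
    out = _node(s, (x,))

    def bw():
        if x.requires_grad:
            x._accumulate(out.grad * s * (1.0 - s))
    out._backward = bw
    return out


def log(x: Tensor) -> Tensor:
    out = _node(np.log(x.data), (x,))

    def bw():
        if x.requires_grad:
            x._accumulate(out.grad / x.data)
    out._backward = bw
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; the gradient is passed through inside [lo, hi] only."""
    out = _node(np.clip(x.data, lo, hi), (x,))
    mask = (x.data >= lo) & (x.data <= hi)

    def bw():
        if x.requires_grad:
            x._accumulate(out.grad * mask)
    out._backward = bw
    return out


# -- structural ops --------------------------------------------------------

def concat(tensors: list, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    out._parents = tuple(t for t in tensors if t.requires_grad)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw():
        for t, o, s in zip(tensors, offsets, sizes):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(o, o + s)
                t._accumulate(out.grad[tuple(sl)])
    out._backward = bw
    return out


def channel_resize(x: Tensor, out_channels: int) -> Tensor:
    """Parameter-free channel matching for identity shortcuts (NCHW).

    Extra channels are zero-padded; surplus channels are dropped.  This is
    the classic projection-free shortcut (zero-pad variant) so a residual
    unit can keep its skip path convolution-free.
    """
    n, c, h, w = x.data.shape
    if out_channels == c:
        return x
    if out_channels > c:
        d = np.zeros((n, out_channels, h, w), dtype=np.float32)
        d[:, :c] = x.data
    else:
        d = x.data[:, :out_channels].copy()
    out = _node(d, (x,))

    def bw():
        if not x.requires_grad:
            return
        if out_channels > c:
            x._accumulate(out.grad[:, :c])
        else:
            g = np.zeros((n, c, h, w), dtype=np.float32)
            g[:, :out_channels] = out.grad
            x._accumulate(g)
    out._backward = bw
    return out


def _edge_pad_backward(gp: np.ndarray, ph: int, pw: int,
                       h: int, w: int) -> np.ndarray:
    """Fold the gradient of an edge-replicated pad back onto the core."""
    g = gp[:, :, ph:ph + h, pw:pw + w].copy()
    if ph:
        g[:, :, 0, :] += gp[:, :, :ph, pw:pw + w].sum(axis=2)
        g[:, :, -1, :] += gp[:, :, ph + h:, pw:pw + w].sum(axis=2)
    if pw:
        g[:, :, :, 0] += gp[:, :, ph:ph + h, :pw].sum(axis=3)
        g[:, :, :, -1] += gp[:, :, ph:ph + h, pw + w:].sum(axis=3)
    if ph and pw:
        g[:, :, 0, 0] += gp[:, :, :ph, :pw].sum(axis=(2, 3))
        g[:, :, 0, -1] += gp[:, :, :ph, pw + w:].sum(axis=(2, 3))
        g[:, :, -1, 0] += gp[:, :, ph + h:, :pw].sum(axis=(2, 3))
        g[:, :, -1, -1] += gp[:, :, ph + h:, pw + w:].sum(axis=(2, 3))
    return g


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, dilation: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW, 'same' replicate padding at stride 1."""
    n, c, h, ww = x.data.shape
    f, cw, kh, kw = w.data.shape
    assert c == cw, f"channel mismatch {c} vs {cw}"
    ph = dilation * (kh - 1) // 2
    pw = dilation * (kw - 1) // 2
    xp = (np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)), mode="edge")
          if (ph or pw) else x.data)
    eh = dilation * (kh - 1) + 1
    ew = dilation * (kw - 1) + 1
    view = sliding_window_view(xp, (eh, ew), axis=(2, 3))
    view = view[:, :, ::stride, ::stride, ::dilation, ::dilation]
    ho, wo = view.shape[2], view.shape[3]
    cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)
                                ).reshape(n * ho * wo, c * kh * kw)
    y = cols @ w.data.reshape(f, -1).T
    if b is not None:
        y += b.data
    out = _node(y.reshape(n, ho, wo, f).transpose(0, 3, 1, 2),
                (x, w) if b is None else (x, w, b))

    def bw():
        g = np.ascontiguousarray(out.grad.transpose(0, 2, 3, 1)
                                 ).reshape(n * ho * wo, f)
        if w.requires_grad:
            w._accumulate((g.T @ cols).reshape(f, c, kh, kw))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=0))
        if not x.requires_grad:
            return
        if stride == 1:
            # gradient wrt the padded input = full correlation of the
            # output gradient with the flipped kernel (second im2col matmul)
            pd = dilation * (kh - 1)
            qd = dilation * (kw - 1)
            gp_in = np.pad(out.grad, ((0, 0), (0, 0), (pd, pd), (qd, qd)))
            gview = sliding_window_view(gp_in, (dilation * (kh - 1) + 1,
                                                dilation * (kw - 1) + 1),
                                        axis=(2, 3))[..., ::dilation, ::dilation]
            hp, wp = gview.shape[2], gview.shape[3]
            gcols = np.ascontiguousarray(gview.transpose(0, 2, 3, 1, 4, 5)
                                         ).reshape(n * hp * wp, f * kh * kw)
            wflip = np.ascontiguousarray(
                w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            ).reshape(c, -1)
            gp = (gcols @ wflip.T).reshape(n, hp, wp, c).transpose(0, 3, 1, 2)
        else:
            dcols = (g @ w.data.reshape(f, -1)).reshape(n, ho, wo, c, kh, kw)
            dcols = dcols.transpose(0, 3, 1, 2, 4, 5)
            gp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gp[:, :,
                       i * dilation: i * dilation + stride * ho: stride,
                       j * dilation: j * dilation + stride * wo: stride
                       ] += dcols[:, :, :, :, i, j]
        if ph or pw:
            x._accumulate(_edge_pad_backward(gp, ph, pw, h, ww))
        else:
            x._accumulate(gp)
    out._backward = bw
    return out


def conv_transpose2d_2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution, kernel 2x2, stride 2 (the classic up-conv).

    Weight layout (C_in, C_out, 2, 2); output spatial size doubles.
    """
    n, c, h, ww = x.data.shape
    cin, f, kh, kw = w.data.shape
    assert c == cin and kh == 2 and kw == 2
    y = np.zeros((n, f, 2 * h, 2 * ww), dtype=np.float32)
    for i in range(2):
        for j in range(2):
            y[:, :, i::2, j::2] = np.einsum(
                "nchw,cf->nfhw", x.data, w.data[:, :, i, j], optimize=True)
    if b is not None:
        y += b.data.reshape(1, f, 1, 1)
    out = _node(y, (x, w) if b is None else (x, w, b))

    def bw():
        if b is not None and b.requires_grad:
            b._accumulate(out.grad.sum(axis=(0, 2, 3)))
        for i in range(2):
            for j in range(2):
                gij = out.grad[:, :, i::2, j::2]
                if w.requires_grad:
                    dw = np.einsum("nchw,nfhw->cf", x.data, gij, optimize=True)
                    full = np.zeros_like(w.data)
                    full[:, :, i, j] = dw
                    w._accumulate(full)
                if x.requires_grad:
                    x._accumulate(np.einsum(
                        "nfhw,cf->nchw", gij, w.data[:, :, i, j], optimize=True))
    out._backward = bw
    return out


def maxpool2d_2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    assert h % 2 == 0 and w % 2 == 0, "max pooling needs even spatial dims"
    v = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    vv = np.ascontiguousarray(v.transpose(0, 1, 2, 4, 3, 5)
                              ).reshape(n, c, h // 2, w // 2, 4)
    idx = vv.argmax(axis=-1)
    out = _node(np.take_along_axis(vv, idx[..., None], axis=-1)[..., 0], (x,))

    def bw():
        if not x.requires_grad:
            return
        dvv = np.zeros_like(vv)
        np.put_along_axis(dvv, idx[..., None], out.grad[..., None], axis=-1)
        g = dvv.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(g.reshape(n, c, h, w))
    out._backward = bw
    return out


def upsample_nearest_2x(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    out = _node(x.data.repeat(2, axis=2).repeat(2, axis=3), (x,))

    def bw():
        if x.requires_grad:
            x._accumulate(out.grad.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))
    out._backward = bw
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    n, c, h, w = x.data.shape
    out = _node(x.data.mean(axis=(2, 3)), (x,))

    def bw():
        if x.requires_grad:
            g = out.grad[:, :, None, None] / (h * w)
            x._accumulate(np.broadcast_to(g, x.data.shape).astype(np.float32))
    out._backward = bw
    return out
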
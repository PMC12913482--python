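"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set the dual-tower network needs: broadcasting
arithmetic, (batched) matmul, ReLU, stable softmax/log-softmax, reductions,
reshape/transpose/concat/indexing, 2-D stride-1 "same" convolution via im2col,
max pooling, and embedding lookup. Gradients accumulate on a dynamic tape and
are released after :meth:`Tensor.backward`.

Convolution stores only its *inputs* and re-materialises the im2col matrix in
the backward pass, keeping peak memory proportional to activations rather than
unfolded patches.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "embedding_lookup",
    "log_softmax",
    "max_pool2d",
    "relu",
    "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast up from ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = tuple(p for p in parents if p.requires_grad)
        self._backward = backward

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            if g.dtype == self.data.dtype and g.flags.owndata and g.flags.writeable:
                self.grad = g
            else:
                self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is None:
                continue  # leaf (parameter/input): keep its grad
            if node.grad is not None:
                node._backward(node.grad)
            # free the tape as we go
            node._backward = None
            node._parents = ()
            if node is not self:
                node.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other, self.dtype)
        out_data = self.data + other.data

        def backward(g):
            handed = None
            if self.requires_grad:
                handed = _unbroadcast(g, self.data.shape)
                self._accumulate(handed)
            if other.requires_grad:
                gb = _unbroadcast(g, other.data.shape)
                if gb is handed:  # same array to both parents: avoid aliasing
                    gb = gb.copy()
                other._accumulate(gb)

        return Tensor(out_data, self.requires_grad or other.requires_grad,
                      (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return Tensor(-self.data, self.requires_grad, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return _as_tensor(other, self.dtype) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other, self.dtype)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, self.requires_grad or other.requires_grad,
                      (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other, self.dtype)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape))

        return Tensor(out_data, self.requires_grad or other.requires_grad,
                      (self, other), backward)

    def __matmul__(self, other):
        other = _as_tensor(other, self.dtype)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        return Tensor(out_data, self.requires_grad or other.requires_grad,
                      (self, other), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor(out_data, self.requires_grad, (self,), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        orig = self.data.shape

        def backward(g):
            self._accumulate(g.reshape(orig))

        return Tensor(out_data, self.requires_grad, (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        return Tensor(self.data.transpose(axes), self.requires_grad, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, axes)
            self._accumulate(np.broadcast_to(g, shape).copy())

        return Tensor(out_data, self.requires_grad, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def square(self):
        return self * self

    def item(self) -> float:
        return float(self.data)


def _as_tensor(x, dtype) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


# ---------------------------------------------------------------------------
# nonlinearities and normalising maps
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out_data = np.maximum(x.data, 0)

    def backward(g):
        x._accumulate(g * (x.data > 0))

    return Tensor(out_data, x.requires_grad, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accumulate(s * (g - dot))

    return Tensor(s, x.requires_grad, (x,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    ls = shifted - np.log(np.exp(shifted).sum(axis=axis, keepdims=True))

    def backward(g):
        x._accumulate(g - np.exp(ls) * g.sum(axis=axis, keepdims=True))

    return Tensor(ls, x.requires_grad, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(out_data, any(t.requires_grad for t in tensors), tuple(tensors),
                  backward)


# ---------------------------------------------------------------------------
# convolution / pooling / embedding
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Unfold a padded (B, C, H, W) array into (B*H'*W', C*kh*kw) patches."""
    view = sliding_window_view(x, (kh, kw), axis=(2, 3))  # (B,C,H',W',kh,kw)
    b, c, h, w = view.shape[:4]
    return view.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * kh * kw), (b, h, w)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Stride-1 'same' 2-D convolution (odd kernels only).

    x: (B, C, H, W); w: (O, C, kh, kw); b: (O,).
    """
    out_ch, in_ch, kh, kw = w.data.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv2d supports odd kernel sizes only")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols, (bsz, oh, ow) = _im2col(xp, kh, kw)
    wmat = w.data.reshape(out_ch, -1)
    out = cols @ wmat.T
    out = out.reshape(bsz, oh, ow, out_ch).transpose(0, 3, 1, 2)
    out += b.data[None, :, None, None]

    def backward(g):
        gcols = g.transpose(0, 2, 3, 1).reshape(-1, out_ch)  # (B*H*W, O)
        if w.requires_grad:
            cols2, _ = _im2col(np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))),
                               kh, kw)
            w._accumulate((gcols.T @ cols2).reshape(w.data.shape))
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # grad wrt input = 'same' conv of g with the spatially flipped,
            # channel-transposed kernel
            w_flip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C,O,kh,kw)
            gp = np.pad(g, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
            gc, (bsz2, oh2, ow2) = _im2col(gp, kh, kw)
            gx = gc @ w_flip.reshape(in_ch, -1).T
            x._accumulate(gx.reshape(bsz2, oh2, ow2, in_ch).transpose(0, 3, 1, 2))

    return Tensor(out, x.requires_grad or w.requires_grad or b.requires_grad,
                  (x, w, b), backward)


def max_pool2d(x: Tensor, kernel: int | tuple[int, int]) -> Tensor:
    """Non-overlapping max pooling; trailing rows/cols that do not fill a
    window are dropped (floor semantics). ``kernel`` may be an int or an
    (height, width) pair."""
    kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
    bsz, c, h, w = x.data.shape
    oh, ow = h // kh, w // kw
    trimmed = x.data[:, :, : oh * kh, : ow * kw]
    windows = trimmed.reshape(bsz, c, oh, kh, ow, kw)
    flat = windows.transpose(0, 1, 2, 4, 3, 5).reshape(bsz, c, oh, ow, kh * kw)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        gflat = np.zeros((bsz, c, oh, ow, kh * kw), dtype=x.data.dtype)
        np.put_along_axis(gflat, arg[..., None], g[..., None], axis=-1)
        gwin = gflat.reshape(bsz, c, oh, ow, kh, kw).transpose(0, 1, 2, 4, 3, 5)
        if (oh * kh, ow * kw) == (h, w):
            x._accumulate(np.ascontiguousarray(gwin).reshape(bsz, c, h, w))
        else:
            gx = np.zeros_like(x.data)
            gx[:, :, : oh * kh, : ow * kw] = gwin.reshape(bsz, c, oh * kh, ow * kw)
            x._accumulate(gx)

    return Tensor(out, x.requires_grad, (x,), backward)


def embedding_lookup(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup with scatter-add gradient (trainable embedding ablation)."""
    ids = np.asarray(ids)
    out = table.data[ids]

    def backward(g):
        full = np.zeros_like(table.data)
        np.add.at(full, ids, g)
        table._accumulate(full)

    return Tensor(out, table.requires_grad, (table,), backward)
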
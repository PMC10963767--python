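"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: each :class:`Tensor` wraps an
``ndarray`` and records the operation that produced it. ``Tensor.backward``
topologically sorts the tape and accumulates gradients into ``.grad`` for
every tensor in the graph (intermediates included, which Grad-CAM relies
on). Float64 throughout — the networks here are desk-scale and exactness
beats throughput.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concatenate",
    "maximum",
    "matmul",
    "conv2d",
    "softmax",
    "log_softmax",
    "adaptive_avg_pool2d",
]


class Tensor:
    """An ndarray with a gradient tape entry.

    Parameters
    ----------
    data : array-like
        Values; copied to float64.
    requires_grad : bool
        Leaf flag. Non-leaf tensors created by ops inherit the need for
        gradients from their parents.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (scalar, unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)

        def bw(g):
            _send(self, _unbroadcast(g, self.shape))
            _send(other, _unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, _parents=(self, other), _backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            _send(self, -g)

        return Tensor(-self.data, _parents=(self,), _backward=bw)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)

        def bw(g):
            _send(self, _unbroadcast(g * other.data, self.shape))
            _send(other, _unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, _parents=(self, other), _backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)

        def bw(g):
            _send(self, _unbroadcast(g / other.data, self.shape))
            _send(other, _unbroadcast(-g * self.data / other.data**2, other.shape))

        return Tensor(self.data / other.data, _parents=(self, other), _backward=bw)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p: float):
        def bw(g):
            _send(self, g * p * self.data ** (p - 1))

        return Tensor(self.data**p, _parents=(self,), _backward=bw)

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            _send(self, full)

        return Tensor(self.data[idx], _parents=(self,), _backward=bw)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bw(g):
            _send(self, g.reshape(old))

        return Tensor(self.data.reshape(shape), _parents=(self,), _backward=bw)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def bw(g):
            _send(self, g.transpose(inv))

        return Tensor(self.data.transpose(axes), _parents=(self,), _backward=bw)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if axis is None:
                _send(self, np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            _send(self, np.broadcast_to(gg, self.shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,), _backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod([self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- pointwise nonlinearities ----------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g):
            _send(self, g * mask)

        return Tensor(self.data * mask, _parents=(self,), _backward=bw)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def bw(g):
            _send(self, g * s * (1 - s))

        return Tensor(s, _parents=(self,), _backward=bw)

    def exp(self):
        e = np.exp(self.data)

        def bw(g):
            _send(self, g * e)

        return Tensor(e, _parents=(self,), _backward=bw)

    def log(self):
        def bw(g):
            _send(self, g / self.data)

        return Tensor(np.log(self.data), _parents=(self,), _backward=bw)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _send(t: Tensor, g: np.ndarray) -> None:
    if t.requires_grad:
        t._accumulate(g)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a gradient back to the shape it was broadcast from."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _send(t, piece)

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _backward=bw,
    )


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise max; ties route the gradient to the first argument."""
    a, b = _as_tensor(a), _as_tensor(b)
    take_a = a.data >= b.data

    def bw(g):
        _send(a, _unbroadcast(g * take_a, a.shape))
        _send(b, _unbroadcast(g * ~take_a, b.shape))

    return Tensor(np.maximum(a.data, b.data), _parents=(a, b), _backward=bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product with numpy batching semantics."""
    a, b = _as_tensor(a), _as_tensor(b)

    def bw(g):
        if a.requires_grad:
            bt = np.swapaxes(b.data, -1, -2) if b.ndim >= 2 else b.data
            ga = g @ bt if b.ndim >= 2 else np.outer(g, b.data) if a.ndim == 2 else g * b.data
            _send(a, _unbroadcast(ga, a.shape))
        if b.requires_grad:
            at = np.swapaxes(a.data, -1, -2) if a.ndim >= 2 else a.data
            gb = at @ g if a.ndim >= 2 else np.outer(a.data, g) if b.ndim == 2 else g * a.data
            _send(b, _unbroadcast(gb, b.shape))

    return Tensor(a.data @ b.data, _parents=(a, b), _backward=bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        _send(x, s * (g - (g * s).sum(axis=axis, keepdims=True)))

    return Tensor(s, _parents=(x,), _backward=bw)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = z - lse
    s = np.exp(out)

    def bw(g):
        _send(x, g - s * g.sum(axis=axis, keepdims=True))

    return Tensor(out, _parents=(x,), _backward=bw)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    # x: (B, C, Hp, Wp) -> (B, C*kh*kw, Ho*Wo)
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, :, :]  # (B, C, Ho, Wo, kh, kw)
    b, c, ho, wo = win.shape[:4]
    return win.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * kh * kw, ho * wo), ho, wo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, via im2col."""
    x, w = _as_tensor(x), _as_tensor(w)
    B, C, H, W = x.shape
    O, Cw, kh, kw = w.shape
    if C != Cw:
        raise ValueError(f"conv2d channel mismatch: input has {C}, kernel expects {Cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols, ho, wo = _im2col(xp, kh, kw, stride)
    wm = w.data.reshape(O, -1)
    out = np.einsum("ok,bkl->bol", wm, cols).reshape(B, O, ho, wo)
    if b is not None:
        out = out + b.data.reshape(1, O, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        gl = g.reshape(B, O, ho * wo)
        if b is not None and b.requires_grad:
            _send(b, g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.einsum("bol,bkl->ok", gl, cols).reshape(w.shape)
            _send(w, gw)
        if x.requires_grad:
            gcols = np.einsum("ok,bol->bkl", wm, gl)  # (B, C*kh*kw, L)
            gxp = np.zeros_like(xp)
            gc = gcols.reshape(B, C, kh, kw, ho, wo)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += gc[:, :, i, j]
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            _send(x, gxp)

    return Tensor(out, _parents=parents, _backward=bw)


def adaptive_avg_pool2d(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Average pooling to a target grid; bins follow the floor/ceil rule."""
    x = _as_tensor(x)
    B, C, H, W = x.shape
    oh, ow = out_hw
    hb = [(int(np.floor(i * H / oh)), int(np.ceil((i + 1) * H / oh))) for i in range(oh)]
    wb = [(int(np.floor(j * W / ow)), int(np.ceil((j + 1) * W / ow))) for j in range(ow)]
    out = np.empty((B, C, oh, ow))
    for i, (h0, h1) in enumerate(hb):
        for j, (w0, w1) in enumerate(wb):
            out[:, :, i, j] = x.data[:, :, h0:h1, w0:w1].mean(axis=(2, 3))

    def bw(g):
        gx = np.zeros_like(x.data)
        for i, (h0, h1) in enumerate(hb):
            for j, (w0, w1) in enumerate(wb):
                area = (h1 - h0) * (w1 - w0)
                gx[:, :, h0:h1, w0:w1] += g[:, :, i, j][:, :, None, None] / area
        _send(x, gx)

    return Tensor(out, _parents=(x,), _backward=bw)
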
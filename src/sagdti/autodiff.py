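"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based autodiff engine sufficient for the attention, graph-attention
and convolutional blocks in this package. Every operation builds a node in a
DAG; :meth:`Tensor.backward` runs a topological sort and accumulates gradients.

Design notes
------------
* Broadcasting follows NumPy rules; gradients of broadcast operands are
  reduced back to the operand shape (`_unbroadcast`).
* `softmax` subtracts a detached row-max for stability; because softmax is
  shift-invariant the resulting gradient is exact.
* `conv2d` is stride-1 with explicit zero padding, implemented with
  `sliding_window_view` + matmul in the forward pass and a small kh*kw loop in
  the backward pass.
* Ties in `maximum`/`max_pool2d` send the full gradient to the first argmax.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "matmul",
    "softmax",
    "layer_norm",
    "conv2d",
    "max_pool2d",
    "maximum",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An n-d array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, _parents=(), name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = None
        self.name = name

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
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
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # tear the graph down so memory is reclaimed by refcount alone
        # (single-shot backward; leaf gradients survive)
        for node in topo:
            if node._parents:
                node._backward = None
                node._parents = ()
                node.grad = None

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = _node(self.data + other.data, (self, other))

        def bw(g):
            _send(self, _unbroadcast(g, self.data.shape))
            _send(other, _unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        out._backward = lambda g: _send(self, -g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _node(self.data * other.data, (self, other))

        def bw(g):
            _send(self, _unbroadcast(g * other.data, self.data.shape))
            _send(other, _unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _node(self.data / other.data, (self, other))

        def bw(g):
            _send(self, _unbroadcast(g / other.data, self.data.shape))
            _send(other, _unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = _node(self.data**p, (self,))
        out._backward = lambda g: _send(self, g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        return matmul(self, other)

    # ------------------------------------------------------------ shape ops
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _node(self.data.reshape(shape), (self,))
        out._backward = lambda g: _send(self, g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = _node(self.data.transpose(axes), (self,))
        out._backward = lambda g: _send(self, g.transpose(inv))
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out = _node(self.data[idx], (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            _send(self, full)

        out._backward = bw
        return out

    def take(self, indices, axis: int = 0):
        """Gather along `axis` with an integer index array (embedding lookup)."""
        indices = np.asarray(indices)
        out = _node(np.take(self.data, indices, axis=axis), (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            if axis == 0:
                np.add.at(full, indices.ravel(), g.reshape(indices.size, *self.data.shape[1:]))
            else:  # pragma: no cover - axis 0 is the only use in this package
                idx = [slice(None)] * self.data.ndim
                for k, i in enumerate(indices.ravel()):
                    idx[axis] = i
                    full[tuple(idx)] += np.take(g, k, axis=axis)
            _send(self, full)

        out._backward = bw
        return out

    # ----------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if axis is None:
                _send(self, np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            _send(self, np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Maximum along one axis; gradient flows to the first argmax only."""
        arg = np.argmax(self.data, axis=axis)
        val = np.take_along_axis(self.data, np.expand_dims(arg, axis), axis=axis)
        out_data = val if keepdims else np.squeeze(val, axis=axis)
        out = _node(out_data, (self,))

        def bw(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(arg, axis), g, axis=axis)
            _send(self, full)

        out._backward = bw
        return out

    # -------------------------------------------------------- element-wise
    def exp(self):
        e = np.exp(self.data)
        out = _node(e, (self,))
        # closure captures the array, not the node, to avoid a reference cycle
        out._backward = lambda g: _send(self, g * e)
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        out._backward = lambda g: _send(self, g / self.data)
        return out

    def sqrt(self):
        return self**0.5

    def relu(self):
        out = _node(np.maximum(self.data, 0.0), (self,))
        out._backward = lambda g: _send(self, g * (self.data > 0))
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = _node(np.where(self.data > 0, self.data, slope * self.data), (self,))
        out._backward = lambda g: _send(self, g * np.where(self.data > 0, 1.0, slope))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = _node(s, (self,))
        out._backward = lambda g: _send(self, g * s * (1.0 - s))
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = _node(t, (self,))
        out._backward = lambda g: _send(self, g * (1.0 - t**2))
        return out

    def clip_probs(self, eps: float = 1e-7):
        """Clamp to [eps, 1-eps]; straight-through gradient inside the window."""
        c = np.clip(self.data, eps, 1.0 - eps)
        out = _node(c, (self,))
        out._backward = lambda g: _send(self, g * ((self.data > eps) & (self.data < 1.0 - eps)))
        return out


def _node(data: np.ndarray, parents: tuple) -> Tensor:
    # intermediates inherit requires_grad from their parents; graphs with no
    # trainable ancestor are pruned so forward-only code stays cheap
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, _parents=tuple(parents) if req else ())


def _send(t: Tensor, g: np.ndarray):
    if t.requires_grad:
        t._accumulate(g)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = _node(a.data @ b.data, (a, b))

    def bw(g):
        if b.data.ndim == 1:
            ga = np.multiply.outer(g, b.data) if a.data.ndim > 1 else g * b.data
            gb = (a.data * g[..., None]).sum(axis=tuple(range(a.data.ndim - 1))) if a.data.ndim > 1 else a.data * g
            _send(a, _unbroadcast(np.asarray(ga), a.data.shape))
            _send(b, _unbroadcast(np.asarray(gb), b.data.shape))
            return
        if a.data.ndim == 1:
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.multiply.outer(a.data, g) if b.data.ndim == 2 else a.data[:, None] * g[..., None, :]
            _send(a, _unbroadcast(ga, a.data.shape))
            _send(b, _unbroadcast(gb, b.data.shape))
            return
        _send(a, _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape))
        _send(b, _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape))

    out._backward = bw
    return out


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _send(t, piece)

    out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1, mask: np.ndarray | None = None) -> Tensor:
    """Numerically stable softmax; positions where `mask` is False get weight
    exactly 0 and are excluded from the normalization.

    Rows whose mask is entirely False come out all-zero.
    """
    x = as_tensor(x)
    if mask is not None:
        mask = np.broadcast_to(np.asarray(mask, dtype=bool), x.data.shape)
        neg = Tensor(np.where(mask, 0.0, -1e30))
        x = x * Tensor(mask.astype(np.float64)) + neg
    m = Tensor(np.max(x.data, axis=axis, keepdims=True))  # detached shift
    e = (x - m).exp()
    if mask is not None:
        e = e * Tensor(mask.astype(np.float64))
    denom = e.sum(axis=axis, keepdims=True)
    denom = denom + Tensor(np.where(denom.data == 0.0, 1.0, 0.0))  # all-masked rows
    return e / denom


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / (var + eps) ** 0.5 * gain + bias


def conv2d(x: Tensor, filters: Tensor, bias: Tensor | None = None, padding: str = "same") -> Tensor:
    """2-D convolution (cross-correlation), stride 1.

    x: (N, C, H, W); filters: (O, C, kh, kw); returns (N, O, H', W').
    `padding='same'` zero-pads so spatial dims are preserved (odd kernels).
    """
    x, filters = as_tensor(x), as_tensor(filters)
    n, c, h, w = x.data.shape
    o, c2, kh, kw = filters.data.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input has {c}, filters expect {c2}")
    if padding == "same":
        ph, pw = kh // 2, kw // 2
    elif padding == "valid":
        ph = pw = 0
    else:
        raise ValueError(f"unknown padding {padding!r}")
    if h + 2 * ph < kh or w + 2 * pw < kw:
        raise ValueError(f"filter {kh}x{kw} larger than padded map {h + 2 * ph}x{w + 2 * pw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    hh, ww = h + 2 * ph - kh + 1, w + 2 * pw - kw + 1
    taps = list((i, j) for i in range(kh) for j in range(kw))
    if c == 1:
        # single-channel fast path: kh*kw shift-scale-accumulate passes
        xp1 = xp[:, 0]
        out_data = np.zeros((n, o, hh, ww))
        for i, j in taps:
            out_data += filters.data[None, :, 0, i, j, None, None] * xp1[:, None, i : i + hh, j : j + ww]
    else:
        cols = [np.ascontiguousarray(xp[:, :, i : i + hh, j : j + ww]).reshape(n, c, hh * ww)
                for i, j in taps]
        out_flat = np.zeros((n, o, hh * ww))
        for t, (i, j) in enumerate(taps):
            out_flat += np.matmul(filters.data[:, :, i, j], cols[t])
        out_data = out_flat.reshape(n, o, hh, ww)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, o, 1, 1)
    parents = (x, filters) if bias is None else (x, filters, bias)
    out = _node(out_data, parents)

    def bw(g):
        dfil = np.empty_like(filters.data)
        gxp = np.zeros_like(xp)
        if c == 1:
            for i, j in taps:
                sl = xp[:, 0, i : i + hh, j : j + ww]
                dfil[:, 0, i, j] = np.tensordot(g, sl, axes=([0, 2, 3], [0, 1, 2]))
                gxp[:, 0, i : i + hh, j : j + ww] += np.tensordot(g, filters.data[:, 0, i, j],
                                                                  axes=([1], [0]))
        else:
            gf = np.ascontiguousarray(g).reshape(n, o, hh * ww)
            for t, (i, j) in enumerate(taps):
                dfil[:, :, i, j] = np.tensordot(gf, cols[t], axes=([0, 2], [0, 2]))
                gxp[:, :, i : i + hh, j : j + ww] += np.matmul(
                    filters.data[:, :, i, j].T, gf).reshape(n, c, hh, ww)
        _send(filters, dfil)
        if bias is not None:
            _send(bias, g.sum(axis=(0, 2, 3)).reshape(bias.data.shape))
        gx = gxp[:, :, ph : ph + h, pw : pw + w] if (ph or pw) else gxp
        _send(x, gx)

    out._backward = bw
    return out


def max_pool2d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping max pooling; trailing rows/cols not filling a window are dropped."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    h2, w2 = h // size, w // size
    if h2 == 0 or w2 == 0:
        raise ValueError(f"pool size {size} larger than map {h}x{w}")
    xv = x.data[:, :, : h2 * size, : w2 * size].reshape(n, c, h2, size, w2, size)
    cands = [xv[:, :, :, i, :, j] for i in range(size) for j in range(size)]
    out_data = cands[0]
    for cand in cands[1:]:
        out_data = np.maximum(out_data, cand)
    out = _node(out_data.copy(), (x,))

    def bw(g):
        gv = np.zeros((n, c, h2, size, w2, size))
        taken = np.zeros(out_data.shape, dtype=bool)
        for k, (i, j) in enumerate((i, j) for i in range(size) for j in range(size)):
            hit = (cands[k] == out_data) & ~taken  # first argmax wins ties
            gv[:, :, :, i, :, j] = np.where(hit, g, 0.0)
            taken |= hit
        gx = np.zeros_like(x.data)
        gx[:, :, : h2 * size, : w2 * size] = gv.reshape(n, c, h2 * size, w2 * size)
        _send(x, gx)

    out._backward = bw
    return out


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Element-wise maximum; ties route the gradient to the first operand."""
    a, b = as_tensor(a), as_tensor(b)
    take_a = a.data >= b.data
    out = _node(np.where(take_a, a.data, b.data), (a, b))

    def bw(g):
        _send(a, _unbroadcast(g * take_a, a.data.shape))
        _send(b, _unbroadcast(g * ~take_a, b.data.shape))

    out._backward = bw
    return out


class Adam:
    """Adam optimizer with bias correction (Kingma & Ba)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
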
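"""Compact reverse-mode automatic differentiation over numpy arrays.

The engine supports higher-order differentiation: every vector-Jacobian
product is itself expressed with :class:`Tensor` operations, so calling
:func:`grad` with ``create_graph=True`` yields gradients that are again
differentiable.  This is what the WGAN-GP gradient penalty needs — the
training objective contains the norm of an *input* gradient, and optimizing
it requires differentiating through that gradient with respect to the
network parameters.

Only the operations needed by small convolutional image networks are
implemented: broadcasting arithmetic, matmul, reductions, shape surgery,
im2col/col2im (the linear pair from which convolution and transposed
convolution are built) and a handful of pointwise nonlinearities.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "grad",
    "concat",
    "im2col",
    "col2im",
    "log_softmax",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x))


class Tensor:
    __slots__ = ("data", "requires_grad", "grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False, dtype=None):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data, dtype=dtype)
        if arr.dtype.kind != "f":
            arr = arr.astype(np.float64)
        self.data = arr
        self.requires_grad = bool(requires_grad)
        self.grad = None  # ndarray, filled by backward()
        self._parents: tuple = ()
        self._vjp = None

    # -- basic protocol ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph construction ----------------------------------------------
    @staticmethod
    def _make(data, parents, vjp) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._vjp = vjp
        return out

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        a, b = self, other
        return Tensor._make(
            a.data + b.data,
            (a, b),
            lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        a, b = self, other
        return Tensor._make(
            a.data * b.data,
            (a, b),
            lambda g: (_unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape)),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * _as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self**-1.0

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        a = self
        out_data = a.data**p
        return Tensor._make(out_data, (a,), lambda g: (g * (p * a ** (p - 1.0)),))

    # -- pointwise --------------------------------------------------------
    def exp(self):
        a = self
        out = Tensor._make(np.exp(a.data), (a,), None)
        out._vjp = (lambda g: (g * out,)) if out._parents else None
        return out

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: (g * a**-1.0,))

    def sqrt(self):
        return self**0.5

    def abs(self):
        a = self
        sign = np.sign(a.data)
        return Tensor._make(np.abs(a.data), (a,), lambda g: (g * Tensor(sign),))

    def leaky_relu(self, slope: float = 0.01):
        a = self
        m = np.where(a.data > 0, 1.0, slope).astype(a.dtype)
        return Tensor._make(a.data * m, (a,), lambda g: (g * Tensor(m),))

    def relu(self):
        return self.leaky_relu(0.0)

    def sigmoid(self):
        a = self
        with np.errstate(over="ignore"):
            s = 1.0 / (1.0 + np.exp(-a.data))
        out = Tensor._make(s, (a,), None)
        out._vjp = (lambda g: (g * out * (1.0 - out),)) if out._parents else None
        return out

    def tanh(self):
        a = self
        t = np.tanh(a.data)
        out = Tensor._make(t, (a,), None)
        out._vjp = (lambda g: (g * (1.0 - out * out),)) if out._parents else None
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        if axis is None:
            axes = tuple(range(a.ndim))
        elif isinstance(axis, int):
            axes = (axis % a.ndim,)
        else:
            axes = tuple(ax % a.ndim for ax in axis)

        def vjp(g):
            gg = g
            if not keepdims and axes:
                shape = list(a.shape)
                for ax in axes:
                    shape[ax] = 1
                gg = gg.reshape(tuple(shape))
            return (gg.broadcast_to(a.shape),)

        return Tensor._make(a.data.sum(axis=axes or None, keepdims=keepdims), (a,), vjp)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        elif isinstance(axis, int):
            n = self.shape[axis]
        else:
            n = 1
            for ax in axis:
                n *= self.shape[ax]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape surgery ----------------------------------------------------
    def reshape(self, shape):
        a = self
        return Tensor._make(a.data.reshape(shape), (a,), lambda g: (g.reshape(a.shape),))

    def transpose(self, axes):
        a = self
        inv = np.argsort(axes)
        return Tensor._make(
            a.data.transpose(axes), (a,), lambda g: (g.transpose(tuple(inv)),)
        )

    def swap_last2(self):
        axes = tuple(range(self.ndim - 2)) + (self.ndim - 1, self.ndim - 2)
        return self.transpose(axes)

    def broadcast_to(self, shape):
        a = self
        if a.shape == tuple(shape):
            return a
        return Tensor._make(
            np.broadcast_to(a.data, shape).copy(),
            (a,),
            lambda g: (_unbroadcast(g, a.shape),),
        )

    def __getitem__(self, idx):
        a = self
        return Tensor._make(a.data[idx], (a,), lambda g: (g.embed(a.shape, idx),))

    def embed(self, shape, idx):
        """Scatter ``self`` into a zero array of ``shape`` at basic-slice ``idx``."""
        a = self

        def vjp(g):
            return (g[idx],)

        z = np.zeros(shape, dtype=a.dtype)
        z[idx] = a.data
        return Tensor._make(z, (a,), vjp)

    # -- linear algebra ---------------------------------------------------
    def __matmul__(self, other):
        other = _as_tensor(other)
        # vector operands: promote to matrices, then drop the unit axis
        if other.ndim == 1:
            out = self @ other.reshape(other.shape + (1,))
            return out.reshape(out.shape[:-1])
        if self.ndim == 1:
            out = self.reshape((1,) + self.shape) @ other
            return out.reshape(out.shape[:-2] + out.shape[-1:])
        a, b = self, other

        def vjp(g):
            ga = g @ b.swap_last2() if b.ndim >= 2 else None
            gb = a.swap_last2() @ g if a.ndim >= 2 else None
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), vjp)

    def backward(self, create_graph: bool = False):
        """Accumulate d(self)/d(leaf) into ``.grad`` of all requires-grad leaves."""
        if self.size != 1:
            raise ValueError("backward() requires a scalar output")
        leaves = [t for t in _toposort(self) if t.requires_grad and t._vjp is None]
        grads = grad(self, leaves, create_graph=create_graph, allow_unused=True)
        for leaf, g in zip(leaves, grads):
            if g is None:
                continue
            if leaf.grad is None:
                leaf.grad = np.array(g.data, copy=True)
            else:
                leaf.grad += g.data


def _unbroadcast(g, shape):
    if g is None:
        return None
    shape = tuple(shape)
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _toposort(root: Tensor):
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order  # children after parents; reverse for backprop


def grad(output: Tensor, inputs, grad_output=None, create_graph: bool = False,
         allow_unused: bool = False):
    """Gradients of a scalar ``output`` with respect to ``inputs``.

    With ``create_graph=True`` the returned tensors are part of the autodiff
    graph, so expressions built from them can be differentiated again.
    """
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))
    table: dict[int, Tensor] = {id(output): grad_output}
    order = _toposort(output)
    ctx = no_grad() if not create_graph else None
    if ctx:
        ctx.__enter__()
    try:
        for node in reversed(order):
            g = table.pop(id(node), None)
            if g is None or node._vjp is None:
                if g is not None:
                    table[id(node)] = g
                continue
            parent_grads = node._vjp(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                acc = table.get(id(p))
                table[id(p)] = pg if acc is None else acc + pg
    finally:
        if ctx:
            ctx.__exit__(None, None, None)
    out = []
    for t in inputs:
        g = table.get(id(t))
        if g is None and not allow_unused:
            raise RuntimeError("an input is not reachable from the output graph")
        if g is not None and not create_graph:
            g = g.detach()
        out.append(g)
    return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    axis = axis % tensors[0].ndim
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def vjp(g):
        outs = []
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * t.ndim
            idx[axis] = slice(int(start), int(stop))
            outs.append(g[tuple(idx)])
        return tuple(outs)

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), vjp
    )


# -- convolution primitives -----------------------------------------------

def _im2col_forward(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    n, c, h, w = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (n, c, oh, ow, kh, kw)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, oh * ow)
    return np.ascontiguousarray(cols)


def _col2im_forward(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int) -> np.ndarray:
    n, c, h, w = x_shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    cols6 = cols.reshape(n, c, kh, kw, oh, ow)
    out = np.zeros(x_shape, dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols6[
                :, :, i, j
            ]
    return out


def im2col(x: Tensor, kh: int, kw: int, stride: int = 1) -> Tensor:
    """Extract sliding (kh, kw) patches of an (N, C, H, W) tensor into columns."""
    x = _as_tensor(x)
    x_shape = x.shape
    return Tensor._make(
        _im2col_forward(x.data, kh, kw, stride),
        (x,),
        lambda g: (col2im(g, x_shape, kh, kw, stride),),
    )


def col2im(cols: Tensor, x_shape, kh: int, kw: int, stride: int = 1) -> Tensor:
    """Adjoint of :func:`im2col`: overlap-add columns back onto the image grid."""
    cols = _as_tensor(cols)
    return Tensor._make(
        _col2im_forward(cols.data, tuple(x_shape), kh, kw, stride),
        (cols,),
        lambda g: (im2col(g, kh, kw, stride),),
    )


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-softmax (max-shift uses a detached constant)."""
    x = _as_tensor(x)
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()
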
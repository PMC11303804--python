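"""Minimal reverse-mode automatic differentiation on numpy arrays.

The force field is an energy model whose forces are exact gradients with
respect to atomic positions, and whose training loss contains those forces —
so the library needs gradients *of* gradients.  Every backward rule below is
itself expressed in traced :class:`Tensor` operations, which makes repeated
differentiation (double backprop) work out of the box.

Only the primitives the network actually uses are implemented; all arrays are
float64.  This is deliberately a small tape, not a framework.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "astensor", "add", "sub", "mul", "div", "neg", "power",
    "exp", "log", "sqrt", "sin", "cos", "tanh", "sigmoid", "silu",
    "sum_", "reshape", "broadcast_to", "transpose", "matmul",
    "gather", "scatter_add", "take_cols", "concat", "slice_", "backward",
]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "parents", "vjp")

    def __init__(self, data, parents=(), vjp=None):
        if isinstance(data, np.ndarray) and data.dtype == np.float64:
            self.data = data
        else:
            self.data = np.asarray(data, dtype=np.float64)
        self.parents = parents
        self.vjp = vjp

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # operator sugar -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return slice_(self, key)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape})"


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = sum_(g, axis=tuple(range(extra)))
    axes = tuple(
        i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1
    )
    if axes:
        g = sum_(g, axis=axes, keepdims=True)
    if g.shape != tuple(shape):
        g = reshape(g, shape)
    return g


# elementwise ---------------------------------------------------------------

_SCALARS = (int, float, np.floating, np.integer)


def add(a, b):
    if isinstance(b, _SCALARS):  # constant: gradient passes through unchanged
        a = astensor(a)
        return Tensor(a.data + b, (a,), lambda g: (g,))
    if isinstance(a, _SCALARS):
        b = astensor(b)
        return Tensor(a + b.data, (b,), lambda g: (g,))
    a, b = astensor(a), astensor(b)
    return Tensor(
        a.data + b.data, (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def sub(a, b):
    if isinstance(b, _SCALARS):
        a = astensor(a)
        return Tensor(a.data - b, (a,), lambda g: (g,))
    if isinstance(a, _SCALARS):
        b = astensor(b)
        return Tensor(a - b.data, (b,), lambda g: (neg(g),))
    a, b = astensor(a), astensor(b)
    return Tensor(
        a.data - b.data, (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(neg(g), b.shape)),
    )


def mul(a, b):
    if isinstance(b, _SCALARS):
        a = astensor(a)
        return Tensor(a.data * b, (a,), lambda g: (mul(g, b),))
    if isinstance(a, _SCALARS):
        b = astensor(b)
        return Tensor(a * b.data, (b,), lambda g: (mul(g, a),))
    a, b = astensor(a), astensor(b)
    return Tensor(
        a.data * b.data, (a, b),
        lambda g: (_unbroadcast(mul(g, b), a.shape), _unbroadcast(mul(g, a), b.shape)),
    )


def div(a, b):
    if isinstance(b, _SCALARS):
        return mul(a, 1.0 / b)
    a, b = astensor(a), astensor(b)
    return Tensor(
        a.data / b.data, (a, b),
        lambda g: (
            _unbroadcast(div(g, b), a.shape),
            _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.shape),
        ),
    )


def neg(a):
    a = astensor(a)
    return Tensor(-a.data, (a,), lambda g: (neg(g),))


def power(a, p):
    a = astensor(a)
    p = float(p)
    return Tensor(
        a.data ** p, (a,),
        lambda g: (mul(g, mul(p, power(a, p - 1.0))),),
    )


def exp(a):
    a = astensor(a)
    out = Tensor(np.exp(a.data), (a,), None)
    out.vjp = lambda g: (mul(g, out),)
    return out


def log(a):
    a = astensor(a)
    return Tensor(np.log(a.data), (a,), lambda g: (div(g, a),))


def sqrt(a):
    a = astensor(a)
    out = Tensor(np.sqrt(a.data), (a,), None)
    out.vjp = lambda g: (div(g, mul(2.0, out)),)
    return out


def sin(a):
    a = astensor(a)
    return Tensor(np.sin(a.data), (a,), lambda g: (mul(g, cos(a)),))


def cos(a):
    a = astensor(a)
    return Tensor(np.cos(a.data), (a,), lambda g: (neg(mul(g, sin(a))),))


def tanh(a):
    a = astensor(a)
    out = Tensor(np.tanh(a.data), (a,), None)
    out.vjp = lambda g: (mul(g, sub(1.0, mul(out, out))),)
    return out


def sigmoid(a):
    # 0.5*(tanh(x/2)+1): numerically stable for large |x|
    return mul(0.5, add(tanh(mul(0.5, astensor(a))), 1.0))


def silu(a):
    a = astensor(a)
    return mul(a, sigmoid(a))


# shape ---------------------------------------------------------------------

def sum_(a, axis=None, keepdims=False):
    a = astensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        gg = g
        if not keepdims and axis is not None:
            ax = (axis,) if isinstance(axis, int) else tuple(axis)
            shp = list(g.shape)
            for i in sorted(a_ % a.ndim for a_ in ax):
                shp.insert(i, 1)
            gg = reshape(gg, tuple(shp))
        elif not keepdims and axis is None:
            gg = reshape(gg, (1,) * a.ndim)
        return (broadcast_to(gg, a.shape),)

    return Tensor(out_data, (a,), vjp)


def reshape(a, shape):
    a = astensor(a)
    return Tensor(
        a.data.reshape(shape), (a,), lambda g: (reshape(g, a.shape),)
    )


def broadcast_to(a, shape):
    a = astensor(a)
    return Tensor(
        np.broadcast_to(a.data, shape).copy(), (a,),
        lambda g: (_unbroadcast(g, a.shape),),
    )


def transpose(a, axes=None):
    a = astensor(a)
    if axes is None:
        axes = tuple(reversed(range(a.ndim)))
    inv = [0] * len(axes)
    for i, ax in enumerate(axes):
        inv[ax] = i
    inv = tuple(inv)
    return Tensor(
        np.transpose(a.data, axes), (a,), lambda g: (transpose(g, inv),)
    )


def matmul(a, b):
    """2-D @ 2-D matrix product."""
    a, b = astensor(a), astensor(b)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")
    return Tensor(
        a.data @ b.data, (a, b),
        lambda g: (matmul(g, transpose(b)), matmul(transpose(a), g)),
    )


# indexing ------------------------------------------------------------------

def gather(a, idx):
    """Select rows ``a[idx]`` along axis 0 (``idx`` an int array)."""
    a = astensor(a)
    idx = np.asarray(idx, dtype=np.intp)
    return Tensor(
        a.data[idx], (a,), lambda g: (scatter_add(g, idx, a.shape[0]),)
    )


def scatter_add(src, idx, n_rows):
    """Rows of ``src`` summed into a (n_rows, ...) array at positions idx."""
    src = astensor(src)
    idx = np.asarray(idx, dtype=np.intp)
    out = np.zeros((n_rows,) + src.shape[1:], dtype=np.float64)
    np.add.at(out, idx, src.data)
    return Tensor(out, (src,), lambda g: (gather(g, idx),))


def take_cols(a, idx):
    """Select columns ``a[:, idx]`` (``idx`` an int array)."""
    a = astensor(a)
    idx = np.asarray(idx, dtype=np.intp)

    def vjp(g):
        # accumulate columns back: scatter along axis 1 via transpose
        return (transpose(scatter_add(transpose(g), idx, a.shape[1])),)

    return Tensor(a.data[:, idx], (a,), vjp)


def concat(tensors, axis=0):
    tensors = [astensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def vjp(g):
        outs = []
        for k in range(len(tensors)):
            key = [slice(None)] * g.ndim
            key[axis] = slice(int(offs[k]), int(offs[k + 1]))
            outs.append(slice_(g, tuple(key)))
        return tuple(outs)

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), vjp
    )


def slice_(a, key):
    """Basic (non-fancy) slicing with gradient support."""
    a = astensor(a)
    return Tensor(a.data[key], (a,), lambda g: (_unslice(g, key, a.shape),))


def _unslice(g, key, shape):
    g = astensor(g)

    def vjp(gg):
        return (slice_(gg, key),)

    out = np.zeros(shape, dtype=np.float64)
    out[key] = g.data
    return Tensor(out, (g,), vjp)


# backward ------------------------------------------------------------------

def _toposort(root: Tensor):
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack.append((p, False))
    return order  # parents before children


def backward(output: Tensor, wrt, seed=None):
    """Gradients of ``output`` w.r.t. each tensor in ``wrt``.

    ``seed`` is the upstream cotangent (defaults to ones, i.e. the plain
    gradient for a scalar output).  The returned tensors carry their own
    graph, so they can be differentiated again.
    """
    single = isinstance(wrt, Tensor)
    wrt_list = [wrt] if single else list(wrt)
    grads = {id(output): seed if seed is not None else Tensor(np.ones_like(output.data))}
    wanted = {id(w) for w in wrt_list}
    for node in reversed(_toposort(output)):
        g = grads.get(id(node))
        if g is None or node.vjp is None:
            continue
        for parent, pg in zip(node.parents, node.vjp(g)):
            if pg is None:
                continue
            acc = grads.get(id(parent))
            grads[id(parent)] = pg if acc is None else add(acc, pg)
        if id(node) not in wanted:
            del grads[id(node)]
    out = [
        grads.get(id(w), Tensor(np.zeros_like(w.data))) for w in wrt_list
    ]
    return out[0] if single else out
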
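"""Reverse-mode automatic differentiation on numpy arrays.

A small define-by-run tape. Every operation records vector-Jacobian
products (VJPs) that are themselves expressed in terms of the ops in this
module, so :func:`grad` can be called with ``create_graph=True`` and the
resulting gradient tensors differentiated again. Second-order gradients
are required by the Wasserstein critic's gradient penalty, whose value
depends on the gradient of the critic with respect to its *input* while
the training update needs the derivative of that quantity with respect to
the critic's *parameters*.

Only the primitives needed by the stain-transfer networks are provided:
elementwise arithmetic, conv2d (with the pair of transposed/weight-grad
convolutions that make it twice differentiable), nearest-neighbour
up/down-sampling, dense layers and a handful of reductions. All data is
float64, NCHW layout for images.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

_GRAD_ENABLED = True


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


@contextlib.contextmanager
def set_grad_enabled(mode: bool):
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = mode
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def no_grad():
    return set_grad_enabled(False)


class Tensor:
    """A numpy array plus the tape edges needed for backpropagation."""

    __slots__ = ("data", "requires_grad", "_vjps", "_cols_cache")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.requires_grad = bool(requires_grad)
        # list of (parent Tensor, vjp: cotangent Tensor -> cotangent Tensor)
        self._vjps: list[tuple["Tensor", Callable]] = []
        self._cols_cache: dict | None = None  # im2col reuse between fwd/bwd

    # -- conveniences ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(_as_tensor(other)))

    def __rsub__(self, other):
        return add(_as_tensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return mul(self, 1.0 / other)
        return mul(self, pow_(other, -1.0))

    def __pow__(self, p):
        return pow_(self, p)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents_vjps) -> Tensor:
    """Create an op output, recording edges only when the tape is live."""
    out = Tensor(data)
    if _GRAD_ENABLED:
        vjps = [(p, fn) for p, fn in parents_vjps if p.requires_grad or p._vjps]
        if vjps:
            out.requires_grad = True
            out._vjps = vjps
    return out


# -- broadcasting helpers ------------------------------------------------

def _sum_to_shape(t: Tensor, shape: tuple) -> Tensor:
    """Reduce a broadcast cotangent back to ``shape`` (graph-recorded)."""
    if t.shape == shape:
        return t
    ndim_extra = t.ndim - len(shape)
    axes = tuple(range(ndim_extra)) + tuple(
        i + ndim_extra for i, s in enumerate(shape) if s == 1 and t.shape[i + ndim_extra] != 1
    )
    out = sum_(t, axis=axes, keepdims=True) if axes else t
    return reshape(out, shape)


# -- elementwise ---------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(
        a.data + b.data,
        [(a, lambda g: _sum_to_shape(g, a.shape)), (b, lambda g: _sum_to_shape(g, b.shape))],
    )


def neg(a) -> Tensor:
    a = _as_tensor(a)
    return _make(-a.data, [(a, lambda g: neg(g))])


def mul(a, b) -> Tensor:
    if isinstance(b, (int, float)):
        a = _as_tensor(a)
        c = float(b)
        return _make(a.data * c, [(a, lambda g: mul(g, c))])
    if isinstance(a, (int, float)):
        return mul(b, a)
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(
        a.data * b.data,
        [
            (a, lambda g: _sum_to_shape(mul(g, b), a.shape)),
            (b, lambda g: _sum_to_shape(mul(g, a), b.shape)),
        ],
    )


def pow_(a, p: float) -> Tensor:
    a = _as_tensor(a)
    p = float(p)
    return _make(a.data ** p, [(a, lambda g: mul(mul(g, pow_(a, p - 1.0)), p))])


def sqrt(a) -> Tensor:
    return pow_(a, 0.5)


def exp(a) -> Tensor:
    # VJP factors below are captured as constants (no self-reference into
    # the output node): exact to first order, and these saturating /
    # exponential ops never sit on the twice-differentiated critic path.
    a = _as_tensor(a)
    out_data = np.exp(a.data)
    fac = Tensor(out_data)
    return _make(out_data, [(a, lambda g: mul(g, fac))])


def log(a) -> Tensor:
    a = _as_tensor(a)
    return _make(np.log(a.data), [(a, lambda g: mul(g, pow_(a, -1.0)))])


def tanh(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.tanh(a.data)
    fac = Tensor(1.0 - out_data * out_data)
    return _make(out_data, [(a, lambda g: mul(g, fac))])


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))
    fac = Tensor(out_data * (1.0 - out_data))
    return _make(out_data, [(a, lambda g: mul(g, fac))])


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = _as_tensor(a)
    factor = np.where(a.data > 0, 1.0, slope).astype(a.data.dtype, copy=False)
    fac_t = Tensor(factor)  # piecewise-constant: correct a.e. for 2nd order too
    return _make(a.data * factor, [(a, lambda g: mul(g, fac_t))])


def relu(a) -> Tensor:
    return leaky_relu(a, 0.0)


def abs_(a) -> Tensor:
    a = _as_tensor(a)
    sign = Tensor(np.sign(a.data).astype(a.data.dtype, copy=False))
    return _make(np.abs(a.data), [(a, lambda g: mul(g, sign))])


# -- shape ops -----------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    orig = a.shape
    return _make(a.data.reshape(shape), [(a, lambda g: reshape(g, orig))])


def broadcast_to(a, shape) -> Tensor:
    a = _as_tensor(a)
    orig = a.shape
    return _make(np.broadcast_to(a.data, shape).copy(), [(a, lambda g: _sum_to_shape(g, orig))])


def transpose2d(a) -> Tensor:
    a = _as_tensor(a)
    return _make(a.data.T.copy(), [(a, lambda g: transpose2d(g))])


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    vjps = []
    for t, off, size in zip(tensors, offsets[:-1], sizes):
        vjps.append((t, (lambda off=int(off), size=int(size): lambda g: narrow(g, axis, off, size))()))
    return _make(np.concatenate([t.data for t in tensors], axis=axis), vjps)


def narrow(a, axis: int, start: int, length: int) -> Tensor:
    a = _as_tensor(a)
    idx = [slice(None)] * a.ndim
    idx[axis] = slice(start, start + length)
    orig_shape = a.shape
    return _make(
        a.data[tuple(idx)].copy(),
        [(a, lambda g: _embed(g, orig_shape, axis, start))],
    )


def _embed(g: Tensor, shape: tuple, axis: int, start: int) -> Tensor:
    g = _as_tensor(g)
    length = g.shape[axis]
    data = np.zeros(shape, dtype=g.data.dtype)
    idx = [slice(None)] * len(shape)
    idx[axis] = slice(start, start + length)
    data[tuple(idx)] = g.data
    return _make(data, [(g, lambda c: narrow(c, axis, start, length))])


# -- reductions ----------------------------------------------------------

def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    orig = a.shape
    if axis is None:
        axes = tuple(range(a.ndim))
    elif isinstance(axis, int):
        axes = (axis,)
    else:
        axes = tuple(axis)

    def vjp(g):
        kept = g
        if not keepdims:
            shape = list(orig)
            for ax in axes:
                shape[ax] = 1
            kept = reshape(g, tuple(shape))
        return broadcast_to(kept, orig)

    return _make(a.data.sum(axis=axes, keepdims=keepdims), [(a, vjp)])


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


# -- convolution family --------------------------------------------------
#
# y = conv2d(x, w)  is bilinear in (x, w); its two partial adjoints,
# conv2d_dx and conv2d_dw, are primitives whose VJPs refer back to each
# other and to conv2d, which is what makes the family twice
# differentiable without any extra machinery.

def _conv_geometry(H, W, kh, kw, stride, pad):
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (W + 2 * pad - kw) // stride + 1
    return Ho, Wo


def _im2col(x: np.ndarray, kh, kw, stride, pad):
    N, C, H, W = x.shape
    Ho, Wo = _conv_geometry(H, W, kh, kw, stride, pad)
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((N, C, kh, kw, Ho, Wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride]
    return cols.reshape(N, C * kh * kw, Ho * Wo), Ho, Wo


def _col2im(cols: np.ndarray, xshape, kh, kw, stride, pad, Ho, Wo):
    N, C, H, W = xshape
    out = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(N, C, kh, kw, Ho, Wo)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += cols[:, :, i, j]
    return out[:, :, pad : pad + H, pad : pad + W] if pad else out


def _cached_im2col(x: Tensor, kh, kw, stride, pad):
    """im2col of a graph tensor, memoized while the tape holds it alive.

    Only non-leaf tensors are cached: intermediates are immutable once
    produced, whereas leaf data may be mutated in place between calls.
    """
    key = (kh, kw, stride, pad)
    if x._cols_cache is not None and key in x._cols_cache:
        return x._cols_cache[key]
    result = _im2col(x.data, kh, kw, stride, pad)
    if _GRAD_ENABLED and x._vjps:
        if x._cols_cache is None:
            x._cols_cache = {}
        x._cols_cache[key] = result
    return result


def conv2d(x, w, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW input, (Cout, Cin, kh, kw) weight."""
    x, w = _as_tensor(x), _as_tensor(w)
    N, C, H, W = x.shape
    Co, Ci, kh, kw = w.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input has {C}, weight expects {Ci}")
    cols, Ho, Wo = _cached_im2col(x, kh, kw, stride, pad)
    y = np.matmul(w.data.reshape(Co, -1), cols).reshape(N, Co, Ho, Wo)
    return _make(
        y,
        [
            (x, lambda g: conv2d_dx(g, w, x.shape, stride, pad)),
            (w, lambda g: conv2d_dw(x, g, w.shape, stride, pad)),
        ],
    )


def conv2d_dx(gy, w, xshape, stride: int = 1, pad: int = 0) -> Tensor:
    """Adjoint of conv2d with respect to its input (a transposed conv)."""
    gy, w = _as_tensor(gy), _as_tensor(w)
    Co, Ci, kh, kw = w.shape
    N = gy.shape[0]
    Ho, Wo = gy.shape[2], gy.shape[3]
    g_flat = gy.data.reshape(N, Co, Ho * Wo)
    cols = np.matmul(w.data.reshape(Co, -1).T, g_flat)
    dx = _col2im(cols, xshape, kh, kw, stride, pad, Ho, Wo)
    return _make(
        dx,
        [
            (gy, lambda c: conv2d(c, w, stride, pad)),
            (w, lambda c: conv2d_dw(c, gy, w.shape, stride, pad)),
        ],
    )


def conv2d_dw(x, gy, wshape, stride: int = 1, pad: int = 0) -> Tensor:
    """Adjoint of conv2d with respect to its weight."""
    x, gy = _as_tensor(x), _as_tensor(gy)
    Co, Ci, kh, kw = wshape
    N = x.shape[0]
    cols, Ho, Wo = _cached_im2col(x, kh, kw, stride, pad)
    g_flat = gy.data.reshape(N, Co, Ho * Wo)
    dw = np.matmul(g_flat, cols.transpose(0, 2, 1)).sum(axis=0).reshape(wshape)
    return _make(
        dw,
        [
            (x, lambda c: conv2d_dx(gy, c, x.shape, stride, pad)),
            (gy, lambda c: conv2d(x, c, stride, pad)),
        ],
    )


def upsample_nearest2(x) -> Tensor:
    """Nearest-neighbour 2x upsampling of an NCHW tensor."""
    x = _as_tensor(x)
    data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    return _make(data, [(x, lambda g: block_sum2(g))])


def block_sum2(x) -> Tensor:
    """Sum over non-overlapping 2x2 blocks (adjoint of 2x nearest upsampling)."""
    x = _as_tensor(x)
    N, C, H, W = x.shape
    data = x.data.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))
    return _make(data, [(x, lambda g: upsample_nearest2(g))])


def avg_pool2(x) -> Tensor:
    return mul(block_sum2(x), 0.25)


# -- dense ---------------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(
        a.data @ b.data,
        [
            (a, lambda g: matmul(g, transpose2d(b))),
            (b, lambda g: matmul(transpose2d(a), g)),
        ],
    )


def log_softmax(x, axis: int = 1) -> Tensor:
    x = _as_tensor(x)
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant; softmax shift-invariant
    z = add(x, neg(broadcast_to(shift, x.shape)))
    lse = log(sum_(exp(z), axis=axis, keepdims=True))
    return add(z, neg(broadcast_to(lse, x.shape)))


def softmax(x, axis: int = 1) -> Tensor:
    return exp(log_softmax(x, axis=axis))


# -- the driver ----------------------------------------------------------

def _topo_order(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node._vjps:
            if id(parent) not in seen:
                stack.append((parent, False))
    return order


def grad(output: Tensor, inputs: Sequence[Tensor], create_graph: bool = False) -> list[Tensor]:
    """Gradients of a scalar ``output`` with respect to ``inputs``.

    With ``create_graph=True`` the returned tensors carry tape edges and can
    be differentiated again (needed for the gradient penalty).
    """
    if output.data.size != 1:
        raise ValueError("grad() requires a scalar output")
    order = _topo_order(output)
    cot: dict[int, Tensor] = {id(output): Tensor(np.ones_like(output.data))}
    with set_grad_enabled(create_graph):
        for node in reversed(order):
            g = cot.get(id(node))
            if g is None:
                continue
            for parent, vjp in node._vjps:
                contrib = vjp(g)
                prev = cot.get(id(parent))
                cot[id(parent)] = contrib if prev is None else add(prev, contrib)
    results = []
    for inp in inputs:
        g = cot.get(id(inp))
        results.append(g if g is not None else Tensor(np.zeros_like(inp.data)))
    return results
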
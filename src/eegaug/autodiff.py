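"""Minimal reverse-mode tensor autodiff over numpy arrays.

The engine exists because the gradient-penalty term of the Wasserstein
critic loss needs the gradient (with respect to the critic *parameters*)
of a quantity that itself contains a gradient (with respect to the critic
*input*).  Every backward rule below is therefore expressed in terms of
the same primitive operations, so calling :func:`grad` with
``create_graph=True`` yields a differentiable expression and second-order
gradients fall out of the ordinary machinery.

Only what the networks in this package need is implemented: elementwise
arithmetic, matmul with broadcasting, reductions, shape ops, im2col /
col2im (the adjoint pair from which convolution and transposed
convolution are composed), and a max-pool primitive.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "no_grad", "grad", "concat", "im2col", "col2im",
           "maxpool2d", "leaky_relu", "relu"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph recording."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    __slots__ = ("data", "requires_grad", "_parents")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self._parents = ()  # tuple of (Tensor, vjp) pairs

    # -- basic protocol -------------------------------------------------
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

    def item(self):
        return self.data.item()

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        if isinstance(other, Tensor):
            return add(self, -other)
        return add(self, -np.asarray(other) if isinstance(other, np.ndarray)
                   else -other)

    def __rsub__(self, other):
        return add(-self, other)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # -- convenience ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes if axes else None)

    def detach(self):
        return Tensor(self.data)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data, parents):
    """Build a result tensor, recording parents only when tracking is on."""
    out = Tensor(data)
    live = [(p, vjp) for p, vjp in parents if p.requires_grad]
    if _GRAD_ENABLED and live:
        out.requires_grad = True
        out._parents = tuple(live)
    return out


def _unbroadcast(t: Tensor, shape) -> Tensor:
    """Sum ``t`` down to ``shape`` (reverses numpy broadcasting)."""
    if t.shape == tuple(shape):
        return t
    extra = t.ndim - len(shape)
    if extra > 0:
        t = tsum(t, axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and t.shape[i] != 1)
    if axes:
        t = tsum(t, axis=axes, keepdims=True)
    return reshape(t, tuple(shape))


# -- elementwise ops ----------------------------------------------------

def _is_pyscalar(x):
    # python scalars promote "weakly" in numpy, keeping float32 graphs float32
    return isinstance(x, (int, float)) and not isinstance(x, bool)


def add(a, b):
    if _is_pyscalar(a):
        a, b = b, a
    if _is_pyscalar(b):
        a = as_tensor(a)
        return _make(a.data + b, [(a, lambda g: g)])
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data + b.data,
                 [(a, lambda g: _unbroadcast(g, a.shape)),
                  (b, lambda g: _unbroadcast(g, b.shape))])


def mul(a, b):
    if _is_pyscalar(a):
        a, b = b, a
    if _is_pyscalar(b):
        a = as_tensor(a)
        return _make(a.data * b, [(a, lambda g: mul(g, b))])
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data * b.data,
                 [(a, lambda g: _unbroadcast(mul(g, b), a.shape)),
                  (b, lambda g: _unbroadcast(mul(g, a), b.shape))])


def div(a, b):
    if _is_pyscalar(b):
        return mul(a, 1.0 / b)
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data / b.data,
                 [(a, lambda g: _unbroadcast(div(g, b), a.shape)),
                  (b, lambda g: _unbroadcast(mul(g, div(-a, mul(b, b))), b.shape))])


def power(a, p):
    a = as_tensor(a)
    p = float(p)
    return _make(a.data ** p,
                 [(a, lambda g: mul(g, mul(p, power(a, p - 1.0))))])


def exp(a):
    a = as_tensor(a)
    out = _make(np.exp(a.data), [(a, lambda g: mul(g, exp(a)))])
    return out


def log(a):
    a = as_tensor(a)
    return _make(np.log(a.data), [(a, lambda g: div(g, a))])


def sqrt(a):
    return power(a, 0.5)


def tanh(a):
    a = as_tensor(a)
    return _make(np.tanh(a.data),
                 [(a, lambda g: mul(g, 1.0 - power(tanh(a), 2.0)))])


def leaky_relu(a, slope=0.2):
    a = as_tensor(a)
    one = a.dtype.type(1.0)
    mask = Tensor(np.where(a.data > 0, one, a.dtype.type(slope)))
    return _make(a.data * mask.data, [(a, lambda g: mul(g, mask))])


def relu(a):
    return leaky_relu(a, 0.0)


# -- matmul -------------------------------------------------------------

def _swap(t: Tensor) -> Tensor:
    axes = list(range(t.ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return transpose(t, tuple(axes))


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def vjp_a(g):
        r = matmul(g, _swap(b))
        return _unbroadcast(r, a.shape)

    def vjp_b(g):
        r = matmul(_swap(a), g)
        return _unbroadcast(r, b.shape)

    return _make(np.matmul(a.data, b.data), [(a, vjp_a), (b, vjp_b)])


# -- reductions / shape -------------------------------------------------

def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)
    if axis is None:
        ax = tuple(range(a.ndim))
    elif isinstance(axis, int):
        ax = (axis % a.ndim,)
    else:
        ax = tuple(i % a.ndim for i in axis)

    def vjp(g):
        if not keepdims:
            shp = list(a.shape)
            for i in ax:
                shp[i] = 1
            g = reshape(g, tuple(shp))
        return broadcast_to(g, a.shape)

    return _make(a.data.sum(axis=ax, keepdims=keepdims), [(a, vjp)])


def tmean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    if axis is None:
        n = a.size
    elif isinstance(axis, int):
        n = a.shape[axis % a.ndim]
    else:
        n = int(np.prod([a.shape[i % a.ndim] for i in axis]))
    return mul(tsum(a, axis, keepdims), 1.0 / n)


def broadcast_to(a, shape):
    a = as_tensor(a)
    if a.shape == tuple(shape):
        return a
    return _make(np.broadcast_to(a.data, shape).copy(),
                 [(a, lambda g: _unbroadcast(g, a.shape))])


def reshape(a, shape):
    a = as_tensor(a)
    return _make(a.data.reshape(shape), [(a, lambda g: reshape(g, a.shape))])


def transpose(a, axes=None):
    a = as_tensor(a)
    if axes is None:
        axes = tuple(reversed(range(a.ndim)))
    inv = tuple(np.argsort(axes))
    return _make(a.data.transpose(axes), [(a, lambda g: transpose(g, inv))])


def getitem(a, idx):
    a = as_tensor(a)
    return _make(a.data[idx], [(a, lambda g: scatter(g, idx, a.shape))])


def scatter(a, idx, shape):
    """Zeros of ``shape`` with ``a`` placed at basic-slice ``idx`` (adjoint of getitem)."""
    a = as_tensor(a)
    z = np.zeros(shape, dtype=a.dtype)
    z[idx] = a.data
    return _make(z, [(a, lambda g: getitem(g, idx))])


def concat(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    parents = []
    start = 0
    for t in tensors:
        n = t.shape[axis]
        sl = [slice(None)] * data.ndim
        sl[axis] = slice(start, start + n)
        sl = tuple(sl)
        parents.append((t, (lambda s: lambda g: getitem(g, s))(sl)))
        start += n
    return _make(data, parents)


# -- convolution primitives --------------------------------------------

def _conv_geom(H, W, kh, kw, sh, sw, ph, pw):
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1
    return Ho, Wo


def im2col(x, kh, kw, sh, sw, ph, pw):
    """(N,C,H,W) -> (C*kh*kw, N*Ho*Wo) patch matrix; adjoint of col2im.

    The merged column layout lets the convolution run as one large GEMM
    instead of a batch of skinny ones.
    """
    x = as_tensor(x)
    N, C, H, W = x.shape
    Ho, Wo = _conv_geom(H, W, kh, kw, sh, sw, ph, pw)
    if ph or pw:
        xp = np.zeros((N, C, H + 2 * ph, W + 2 * pw), dtype=x.dtype)
        xp[:, :, ph:ph + H, pw:pw + W] = x.data
    else:
        xp = x.data
    # windows: (N, C, Ho, Wo, kh, kw) strided view; one big copy reorders it
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw]
    out_data = np.ascontiguousarray(win.transpose(1, 4, 5, 0, 2, 3)
                                    ).reshape(C * kh * kw, N * Ho * Wo)

    def vjp(g):
        return col2im(g, N, (C, H, W), kh, kw, sh, sw, ph, pw)

    return _make(out_data, [(x, vjp)])


try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not (a and callable(a[0])) else a[0]


@_njit(cache=False)
def _col2im_kernel(cv, out, kh, kw, sh, sw, ph, pw):  # pragma: no cover - jitted
    N, C, H, W = out.shape
    Ho, Wo = cv.shape[4], cv.shape[5]
    for n in range(N):
        for c in range(C):
            for di in range(kh):
                for dj in range(kw):
                    for ho in range(Ho):
                        row = di + sh * ho - ph
                        if row < 0 or row >= H:
                            continue
                        for wo in range(Wo):
                            col = dj + sw * wo - pw
                            if 0 <= col < W:
                                out[n, c, row, col] += cv[c, di, dj, n, ho, wo]


def col2im(cols, N, chw, kh, kw, sh, sw, ph, pw):
    """(C*kh*kw, N*Ho*Wo) -> (N,C,H,W) by overlap-add; adjoint of im2col."""
    cols = as_tensor(cols)
    C, H, W = chw
    Ho, Wo = _conv_geom(H, W, kh, kw, sh, sw, ph, pw)
    cv = np.ascontiguousarray(cols.data).reshape(C, kh, kw, N, Ho, Wo)
    out = np.zeros((N, C, H, W), dtype=cols.dtype)
    _col2im_kernel(cv, out, kh, kw, sh, sw, ph, pw)

    def vjp(g):
        return im2col(g, kh, kw, sh, sw, ph, pw)

    return _make(out, [(cols, vjp)])


def maxpool2d(x, p=2):
    """Non-overlapping p x p max pooling; ties share gradient equally."""
    x = as_tensor(x)
    N, C, H, W = x.shape
    if H % p or W % p:
        raise ValueError(f"maxpool2d: spatial dims {(H, W)} not divisible by {p}")
    Ho, Wo = H // p, W // p
    xr = x.data.reshape(N, C, Ho, p, Wo, p)
    m = xr.max(axis=(3, 5), keepdims=True)
    mask = (xr == m)
    mask = mask / mask.sum(axis=(3, 5), keepdims=True)
    mask_t = Tensor(mask.astype(x.dtype, copy=False))

    def vjp(g):
        gr = reshape(g, (N, C, Ho, 1, Wo, 1))
        return reshape(mul(broadcast_to(gr, (N, C, Ho, p, Wo, p)), mask_t),
                       (N, C, H, W))

    return _make(m.reshape(N, C, Ho, Wo), [(x, vjp)])


# -- backprop -----------------------------------------------------------

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
        for p, _ in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    return order  # children after parents


def grad(output: Tensor, inputs, create_graph=False, seed=None):
    """Cotangents of ``output`` w.r.t. each tensor in ``inputs``.

    ``output`` may have any shape; ``seed`` (default: ones) is the
    cotangent it is seeded with.  With ``create_graph=True`` the returned
    tensors carry their own graphs and can be differentiated again.
    """
    single = isinstance(inputs, Tensor)
    inputs = [inputs] if single else list(inputs)
    cot = {id(output): as_tensor(np.ones_like(output.data) if seed is None else seed)}
    input_ids = {id(t) for t in inputs}

    order = _toposort(output)  # parents before children
    # prune branches that cannot reach a requested input
    reach = {}
    for node in order:
        reach[id(node)] = id(node) in input_ids or any(
            reach[id(p)] for p, _ in node._parents)

    def run():
        for node in reversed(order):
            g = cot.pop(id(node), None)
            if g is None:
                continue
            for p, vjp in node._parents:
                if not reach[id(p)]:
                    continue
                contrib = vjp(g)
                prev = cot.get(id(p))
                cot[id(p)] = contrib if prev is None else add(prev, contrib)
            if id(node) in input_ids:
                cot[id(node)] = g
        return [cot.get(id(t), Tensor(np.zeros_like(t.data))) for t in inputs]

    if create_graph:
        res = run()
    else:
        with no_grad():
            res = run()
    return res[0] if single else res
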
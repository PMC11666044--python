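"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operations that
produced it; calling :meth:`Tensor.backward` on a scalar result accumulates
gradients into every upstream tensor created with ``requires_grad=True``.
Only the primitives needed by the dense / convolutional / graph-convolutional
models in this package are implemented; each primitive's adjoint is written
explicitly and is validated against central finite differences in the test
suite.

All arithmetic is float64. This favours run-to-run reproducibility and
gradient-check fidelity over speed, which is appropriate for the small,
CPU-sized networks this package trains.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv3d", "log_softmax", "softplus", "take_pairs"]


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float64))


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the adjoint of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph construction helpers -------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data
        a, b = self.data, other.data

        def backward(g):
            return (_unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        def backward(g):
            return (-g,)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        return self * _as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)
        out_data = self.data ** e
        x = self.data

        def backward(g):
            return (g * e * x ** (e - 1.0),)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)
        a, b = self.data, other.data
        out_data = a @ b

        def backward(g):
            return (g @ b.T, a.T @ g)

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            return (g * mask,)

        return Tensor._make(self.data * mask, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        x = self.data

        def backward(g):
            return (g / x,)

        return Tensor._make(np.log(x), (self,), backward)

    def sqrt(self):
        return self ** 0.5

    # -- reductions / shape ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).copy(),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            return (g.reshape(old),)

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    # -- autodiff driver -------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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

        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None or node._backward is None:
                if g is not None and node.requires_grad:
                    node.grad = g if node.grad is None else node.grad + g
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


# -- free-function primitives --------------------------------------------

def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


def log_softmax(t: Tensor, axis: int = -1) -> Tensor:
    x = t.data
    shifted = x - x.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse
    softmax = np.exp(out_data)

    def backward(g):
        return (g - softmax * g.sum(axis=axis, keepdims=True),)

    return Tensor._make(out_data, (t,), backward)


def softplus(t: Tensor) -> Tensor:
    """log(1 + exp(x)), computed stably; adjoint is the logistic sigmoid."""
    x = t.data
    out_data = np.logaddexp(0.0, x)
    sig = 1.0 / (1.0 + np.exp(-x))

    def backward(g):
        return (g * sig,)

    return Tensor._make(out_data, (t,), backward)


def take_pairs(t: Tensor, rows: np.ndarray, cols: np.ndarray) -> Tensor:
    """Gather ``t[rows[i], cols[i]]`` as a 1-D tensor."""
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    shape = t.data.shape

    def backward(g):
        out = np.zeros(shape)
        np.add.at(out, (rows, cols), g)
        return (out,)

    return Tensor._make(t.data[rows, cols], (t,), backward)


def _im2col3d(xp: np.ndarray, k: int) -> np.ndarray:
    """(N, C, D, H, W) padded input -> (N*Do*Ho*Wo, C*k^3) patch matrix."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    # win: (N, C, Do, Ho, Wo, k, k, k) -> (N, Do, Ho, Wo, C, k, k, k)
    win = win.transpose(0, 2, 3, 4, 1, 5, 6, 7)
    n, do, ho, wo = win.shape[:4]
    return win.reshape(n * do * ho * wo, -1), (n, do, ho, wo)


def conv3d(x: Tensor, w: Tensor, padding: int = 0) -> Tensor:
    """3-D cross-correlation, stride 1.

    ``x``: (N, C_in, D, H, W); ``w``: (C_out, C_in, k, k, k). Output spatial
    size is ``D + 2*padding - k + 1`` per axis.
    """
    k = w.data.shape[2]
    if k == 1 and padding == 0:
        # pointwise convolution: a matmul over the channel axis
        wmat = w.data[:, :, 0, 0, 0]  # (C_out, C_in)
        out_data = np.einsum("oc,ncdhw->nodhw", wmat, x.data, optimize=True)
        w_shape = w.data.shape

        def backward_1x1(g):
            gx = np.einsum("oc,nodhw->ncdhw", wmat, g, optimize=True)
            gw = np.einsum("nodhw,ncdhw->oc", g, x.data, optimize=True)
            return (gx, gw.reshape(w_shape))

        return Tensor._make(out_data, (x, w), backward_1x1)
    pad = padding
    if pad:
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    else:
        xp = x.data
    cols, (n, do, ho, wo) = _im2col3d(xp, k)
    c_out = w.data.shape[0]
    wmat = w.data.reshape(c_out, -1)  # (C_out, C_in*k^3)
    out = cols @ wmat.T  # (N*Do*Ho*Wo, C_out)
    out_data = out.reshape(n, do, ho, wo, c_out).transpose(0, 4, 1, 2, 3)
    x_shape = x.data.shape
    xp_shape = xp.shape

    def backward(g):
        gmat = g.transpose(0, 2, 3, 4, 1).reshape(-1, c_out)  # (N*Do*Ho*Wo, C_out)
        gw = (gmat.T @ cols).reshape(w.data.shape)
        gcols = gmat @ wmat  # (N*Do*Ho*Wo, C_in*k^3)
        gx_p = np.zeros(xp_shape)
        gcols = gcols.reshape(n, do, ho, wo, -1, k, k, k)
        # scatter-add each kernel offset back onto the padded grid
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    gx_p[:, :, a : a + do, b : b + ho, c : c + wo] += gcols[
                        :, :, :, :, :, a, b, c
                    ].transpose(0, 4, 1, 2, 3)
        if pad:
            gx = gx_p[:, :, pad:-pad, pad:-pad, pad:-pad]
        else:
            gx = gx_p
        return (gx.reshape(x_shape), gw)

    return Tensor._make(out_data, (x, w), backward)
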
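"""A small reverse-mode automatic-differentiation engine on numpy arrays.

This is the substrate for the capsule autoencoder and the control networks:
a tape of ``Tensor`` nodes, each holding a float32 array, its parents and a
closure that accumulates gradients into the parents.  Convolution and
transposed convolution are implemented as im2col/col2im matrix products so
that training runs at BLAS speed on a single CPU.

Only the operations the models need are provided; all of them support the
broadcasting required by capsule routing (e.g. ``[N,I,1] * [N,I,D]``).
Gradient correctness is checked against finite differences in the test
suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

Array = np.ndarray


def _as_array(x) -> Array:
    """Floating arrays keep their dtype; everything else becomes float32."""
    a = np.asarray(x)
    if not np.issubdtype(a.dtype, np.floating):
        a = a.astype(np.float32)
    return a


class Tensor:
    """A node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[Array], None] | None = None,
    ):
        self.data = _as_array(data)
        self.grad: Array | None = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: Array) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(
        self, grad: Array | None = None, retain_grads: bool = False
    ) -> None:
        """Backpropagate from this node (default seed: ones).

        Unless ``retain_grads`` is set, gradients of interior nodes are
        released as soon as they have been propagated — only leaf tensors
        (parameters and inputs) keep ``.grad``.
        """
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = (
            np.ones_like(self.data) if grad is None else _as_array(grad)
        )
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
                if not retain_grads and t._parents:
                    t.grad = None

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g: Array) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    out._backward = backward
    return out


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g: Array) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    out._backward = backward
    return out


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data @ b.data, parents=(a, b))

    def backward(g: Array) -> None:
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.shape))

    out._backward = backward
    return out


def power(a, exponent: float) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data**exponent, parents=(a,))

    def backward(g: Array) -> None:
        if a.requires_grad:
            a._accumulate(g * exponent * a.data ** (exponent - 1.0))

    out._backward = backward
    return out


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def exp(a) -> Tensor:
    a = _wrap(a)
    y = np.exp(a.data)
    out = Tensor(y, parents=(a,))

    # capture the array, not the Tensor: a self-reference through the
    # closure would make every graph a reference cycle for the GC
    def backward(g: Array) -> None:
        if a.requires_grad:
            a._accumulate(g * y)

    out._backward = backward
    return out


def log(a) -> Tensor:
    a = _wrap(a)
    out = Tensor(np.log(a.data), parents=(a,))

    def backward(g: Array) -> None:
        if a.requires_grad:
            a._accumulate(g / a.data)

    out._backward = backward
    return out


def absolute(a) -> Tensor:
    a = _wrap(a)
    out = Tensor(np.abs(a.data), parents=(a,))

    def backward(g: Array) -> None:
        if a.requires_grad:
            a._accumulate(g * np.sign(a.data))

    out._backward = backward
    return out


def relu(a) -> Tensor:
    a = _wrap(a)
    out = Tensor(np.maximum(a.data, 0.0), parents=(a,))

    def backward(g: Array) -> None:
        if a.requires_grad:
            a._accumulate(g * (a.data > 0))

    out._backward = backward
    return out


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    # tanh form is overflow-safe for large |x|
    y = 0.5 * (1.0 + np.tanh(0.5 * a.data))
    out = Tensor(y, parents=(a,))

    def backward(g: Array) -> None:
        if a.requires_grad:
            a._accumulate(g * y * (1.0 - y))

    out._backward = backward
    return out


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data.reshape(shape), parents=(a,))

    def backward(g: Array) -> None:
        if a.requires_grad:
            a._accumulate(g.reshape(a.shape))

    out._backward = backward
    return out


def transpose(a, axes) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data.transpose(axes), parents=(a,))
    inv = np.argsort(axes)

    def backward(g: Array) -> None:
        if a.requires_grad:
            a._accumulate(g.transpose(inv))

    out._backward = backward
    return out


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,))

    def backward(g: Array) -> None:
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.shape).copy())

    out._backward = backward
    return out


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in np.atleast_1d(axis)]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
    )
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: Array) -> None:
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = backward
    return out


def softmax(a, axis: int) -> Tensor:
    a = _wrap(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    y = ez / ez.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(a,))

    def backward(g: Array) -> None:
        if a.requires_grad:
            dot = (g * y).sum(axis=axis, keepdims=True)
            a._accumulate(y * (g - dot))

    out._backward = backward
    return out


def cross_entropy(logits: Tensor, labels: Array) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under softmax of ``logits``."""
    logits = _wrap(logits)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    n = logits.shape[0]
    loss_val = -logp[np.arange(n), labels].mean()
    out = Tensor(loss_val, parents=(logits,))

    def backward(g: Array) -> None:
        if logits.requires_grad:
            p = np.exp(logp)
            p[np.arange(n), labels] -= 1.0
            logits._accumulate(g * p / n)

    out._backward = backward
    return out


# -- convolution ---------------------------------------------------------


def _im2col(x: Array, k: int, stride: int) -> Array:
    """Extract k x k windows at the given stride.

    x: [N, C, H, W] -> cols [N, Ho, Wo, C*k*k] with Ho = (H-k)//stride + 1.
    """
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, :, :]  # [N, C, Ho, Wo, k, k]
    win = win.transpose(0, 2, 3, 1, 4, 5)  # [N, Ho, Wo, C, k, k]
    n, ho, wo = win.shape[:3]
    return np.ascontiguousarray(win).reshape(n, ho, wo, -1)


def _col2im(
    cols: Array, x_shape: tuple[int, ...], k: int, stride: int
) -> Array:
    """Scatter-add column gradients back to the input layout (adjoint of _im2col)."""
    n, c, h, w = x_shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    cols = cols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    dx = np.zeros(x_shape, dtype=cols.dtype)
    for a in range(k):
        for b in range(k):
            dx[:, :, a : a + stride * ho : stride, b : b + stride * wo : stride] += cols[
                :, :, :, :, a, b
            ]
    return dx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1) -> Tensor:
    """2-D cross-correlation (no padding): x [N,C,H,W], w [F,C,k,k] -> [N,F,Ho,Wo]."""
    x, w = _wrap(x), _wrap(w)
    f, c, k, _ = w.shape
    cols = _im2col(x.data, k, stride)  # [N, Ho, Wo, C*k*k]
    n, ho, wo, _ = cols.shape
    wmat = w.data.reshape(f, -1)
    y = cols.reshape(-1, c * k * k) @ wmat.T
    if b is not None:
        y = y + b.data
    y = y.reshape(n, ho, wo, f).transpose(0, 3, 1, 2)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(np.ascontiguousarray(y), parents=parents)

    def backward(g: Array) -> None:
        gmat = g.transpose(0, 2, 3, 1).reshape(-1, f)  # [N*Ho*Wo, F]
        if b is not None and b.requires_grad:
            b._accumulate(gmat.sum(axis=0))
        if w.requires_grad:
            cols2 = _im2col(x.data, k, stride).reshape(-1, c * k * k)
            w._accumulate((gmat.T @ cols2).reshape(w.shape))
        if x.requires_grad:
            dcols = gmat @ wmat  # [N*Ho*Wo, C*k*k]
            x._accumulate(_col2im(dcols.reshape(n, ho, wo, -1), x.shape, k, stride))

    out._backward = backward
    return out


def conv_transpose2d(
    x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0
) -> Tensor:
    """Transposed convolution: x [N,C,H,W], w [C,F,k,k] -> [N,F,Ho,Wo].

    Ho = (H-1)*stride + k - 2*padding.  Forward is the adjoint of ``conv2d``
    with the same stride on a ``padding``-padded output.
    """
    x, w = _wrap(x), _wrap(w)
    n, c, h, wdt = x.shape
    _, f, k, _ = w.shape
    ho_full = (h - 1) * stride + k
    wo_full = (wdt - 1) * stride + k
    xmat = x.data.transpose(0, 2, 3, 1).reshape(-1, c)  # [N*H*W, C]
    cols = xmat @ w.data.reshape(c, -1)  # [N*H*W, F*k*k]
    y_full = _col2im(
        cols.reshape(n, h, wdt, -1), (n, f, ho_full, wo_full), k, stride
    )
    y = y_full[:, :, padding : ho_full - padding, padding : wo_full - padding]
    if b is not None:
        y = y + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(np.ascontiguousarray(y), parents=parents)

    def backward(g: Array) -> None:
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        gp = np.pad(
            g, ((0, 0), (0, 0), (padding, padding), (padding, padding))
        )
        gcols = _im2col(gp, k, stride).reshape(-1, f * k * k)  # [N*H*W, F*k*k]
        if w.requires_grad:
            w._accumulate((xmat.T @ gcols).reshape(w.shape))
        if x.requires_grad:
            dx = gcols @ w.data.reshape(c, -1).T  # [N*H*W, C]
            x._accumulate(
                dx.reshape(n, h, wdt, c).transpose(0, 3, 1, 2).copy()
            )

    out._backward = backward
    return out


def caps_predict(u: Tensor, w: Tensor) -> Tensor:
    """Per-capsule linear predictions: u [N,I,Dl], w [I,Dh,Dl] -> [N,I,Dh]."""
    u, w = _wrap(u), _wrap(w)
    out = Tensor(np.einsum("iab,nib->nia", w.data, u.data), parents=(u, w))

    def backward(g: Array) -> None:
        if w.requires_grad:
            w._accumulate(np.einsum("nia,nib->iab", g, u.data))
        if u.requires_grad:
            u._accumulate(np.einsum("iab,nia->nib", w.data, g))

    out._backward = backward
    return out


# -- parameters and optimizer --------------------------------------------


def parameter(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    """He-style normal init scaled by 1/sqrt(fan_in)."""
    data = rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)
    return Tensor(data.astype(np.float32), requires_grad=True)


def zeros_parameter(shape) -> Tensor:
    return Tensor(np.zeros(shape, dtype=np.float32), requires_grad=True)


class Adam:
    """Adaptive moment estimation over a named parameter dict."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
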
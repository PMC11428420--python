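"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Only the operations the denoising networks need are implemented: elementwise
arithmetic with broadcasting, matmul, reductions, activations, shape
manipulation, 2D padding (zero/reflect) and strided 2D convolution.  Gradients
are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward` over a
topologically sorted graph.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "no_grad",
    "is_grad_enabled",
    "concatenate",
    "conv2d",
    "pad2d",
]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after a broadcast forward op."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype.kind not in "fc":
            self.data = self.data.astype(np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if is_grad_enabled() and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic protocol -------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def __len__(self):
        return len(self.data)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / (other.data ** 2), other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise functions ------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g / (2.0 * out_data),))

    def abs(self):
        sign = np.sign(self.data)
        return Tensor._make(np.abs(self.data), (self,), lambda g: (g * sign,))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(
            out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),)
        )

    def leaky_relu(self, negative_slope: float = 0.2):
        mask = np.where(self.data > 0, 1.0, negative_slope)
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def relu(self):
        return self.leaky_relu(0.0)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed through only inside the bounds."""
        inside = ((self.data >= lo) & (self.data <= hi)).astype(self.data.dtype)
        return Tensor._make(
            np.clip(self.data, lo, hi), (self,), lambda g: (g * inside,)
        )

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(orig),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, idx, g)
            return (gx,)

        return Tensor._make(out_data, (self,), backward)

    # -- backward pass --------------------------------------------------------

    def backward(self, grad=None):
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)

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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if not p.requires_grad or pg is None:
                    continue
                key = id(p)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg
        # leaves reached directly (self may be a leaf)
        if self._backward is None and self.grad is None:
            self.grad = np.asarray(grad, dtype=self.data.dtype)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- multi-input ops ----------------------------------------------------------


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


def pad2d(x: Tensor, pad, mode: str = "zero") -> Tensor:
    """Pad the trailing two axes of an NCHW tensor.

    ``pad`` is ``(top, bottom, left, right)``.
    """
    x = as_tensor(x)
    pt, pb, pl, pr = pad
    spec = [(0, 0)] * (x.ndim - 2) + [(pt, pb), (pl, pr)]
    if mode == "zero":
        out_data = np.pad(x.data, spec, mode="constant")
    elif mode == "reflect":
        out_data = np.pad(x.data, spec, mode="reflect")
    else:
        raise ValueError(f"unknown pad mode {mode!r}")

    H, W = x.shape[-2], x.shape[-1]

    if mode == "zero":

        def backward(g):
            sl = (Ellipsis, slice(pt, pt + H), slice(pl, pl + W))
            return (np.ascontiguousarray(g[sl]),)

    else:
        # reflection: fold padded rows/cols back onto their source positions
        row_idx = np.pad(np.arange(H), (pt, pb), mode="reflect")
        col_idx = np.pad(np.arange(W), (pl, pr), mode="reflect")

        def backward(g):
            tmp = np.zeros(g.shape[:-2] + (H, g.shape[-1]), dtype=g.dtype)
            np.add.at(tmp.swapaxes(0, -2), row_idx, g.swapaxes(0, -2))
            gx = np.zeros(g.shape[:-2] + (H, W), dtype=g.dtype)
            np.add.at(gx.swapaxes(0, -1), col_idx, tmp.swapaxes(0, -1))
            return (gx,)

    return Tensor._make(out_data, (x,), backward)


def _im2col_view(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N,C,H,W) -> strided view (N,C,k,k,Ho,Wo); no copy."""
    N, C, H, W = xp.shape
    Ho = (H - k) // stride + 1
    Wo = (W - k) // stride + 1
    sN, sC, sH, sW = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp,
        shape=(N, C, k, k, Ho, Wo),
        strides=(sN, sC, sH, sW, sH * stride, sW * stride),
        writeable=False,
    )


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, pad_mode: str = "zero") -> Tensor:
    """2D cross-correlation on NCHW input with OIkk weight."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    x = as_tensor(x)
    weight = as_tensor(weight)
    if padding:
        x = pad2d(x, (padding, padding, padding, padding), mode=pad_mode)

    k = weight.shape[-1]
    xp = np.ascontiguousarray(x.data)
    cols = _im2col_view(xp, k, stride)
    # (O,C,k,k) . (N,C,k,k,Ho,Wo) -> (O,N,Ho,Wo)
    out_data = np.tensordot(weight.data, cols, axes=([1, 2, 3], [1, 2, 3]))
    out_data = np.ascontiguousarray(out_data.transpose(1, 0, 2, 3))
    N, C, H, W = xp.shape
    _, O, Ho, Wo = out_data.shape

    def backward(g):
        gw = np.tensordot(g, cols, axes=([0, 2, 3], [0, 4, 5]))
        gx = np.zeros_like(xp)
        # scatter each kernel tap back onto the (strided) input positions
        for i in range(k):
            for j in range(k):
                # (N,Ho,Wo,C) from (N,O,Ho,Wo) . (O,C)
                contrib = np.tensordot(g, weight.data[:, :, i, j], axes=([1], [0]))
                gx[:, :, i:i + Ho * stride:stride, j:j + Wo * stride:stride] += (
                    contrib.transpose(0, 3, 1, 2)
                )
        return (gx, gw)

    out = Tensor._make(out_data, (x, weight), backward)
    if bias is not None:
        out = out + as_tensor(bias).reshape(1, -1, 1, 1)
    return out
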
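"""Minimal reverse-mode automatic differentiation over numpy arrays.

The recurrent and convolutional models in this package are small enough
that a dedicated tensor engine in pure numpy (float64 throughout, fully
deterministic, single-threaded) is both sufficient and the easiest way to
guarantee bit-identical training runs across processes.

Only the primitives the models need are implemented: elementwise
arithmetic with broadcasting, matmul, the sigmoid/tanh/leaky-ReLU
nonlinearities, exp/log/sqrt, reductions, concatenation, slicing, and a
1-D convolution with "same" padding.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "sigmoid",
    "tanh",
    "matmul",
    "conv1d",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    for _ in range(extra):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    # -- infrastructure ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self, grad=None):
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accumulate(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))
        a, b = self.data, other.data

        def backward(g):
            if self.requires_grad:
                if a.ndim == 1 and b.ndim == 2:
                    self._accumulate(g @ b.T)
                elif a.ndim == 2 and b.ndim == 1:
                    self._accumulate(np.outer(g, b))
                elif a.ndim == 1 and b.ndim == 1:
                    self._accumulate(g * b)
                else:
                    self._accumulate(_unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape))
            if other.requires_grad:
                if a.ndim == 1 and b.ndim == 2:
                    other._accumulate(np.outer(a, g))
                elif a.ndim == 2 and b.ndim == 1:
                    other._accumulate(a.T @ g)
                elif a.ndim == 1 and b.ndim == 1:
                    other._accumulate(g * a)
                else:
                    other._accumulate(_unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape))

        out._backward = backward
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = backward
        return out

    # -- nonlinearities ---------------------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out.data)

        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = backward
        return out

    def sqrt(self):
        return self**0.5

    def tanh(self):
        out = Tensor(np.tanh(self.data), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out.data**2))

        out._backward = backward
        return out

    def sigmoid(self):
        # numerically stable logistic
        val = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500))),
            np.exp(np.clip(self.data, -500, 500))
            / (1.0 + np.exp(np.clip(self.data, -500, 500))),
        )
        out = Tensor(val, _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out.data * (1.0 - out.data))

        out._backward = backward
        return out

    def leaky_relu(self, slope: float):
        out = Tensor(np.where(self.data >= 0, self.data, slope * self.data), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * np.where(self.data >= 0, 1.0, slope))

        out._backward = backward
        return out

    def clip_min(self, floor: float):
        """max(x, floor); gradient passes only where x > floor."""
        out = Tensor(np.maximum(self.data, floor), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > floor))

        out._backward = backward
        return out

    # -- reductions and reshaping ----------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))
        shape = self.data.shape

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        orig = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        out._backward = backward
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor(self.data.transpose(axes), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                if axes is None:
                    self._accumulate(g.transpose())
                else:
                    self._accumulate(g.transpose(np.argsort(axes)))

        out._backward = backward
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))
        shape = self.data.shape

        def backward(g):
            if self.requires_grad:
                full = np.zeros(shape, dtype=np.float64)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = backward
        return out


# -- dispatching helpers (work on Tensors and plain ndarrays alike) --------


def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def sigmoid(x):
    if isinstance(x, Tensor):
        return x.sigmoid()
    x = np.asarray(x, dtype=np.float64)
    return np.where(
        x >= 0,
        1.0 / (1.0 + np.exp(-np.clip(x, -500, 500))),
        np.exp(np.clip(x, -500, 500)) / (1.0 + np.exp(np.clip(x, -500, 500))),
    )


def tanh(x):
    return x.tanh() if isinstance(x, Tensor) else np.tanh(x)


def matmul(a, b):
    if _is_tensor(a, b):
        return Tensor._lift(a) @ Tensor._lift(b)
    return a @ b


def concat(parts, axis=-1):
    """Concatenate a list of Tensors (or ndarrays) along ``axis``."""
    if not _is_tensor(*parts):
        return np.concatenate(parts, axis=axis)
    parts = [Tensor._lift(p) for p in parts]
    out = Tensor(np.concatenate([p.data for p in parts], axis=axis), _parents=tuple(parts))
    sizes = [p.data.shape[axis] for p in parts]

    def backward(g):
        splits = np.cumsum(sizes)[:-1]
        for p, gp in zip(parts, np.split(g, splits, axis=axis)):
            if p.requires_grad:
                p._accumulate(gp)

    out._backward = backward
    return out


def _same_pad(length: int, kernel: int, stride: int) -> tuple[int, int, int]:
    out_len = -(-length // stride)  # ceil
    total = max((out_len - 1) * stride + kernel - length, 0)
    return out_len, total // 2, total - total // 2


def conv1d(x, weight, bias, stride: int = 1):
    """1-D convolution with "same" padding.

    x: [N, C_in, L]; weight: [C_out, C_in, K]; bias: [C_out].
    Output: [N, C_out, ceil(L / stride)].
    """
    xt, wt, bt = Tensor._lift(x), Tensor._lift(weight), Tensor._lift(bias)
    xd, wd, bd = xt.data, wt.data, bt.data
    n, c_in, length = xd.shape
    c_out, c_in_w, kernel = wd.shape
    if c_in != c_in_w:
        raise ValueError(f"channel mismatch: input has {c_in}, kernel expects {c_in_w}")
    if length < kernel:
        raise ValueError(f"input length {length} shorter than kernel {kernel}")
    out_len, pad_l, pad_r = _same_pad(length, kernel, stride)
    xp = np.pad(xd, ((0, 0), (0, 0), (pad_l, pad_r)))
    idx = stride * np.arange(out_len)[:, None] + np.arange(kernel)[None, :]  # [out_len, K]
    patches = xp[:, :, idx]  # [N, C_in, out_len, K]
    patches = patches.transpose(0, 2, 1, 3).reshape(n, out_len, c_in * kernel)
    w_flat = wd.reshape(c_out, c_in * kernel)
    val = patches @ w_flat.T + bd  # [N, out_len, C_out]
    val = val.transpose(0, 2, 1)

    if not _is_tensor(x, weight, bias):
        return val

    out = Tensor(val, _parents=(xt, wt, bt))

    def backward(g):
        g_flat = g.transpose(0, 2, 1)  # [N, out_len, C_out]
        if bt.requires_grad:
            bt._accumulate(g_flat.sum(axis=(0, 1)))
        if wt.requires_grad:
            dw = np.einsum("nlo,nlk->ok", g_flat, patches)
            wt._accumulate(dw.reshape(c_out, c_in, kernel))
        if xt.requires_grad:
            dpatch = g_flat @ w_flat  # [N, out_len, C_in*K]
            dpatch = dpatch.reshape(n, out_len, c_in, kernel).transpose(0, 2, 1, 3)
            dxp = np.zeros_like(xp)
            np.add.at(dxp, (slice(None), slice(None), idx), dpatch)
            xt._accumulate(dxp[:, :, pad_l : pad_l + length])

    out._backward = backward
    return out
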
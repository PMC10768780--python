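"""A small reverse-mode automatic differentiation engine on numpy arrays.

The hybrid network is expressed in terms of these ``Tensor`` operations; the
same forward code therefore serves inference (numpy in, numpy out) and
gradient-based training.  Only the operations the network needs are provided:
broadcast arithmetic, matmul (with matching batch dimensions), the sigmoid /
tanh / ReLU nonlinearities, 1-D cross-correlation and max pooling, softmax,
concatenation, reshaping and reductions.

Gradients accumulate in ``Tensor.grad`` after ``backward()`` on a scalar.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over axes that were broadcast in the forward pass."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], tuple[np.ndarray, ...]] | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
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
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg
            if node is self or node._parents == ():
                node.grad = g if node.grad is None else node.grad + g
        # leaves reached through grads dict but never popped (shouldn't happen
        # with a correct topo order) would be silently dropped; assert empty.
        assert not grads, "gradient graph traversal left unconsumed gradients"

    # -- operator sugar ------------------------------------------------------

    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), _as_tensor(-1.0)))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, _as_tensor(-1.0)))

    def __neg__(self):
        return mul(self, _as_tensor(-1.0))

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# primitive ops


def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data
    return Tensor._make(
        data, (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data
    return Tensor._make(
        data, (a, b),
        lambda g: (
            _unbroadcast(g * b.data, a.shape),
            _unbroadcast(g * a.data, b.shape),
        ),
    )


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product; batch dimensions (if any) must match exactly."""
    data = a.data @ b.data

    def backward(g: np.ndarray):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

    return Tensor._make(data, (a, b), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60.0, 60.0)))
    return Tensor._make(s, (x,), lambda g: (g * s * (1.0 - s),))


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    return Tensor._make(t, (x,), lambda g: (g * (1.0 - t * t),))


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor._make(x.data * mask, (x,), lambda g: (g * mask,))


def log(x: Tensor) -> Tensor:
    return Tensor._make(np.log(x.data), (x,), lambda g: (g / x.data,))


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    data = np.clip(x.data, lo, hi)
    mask = (x.data > lo) & (x.data < hi)
    return Tensor._make(data, (x,), lambda g: (g * mask,))


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    old = x.shape
    return Tensor._make(
        x.data.reshape(shape), (x,), lambda g: (g.reshape(old),)
    )


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: np.ndarray):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(data, tuple(tensors), backward)


def mean(x: Tensor) -> Tensor:
    n = x.data.size
    return Tensor._make(
        np.array(x.data.mean()), (x,),
        lambda g: (np.full(x.shape, float(g) / n),),
    )


def sum_axis(x: Tensor, axis: int) -> Tensor:
    data = x.data.sum(axis=axis)

    def backward(g: np.ndarray):
        return (np.expand_dims(g, axis).repeat(x.shape[axis], axis=axis),)

    return Tensor._make(data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g: np.ndarray):
        dot = (g * s).sum(axis=axis, keepdims=True)
        return (s * (g - dot),)

    return Tensor._make(s, (x,), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when rng is None (inference) or rate == 0."""
    if rng is None or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep) / keep
    return Tensor._make(x.data * mask, (x,), lambda g: (g * mask,))


# ---------------------------------------------------------------------------
# 1-D convolution / pooling


def _conv_windows(x: np.ndarray, kernel: int, stride: int, pad: int,
                  dilation: int) -> np.ndarray:
    """View (B, C, L_pad) as (B, C, L_out, kernel) windows."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    B, C, L = x.shape
    span = dilation * (kernel - 1) + 1
    L_out = (L - span) // stride + 1
    if L_out < 1:
        raise ValueError("convolution output length < 1")
    sB, sC, sL = x.strides
    return np.lib.stride_tricks.as_strided(
        x, shape=(B, C, L_out, kernel),
        strides=(sB, sC, sL * stride, sL * dilation),
    ), x.shape[2]


def conv1d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1,
           pad: int = 0, dilation: int = 1) -> Tensor:
    """1-D cross-correlation: x (B, C_in, L) * weight (C_out, C_in, k) + bias."""
    windows, L_pad = _conv_windows(x.data, weight.shape[2], stride, pad, dilation)
    out = np.einsum("bclk,ock->bol", windows, weight.data, optimize=True)
    out = out + bias.data[None, :, None]
    B, C_in, L = x.shape
    C_out, _, kernel = weight.shape
    L_out = out.shape[2]

    def backward(g: np.ndarray):
        gw = np.einsum("bol,bclk->ock", g, windows, optimize=True)
        gb = g.sum(axis=(0, 2))
        gx_pad = np.zeros((B, C_in, L_pad))
        for kk in range(kernel):
            contrib = np.einsum("bol,oc->bcl", g, weight.data[:, :, kk], optimize=True)
            start = kk * dilation
            gx_pad[:, :, start: start + stride * L_out: stride] += contrib
        gx = gx_pad[:, :, pad: L_pad - pad] if pad else gx_pad
        return gx, gw, gb

    return Tensor._make(out, (x, weight, bias), backward)


def maxpool1d(x: Tensor, kernel: int, stride: int) -> Tensor:
    """Per-channel window maxima; channel count unchanged."""
    B, C, L = x.shape
    if L < kernel:
        raise ValueError(f"pooling kernel {kernel} exceeds length {L}")
    windows, _ = _conv_windows(x.data, kernel, stride, 0, 1)
    arg = windows.argmax(axis=3)
    out = np.take_along_axis(windows, arg[..., None], axis=3)[..., 0]
    L_out = out.shape[2]
    src = (np.arange(L_out) * stride)[None, None, :] + arg  # index into L

    def backward(g: np.ndarray):
        gx = np.zeros((B, C, L))
        b_idx = np.arange(B)[:, None, None]
        c_idx = np.arange(C)[None, :, None]
        np.add.at(gx, (b_idx, c_idx, src), g)
        return (gx,)

    return Tensor._make(out, (x,), backward)
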
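"""Tape-based reverse-mode autodiff over numpy arrays.

Tensors form a DAG; ``Tensor.backward()`` walks it in reverse topological
order.  Gradients are only computed along paths that reach a tensor with
``requires_grad=True``, so frozen subnetworks (e.g. a frozen encoder) cost
nothing in the backward pass.

Array layout is channels-first with a batch axis: ``(N, C, D, H, W)``.
"""

from __future__ import annotations

from typing import Callable, List, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "conv3d",
    "relu",
    "instance_norm",
    "avg_pool2",
    "upsample2",
    "concat",
    "softmax_channel",
    "soft_dice_loss",
    "mse_loss",
]


class Tensor:
    """A numpy array plus the bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: Tuple["Tensor", ...] = (),
        backward_fn: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None,
        name: str = "",
    ) -> None:
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward_fn
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar")
            grad = np.ones_like(self.data)
        # reverse topological order over the subgraph that requires grad
        order: List[Tensor] = []
        seen = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(order):
            if t._backward is None or t.grad is None:
                continue
            for parent, g in zip(t._parents, t._backward(t.grad)):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(parent.data.dtype, copy=False)
                else:
                    parent.grad = parent.grad + g.astype(parent.data.dtype, copy=False)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _windows(x: np.ndarray, k: int) -> np.ndarray:
    """Sliding k^3 windows over the spatial axes of (N, C, D, H, W)."""
    return sliding_window_view(x, (k, k, k), axis=(2, 3, 4))


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Stride-1 'same' 3D convolution (zero padding); kernel must be odd."""
    k = w.data.shape[2]
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x.data
    win = _windows(xp, k)
    out = np.einsum("ncdhwijk,ocijk->nodhw", win, w.data, optimize=True)
    out += b.data[None, :, None, None, None]

    def backward(g: np.ndarray):
        gw = np.einsum("ncdhwijk,nodhw->ocijk", win, g, optimize=True)
        gb = g.sum(axis=(0, 2, 3, 4))
        gx = None
        if x.requires_grad:
            gp = np.pad(g, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else g
            gwin = _windows(gp, k)
            wf = w.data[:, :, ::-1, ::-1, ::-1]
            gx = np.einsum("nodhwijk,ocijk->ncdhw", gwin, wf, optimize=True)
        return gx, gw, gb

    return Tensor(out, parents=(x, w, b), backward_fn=backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, parents=(x,),
                  backward_fn=lambda g: (g * mask,))


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over the spatial axes."""
    axes = (2, 3, 4)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gma = gamma.data[None, :, None, None, None]
    out = gma * xhat + beta.data[None, :, None, None, None]

    def backward(g: np.ndarray):
        ggamma = (g * xhat).sum(axis=(0, 2, 3, 4))
        gbeta = g.sum(axis=(0, 2, 3, 4))
        gx = None
        if x.requires_grad:
            gh = g * gma
            m1 = gh.mean(axis=axes, keepdims=True)
            m2 = (gh * xhat).mean(axis=axes, keepdims=True)
            gx = inv * (gh - m1 - xhat * m2)
        return gx, ggamma, gbeta

    return Tensor(out, parents=(x, gamma, beta), backward_fn=backward)


def avg_pool2(x: Tensor) -> Tensor:
    """2x2x2 average pooling; spatial dims must be even."""
    n, c, d, h, w = x.data.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"spatial size {(d, h, w)} not divisible by 2")
    r = x.data.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
    out = r.mean(axis=(3, 5, 7))

    def backward(g: np.ndarray):
        gx = np.repeat(np.repeat(np.repeat(g, 2, axis=2), 2, axis=3), 2, axis=4) / 8.0
        return (gx,)

    return Tensor(out, parents=(x,), backward_fn=backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of the spatial axes."""
    out = np.repeat(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), 2, axis=4)

    def backward(g: np.ndarray):
        n, c, d, h, w = g.shape
        gx = g.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(3, 5, 7))
        return (gx,)

    return Tensor(out, parents=(x,), backward_fn=backward)


def concat(xs: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = np.concatenate([t.data for t in xs], axis=axis)
    sizes = [t.data.shape[axis] for t in xs]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: np.ndarray):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, parents=tuple(xs), backward_fn=backward)


def softmax_channel(x: Tensor) -> Tensor:
    """Softmax along the channel axis (axis 1)."""
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)

    def backward(g: np.ndarray):
        dot = (g * p).sum(axis=1, keepdims=True)
        return (p * (g - dot),)

    return Tensor(p, parents=(x,), backward_fn=backward)


def soft_dice_loss(p: Tensor, target: np.ndarray, eps: float = 1e-5,
                   channel: int = 1) -> Tensor:
    """Soft Dice loss on one probability channel against a binary target.

    ``loss = 1 - (2 * sum(p*t) + eps) / (sum(p) + sum(t) + eps)`` computed
    jointly over the batch; continuous probabilities, no thresholding.
    """
    t = np.asarray(target, dtype=p.data.dtype)
    pc = p.data[:, channel]
    if pc.shape != t.shape:
        raise ValueError(f"probability grid {pc.shape} != target grid {t.shape}")
    inter = float((pc * t).sum())
    denom = float(pc.sum() + t.sum()) + eps
    num = 2.0 * inter + eps
    loss = 1.0 - num / denom

    def backward(g: np.ndarray):
        gp = np.zeros_like(p.data)
        # d/dpc [1 - num/denom] = -(2 t * denom - num) / denom^2
        gp[:, channel] = -(2.0 * t * denom - num) / denom**2
        return (gp * g,)

    return Tensor(np.asarray(loss, dtype=p.data.dtype), parents=(p,),
                  backward_fn=backward)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    t = np.asarray(target, dtype=pred.data.dtype)
    diff = pred.data - t
    loss = float((diff**2).mean())

    def backward(g: np.ndarray):
        return (g * 2.0 * diff / diff.size,)

    return Tensor(np.asarray(loss, dtype=pred.data.dtype), parents=(pred,),
                  backward_fn=backward)
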
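"""Layer modules with named parameters (for checkpointing and transfer)."""

from __future__ import annotations

from typing import Dict, Iterator, Tuple

import numpy as np

from .autograd import Tensor, conv3d, instance_norm, relu

__all__ = ["Module", "Conv3d", "InstanceNorm3d", "DoubleConv"]

DTYPE = np.float32


class Module:
    """Base class: submodules and parameters discovered via attributes."""

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Tensor]]:
        for attr, value in vars(self).items():
            name = f"{prefix}{attr}"
            if isinstance(value, Tensor):
                yield name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")
                    elif isinstance(item, Tensor):
                        yield f"{name}.{i}", item

    def parameters(self):
        return [t for _, t in self.named_parameters()]

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: Dict[str, np.ndarray], strict: bool = True) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if strict and (missing or extra):
            raise KeyError(f"state mismatch: missing={sorted(missing)}, "
                           f"unexpected={sorted(extra)}")
        for k, t in own.items():
            if k in state:
                if t.data.shape != state[k].shape:
                    raise ValueError(f"shape mismatch for {k}: "
                                     f"{t.data.shape} vs {state[k].shape}")
                t.data = state[k].astype(t.data.dtype).copy()

    def set_requires_grad(self, flag: bool) -> None:
        for _, t in self.named_parameters():
            t.requires_grad = flag

    def zero_grad(self) -> None:
        for _, t in self.named_parameters():
            t.grad = None


class Conv3d(Module):
    """Stride-1 'same' 3D convolution, He-initialized."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator) -> None:
        fan_in = cin * k**3
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, std, size=(cout, cin, k, k, k)).astype(DTYPE),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias)


class InstanceNorm3d(Module):
    def __init__(self, channels: int) -> None:
        self.gamma = Tensor(np.ones(channels, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return instance_norm(x, self.gamma, self.beta)


class DoubleConv(Module):
    """(conv3 -> instance norm -> ReLU) x 2, the U-Net building block."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        self.conv1 = Conv3d(cin, cout, 3, rng)
        self.norm1 = InstanceNorm3d(cout)
        self.conv2 = Conv3d(cout, cout, 3, rng)
        self.norm2 = InstanceNorm3d(cout)

    def __call__(self, x: Tensor) -> Tensor:
        x = relu(self.norm1(self.conv1(x)))
        return relu(self.norm2(self.conv2(x)))
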
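"""Network architectures for lesion segmentation and new-lesion detection.

Two architectures share the same building blocks.  The single time-point
model is a 3D U-Net: encoder and decoder linked by skip connections, with a
two-class softmax head.  The longitudinal model is a siamese-encoder
network: one encoder with shared weights is applied to both time-points,
the per-level feature maps are aggregated (channel concatenation followed by
a convolution back to the original channel count), and a single decoder
produces the new-lesion probability map.  Auxiliary single-channel
(inpainting) and two-channel (lesion generator) regression U-Nets reuse the
same blocks without a softmax head.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List

import numpy as np

from ._nn import (
    Conv3d,
    DoubleConv,
    Module,
    Tensor,
    avg_pool2,
    concat,
    relu,
    softmax_channel,
    upsample2,
)

__all__ = [
    "NetworkSpec",
    "FeatureMapSet",
    "SegmentationUNet",
    "NewLesionNetwork",
    "build_segmentation_unet",
    "build_new_lesion_network",
    "build_inpainting_unet",
    "build_generator_unet",
    "transfer_encoder",
    "save_checkpoint",
    "load_checkpoint",
    "Checkpoint",
]


@dataclasses.dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters.

    The default (4 levels, base 32, growth 2) targets full-size 64-voxel
    patches; tests and desk-scale runs use 2 levels and base 8.
    """

    in_channels: int = 1
    out_channels: int = 2
    levels: int = 4
    base_channels: int = 32
    growth: int = 2

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")

    def channels(self, level: int) -> int:
        return self.base_channels * self.growth**level


@dataclasses.dataclass
class FeatureMapSet:
    """Per-level encoder features: maps[l] has spatial size input / 2^l,
    plus the bottleneck at input / 2^levels."""

    maps: List[Tensor]
    bottleneck: Tensor

    @property
    def levels(self) -> int:
        return len(self.maps)


def _check_divisible(shape, levels: int) -> None:
    f = 2**levels
    if any(s % f for s in shape):
        raise ValueError(f"patch size {tuple(shape)} not divisible by 2^levels = {f}")
    if any(s // f < 2 for s in shape):
        # the bottleneck needs at least 2 voxels per axis to be meaningful
        raise ValueError(f"patch size {tuple(shape)} too small for {levels} "
                         f"encoder levels (bottleneck would collapse)")


class Encoder(Module):
    def __init__(self, spec: NetworkSpec, rng: np.random.Generator) -> None:
        self.spec_levels = spec.levels
        blocks = []
        cin = spec.in_channels
        for level in range(spec.levels):
            blocks.append(DoubleConv(cin, spec.channels(level), rng))
            cin = spec.channels(level)
        self.blocks = blocks
        self.bottleneck = DoubleConv(cin, spec.channels(spec.levels), rng)

    def __call__(self, x: Tensor) -> FeatureMapSet:
        _check_divisible(x.data.shape[2:], self.spec_levels)
        maps = []
        for block in self.blocks:
            x = block(x)
            maps.append(x)
            x = avg_pool2(x)
        return FeatureMapSet(maps, self.bottleneck(x))


class Decoder(Module):
    def __init__(self, spec: NetworkSpec, rng: np.random.Generator) -> None:
        blocks = []
        for level in reversed(range(spec.levels)):
            cin = spec.channels(level + 1) + spec.channels(level)  # up + skip
            blocks.append(DoubleConv(cin, spec.channels(level), rng))
        self.blocks = blocks
        self.head = Conv3d(spec.channels(0), spec.out_channels, 1, rng)

    def __call__(self, fms: FeatureMapSet) -> Tensor:
        x = fms.bottleneck
        for block, skip in zip(self.blocks, reversed(fms.maps)):
            x = block(concat([upsample2(x), skip]))
        return self.head(x)


class AggregationBlock(Module):
    """Concatenate two same-level feature maps (2c channels) and convolve
    back to c channels; 1x1x1 convolution with ReLU."""

    def __init__(self, channels: int, rng: np.random.Generator) -> None:
        self.conv = Conv3d(2 * channels, channels, 1, rng)

    def __call__(self, a: Tensor, b: Tensor) -> Tensor:
        return relu(self.conv(concat([a, b])))


class Aggregator(Module):
    def __init__(self, spec: NetworkSpec, rng: np.random.Generator) -> None:
        self.level_blocks = [AggregationBlock(spec.channels(l), rng)
                             for l in range(spec.levels)]
        self.bottleneck_block = AggregationBlock(spec.channels(spec.levels), rng)

    def __call__(self, fm1: FeatureMapSet, fm2: FeatureMapSet) -> FeatureMapSet:
        if fm1.levels != fm2.levels:
            raise ValueError("feature map sets have different level counts")
        maps = [blk(a, b) for blk, a, b in zip(self.level_blocks, fm1.maps, fm2.maps)]
        return FeatureMapSet(maps, self.bottleneck_block(fm1.bottleneck, fm2.bottleneck))


class SegmentationUNet(Module):
    """Single time-point lesion segmentation: 1 channel in, 2-class softmax out."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator,
                 softmax: bool = True) -> None:
        self.spec = spec
        self.encoder = Encoder(spec, rng)
        self.decoder = Decoder(spec, rng)
        self.softmax = softmax

    def encode(self, patch: Tensor) -> FeatureMapSet:
        return self.encoder(patch)

    def __call__(self, patch: Tensor) -> Tensor:
        logits = self.decoder(self.encoder(patch))
        return softmax_channel(logits) if self.softmax else logits


class NewLesionNetwork(Module):
    """Siamese encoder (shared weights) + per-level aggregation + one decoder.

    The encoder module is applied to both time-points, so weight sharing is
    structural: there is a single set of encoder parameters.  Concatenation
    order is fixed (tp1, tp2); no symmetry is enforced.
    """

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator) -> None:
        self.spec = spec
        self.encoder = Encoder(spec, rng)
        self.aggregator = Aggregator(spec, rng)
        self.decoder = Decoder(spec, rng)

    def encode(self, patch: Tensor) -> FeatureMapSet:
        return self.encoder(patch)

    def __call__(self, tp1: Tensor, tp2: Tensor) -> Tensor:
        fused = self.aggregator(self.encoder(tp1), self.encoder(tp2))
        return softmax_channel(self.decoder(fused))


def build_segmentation_unet(spec: NetworkSpec, seed: int = 0) -> SegmentationUNet:
    return SegmentationUNet(spec, np.random.default_rng(seed))


def build_new_lesion_network(spec: NetworkSpec, seed: int = 0) -> NewLesionNetwork:
    return NewLesionNetwork(spec, np.random.default_rng(seed))


def build_inpainting_unet(levels: int = 2, base_channels: int = 8,
                          seed: int = 0) -> SegmentationUNet:
    """1-channel-to-1-channel regression U-Net (no softmax)."""
    spec = NetworkSpec(in_channels=1, out_channels=1, levels=levels,
                       base_channels=base_channels)
    return SegmentationUNet(spec, np.random.default_rng(seed), softmax=False)


def build_generator_unet(levels: int = 2, base_channels: int = 8,
                         seed: int = 0) -> SegmentationUNet:
    """2-channel (noise-filled image, lesion mask) to 1-channel regression U-Net."""
    spec = NetworkSpec(in_channels=2, out_channels=1, levels=levels,
                       base_channels=base_channels)
    return SegmentationUNet(spec, np.random.default_rng(seed), softmax=False)


def transfer_encoder(source: Module, target: Module) -> None:
    """Copy encoder parameters from ``source`` to ``target`` by layer name.

    Both networks must expose an ``encoder`` submodule with identical
    parameter names and shapes; any unmatched layer raises.
    """
    src = {n: t for n, t in source.named_parameters() if n.startswith("encoder.")}
    dst = {n: t for n, t in target.named_parameters() if n.startswith("encoder.")}
    if set(src) != set(dst):
        missing = sorted(set(src) ^ set(dst))
        raise KeyError(f"encoder layer mismatch between networks: {missing}")
    for name, t in dst.items():
        if t.data.shape != src[name].data.shape:
            raise ValueError(f"encoder shape mismatch at {name}")
        t.data = src[name].data.copy()


@dataclasses.dataclass
class Checkpoint:
    """Serialized weights plus architecture and stage lineage."""

    state: Dict[str, np.ndarray]
    spec: NetworkSpec
    stage: int
    lineage: List[str]
    kind: str = "segmentation"  # or "new_lesion", "inpainting", "generator"
    meta: dict = dataclasses.field(default_factory=dict)


def save_checkpoint(ckpt: Checkpoint, path: str | Path) -> None:
    meta = {
        "spec": dataclasses.asdict(ckpt.spec),
        "stage": ckpt.stage,
        "lineage": ckpt.lineage,
        "kind": ckpt.kind,
        "meta": ckpt.meta,
    }
    np.savez(str(path), __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **ckpt.state)


def load_checkpoint(path: str | Path) -> Checkpoint:
    with np.load(str(path)) as z:
        meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    return Checkpoint(state=state, spec=NetworkSpec(**meta["spec"]),
                      stage=meta["stage"], lineage=meta["lineage"],
                      kind=meta["kind"], meta=meta["meta"])


def network_from_checkpoint(ckpt: Checkpoint) -> Module:
    """Rebuild the architecture recorded in a checkpoint and load its weights."""
    if ckpt.kind == "new_lesion":
        net: Module = build_new_lesion_network(ckpt.spec)
    elif ckpt.kind == "segmentation":
        net = build_segmentation_unet(ckpt.spec)
    elif ckpt.kind in ("inpainting", "generator"):
        net = SegmentationUNet(ckpt.spec, np.random.default_rng(0), softmax=False)
    else:
        raise ValueError(f"unknown checkpoint kind {ckpt.kind!r}")
    net.load_state_dict(ckpt.state)
    return net
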
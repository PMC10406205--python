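"""Three-stage training pipeline and ensemble inference.

Stage 1 trains a single time-point segmentation U-Net (encoder + decoder)
on (FLAIR, lesion mask) pairs.  Stage 2 builds the siamese new-lesion
network around the Stage-1 encoder — which stays frozen from here on — and
pretrains the aggregation blocks and decoder on synthetic longitudinal
pairs.  Stage 3 fine-tunes the same trainable parts on real longitudinal
pairs.  All stages use the soft Dice loss and Adam (learning rate 1e-4,
beta1 0.9).

Inference averages the class probabilities of an ensemble of networks
(trained on different training/validation splits) over sliding-window
patches and picks the class with the highest averaged probability.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable, List, Sequence, Tuple

import numpy as np

from ._nn import Adam, Tensor, soft_dice_loss
from .augment import AugmentationConfig, random_augment
from .io_volumes import LesionMask, PatchSpec, Volume
from .networks import (
    Checkpoint,
    NetworkSpec,
    NewLesionNetwork,
    SegmentationUNet,
    build_new_lesion_network,
    build_segmentation_unet,
    network_from_checkpoint,
    transfer_encoder,
)
from .synthesis import LongitudinalSample

__all__ = [
    "TrainConfig",
    "dice_loss",
    "sample_training_patch",
    "train_stage",
    "train_ensemble",
    "ensemble_predict",
    "predict_pair",
]

logger = logging.getLogger(__name__)

DICE_EPS = 1e-5

Pair = Tuple[Volume, Volume, LesionMask]


@dataclasses.dataclass
class TrainConfig:
    """Optimization settings; defaults follow the published configuration
    (64-voxel patches, lr 1e-4, Adam beta1 0.9, five-network ensemble)."""

    patch_size: Tuple[int, int, int] = (64, 64, 64)
    learning_rate: float = 1e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    ensemble_size: int = 5
    steps: int = 1000
    batch_size: int = 4
    stage: int = 1
    freeze_encoder: bool | None = None  # derived from stage when None
    val_fraction: float = 0.2
    positive_fraction: float = 0.5
    support_threshold: float = 0.1
    augment: AugmentationConfig | None = None
    mix_synthetic: bool = False  # stage 3: also draw synthetic pairs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage not in (1, 2, 3):
            raise ValueError("stage must be 1, 2 or 3")
        if self.freeze_encoder is None:
            self.freeze_encoder = self.stage != 1
        if not self.freeze_encoder and self.stage != 1:
            raise ValueError("the encoder may only train in stage 1")
        if not (0 <= self.positive_fraction <= 1):
            raise ValueError("positive_fraction must lie in [0, 1]")


def dice_loss(probabilities: np.ndarray, target_mask: np.ndarray,
              eps: float = DICE_EPS) -> float:
    """Soft Dice loss 1 - (2*sum(p*t)+eps)/(sum(p)+sum(t)+eps) in [0, 1]."""
    p = np.asarray(probabilities, dtype=np.float64)
    t = np.asarray(target_mask, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"probability grid {p.shape} != target grid {t.shape}")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return float(1.0 - (2.0 * (p * t).sum() + eps) / (p.sum() + t.sum() + eps))


def _clamped_start(center, size, shape):
    return tuple(
        int(np.clip(c - s // 2, 0, n - s)) for c, s, n in zip(center, size, shape)
    )


def sample_training_patch(
    volumes: Sequence[Volume],
    mask: LesionMask,
    rng: np.random.Generator,
    positive_fraction: float = 0.5,
    patch_size: Tuple[int, int, int] = (64, 64, 64),
    support: np.ndarray | None = None,
    support_threshold: float = 0.1,
) -> Tuple[List[np.ndarray], np.ndarray, PatchSpec]:
    """Draw one training patch, oversampling the positive class.

    With probability ``positive_fraction`` the patch center is a positive
    voxel of ``mask``; otherwise it is uniform over the brain support.  The
    patch window is clamped inside the grid, so a positive-centered patch
    always contains at least one positive voxel.
    """
    shape = volumes[0].shape
    if any(p > s for p, s in zip(patch_size, shape)):
        raise ValueError(f"patch {patch_size} larger than volume {shape}")
    if support is None:
        support = volumes[0].data > support_threshold
    pos = np.argwhere(mask.data > 0)
    want_positive = rng.random() < positive_fraction
    if want_positive and len(pos) == 0:
        logger.warning("positive patch requested but the mask is empty; "
                       "falling back to a uniform draw")
        want_positive = False
    if want_positive:
        center = tuple(int(c) for c in pos[rng.integers(len(pos))])
    else:
        cand = np.argwhere(support)
        if len(cand) == 0:
            cand = np.argwhere(np.ones(shape, dtype=bool))
        center = tuple(int(c) for c in cand[rng.integers(len(cand))])
    start = _clamped_start(center, patch_size, shape)
    sl = tuple(slice(a, a + s) for a, s in zip(start, patch_size))
    patches = [np.ascontiguousarray(v.data[sl], dtype=np.float64) for v in volumes]
    target = np.ascontiguousarray(mask.data[sl], dtype=np.float64)
    spec = PatchSpec(tuple(a + s // 2 for a, s in zip(start, patch_size)),
                     tuple(patch_size))
    return patches, target, spec


def _augment_patch(arrs: List[np.ndarray], cfg: AugmentationConfig,
                   rng: np.random.Generator, spacing) -> List[np.ndarray]:
    out = []
    for a in arrs:
        v, _ = random_augment(Volume(a, spacing), cfg, rng)
        out.append(v.data.astype(np.float64))
    return out


def _pair_items(item) -> Pair:
    if isinstance(item, LongitudinalSample):
        return item.tp1, item.tp2, item.new_mask
    return item


def _batch(data, cfg: TrainConfig, rng: np.random.Generator, siamese: bool):
    xs1, xs2, ts = [], [], []
    for _ in range(cfg.batch_size):
        item = data(rng) if callable(data) else data[rng.integers(len(data))]
        if siamese:
            tp1, tp2, mask = _pair_items(item)
            (p1, p2), t, _ = sample_training_patch(
                (tp1, tp2), mask, rng, cfg.positive_fraction, cfg.patch_size,
                support_threshold=cfg.support_threshold,
            )
            if cfg.augment is not None:
                p1, = _augment_patch([p1], cfg.augment, rng, tp1.spacing)
                p2, = _augment_patch([p2], cfg.augment, rng, tp2.spacing)
            xs1.append(p1)
            xs2.append(p2)
            ts.append(t)
        else:
            vol, mask = item
            (p,), t, _ = sample_training_patch(
                (vol,), mask, rng, cfg.positive_fraction, cfg.patch_size,
                support_threshold=cfg.support_threshold,
            )
            if cfg.augment is not None:
                p, = _augment_patch([p], cfg.augment, rng, vol.spacing)
            xs1.append(p)
            ts.append(t)
    x1 = Tensor(np.stack(xs1)[:, None].astype(np.float32))
    t = np.stack(ts)
    if siamese:
        x2 = Tensor(np.stack(xs2)[:, None].astype(np.float32))
        return x1, x2, t
    return x1, None, t


def _val_loss(net, val_batches, siamese: bool) -> float:
    losses = []
    for x1, x2, t in val_batches:
        p = net(x1, x2) if siamese else net(x1)
        losses.append(float(soft_dice_loss(p, t, eps=DICE_EPS).data))
    return float(np.mean(losses)) if losses else np.inf


def train_stage(
    stage: int,
    data,
    cfg: TrainConfig,
    spec: NetworkSpec | None = None,
    base_checkpoint: Checkpoint | None = None,
    val_data=None,
    callback: Callable[[int, float], None] | None = None,
) -> Checkpoint:
    """Run one pipeline stage and return its checkpoint.

    ``data`` is a list of (Volume, LesionMask) pairs for stage 1, or of
    (tp1, tp2, new_mask) triples / LongitudinalSamples for stages 2 and 3
    (a callable ``data(rng) -> sample`` is also accepted, for on-the-fly
    synthesis).  Stage 2 requires a stage-1 checkpoint, stage 3 a stage-2
    checkpoint; the encoder is frozen in both.
    """
    cfg = dataclasses.replace(cfg, stage=stage, freeze_encoder=None)
    rng = np.random.default_rng(cfg.seed)
    siamese = stage != 1

    if stage == 1:
        if spec is None:
            raise ValueError("stage 1 requires a NetworkSpec")
        net: SegmentationUNet | NewLesionNetwork = build_segmentation_unet(
            spec, seed=int(rng.integers(2**31))
        )
        lineage = ["stage1"]
        kind = "segmentation"
    elif stage == 2:
        if base_checkpoint is None or base_checkpoint.stage != 1:
            raise ValueError("stage 2 requires a stage-1 checkpoint")
        src = network_from_checkpoint(base_checkpoint)
        net = build_new_lesion_network(base_checkpoint.spec,
                                       seed=int(rng.integers(2**31)))
        transfer_encoder(src, net)
        net.encoder.set_requires_grad(False)
        lineage = base_checkpoint.lineage + ["stage2"]
        kind = "new_lesion"
    else:
        if base_checkpoint is None or base_checkpoint.stage != 2:
            raise ValueError("stage 3 requires a stage-2 checkpoint")
        if base_checkpoint.kind != "new_lesion":
            raise ValueError("stage 3 expects a new-lesion checkpoint")
        net = network_from_checkpoint(base_checkpoint)
        net.encoder.set_requires_grad(False)
        lineage = base_checkpoint.lineage + ["stage3"]
        kind = "new_lesion"

    opt = Adam(list(net.named_parameters()), lr=cfg.learning_rate,
               beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)

    val_batches = []
    if val_data:
        vrng = np.random.default_rng(cfg.seed + 1)
        for _ in range(min(8, 2 * len(val_data))):
            val_batches.append(_batch(val_data, cfg, vrng, siamese))

    best_state = net.state_dict()
    best_val = _val_loss(net, val_batches, siamese) if val_batches else np.inf
    check_every = max(1, cfg.steps // 5)

    for step in range(cfg.steps):
        x1, x2, t = _batch(data, cfg, rng, siamese)
        p = net(x1, x2) if siamese else net(x1)
        loss = soft_dice_loss(p, t, eps=DICE_EPS)
        opt.zero_grad()
        loss.backward()
        opt.step()
        if callback is not None:
            callback(step, float(loss.data))
        if val_batches and ((step + 1) % check_every == 0 or step + 1 == cfg.steps):
            vl = _val_loss(net, val_batches, siamese)
            if vl < best_val:
                best_val = vl
                best_state = net.state_dict()

    state = best_state if val_batches else net.state_dict()
    return Checkpoint(state=state, spec=net.spec, stage=stage, lineage=lineage,
                      kind=kind, meta={"val_loss": None if not val_batches
                                       else float(best_val),
                                       "steps": cfg.steps, "seed": cfg.seed})


def train_ensemble(
    stage: int,
    data: Sequence,
    cfg: TrainConfig,
    base_checkpoint: Checkpoint | None = None,
    spec: NetworkSpec | None = None,
) -> List[Checkpoint]:
    """Train ``cfg.ensemble_size`` networks on different train/validation splits.

    Samples are assigned to folds by shuffled index (seeded); network k
    holds out fold k for validation and keeps its best-validation state.
    """
    n = len(data)
    k = cfg.ensemble_size
    fold_rng = np.random.default_rng(cfg.seed)
    order = fold_rng.permutation(n)
    folds = [sorted(order[i::k]) for i in range(k)]
    ckpts = []
    for i, fold in enumerate(folds):
        hold = set(fold)
        train = [data[j] for j in range(n) if j not in hold]
        val = [data[j] for j in sorted(hold)]
        member_cfg = dataclasses.replace(cfg, seed=cfg.seed + 1000 * (i + 1),
                                         freeze_encoder=None)
        ckpts.append(train_stage(stage, train, member_cfg, spec=spec,
                                 base_checkpoint=base_checkpoint,
                                 val_data=val or None))
    return ckpts


def _window_starts(dim: int, patch: int, stride: int) -> List[int]:
    starts = list(range(0, max(dim - patch, 0) + 1, stride))
    if starts[-1] != dim - patch:
        starts.append(dim - patch)
    return starts


def _model_probability(net, tp1: Volume, tp2: Volume | None,
                       patch_size, stride=None, chunk: int = 8) -> np.ndarray:
    """Sliding-window lesion-class probability with uniform overlap averaging.

    Windows are batched through the network in chunks for speed.
    """
    shape = tp1.shape
    stride = stride or tuple(max(1, p // 2) for p in patch_size)
    acc = np.zeros(shape, dtype=np.float64)
    cnt = np.zeros(shape, dtype=np.float64)
    slices = [
        (slice(sx, sx + patch_size[0]),
         slice(sy, sy + patch_size[1]),
         slice(sz, sz + patch_size[2]))
        for sx in _window_starts(shape[0], patch_size[0], stride[0])
        for sy in _window_starts(shape[1], patch_size[1], stride[1])
        for sz in _window_starts(shape[2], patch_size[2], stride[2])
    ]
    for i in range(0, len(slices), chunk):
        batch = slices[i:i + chunk]
        x1 = Tensor(np.stack([tp1.data[sl] for sl in batch])[:, None]
                    .astype(np.float32))
        if tp2 is not None:
            x2 = Tensor(np.stack([tp2.data[sl] for sl in batch])[:, None]
                        .astype(np.float32))
            p = net(x1, x2).data[:, 1]
        else:
            p = net(x1).data[:, 1]
        for j, sl in enumerate(batch):
            acc[sl] += p[j]
            cnt[sl] += 1.0
    return acc / np.maximum(cnt, 1.0)


def ensemble_predict(
    checkpoints: Sequence[Checkpoint],
    tp1: Volume,
    tp2: Volume | None = None,
    patch_size: Tuple[int, int, int] | None = None,
    stride: Tuple[int, int, int] | None = None,
) -> LesionMask:
    """Average per-voxel class probabilities across the ensemble and argmax.

    A voxel is labelled lesion when its averaged lesion probability exceeds
    0.5; an exact tie resolves to background.
    """
    if not checkpoints:
        raise ValueError("at least one checkpoint is required")
    kinds = {c.kind for c in checkpoints}
    specs = {c.spec for c in checkpoints}
    if len(kinds) > 1 or len(specs) > 1:
        raise ValueError("ensemble checkpoints must share kind and architecture")
    patch_size = patch_size or tuple(min(64, s) for s in tp1.shape)
    f = 2 ** next(iter(specs)).levels
    patch_size = tuple(p - p % f for p in patch_size)
    probs = []
    for ckpt in checkpoints:
        net = network_from_checkpoint(ckpt)
        probs.append(_model_probability(net, tp1, tp2, patch_size, stride))
    avg = np.mean(probs, axis=0)
    return LesionMask((avg > 0.5).astype(np.uint8), tp1.spacing)


def predict_pair(checkpoints: Sequence[Checkpoint], tp1: Volume, tp2: Volume,
                 **kw) -> LesionMask:
    """New-lesion prediction for a longitudinal pair."""
    return ensemble_predict(checkpoints, tp1, tp2, **kw)
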
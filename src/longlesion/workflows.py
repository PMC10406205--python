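"""End-to-end desk-scale workflows on phantom data.

These functions wire the full pipeline together at sizes a single CPU
handles in minutes: small phantoms (48-voxel grids), 2-level base-8
networks, 16-voxel training patches and a 3-network ensemble.  They are
used by the test suite and the reproduction script, and serve as worked
examples of the library API.
"""

from __future__ import annotations

import dataclasses
from typing import List, Tuple

import numpy as np

from .augment import AugmentationConfig
from .evaluate import EvalReport, evaluate_cohort
from .io_volumes import LesionMask, Volume
from .networks import NetworkSpec
from .phantom import PhantomConfig, make_longitudinal_truth, make_phantom
from .synthesis import SynthesisConfig, synthesize_pair
from .training import TrainConfig, ensemble_predict, train_ensemble, train_stage

__all__ = ["ScaledRunConfig", "scaled_end_to_end", "make_test_pairs"]


@dataclasses.dataclass
class ScaledRunConfig:
    """Study conditions for the desk-scale end-to-end run.

    Training uses 12 single time-point phantoms, 40 synthetic longitudinal
    pairs, and a 3-network stage-2 ensemble; evaluation uses 10 held-out
    easy pairs (large, high-contrast new lesions).  The learning rate is
    raised to 2e-3 for these short schedules (the full-scale default is
    1e-4 over far more steps).
    """

    phantom_shape: Tuple[int, int, int] = (48, 48, 48)
    n_train_phantoms: int = 12
    n_synthetic_pairs: int = 40
    n_test_pairs: int = 10
    stage1_steps: int = 150
    stage2_steps: int = 350
    ensemble_size: int = 3
    batch_size: int = 4
    patch_size: Tuple[int, int, int] = (12, 12, 12)
    learning_rate: float = 2e-3
    levels: int = 2
    base_channels: int = 8


def _train_phantom_cfg(shape, seed: int) -> PhantomConfig:
    return PhantomConfig(shape=shape, n_lesions=3, lesion_radius_range=(2.0, 3.5),
                         seed=seed)


def _easy_pair_cfg(shape, seed: int) -> PhantomConfig:
    # easy regime: few, large, high-contrast lesions over low noise
    return PhantomConfig(shape=shape, n_lesions=1, lesion_radius_range=(2.5, 4.0),
                         lesion_contrast=0.5, noise_sd=0.02, seed=seed)


def make_test_pairs(cfg: ScaledRunConfig, seed: int
                    ) -> List[Tuple[Volume, Volume, LesionMask]]:
    """Held-out evaluation pairs with known new-lesion masks."""
    pairs = []
    for i in range(cfg.n_test_pairs):
        tp1, tp2, new = make_longitudinal_truth(
            _easy_pair_cfg(cfg.phantom_shape, seed=seed * 10000 + 5000 + i), n_new=2
        )
        pairs.append((tp1, tp2, new))
    return pairs


def scaled_end_to_end(seed: int, cfg: ScaledRunConfig = ScaledRunConfig(),
                      with_augmentation: bool = True) -> dict:
    """Stage 1 -> synthetic pairs -> stage-2 ensemble -> lesion-wise scores.

    Trains the detector purely on synthetic longitudinal pairs (no real
    pairs, mirroring a zero-longitudinal-data regime) and evaluates it on
    held-out phantom pairs.  Returns the evaluation report plus the
    checkpoints, keyed by name.
    """
    rng = np.random.default_rng(seed)

    # single time-point training data
    stage1_data = []
    for i in range(cfg.n_train_phantoms):
        vol, mask, tissue, atlas = make_phantom(
            _train_phantom_cfg(cfg.phantom_shape, seed=seed * 10000 + i)
        )
        stage1_data.append((vol, mask, tissue, atlas))

    spec = NetworkSpec(in_channels=1, out_channels=2, levels=cfg.levels,
                       base_channels=cfg.base_channels)
    t_cfg = TrainConfig(patch_size=cfg.patch_size, learning_rate=cfg.learning_rate,
                        steps=cfg.stage1_steps, batch_size=cfg.batch_size,
                        ensemble_size=cfg.ensemble_size, stage=1,
                        seed=int(rng.integers(2**31)))
    ckpt1 = train_stage(1, [(v, m) for v, m, _, _ in stage1_data], t_cfg, spec=spec)

    # synthetic longitudinal pairs from the same single time-point data
    aug_cfg = AugmentationConfig() if with_augmentation else None
    pairs = []
    for i in range(cfg.n_synthetic_pairs):
        vol, mask, tissue, atlas = stage1_data[i % len(stage1_data)]
        syn_cfg = SynthesisConfig(seed=int(rng.integers(2**31)))
        pairs.append(synthesize_pair(vol, mask, tissue, atlas, syn_cfg, aug_cfg))

    t2_cfg = dataclasses.replace(t_cfg, stage=2, steps=cfg.stage2_steps,
                                 freeze_encoder=None,
                                 seed=int(rng.integers(2**31)))
    ensemble = train_ensemble(2, pairs, t2_cfg, base_checkpoint=ckpt1)

    # held-out evaluation
    test_pairs = make_test_pairs(cfg, seed)
    preds = []
    for tp1, tp2, _ in test_pairs:
        pred = ensemble_predict(ensemble, tp1, tp2,
                                patch_size=(32, 32, 32), stride=(16, 16, 16))
        preds.append(pred)
    report: EvalReport = evaluate_cohort(
        [(p, new) for p, (_, _, new) in zip(preds, test_pairs)]
    )
    return {"stage1": ckpt1, "ensemble": ensemble, "report": report,
            "predictions": preds, "test_pairs": test_pairs}
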
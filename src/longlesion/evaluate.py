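"""Voxel-wise and lesion-wise evaluation of new-lesion segmentations.

Voxel metrics are Dice, positive predictive value (precision) and true
positive rate (sensitivity) computed from voxel confusion counts:

    Dice = 2 TP / ((TP + FN) + (TP + FP))
    PPV  = TP / (TP + FP),   TPR = TP / (TP + FN)

Lesion-wise metrics follow the detection rules used by the MS new-lesion
challenge evaluation tooling: connected components smaller than 3 mm^3 are
removed from both masks; a ground-truth lesion counts as detected when at
least 10% of it is covered by the prediction (lesion sensitivity SL); a
predicted lesion counts as a true positive when at least 65% of it overlaps
ground truth and no more than 70% of it lies outside (lesion PPV, PL);
LesF1 is the harmonic mean of SL and PL.  The aggregate score is the mean
of Dice and LesF1.  Cohort comparisons use the paired two-sided Wilcoxon
signed-rank test with significance at p < 0.05.

Boundary reading: all thresholds are inclusive ("at least" / "no more
than"), so a component of exactly 3 mm^3 is kept and an overlap exactly at
a threshold passes.  A predicted lesion overlapped >= 65% necessarily lies
<= 35% outside, so the 70% clause can never reject on its own; it is
applied literally anyway and both thresholds are configurable.
"""

from __future__ import annotations

import dataclasses
import math
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, stats

from .io_volumes import GridMismatchError, LesionMask

__all__ = [
    "ConfusionCounts",
    "VoxelMetrics",
    "DetectionRules",
    "LesionMetrics",
    "EvalReport",
    "CaseResult",
    "voxel_confusion",
    "voxel_metrics",
    "filter_small_lesions",
    "lesion_metrics",
    "avg_score",
    "paired_wilcoxon",
    "evaluate_case",
    "evaluate_cohort",
]

STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

P_SIGNIFICANT = 0.05


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclasses.dataclass(frozen=True)
class VoxelMetrics:
    """Dice / PPV / TPR; ``None`` flags an undefined value (zero denominator)."""

    dice: Optional[float]
    ppv: Optional[float]
    tpr: Optional[float]


@dataclasses.dataclass(frozen=True)
class DetectionRules:
    min_lesion_volume: float = 3.0  # mm^3
    sl_overlap_min: float = 0.10
    pl_overlap_min: float = 0.65
    pl_outside_max: float = 0.70


@dataclasses.dataclass
class LesionMetrics:
    """Lesion-wise detection metrics plus the per-lesion match table."""

    SL: Optional[float]
    PL: Optional[float]
    les_f1: Optional[float]
    gt_table: List[dict] = dataclasses.field(default_factory=list)
    pred_table: List[dict] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class CaseResult:
    case_id: str
    voxel: VoxelMetrics
    lesion: LesionMetrics
    avg: Optional[float]


@dataclasses.dataclass
class EvalReport:
    cases: List[CaseResult]
    mean_dice: Optional[float]
    mean_les_f1: Optional[float]
    mean_avg: Optional[float]
    n_excluded: int  # cases with undefined metrics, excluded from the means


def _check_grids(pred: LesionMask, gt: LesionMask) -> None:
    if pred.shape != gt.shape:
        raise GridMismatchError(f"grids differ: {pred.shape} vs {gt.shape}")
    if any(abs(a - b) > 1e-3 for a, b in zip(pred.spacing, gt.spacing)):
        raise GridMismatchError(f"spacings differ: {pred.spacing} vs {gt.spacing}")


def voxel_confusion(pred: LesionMask, gt: LesionMask) -> ConfusionCounts:
    """TP/FP/FN voxel counts between a prediction and the ground truth."""
    _check_grids(pred, gt)
    p = pred.data > 0
    g = gt.data > 0
    return ConfusionCounts(
        TP=int((p & g).sum()), FP=int((p & ~g).sum()), FN=int((~p & g).sum())
    )


def voxel_metrics(c: ConfusionCounts) -> VoxelMetrics:
    """Dice, PPV and TPR from confusion counts.

    Zero denominators yield ``None`` flags, except that Dice is 1 when both
    masks are empty (a perfect empty prediction).
    """
    dice_den = (c.TP + c.FN) + (c.TP + c.FP)
    dice = 1.0 if dice_den == 0 else 2.0 * c.TP / dice_den
    ppv = None if c.TP + c.FP == 0 else c.TP / (c.TP + c.FP)
    tpr = None if c.TP + c.FN == 0 else c.TP / (c.TP + c.FN)
    return VoxelMetrics(dice=dice, ppv=ppv, tpr=tpr)


def _components(mask: LesionMask) -> Tuple[np.ndarray, int]:
    return ndimage.label(mask.data > 0, structure=STRUCT_26)


def filter_small_lesions(mask: LesionMask,
                         rules: DetectionRules = DetectionRules()) -> LesionMask:
    """Remove connected components smaller than the minimum lesion volume.

    Ties are kept: a component of exactly ``min_lesion_volume`` survives.
    """
    lab, n = _components(mask)
    if n == 0:
        return mask.with_data(np.zeros_like(mask.data))
    vox_vol = mask.voxel_volume_mm3
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes * vox_vol >= rules.min_lesion_volume) + 1
    out = np.isin(lab, keep).astype(np.uint8)
    return mask.with_data(out)


def lesion_metrics(pred: LesionMask, gt: LesionMask,
                   rules: DetectionRules = DetectionRules()) -> LesionMetrics:
    """Lesion sensitivity (SL), lesion PPV (PL) and their harmonic mean.

    Expects masks already filtered with :func:`filter_small_lesions`.
    Matching is per-component by any-overlap against the other mask; no
    one-to-one assignment is made.
    """
    _check_grids(pred, gt)
    p = pred.data > 0
    g = gt.data > 0
    gt_lab, n_gt = _components(gt)
    pred_lab, n_pred = _components(pred)

    gt_table = []
    detected = 0
    for l in range(1, n_gt + 1):
        comp = gt_lab == l
        size = int(comp.sum())
        overlap = int((comp & p).sum()) / size
        ok = overlap >= rules.sl_overlap_min
        detected += ok
        gt_table.append({"label": l, "voxels": size, "overlap_fraction": overlap,
                         "detected": bool(ok)})

    pred_table = []
    true_pos = 0
    for l in range(1, n_pred + 1):
        comp = pred_lab == l
        size = int(comp.sum())
        inside = int((comp & g).sum()) / size
        outside = int((comp & ~g).sum()) / size
        ok = inside >= rules.pl_overlap_min and outside <= rules.pl_outside_max
        true_pos += ok
        pred_table.append({"label": l, "voxels": size, "inside_fraction": inside,
                           "outside_fraction": outside, "true_positive": bool(ok)})

    sl = None if n_gt == 0 else detected / n_gt
    pl = None if n_pred == 0 else true_pos / n_pred
    if sl is None or pl is None:
        f1 = None
    elif sl + pl == 0:
        f1 = 0.0
    else:
        f1 = 2.0 * sl * pl / (sl + pl)
    return LesionMetrics(SL=sl, PL=pl, les_f1=f1, gt_table=gt_table,
                         pred_table=pred_table)


def avg_score(v: VoxelMetrics, l: LesionMetrics) -> Optional[float]:
    """Aggregate score: the mean of Dice and LesF1 (``None`` propagates)."""
    if v.dice is None or l.les_f1 is None:
        return None
    return (v.dice + l.les_f1) / 2.0


def paired_wilcoxon(scores_a: Sequence[float],
                    scores_b: Sequence[float]) -> Tuple[float, float, dict]:
    """Two-sided paired Wilcoxon signed-rank test on per-case scores.

    Zero differences are dropped.  Returns (statistic, p, info) where info
    carries ``significant`` (p < 0.05) and ``degenerate`` (all differences
    zero, reported as p = 1).
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired score lists must have equal length")
    if len(a) < 6:
        raise ValueError("at least 6 paired cases are required")
    diff = a - b
    if np.all(diff == 0):
        return 0.0, 1.0, {"significant": False, "degenerate": True}
    stat, p = stats.wilcoxon(a, b, zero_method="wilcox",
                             alternative="two-sided")
    return float(stat), float(p), {"significant": bool(p < P_SIGNIFICANT),
                                   "degenerate": False}


def evaluate_case(pred: LesionMask, gt: LesionMask,
                  rules: DetectionRules = DetectionRules(),
                  case_id: str = "case") -> CaseResult:
    """Full per-case evaluation: small-lesion filtering on both masks,
    voxel metrics on the filtered masks, lesion metrics, aggregate score."""
    pred_f = filter_small_lesions(pred, rules)
    gt_f = filter_small_lesions(gt, rules)
    v = voxel_metrics(voxel_confusion(pred_f, gt_f))
    l = lesion_metrics(pred_f, gt_f, rules)
    return CaseResult(case_id=case_id, voxel=v, lesion=l, avg=avg_score(v, l))


def evaluate_cohort(pairs: Sequence[Tuple[LesionMask, LesionMask]],
                    rules: DetectionRules = DetectionRules(),
                    case_ids: Sequence[str] | None = None) -> EvalReport:
    """Evaluate many (pred, gt) pairs; cohort means exclude undefined cases."""
    ids = case_ids or [f"case{i:03d}" for i in range(len(pairs))]
    cases = [evaluate_case(p, g, rules, cid) for (p, g), cid in zip(pairs, ids)]
    defined = [c for c in cases
               if c.avg is not None and not math.isnan(c.avg)]
    if defined:
        mean_dice = float(np.mean([c.voxel.dice for c in defined]))
        mean_f1 = float(np.mean([c.lesion.les_f1 for c in defined]))
        mean_avg = float(np.mean([c.avg for c in defined]))
    else:
        mean_dice = mean_f1 = mean_avg = None
    return EvalReport(cases=cases, mean_dice=mean_dice, mean_les_f1=mean_f1,
                      mean_avg=mean_avg, n_excluded=len(cases) - len(defined))
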
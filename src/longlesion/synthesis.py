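"""Synthetic longitudinal pair generation from single time-point scans.

From one FLAIR volume and its lesion mask, the pipeline fabricates two
time-points with a known new-lesion mask in three steps:

1. geometric augmentation (flips / orthogonal rotations) of the scan and
   mask, duplication into two copies, and later independent quality
   augmentation of each copy;
2. per-lesion fates: each connected component is kept in both time-points,
   inpainted (removed) from one of them, or from both — a lesion removed
   from the first time-point only is, by construction, a *new* lesion;
3. synthetic lesions generated at realistic locations (white/gray-matter
   restricted, lesion-atlas weighted) in one or both time-points; only the
   lesions generated in the second time-point alone join the new-lesion
   mask.

Lesions removed from the second time-point only are *disappearing* lesions:
they are generated but never labelled, since the detection target is new
lesions.

The inpainting and generation sub-models are pluggable: a trained
regression U-Net can be used, and a classical fallback (distance-weighted
shell-mean fill with matched noise; atlas-shaped tapered hyperintense blob)
makes the pipeline fully testable without any trained weights.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .augment import AugmentationConfig, random_augment
from .io_volumes import LesionMask, Volume
from .phantom import BLOB_MASK_LEVEL, STRUCT_26, LesionAtlas, TissueMap, lesion_blob

__all__ = [
    "LesionComponent",
    "LesionFate",
    "LongitudinalSample",
    "SynthesisConfig",
    "FATES",
    "split_lesions",
    "assign_fates",
    "inpaint_components",
    "classical_inpainter",
    "classical_generate_lesion",
    "corrupt_for_inpainting",
    "prepare_generator_sample",
    "sample_generation_sites",
    "synthesize_pair",
    "reconstruct_new_mask",
]

FATES = ("keep_both", "remove_tp1", "remove_tp2", "remove_both")

#: dilation (voxels) of an inpainting region beyond the component, removing
#: partial-volume rims
INPAINT_DILATION = 1


@dataclasses.dataclass
class LesionComponent:
    """One 26-connected lesion, as produced by :func:`split_lesions`."""

    label: int
    voxels: np.ndarray  # (n, 3) integer coordinates
    volume_mm3: float

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.voxels.T)] = True
        return m


@dataclasses.dataclass
class LesionFate:
    component: LesionComponent
    fate: str

    def __post_init__(self) -> None:
        if self.fate not in FATES:
            raise ValueError(f"unknown fate {self.fate!r}; expected one of {FATES}")


@dataclasses.dataclass
class GeneratedSite:
    """A synthetic lesion placed during step three."""

    center: Tuple[int, int, int]
    placement: str  # tp2_only | tp1_only | both
    mask: np.ndarray  # boolean support of the generated lesion


@dataclasses.dataclass
class LongitudinalSample:
    tp1: Volume
    tp2: Volume
    new_mask: LesionMask
    fates: List[LesionFate]
    generated_sites: List[GeneratedSite]
    seed: int
    augment_logs: Tuple[list, list] = ((), ())


@dataclasses.dataclass
class SynthesisConfig:
    """Probabilities and counts governing pair synthesis.

    Fate probabilities order matches :data:`FATES`.  ``remove_tp1`` is
    weighted up because it is the sole source of component-derived new
    lesions.
    """

    fate_probabilities: Tuple[float, float, float, float] = (0.4, 0.3, 0.15, 0.15)
    n_generated_range: Tuple[int, int] = (0, 3)
    generated_placement_probabilities: Dict[str, float] = dataclasses.field(
        default_factory=lambda: {"tp2_only": 0.6, "both": 0.3, "tp1_only": 0.1}
    )
    atlas_threshold: float = 0.0
    generated_radius_range: Tuple[float, float] = (2.0, 4.0)  # mm
    generated_contrast_range: Tuple[float, float] = (0.3, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fate_probabilities) - 1.0) > 1e-9:
            raise ValueError("fate probabilities must sum to 1")
        p = self.generated_placement_probabilities
        if set(p) != {"tp2_only", "tp1_only", "both"}:
            raise ValueError("placement probabilities must cover tp2_only/tp1_only/both")
        if abs(sum(p.values()) - 1.0) > 1e-9:
            raise ValueError("placement probabilities must sum to 1")


# ---------------------------------------------------------------------------
# step two: components and fates


def split_lesions(mask: LesionMask) -> List[LesionComponent]:
    """Separate independent lesions by 26-connectivity.

    Labels are deterministic: ascending first-voxel (raster) index.
    """
    lab, n = ndimage.label(mask.data > 0, structure=STRUCT_26)
    order = sorted(range(1, n + 1), key=lambda l: np.flatnonzero(lab == l)[0])
    vox_vol = mask.voxel_volume_mm3
    comps = []
    for new_label, old_label in enumerate(order, start=1):
        voxels = np.argwhere(lab == old_label)
        comps.append(LesionComponent(new_label, voxels, len(voxels) * vox_vol))
    return comps


def assign_fates(components: Sequence[LesionComponent], cfg: SynthesisConfig,
                 rng: np.random.Generator) -> List[LesionFate]:
    """Draw one fate per component, i.i.d. from ``cfg.fate_probabilities``."""
    draws = rng.choice(len(FATES), size=len(components), p=cfg.fate_probabilities)
    return [LesionFate(c, FATES[d]) for c, d in zip(components, draws)]


# ---------------------------------------------------------------------------
# inpainting


def classical_inpainter(vol_with_noise: np.ndarray, region: np.ndarray) -> np.ndarray:
    """Distance-weighted shell-mean fill plus matched noise.

    Each region voxel gets the inverse-square-distance weighted mean of the
    intensities in a surrounding healthy shell, plus Gaussian noise matched
    to the shell's standard deviation.  Accepts (and ignores) noise-filled
    region content, so it is interface-compatible with a trained model.
    """
    out = vol_with_noise.astype(np.float64).copy()
    region = region.astype(bool)
    if not region.any():
        return out
    lab, n = ndimage.label(region, structure=STRUCT_26)
    rng = np.random.default_rng(
        int(np.abs(vol_with_noise).sum() * 1e3) % 2**31  # deterministic in the input
    )
    for l in range(1, n + 1):
        rmask = lab == l
        shell = ndimage.binary_dilation(rmask, STRUCT_26, iterations=3) & ~region
        if not shell.any():
            continue
        shell_vals = out[shell]
        sd = shell_vals.std()
        rvox = np.argwhere(rmask)
        svox = np.argwhere(shell)
        sval = out[tuple(svox.T)]
        # inverse-square distance weights, vectorized over the region
        d2 = ((rvox[:, None, :] - svox[None, :, :]) ** 2).sum(axis=2).astype(np.float64)
        w = 1.0 / np.maximum(d2, 1.0)
        fill = (w @ sval) / w.sum(axis=1)
        out[tuple(rvox.T)] = fill + rng.normal(0.0, sd, size=len(rvox))
    return out


def inpaint_components(
    vol: Volume,
    components: Sequence[LesionComponent],
    inpainter: Callable[[np.ndarray, np.ndarray], np.ndarray] = classical_inpainter,
    rng: np.random.Generator | None = None,
) -> Volume:
    """Remove the given lesions, replacing them with synthesized healthy tissue.

    The inpainting region is each component dilated by one voxel (to clear
    partial-volume rims).  Regions are first filled with Gaussian draws
    matched to the image's global statistics, then handed to ``inpainter``
    along with the region mask; voxels outside the regions are unchanged
    bitwise.
    """
    if not components:
        return vol.with_data(vol.data.copy())
    region = np.zeros(vol.shape, dtype=bool)
    for comp in components:
        if (comp.voxels < 0).any() or (comp.voxels >= np.asarray(vol.shape)).any():
            raise ValueError(f"component {comp.label} lies outside the grid")
        region |= comp.mask(vol.shape)
    region = ndimage.binary_dilation(region, STRUCT_26, iterations=INPAINT_DILATION)
    rng = rng or np.random.default_rng(0)
    noisy = vol.data.astype(np.float64).copy()
    noisy[region] = rng.normal(float(vol.data.mean()), float(vol.data.std()),
                               size=int(region.sum()))
    filled = inpainter(noisy, region)
    out = vol.data.astype(np.float64).copy()
    out[region] = filled[region]
    return vol.with_data(out.astype(vol.data.dtype))


def corrupt_for_inpainting(
    vol: Volume,
    mask_free_of_lesions: LesionMask,
    rng: np.random.Generator,
    n_regions_range: Tuple[int, int] = (1, 4),
    radius_range_mm: Tuple[float, float] = (2.0, 4.0),
) -> Tuple[Volume, Volume, LesionMask]:
    """Training-pair builder for the inpainting model.

    Lesion-shaped regions at random healthy locations are filled with
    Gaussian draws using the image's global mean and SD; the target is the
    original image.  ``mask_free_of_lesions`` marks voxels that must not be
    corrupted (real lesions / hyperintensities).
    """
    target = vol.with_data(vol.data.copy())
    corrupted = vol.data.astype(np.float64).copy()
    region = np.zeros(vol.shape, dtype=bool)
    n_regions = int(rng.integers(n_regions_range[0], n_regions_range[1] + 1))
    forbidden = mask_free_of_lesions.data > 0
    mean, sd = float(vol.data.mean()), float(vol.data.std())
    spacing = np.asarray(vol.spacing)
    for _ in range(n_regions):
        for _attempt in range(50):
            center = [rng.integers(4, s - 4) for s in vol.shape]
            r_mm = rng.uniform(*radius_range_mm)
            radii = np.maximum(r_mm * rng.uniform(0.7, 1.3, 3) / spacing, 1.0)
            blob = lesion_blob(vol.shape, center, radii) >= BLOB_MASK_LEVEL
            if blob.any() and not (blob & forbidden).any():
                region |= blob
                break
    corrupted[region] = rng.normal(mean, sd, size=int(region.sum()))
    return (
        vol.with_data(corrupted.astype(vol.data.dtype)),
        target,
        LesionMask(region.astype(np.uint8), vol.spacing),
    )


def prepare_generator_sample(
    vol: Volume,
    mask: LesionMask,
    rng: np.random.Generator,
    aug_cfg: AugmentationConfig | None = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Training sample for the lesion generator model.

    Returns a 2-channel input (augmented image with lesion regions replaced
    by random noise; the lesion mask) and the original image as target.
    """
    if not (mask.data > 0).any():
        raise ValueError("generator samples require a non-empty lesion mask")
    augmented = vol
    if aug_cfg is not None:
        augmented, _ = random_augment(vol, aug_cfg, rng)
    ch1 = augmented.data.astype(np.float64).copy()
    m = mask.data > 0
    ch1[m] = rng.normal(float(vol.data.mean()), float(vol.data.std()),
                        size=int(m.sum()))
    return (
        np.stack([ch1, mask.data.astype(np.float64)]),
        vol.data.astype(np.float64).copy(),
    )


# ---------------------------------------------------------------------------
# step three: lesion generation


def sample_generation_sites(
    tissue: TissueMap,
    atlas: LesionAtlas,
    n: int,
    rng: np.random.Generator,
    atlas_threshold: float = 0.0,
    min_separation: int = 2,
    exclude: np.ndarray | None = None,
) -> List[Tuple[int, int, int]]:
    """Draw lesion centers proportional to the atlas, restricted to WM ∪ GM.

    Sites keep a pairwise separation of at least ``min_separation`` voxels
    (Chebyshev) and avoid the optional ``exclude`` support.
    """
    if n == 0:
        return []
    if tissue.shape != atlas.shape:
        raise ValueError("tissue map and atlas must share a grid")
    feasible = tissue.brain & (atlas.data >= atlas_threshold) & (atlas.data > 0)
    if exclude is not None:
        feasible &= ~exclude
    idx = np.flatnonzero(feasible)
    if idx.size == 0:
        raise ValueError("no feasible generation sites (atlas/tissue too restrictive)")
    p = atlas.data.flat[idx]
    p = p / p.sum()
    if min_separation <= 0:
        flat = rng.choice(idx, size=n, p=p)
        return [tuple(int(v) for v in np.unravel_index(f, tissue.shape))
                for f in flat]
    sites: List[Tuple[int, int, int]] = []
    for _ in range(100 * n):
        if len(sites) == n:
            break
        flat = rng.choice(idx, p=p)
        c = tuple(int(v) for v in np.unravel_index(flat, tissue.shape))
        if all(max(abs(a - b) for a, b in zip(c, s)) >= min_separation for s in sites):
            sites.append(c)
    if len(sites) < n:
        raise ValueError(f"could only place {len(sites)}/{n} separated sites")
    return sites


def classical_generate_lesion(
    vol_data: np.ndarray,
    tissue: TissueMap,
    center: Tuple[int, int, int],
    rng: np.random.Generator,
    radius_range_mm: Tuple[float, float] = (2.0, 4.0),
    contrast_range: Tuple[float, float] = (0.3, 0.5),
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> Tuple[np.ndarray, np.ndarray]:
    """Synthesize one hyperintense lesion: Gaussian-tapered blob blended in.

    Returns (additive intensity delta, boolean lesion support).
    """
    r_mm = rng.uniform(*radius_range_mm)
    radii = np.maximum(r_mm * rng.uniform(0.7, 1.3, 3) / np.asarray(spacing), 1.0)
    blob = lesion_blob(vol_data.shape, center, radii)
    support = blob >= BLOB_MASK_LEVEL
    contrast = rng.uniform(*contrast_range)
    return contrast * blob, support


def reconstruct_new_mask(sample: LongitudinalSample, shape) -> np.ndarray:
    """Rebuild the new-lesion mask from the fate log and generated sites.

    New lesions are exactly: components removed from tp1 only, plus lesions
    generated in tp2 only.  Used to verify bookkeeping exactness.
    """
    m = np.zeros(shape, dtype=bool)
    for fate in sample.fates:
        if fate.fate == "remove_tp1":
            m |= fate.component.mask(shape)
    for site in sample.generated_sites:
        if site.placement == "tp2_only":
            m |= site.mask
    return m


def synthesize_pair(
    flair: Volume,
    mask: LesionMask,
    tissue: TissueMap,
    atlas: LesionAtlas,
    cfg: SynthesisConfig,
    aug_cfg: AugmentationConfig | None = None,
    inpainter: Callable[[np.ndarray, np.ndarray], np.ndarray] = classical_inpainter,
    generator: Callable | None = None,
    rng: np.random.Generator | None = None,
) -> LongitudinalSample:
    """Generate one synthetic longitudinal sample with a known new-lesion mask.

    Steps: geometric augmentation and duplication; per-component fates with
    inpainting; atlas-guided lesion generation; independent quality
    augmentation of the two copies.  The new-lesion mask collects components
    removed from tp1 and lesions generated in tp2 only.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    seed = cfg.seed

    # --- step 1a: shared geometric augmentation (flips + orthogonal rotation)
    flip_axes = [a for a in range(3) if rng.random() < 0.5]
    k_rot = int(rng.integers(0, 4))  # quarter-turns in the in-plane axes (0, 1)

    def geom(arr: np.ndarray) -> np.ndarray:
        out = arr
        for a in flip_axes:
            out = np.flip(out, axis=a)
        if k_rot and out.shape[0] == out.shape[1]:
            out = np.rot90(out, k=k_rot, axes=(0, 1))
        return np.ascontiguousarray(out)

    base = flair.with_data(geom(flair.data))
    gmask = LesionMask(geom(mask.data), mask.spacing)
    gtissue = TissueMap(geom(tissue.data), tissue.spacing)
    gatlas_data = geom(atlas.data)
    s = gatlas_data.sum()
    gatlas = LesionAtlas(gatlas_data / s if s > 0 else gatlas_data, atlas.spacing)

    # --- step 2: component fates and inpainting
    components = split_lesions(gmask)
    fates = assign_fates(components, cfg, rng)
    remove_tp1 = [f.component for f in fates if f.fate in ("remove_tp1", "remove_both")]
    remove_tp2 = [f.component for f in fates if f.fate in ("remove_tp2", "remove_both")]
    tp1 = inpaint_components(base, remove_tp1, inpainter, rng)
    tp2 = inpaint_components(base, remove_tp2, inpainter, rng)

    new_mask = np.zeros(base.shape, dtype=bool)
    tp1_support = np.zeros(base.shape, dtype=bool)
    for f in fates:
        cm = f.component.mask(base.shape)
        if f.fate == "remove_tp1":
            new_mask |= cm
        if f.fate in ("keep_both", "remove_tp2"):
            tp1_support |= cm

    # --- step 3: generated lesions
    n_gen = int(rng.integers(cfg.n_generated_range[0], cfg.n_generated_range[1] + 1))
    sites: List[GeneratedSite] = []
    if n_gen:
        exclude = ndimage.binary_dilation(gmask.data > 0, STRUCT_26, iterations=3)
        placements = list(cfg.generated_placement_probabilities)
        weights = [cfg.generated_placement_probabilities[k] for k in placements]
        centers = sample_generation_sites(
            gtissue, gatlas, n_gen, rng, cfg.atlas_threshold,
            min_separation=int(np.ceil(2 * cfg.generated_radius_range[1])) + 2,
            exclude=exclude,
        )
        # generated lesions must not touch existing components or each other:
        # their support is larger than a site's exclusion radius, so each
        # realized blob is checked against an occupancy mask before blending
        occupied = ndimage.binary_dilation(gmask.data > 0, STRUCT_26, iterations=1)
        t1 = tp1.data.astype(np.float64).copy()
        t2 = tp2.data.astype(np.float64).copy()
        for center in centers:
            placement = placements[int(rng.choice(len(placements), p=weights))]
            if generator is not None:
                delta, support = generator(t2, gtissue, center, rng)
            else:
                delta, support = classical_generate_lesion(
                    t2, gtissue, center, rng,
                    cfg.generated_radius_range, cfg.generated_contrast_range,
                    base.spacing,
                )
            if not support.any() or (support & occupied).any():
                continue  # would merge with an existing lesion; drop the site
            occupied |= ndimage.binary_dilation(support, STRUCT_26, iterations=1)
            if placement in ("tp1_only", "both"):
                t1 += delta  # identical realization in both time-points
                tp1_support |= support
            if placement in ("tp2_only", "both"):
                t2 += delta
            if placement == "tp2_only":
                new_mask |= support
            sites.append(GeneratedSite(center, placement, support))
        tp1 = tp1.with_data(t1.astype(tp1.data.dtype))
        tp2 = tp2.with_data(t2.astype(tp2.data.dtype))

    # --- step 1b: independent quality augmentation of the two copies
    log1: list = []
    log2: list = []
    if aug_cfg is not None:
        tp1, log1 = random_augment(tp1, aug_cfg, rng)
        tp2, log2 = random_augment(tp2, aug_cfg, rng)

    assert not (new_mask & tp1_support).any()
    return LongitudinalSample(
        tp1=tp1,
        tp2=tp2,
        new_mask=LesionMask(new_mask.astype(np.uint8), base.spacing),
        fates=fates,
        generated_sites=sites,
        seed=seed,
        augment_logs=(log1, log2),
    )
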
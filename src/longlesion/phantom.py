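"""Brain-like 3D phantoms with hyperintense blob lesions.

The phantom emulates the statistical structure the detection pipeline relies
on: a nested-ellipsoid head (background / CSF / GM / WM), FLAIR-like
intensities (CSF dark, lesions hyperintense relative to WM), smoothed
ellipsoidal lesions placed inside white matter, and a lesion-probability
atlas concentrated on WM.  Every downstream stage — augmentation, time-point
synthesis, training, evaluation — is testable end-to-end on these phantoms
without any external data.
"""

from __future__ import annotations

import dataclasses
from typing import List, Tuple

import numpy as np
from scipy import ndimage

from .io_volumes import LesionMask, Volume

__all__ = [
    "TissueMap",
    "LesionAtlas",
    "PhantomConfig",
    "make_phantom",
    "make_longitudinal_truth",
    "lesion_blob",
    "PlacementError",
]

# tissue labels
BACKGROUND, CSF, GM, WM = 0, 1, 2, 3

#: taper level at which a blob's soft profile is binarized into its mask
BLOB_MASK_LEVEL = 0.3

STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class PlacementError(RuntimeError):
    """Raised when the requested lesions cannot be placed without overlap."""


@dataclasses.dataclass
class TissueMap:
    """Label grid: 0 background, 1 CSF, 2 GM, 3 WM."""

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.uint8)
        labels = np.unique(self.data)
        if not np.isin(labels, (BACKGROUND, CSF, GM, WM)).all():
            raise ValueError(f"unknown tissue labels: {labels}")
        if not (self.data == WM).any():
            raise ValueError("WM region is empty")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self):
        return self.data.shape

    @property
    def wm(self) -> np.ndarray:
        return self.data == WM

    @property
    def brain(self) -> np.ndarray:
        """WM ∪ GM, the support lesions are allowed on."""
        return (self.data == WM) | (self.data == GM)


@dataclasses.dataclass
class LesionAtlas:
    """Probability grid of lesion occurrence; sums to 1, supported on WM ∪ GM."""

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("atlas values must lie in [0, 1]")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self):
        return self.data.shape


@dataclasses.dataclass
class PhantomConfig:
    shape: Tuple[int, int, int] = (96, 96, 96)
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_lesions: int = 6
    lesion_radius_range: Tuple[float, float] = (2.0, 4.5)  # mm
    wm_intensity: float = 0.5
    gm_intensity: float = 0.6
    csf_intensity: float = 0.15
    lesion_contrast: float = 0.4
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_contrast <= 0:
            raise ValueError("lesion_contrast must be > 0 (FLAIR-like hyperintensity)")
        min_vox = self.lesion_radius_range[0] / max(self.spacing)
        if min_vox < 1:
            raise ValueError("lesion radii must be at least one voxel")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")


def _ellipsoid_radius(shape: Tuple[int, int, int]) -> np.ndarray:
    """Normalized radius field: 0 at the volume center, 1 at the head surface."""
    grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    r2 = np.zeros(shape, dtype=np.float64)
    for g, n in zip(grids, shape):
        c = (n - 1) / 2.0
        # head half-axis at 90% of the half-extent
        r2 += ((g - c) / (0.9 * n / 2.0)) ** 2
    return np.sqrt(r2)


def make_tissue_map(shape: Tuple[int, int, int], spacing=(1.0, 1.0, 1.0)) -> TissueMap:
    """Nested-ellipsoid head: WM core, GM shell, CSF rim, background outside."""
    rr = _ellipsoid_radius(shape)
    labels = np.zeros(shape, dtype=np.uint8)
    labels[rr < 1.00] = CSF
    labels[rr < 0.88] = GM
    labels[rr < 0.62] = WM
    return TissueMap(labels, spacing)


def make_atlas(tissue: TissueMap) -> LesionAtlas:
    """WM-weighted lesion-probability atlas, normalized to integrate to 1.

    WM voxels carry most of the mass (periventricular emphasis via a smooth
    center-weighted profile); GM keeps a small share so the support is the
    full WM ∪ GM region.
    """
    rr = _ellipsoid_radius(tissue.shape)
    w = np.zeros(tissue.shape, dtype=np.float64)
    w[tissue.wm] = 1.0
    w[tissue.data == GM] = 0.05
    w *= np.exp(-2.0 * rr**2)  # favor deep WM
    w = ndimage.gaussian_filter(w, sigma=2.0)
    w[~tissue.brain] = 0.0  # support constraint after smoothing
    total = w.sum()
    if total <= 0:
        raise ValueError("atlas support is empty")
    w /= total
    return LesionAtlas(w, tissue.spacing)


def lesion_blob(
    shape: Tuple[int, int, int],
    center: Tuple[float, float, float],
    radii_vox: Tuple[float, float, float],
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Soft lesion profile in [0, 1]: a Gaussian-tapered ellipsoid.

    A super-Gaussian ``exp(-(r/R)^4)`` keeps the interior near 1 with a
    smooth rim, so partial-volume overlap between a mask (profile >=
    ``BLOB_MASK_LEVEL``) and the visible hyperintensity is realistic.
    Anisotropy (random axis scaling) comes from the caller via ``radii_vox``.
    """
    lo = [max(0, int(np.floor(c - 2 * r))) for c, r in zip(center, radii_vox)]
    hi = [min(n, int(np.ceil(c + 2 * r)) + 1) for c, r, n in zip(center, radii_vox, shape)]
    prof = np.zeros(shape, dtype=np.float64)
    if any(h <= l for l, h in zip(lo, hi)):
        return prof
    grids = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii_vox))
    prof[tuple(slice(l, h) for l, h in zip(lo, hi))] = np.exp(-(r2**2))
    return prof


def _draw_radii(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    r_mm = rng.uniform(*cfg.lesion_radius_range)
    aniso = rng.uniform(0.7, 1.3, size=3)
    r_vox = r_mm * aniso / np.asarray(cfg.spacing)
    return np.maximum(r_vox, 1.0)


def _place_lesions(
    cfg: PhantomConfig,
    tissue: TissueMap,
    atlas: LesionAtlas,
    n: int,
    rng: np.random.Generator,
    forbidden: np.ndarray | None = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Place n non-overlapping blobs fully inside WM.

    Returns (soft profile sum, binary mask).  Placement is atlas-guided:
    candidate centers are drawn from the atlas restricted to an eroded WM so
    the full blob fits inside white matter.
    """
    shape = tissue.shape
    profile = np.zeros(shape, dtype=np.float64)
    mask = np.zeros(shape, dtype=np.uint8)
    if n == 0:
        return profile, mask
    occupied = np.zeros(shape, dtype=bool) if forbidden is None else forbidden.copy()

    # candidate centers: WM eroded by the smallest radius; each drawn blob is
    # still rejected unless fully contained in WM
    min_r_vox = max(1, int(np.ceil(cfg.lesion_radius_range[0] / min(cfg.spacing))))
    interior = ndimage.binary_erosion(tissue.wm, iterations=min_r_vox)
    support = interior & (atlas.data > 0)
    idx = np.flatnonzero(support)
    if idx.size == 0:
        raise PlacementError(
            "no WM interior large enough for the requested lesion radii; "
            "use a larger phantom shape or smaller radii"
        )
    p = atlas.data.flat[idx]
    p = p / p.sum()

    placed = 0
    for _ in range(200 * n):
        if placed == n:
            break
        flat = rng.choice(idx, p=p)
        center = np.unravel_index(flat, shape)
        radii = _draw_radii(cfg, rng)
        blob = lesion_blob(shape, center, radii, rng)
        bmask = blob >= BLOB_MASK_LEVEL
        if not bmask.any():
            continue
        # keep components separated so the count is exact under 26-connectivity
        dilated = ndimage.binary_dilation(bmask, STRUCT_26, iterations=2)
        if (dilated & occupied).any() or not bmask[tissue.wm].sum() == bmask.sum():
            continue
        profile = np.maximum(profile, blob)
        mask[bmask] = 1
        occupied |= dilated
        placed += 1
    if placed < n:
        raise PlacementError(
            f"could only place {placed}/{n} non-overlapping lesions; "
            "use a larger phantom shape, fewer lesions, or smaller radii"
        )
    return profile, mask


def _tissue_template(cfg: PhantomConfig, tissue: TissueMap) -> np.ndarray:
    tpl = np.zeros(tissue.shape, dtype=np.float64)
    tpl[tissue.data == CSF] = cfg.csf_intensity
    tpl[tissue.data == GM] = cfg.gm_intensity
    tpl[tissue.data == WM] = cfg.wm_intensity
    # mild smoothing for partial-volume-like boundaries
    return ndimage.gaussian_filter(tpl, sigma=0.6)


def _render(cfg: PhantomConfig, tissue: TissueMap, profile: np.ndarray,
            rng: np.random.Generator) -> Volume:
    data = _tissue_template(cfg, tissue) + cfg.lesion_contrast * profile
    data += rng.normal(0.0, cfg.noise_sd, size=tissue.shape)
    return Volume(data.astype(np.float32), cfg.spacing)


def make_phantom(cfg: PhantomConfig) -> Tuple[Volume, LesionMask, TissueMap, LesionAtlas]:
    """Deterministic phantom: FLAIR-like volume, lesion mask, tissues, atlas.

    The lesion mask has exactly ``cfg.n_lesions`` 26-connected components,
    each fully inside WM, with mean in-lesion hyperintensity at least
    ``lesion_contrast / 2`` above the WM mean.
    """
    rng = np.random.default_rng(cfg.seed)
    tissue = make_tissue_map(cfg.shape, cfg.spacing)
    atlas = make_atlas(tissue)
    profile, mask = _place_lesions(cfg, tissue, atlas, cfg.n_lesions, rng)
    vol = _render(cfg, tissue, profile, rng)
    return vol, LesionMask(mask, cfg.spacing), tissue, atlas


def make_longitudinal_truth(
    cfg: PhantomConfig, n_new: int
) -> Tuple[Volume, Volume, LesionMask]:
    """Ground-truth longitudinal pair: tp2 = tp1 + ``n_new`` extra lesions.

    Shared lesions are identical across time-points (same blob profiles);
    the two volumes differ by independent noise draws plus the new lesions.
    ``new_mask`` marks exactly the added components.
    """
    if n_new < 0:
        raise ValueError("n_new must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    tissue = make_tissue_map(cfg.shape, cfg.spacing)
    atlas = make_atlas(tissue)
    base_profile, base_mask = _place_lesions(cfg, tissue, atlas, cfg.n_lesions, rng)
    occupied = ndimage.binary_dilation(base_mask > 0, STRUCT_26, iterations=2)
    new_profile, new_mask = _place_lesions(cfg, tissue, atlas, n_new, rng,
                                           forbidden=occupied)
    tp1 = _render(cfg, tissue, base_profile, rng)
    tp2 = _render(cfg, tissue, np.maximum(base_profile, new_profile), rng)
    return tp1, tp2, LesionMask(new_mask, cfg.spacing)


def count_components(mask: np.ndarray) -> int:
    """Number of 26-connected components."""
    _, n = ndimage.label(np.asarray(mask) > 0, structure=STRUCT_26)
    return int(n)


def sample_atlas_sites(
    atlas: LesionAtlas, n: int, rng: np.random.Generator
) -> List[Tuple[int, int, int]]:
    """Draw n voxel coordinates i.i.d. proportional to the atlas."""
    idx = np.flatnonzero(atlas.data)
    p = atlas.data.flat[idx]
    p = p / p.sum()
    flat = rng.choice(idx, size=n, p=p)
    return [tuple(int(c) for c in np.unravel_index(f, atlas.shape)) for f in flat]
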
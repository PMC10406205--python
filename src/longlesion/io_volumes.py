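"""NIfTI volume and mask I/O, grid bookkeeping, and 3D patch extraction.

The package works on preprocessed, co-registered 3D FLAIR volumes and binary
lesion masks.  Axis order is (sagittal, coronal, axial): the axial direction
is the last axis.  Coordinates are 0-based voxel indices and patches are
half-open boxes ``[c - s//2, c - s//2 + s)``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Tuple

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "LesionMask",
    "PatchSpec",
    "GridMismatchError",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "extract_patch",
    "insert_patch",
]

#: tolerance (mm) under which two voxel spacings count as the same grid
SPACING_TOL_MM = 1e-3


class GridMismatchError(ValueError):
    """Raised when two images expected on the same voxel grid differ."""


@dataclasses.dataclass
class Volume:
    """A 3D scalar image with its voxel spacing.

    Parameters
    ----------
    data:
        3D array of intensities, axis order (sagittal, coronal, axial).
    spacing:
        Per-axis voxel size in mm, all positive.
    space:
        ``"native"`` or ``"template"``; documents (but does not enforce)
        whether the image has been registered to a standard template.
    affine:
        Optional 4x4 voxel-to-world matrix, propagated unchanged on save.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    space: str = "native"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.space not in ("native", "template"):
            raise ValueError(f"space must be 'native' or 'template', got {self.space!r}")
        n_bad = int(np.size(self.data) - np.isfinite(self.data).sum())
        if n_bad:
            raise ValueError(f"volume contains {n_bad} non-finite voxels")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "Volume | LesionMask", tol: float = SPACING_TOL_MM) -> bool:
        return self.shape == other.shape and all(
            abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing)
        )

    def with_data(self, data: np.ndarray) -> "Volume":
        """Same grid and metadata, new voxel data."""
        return Volume(data, self.spacing, self.space, self.affine)


@dataclasses.dataclass
class LesionMask:
    """A binary lesion mask on the same grid as its companion Volume."""

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.data.ndim}D")
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be 0/1, found {vals[:8]}")
        self.data = self.data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def with_data(self, data: np.ndarray) -> "LesionMask":
        return LesionMask(data, self.spacing, self.affine)


@dataclasses.dataclass(frozen=True)
class PatchSpec:
    """A patch location: integer center voxel and edge lengths in voxels."""

    center: Tuple[int, int, int]
    size: Tuple[int, int, int] = (64, 64, 64)

    def __post_init__(self) -> None:
        if len(self.center) != 3 or len(self.size) != 3:
            raise ValueError("center and size must be voxel triples")
        if any(s < 1 for s in self.size):
            raise ValueError(f"patch size components must be >= 1, got {self.size}")

    @property
    def start(self) -> Tuple[int, int, int]:
        return tuple(int(c) - int(s) // 2 for c, s in zip(self.center, self.size))

    @property
    def stop(self) -> Tuple[int, int, int]:
        return tuple(a + int(s) for a, s in zip(self.start, self.size))


def _spacing_from_header(img: nib.Nifti1Image) -> Tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def load_volume(path: str | Path) -> Volume:
    """Load a 3D NIfTI volume as float32.

    Raises on missing files, non-3D images and non-finite voxels (the error
    names the number of voxels affected).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    elif data.ndim != 3:
        raise ValueError(f"expected 3D image, got {data.ndim}D with shape {data.shape}")
    data = np.ascontiguousarray(data, dtype=np.float32)
    n_bad = int(data.size - np.isfinite(data).sum())
    if n_bad:
        raise ValueError(f"{path} contains {n_bad} non-finite voxels")
    return Volume(data, _spacing_from_header(img), affine=img.affine)


def save_volume(vol: Volume, path: str | Path) -> None:
    """Write a Volume as float32 NIfTI, propagating the affine unchanged."""
    affine = vol.affine if vol.affine is not None else np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def load_mask(path: str | Path, reference: Volume) -> LesionMask:
    """Load a lesion mask and check it shares the reference grid.

    Values are binarized at 0.5 so probabilistic masks are accepted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    elif data.ndim != 3:
        raise ValueError(f"expected 3D mask, got {data.ndim}D")
    if data.size == 0:
        raise ValueError(f"{path} is empty")
    spacing = _spacing_from_header(img)
    if data.shape != reference.shape:
        raise GridMismatchError(
            f"mask shape {data.shape} does not match reference {reference.shape}"
        )
    if any(abs(a - b) > SPACING_TOL_MM for a, b in zip(spacing, reference.spacing)):
        raise GridMismatchError(
            f"mask spacing {spacing} does not match reference {reference.spacing} "
            f"within {SPACING_TOL_MM} mm"
        )
    return LesionMask((data > 0.5).astype(np.uint8), spacing, affine=img.affine)


def save_mask(mask: LesionMask, path: str | Path) -> None:
    """Write a mask as uint8 NIfTI."""
    affine = mask.affine if mask.affine is not None else np.diag(list(mask.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(mask.data, dtype=np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def _overlap_slices(spec: PatchSpec, shape: Tuple[int, int, int]):
    """Per-axis (source slice, destination slice) for the in-bounds region."""
    src, dst = [], []
    for a in range(3):
        lo, hi = spec.start[a], spec.stop[a]
        s_lo, s_hi = max(lo, 0), min(hi, shape[a])
        src.append(slice(s_lo, max(s_hi, s_lo)))
        dst.append(slice(s_lo - lo, max(s_hi, s_lo) - lo))
    return tuple(src), tuple(dst)


def extract_patch(vol: Volume, spec: PatchSpec, pad_value: float = 0.0) -> Volume:
    """Extract a patch, padding out-of-bounds regions with ``pad_value``."""
    out = np.full(spec.size, pad_value, dtype=vol.data.dtype)
    src, dst = _overlap_slices(spec, vol.shape)
    out[dst] = vol.data[src]
    return Volume(out, vol.spacing, vol.space)


def insert_patch(vol: Volume, patch: np.ndarray | Volume, spec: PatchSpec) -> Volume:
    """Write the in-bounds region of ``patch`` back into a copy of ``vol``.

    Inverse of :func:`extract_patch` on the interior.
    """
    pdata = patch.data if isinstance(patch, Volume) else np.asarray(patch)
    if pdata.shape != tuple(spec.size):
        raise ValueError(f"patch shape {pdata.shape} != spec size {spec.size}")
    out = vol.data.copy()
    src, dst = _overlap_slices(spec, vol.shape)
    out[src] = pdata[dst]
    return vol.with_data(out)
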
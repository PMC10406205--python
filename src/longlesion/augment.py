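"""MRI quality-disparity augmentation.

Nine acquisition-artifact operators used to simulate scanner and protocol
variability during training: Gaussian blur, unsharp-mask edge enhancement,
axial subsampling distortion, anisotropic downsampling, additive Gaussian
noise, polynomial bias field, and three k-space artifacts (motion, spike,
ghosting).  A seeded sampler applies a random subset "on the fly" and logs
enough to replay the exact augmentation bitwise.

Intensities are assumed normalized to unit scale (noise SDs are fractions of
that scale).  All operators preserve grid shape and spacing and map finite
input to finite output.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .io_volumes import Volume

__all__ = [
    "AugmentationConfig",
    "gaussian_blur",
    "unsharp_mask",
    "axial_subsample_distortion",
    "anisotropic_downsample",
    "add_gaussian_noise",
    "bias_field",
    "n_bias_coefficients",
    "kspace_artifact",
    "random_augment",
    "replay_augment",
    "OPERATOR_NAMES",
]

OPERATOR_NAMES = (
    "blur",
    "unsharp",
    "axial_subsample",
    "downsample",
    "bias",
    "motion",
    "spike",
    "ghost",
    "noise",
)

# spatial-domain operators run before k-space artifacts; noise is added last,
# mimicking the acquisition chain (tissue signal -> encoding -> receiver noise)
_APPLICATION_ORDER = OPERATOR_NAMES


@dataclasses.dataclass
class AugmentationConfig:
    """Parameter ranges and application probabilities for all nine operators."""

    blur_sd_range: Tuple[float, float] = (0.5, 1.75)  # voxels
    unsharp_sd_range: Tuple[float, float] = (0.5, 1.75)
    unsharp_amount_range: Tuple[float, float] = (0.5, 2.0)
    axial_filter_sizes: Tuple[int, ...] = (2, 3, 4)
    downsample_factor_range: Tuple[float, float] = (1.5, 4.0)
    noise_sd_range: Tuple[float, float] = (0.02, 0.1)
    bias_order: int = 3
    bias_coeff_range: Tuple[float, float] = (-0.3, 0.3)
    motion_rotation_range: Tuple[float, float] = (-5.0, 5.0)  # degrees
    motion_translation_range: Tuple[float, float] = (-4.0, 4.0)  # mm
    motion_n_transforms: int = 2
    spike_rel_magnitude_range: Tuple[float, float] = (0.05, 0.2)  # fraction of |DC|
    ghost_period_range: Tuple[int, int] = (2, 4)
    ghost_attenuation_range: Tuple[float, float] = (0.2, 0.8)
    probabilities: Dict[str, float] | None = None  # default: 1/9 each
    max_ops: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.probabilities is None:
            self.probabilities = {name: 1.0 / 9.0 for name in OPERATOR_NAMES}
        unknown = set(self.probabilities) - set(OPERATOR_NAMES)
        if unknown:
            raise ValueError(f"unknown operators in probabilities: {sorted(unknown)}")
        for name in OPERATOR_NAMES:
            self.probabilities.setdefault(name, 0.0)
        if any(not (0 <= p <= 1) for p in self.probabilities.values()):
            raise ValueError("application probabilities must lie in [0, 1]")
        if set(self.axial_filter_sizes) - {2, 3, 4}:
            raise ValueError("axial filter sizes must be from {2, 3, 4}")


# ---------------------------------------------------------------------------
# spatial-domain operators


def gaussian_blur(vol: Volume, sd: float) -> Volume:
    """Isotropic Gaussian blur; ``sd`` in voxel units, reflective boundaries."""
    if sd < 0:
        raise ValueError(f"blur SD must be >= 0, got {sd}")
    if sd == 0:
        return vol.with_data(vol.data.copy())
    out = ndimage.gaussian_filter(vol.data.astype(np.float64), sigma=sd, mode="reflect")
    return vol.with_data(out.astype(vol.data.dtype))


def unsharp_mask(vol: Volume, sd: float, amount: float) -> Volume:
    """Edge enhancement: vol + amount * (vol - blur(vol, sd))."""
    if amount == 0:
        return vol.with_data(vol.data.copy())
    blurred = gaussian_blur(vol, sd).data.astype(np.float64)
    out = vol.data.astype(np.float64) + amount * (vol.data - blurred)
    return vol.with_data(out.astype(vol.data.dtype))


def axial_subsample_distortion(vol: Volume, sz: int) -> Volume:
    """Mean filter of length ``sz`` along the axial (last) axis.

    Simulates thick-slice acquisition: each output voxel is the mean of
    ``sz`` consecutive axial neighbors, with edge replication.
    """
    if sz not in (2, 3, 4):
        raise ValueError(f"axial filter size must be in {{2, 3, 4}}, got {sz}")
    pad_l, pad_r = (sz - 1) // 2, sz // 2
    x = np.pad(vol.data.astype(np.float64), ((0, 0), (0, 0), (pad_l, pad_r)), mode="edge")
    win = np.lib.stride_tricks.sliding_window_view(x, sz, axis=2)
    out = win.mean(axis=-1)
    return vol.with_data(out.astype(vol.data.dtype))


def anisotropic_downsample(vol: Volume, axis: int, factor: float) -> Volume:
    """Downsample along one axis by ``factor`` and cubic-B-spline upsample back.

    Emulates low through-plane resolution: high-frequency content along the
    axis is attenuated while the grid is unchanged.
    """
    if factor < 1:
        raise ValueError(f"downsample factor must be >= 1, got {factor}")
    if factor == 1:
        return vol.with_data(vol.data.copy())
    shape = vol.data.shape
    small = list(shape)
    small[axis] = max(1, int(round(shape[axis] / factor)))
    x = vol.data.astype(np.float64)
    down = _sk_resize(x, small, order=3, mode="edge", anti_aliasing=True,
                      preserve_range=True)
    up = _sk_resize(down, shape, order=3, mode="edge", anti_aliasing=False,
                    preserve_range=True)
    return vol.with_data(up.astype(vol.data.dtype))


def add_gaussian_noise(vol: Volume, sd: float, rng: np.random.Generator) -> Volume:
    """Additive zero-mean Gaussian noise with standard deviation ``sd``."""
    if sd < 0:
        raise ValueError("noise SD must be >= 0")
    if sd == 0:
        return vol.with_data(vol.data.copy())
    out = vol.data.astype(np.float64) + rng.normal(0.0, sd, size=vol.data.shape)
    return vol.with_data(out.astype(vol.data.dtype))


def n_bias_coefficients(order: int) -> int:
    """Number of 3D monomials x^a y^b z^c with a + b + c <= order."""
    return math.comb(order + 3, 3)


def _bias_basis(shape: Tuple[int, int, int], order: int) -> List[np.ndarray]:
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    basis = []
    for total in range(order + 1):
        for a in range(total + 1):
            for b in range(total - a + 1):
                c = total - a - b
                basis.append(xx**a * yy**b * zz**c)
    return basis


def bias_field(vol: Volume, coeffs: Sequence[float], order: int) -> Volume:
    """Multiplicative smooth inhomogeneity exp(sum_k c_k phi_k(x)).

    The basis phi_k is the set of 3D monomials of total degree <= ``order``
    over coordinates scaled to [-1, 1], ordered by (total degree, then
    lexicographic exponents).
    """
    basis = _bias_basis(vol.data.shape, order)
    if len(coeffs) != len(basis):
        raise ValueError(
            f"expected {len(basis)} coefficients for order {order}, got {len(coeffs)}"
        )
    log_field = np.zeros(vol.data.shape, dtype=np.float64)
    for c, phi in zip(coeffs, basis):
        if c:
            log_field += c * phi
    out = vol.data.astype(np.float64) * np.exp(log_field)
    return vol.with_data(out.astype(vol.data.dtype))


# ---------------------------------------------------------------------------
# k-space operators


def _rotation_matrix(angles_deg: Sequence[float]) -> np.ndarray:
    ax, ay, az = np.deg2rad(angles_deg)
    rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]])
    rz = np.array([[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]])
    return rz @ ry @ rx


def _affine_copy(data: np.ndarray, angles_deg, translation_mm, spacing) -> np.ndarray:
    rot = _rotation_matrix(angles_deg)
    center = (np.asarray(data.shape) - 1) / 2.0
    shift_vox = np.asarray(translation_mm, dtype=np.float64) / np.asarray(spacing)
    # pull transform: offset maps output coords to input coords
    offset = center - rot @ center - rot @ shift_vox
    return ndimage.affine_transform(data, rot, offset=offset, order=1, mode="nearest")


def _motion(vol: Volume, params: dict) -> Volume:
    """Motion: k-space composed from FFTs of affinely transformed copies.

    The frequency axis 1 (phase-encoding) is partitioned into one contiguous
    block per transform; block j is taken from the FFT of copy j.
    """
    transforms = params["transforms"]  # list of {rotation_deg, translation_mm}
    n = len(transforms)
    if n == 0:
        return vol.with_data(vol.data.copy())
    x = vol.data.astype(np.float64)
    k_out = np.empty(x.shape, dtype=np.complex128)
    bounds = np.linspace(0, x.shape[1], n + 1).astype(int)
    for j, t in enumerate(transforms):
        rot = np.asarray(t["rotation_deg"], dtype=float)
        tra = np.asarray(t["translation_mm"], dtype=float)
        if np.all(rot == 0) and np.all(tra == 0):
            moved = x
        else:
            moved = _affine_copy(x, rot, tra, vol.spacing)
        k = np.fft.fftn(moved)
        sl = slice(bounds[j], bounds[j + 1])
        k_out[:, sl, :] = np.fft.fftshift(k, axes=1)[:, sl, :]
    out = np.fft.ifftn(np.fft.ifftshift(k_out, axes=1)).real
    return vol.with_data(out.astype(vol.data.dtype))


def _spike(vol: Volume, params: dict) -> Volume:
    """Add high-magnitude point(s) in k-space (herring-bone artifact)."""
    positions = params["positions"]  # unshifted k-space indices
    magnitudes = params["magnitudes"]  # absolute complex magnitude added
    phases = params.get("phases", [0.0] * len(positions))
    k = np.fft.fftn(vol.data.astype(np.float64))
    for pos, mag, ph in zip(positions, magnitudes, phases):
        k[tuple(int(p) % s for p, s in zip(pos, vol.data.shape))] += mag * np.exp(1j * ph)
    out = np.fft.ifftn(k).real
    return vol.with_data(out.astype(vol.data.dtype))


def _ghost(vol: Volume, params: dict) -> Volume:
    """Attenuate every k-th k-space plane along one axis -> displaced replicas.

    The DC plane (index 0) is never attenuated, so mean intensity is kept.
    """
    axis = int(params["axis"])
    period = int(params["period"])
    attenuation = float(params["attenuation"])
    if period < 2:
        raise ValueError("ghost period must be >= 2")
    if attenuation == 0:
        return vol.with_data(vol.data.copy())
    k = np.fft.fftn(vol.data.astype(np.float64))
    idx = np.arange(vol.data.shape[axis])
    sel = (idx % period == 0) & (idx != 0)
    slicer = [slice(None)] * 3
    slicer[axis] = sel
    k[tuple(slicer)] *= 1.0 - attenuation
    out = np.fft.ifftn(k).real
    return vol.with_data(out.astype(vol.data.dtype))


_KSPACE_KINDS = {"motion": _motion, "spike": _spike, "ghost": _ghost}


def kspace_artifact(vol: Volume, kind: str, params: dict) -> Volume:
    """Apply a k-space artifact of the given ``kind`` (motion, spike, ghost)."""
    try:
        fn = _KSPACE_KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown k-space artifact kind {kind!r}; "
                         f"expected one of {sorted(_KSPACE_KINDS)}") from None
    return fn(vol, params)


# ---------------------------------------------------------------------------
# random sampler


def _draw_params(name: str, cfg: AugmentationConfig, vol: Volume,
                 rng: np.random.Generator) -> dict:
    if name == "blur":
        return {"sd": float(rng.uniform(*cfg.blur_sd_range))}
    if name == "unsharp":
        return {"sd": float(rng.uniform(*cfg.unsharp_sd_range)),
                "amount": float(rng.uniform(*cfg.unsharp_amount_range))}
    if name == "axial_subsample":
        return {"sz": int(rng.choice(cfg.axial_filter_sizes))}
    if name == "downsample":
        return {"axis": int(rng.integers(0, 3)),
                "factor": float(rng.uniform(*cfg.downsample_factor_range))}
    if name == "noise":
        return {"sd": float(rng.uniform(*cfg.noise_sd_range)),
                "noise_seed": int(rng.integers(0, 2**31))}
    if name == "bias":
        n = n_bias_coefficients(cfg.bias_order)
        return {"order": int(cfg.bias_order),
                "coeffs": [float(c) for c in rng.uniform(*cfg.bias_coeff_range, size=n)]}
    if name == "motion":
        transforms = []
        for _ in range(cfg.motion_n_transforms):
            transforms.append({
                "rotation_deg": [float(r) for r in
                                 rng.uniform(*cfg.motion_rotation_range, size=3)],
                "translation_mm": [float(t) for t in
                                   rng.uniform(*cfg.motion_translation_range, size=3)],
            })
        return {"transforms": transforms}
    if name == "spike":
        shape = vol.data.shape
        dc = float(np.abs(np.fft.fftn(vol.data.astype(np.float64)).flat[0])) or 1.0
        pos = [int(rng.integers(1, s)) for s in shape]
        mag = float(rng.uniform(*cfg.spike_rel_magnitude_range)) * dc
        return {"positions": [pos], "magnitudes": [mag],
                "phases": [float(rng.uniform(0, 2 * np.pi))]}
    if name == "ghost":
        return {"axis": int(rng.integers(0, 3)),
                "period": int(rng.integers(cfg.ghost_period_range[0],
                                           cfg.ghost_period_range[1] + 1)),
                "attenuation": float(rng.uniform(*cfg.ghost_attenuation_range))}
    raise ValueError(f"unknown operator {name!r}")


def _apply(name: str, vol: Volume, params: dict) -> Volume:
    if name == "blur":
        return gaussian_blur(vol, params["sd"])
    if name == "unsharp":
        return unsharp_mask(vol, params["sd"], params["amount"])
    if name == "axial_subsample":
        return axial_subsample_distortion(vol, params["sz"])
    if name == "downsample":
        return anisotropic_downsample(vol, params["axis"], params["factor"])
    if name == "noise":
        return add_gaussian_noise(vol, params["sd"],
                                  np.random.default_rng(params["noise_seed"]))
    if name == "bias":
        return bias_field(vol, params["coeffs"], params["order"])
    if name in _KSPACE_KINDS:
        return kspace_artifact(vol, name, params)
    raise ValueError(f"unknown operator {name!r}")


def random_augment(
    vol: Volume, cfg: AugmentationConfig, rng: np.random.Generator
) -> Tuple[Volume, List[dict]]:
    """Apply each operator with its configured probability; return (volume, log).

    At most ``cfg.max_ops`` operators fire per draw (a uniformly chosen
    subset is kept when more fire).  The log records operator order and
    exact parameters; :func:`replay_augment` reproduces the output bitwise.
    """
    fired = [name for name in _APPLICATION_ORDER
             if rng.random() < cfg.probabilities[name]]
    if len(fired) > cfg.max_ops:
        keep = sorted(rng.choice(len(fired), size=cfg.max_ops, replace=False))
        fired = [fired[i] for i in keep]
    log: List[dict] = []
    out = vol
    for name in fired:
        params = _draw_params(name, cfg, out, rng)
        out = _apply(name, out, params)
        log.append({"name": name, "params": params})
    if not fired:
        out = vol.with_data(vol.data.copy())
    return out, log


def replay_augment(vol: Volume, log: List[dict]) -> Volume:
    """Re-apply a logged augmentation; bitwise-identical to the original run."""
    out = vol
    for entry in log:
        out = _apply(entry["name"], out, entry["params"])
    if not log:
        out = vol.with_data(vol.data.copy())
    return out
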
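"""Cohort-median-spacing resampling and patch z-score normalization."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .dataio import VolumeGrid

__all__ = ["median_spacing", "resample_to_spacing", "zscore"]


def median_spacing(spacings) -> tuple[float, float, float]:
    """Per-axis median voxel spacing over a cohort.

    For an even count the lower of the two central values is taken, so the
    target is always an observed spacing.
    """
    arr = np.asarray(list(spacings), dtype=float)
    if arr.size == 0:
        raise ValueError("empty dataset")
    arr = arr.reshape(-1, 3)
    if np.any(arr <= 0):
        raise ValueError("spacings must be strictly positive")
    med = np.sort(arr, axis=0)[(arr.shape[0] - 1) // 2]
    return tuple(float(v) for v in med)


def resample_to_spacing(
    vol: VolumeGrid,
    target: tuple[float, float, float],
    interp: str = "linear",
) -> VolumeGrid:
    """Resample a volume to a new voxel spacing, preserving world positions.

    New shape per axis is round(old_shape * old_spacing / new_spacing);
    ``interp`` is "linear" for images, "nearest" for masks.
    """
    target = np.asarray(target, dtype=float)
    if target.shape != (3,) or np.any(target <= 0):
        raise ValueError(f"target spacing must be 3 positive values, got {target}")
    if interp not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interp!r}")
    old_spacing = vol.spacing
    scale = target / old_spacing  # new-voxel step in old-voxel units
    new_shape = np.maximum(1, np.rint(np.array(vol.shape) * old_spacing / target)).astype(int)
    # new affine scales the direction columns so column norms equal `target`
    new_affine = vol.affine.copy()
    new_affine[:3, :3] = vol.affine[:3, :3] @ np.diag(scale)
    order = 1 if interp == "linear" else 0
    data = vol.data.astype(np.float32 if order else vol.data.dtype)
    out = ndimage.affine_transform(
        data,
        np.diag(scale),
        offset=0.0,
        output_shape=tuple(new_shape),
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    if interp == "nearest":
        out = out.astype(vol.data.dtype)
    return VolumeGrid(out, new_affine)


def zscore(patch: np.ndarray) -> np.ndarray:
    """Zero-mean, unit population-std normalization; constant input -> zeros."""
    patch = np.asarray(patch, dtype=np.float64)
    sd = patch.std()
    if sd == 0:
        return np.zeros_like(patch)
    return (patch - patch.mean()) / sd
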
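"""Weak spherical labels and mask geometry.

A weak label is a sphere (world-mm centre + radius) that encloses the whole
lesion; a voxel-wise mask is "weakened" by replacing it with its
centroid-centred enclosing sphere. Mask geometry (centroid, maximum
diameter) feeds both patch sampling and the detection hit criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import VolumeGrid

__all__ = ["SphereLabel", "MaskStats", "mask_stats", "weaken_mask",
           "make_weak_label", "write_sphere_table", "read_sphere_table"]


@dataclass(frozen=True)
class SphereLabel:
    """World-space sphere: centre in mm, radius in mm."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("sphere radius must be > 0")


@dataclass(frozen=True)
class MaskStats:
    centroid: tuple[float, float, float]
    max_diameter: float  # mm, 3D Feret diameter over voxel centres
    voxel_count: int


def _foreground_world(mask: VolumeGrid) -> np.ndarray:
    fg = np.argwhere(mask.data > 0)
    if fg.shape[0] == 0:
        raise ValueError("mask is empty")
    return mask.voxel_to_world(fg.astype(float)).reshape(-1, 3)

_MAX_DIAMETER_VOXELS = 20000


def mask_stats(mask: VolumeGrid) -> MaskStats:
    """Centroid (mean foreground world position) and max pairwise distance.

    The diameter is a brute-force O(n^2) pairwise scan over foreground voxel
    centres; lesion masks are small, so this doubles as its own oracle.
    """
    pts = _foreground_world(mask)
    centroid = pts.mean(axis=0)
    n = pts.shape[0]
    if n > _MAX_DIAMETER_VOXELS:
        raise ValueError(f"mask too large for pairwise diameter scan ({n} voxels)")
    # pairwise in blocks to bound memory
    max_d2 = 0.0
    block = 2000
    for i in range(0, n, block):
        d2 = ((pts[i:i + block, None, :] - pts[None, :, :]) ** 2).sum(-1)
        max_d2 = max(max_d2, float(d2.max()))
    return MaskStats(tuple(centroid), float(np.sqrt(max_d2)), int(n))


def weaken_mask(mask: VolumeGrid, margin: float = 0.0) -> tuple[SphereLabel, VolumeGrid]:
    """Replace a voxel-wise mask by its enclosing sphere.

    Centre = mask centroid; radius = max centroid-to-foreground-voxel-centre
    distance + margin. With margin >= half the voxel diagonal the raster is
    guaranteed to cover the original mask.
    """
    pts = _foreground_world(mask)
    centroid = pts.mean(axis=0)
    rmax = float(np.sqrt(((pts - centroid) ** 2).sum(-1).max()))
    radius = rmax + float(margin)
    if radius <= 0:
        # single-voxel mask with zero margin: use a tiny positive radius so
        # the sphere still rasterizes to that voxel
        radius = min(mask.spacing) * 1e-3
    sphere = SphereLabel(tuple(centroid), radius)
    return sphere, make_weak_label(sphere, mask)


def make_weak_label(sphere: SphereLabel, grid: VolumeGrid) -> VolumeGrid:
    """Rasterize a sphere: voxel is foreground iff its centre is inside."""
    center_vox = grid.world_to_voxel(np.asarray(sphere.center))
    pad = sphere.radius / grid.spacing + 1.5
    lo = np.maximum(0, np.floor(center_vox - pad)).astype(int)
    hi = np.minimum(np.array(grid.shape), np.ceil(center_vox + pad) + 1).astype(int)
    if np.any(lo >= hi):
        raise ValueError("sphere lies entirely outside the grid")
    idx = np.stack(np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                               indexing="ij"), axis=-1).reshape(-1, 3)
    world = grid.voxel_to_world(idx.astype(float)).reshape(-1, 3)
    inside = ((world - np.asarray(sphere.center)) ** 2).sum(-1) <= sphere.radius ** 2
    out = np.zeros(grid.shape, dtype=np.uint8)
    sel = idx[inside]
    out[sel[:, 0], sel[:, 1], sel[:, 2]] = 1
    if not inside.any():
        raise ValueError("sphere does not cover any voxel centre of the grid")
    return grid.like(out)


def write_sphere_table(rows: list[dict], path: str | Path) -> None:
    """TSV sidecar: subject, lesion id, centre x/y/z mm, radius mm."""
    df = pd.DataFrame(rows, columns=["subject", "lesion", "x", "y", "z", "radius"])
    df.to_csv(path, sep="\t", index=False)


def read_sphere_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
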
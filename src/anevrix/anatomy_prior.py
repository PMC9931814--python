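"""Landmark handling and anatomically-informed training-patch sampling.

Negative patches are drawn at landmark points and on hyperintense (vessel)
voxels so that most negatives match positives in average intensity; a small
quota is sampled uniformly at random. Every negative is rejection-sampled
to be disjoint from the lesion mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .dataio import VolumeGrid

__all__ = ["LandmarkSet", "PatchSample", "map_landmarks",
           "sample_positive_patches", "sample_negative_patches", "augment_patch"]

_AUG_OPS = ("rot90", "rot180", "rot270", "flip_h", "flip_v",
            "contrast", "gamma", "gauss_noise")


@dataclass
class LandmarkSet:
    """Named world-mm points (default registry size: 20)."""

    names: list[str]
    points: np.ndarray  # (N, 3) world mm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.names) != self.points.shape[0]:
            raise ValueError("names/points length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("landmark names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"name": self.names,
                      "x": self.points[:, 0],
                      "y": self.points[:, 1],
                      "z": self.points[:, 2]}).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LandmarkSet":
        df = pd.read_csv(path, sep="\t")
        return cls(list(df["name"]), df[["x", "y", "z"]].to_numpy(float))


@dataclass
class PatchSample:
    intensities: np.ndarray  # (side, side, side)
    label: np.ndarray        # (side, side, side) binary
    provenance: str          # positive | landmark_negative | vessel_negative | random_negative
    offset: tuple[int, int, int]  # minimum corner, half-open window

    def __post_init__(self) -> None:
        if self.intensities.shape != self.label.shape:
            raise ValueError("intensity/label shape mismatch")
        s = self.intensities.shape
        if not (s[0] == s[1] == s[2]):
            raise ValueError("patch must be cubic")
        positive = bool(self.label.any())
        if (self.provenance == "positive") != positive:
            raise ValueError("provenance=positive iff label nonempty")

    @property
    def side(self) -> int:
        return self.intensities.shape[0]


def map_landmarks(atlas_points: LandmarkSet, transform: np.ndarray) -> LandmarkSet:
    """Map landmark points through a 4x4 affine (atlas -> subject space)."""
    transform = np.asarray(transform, dtype=float)
    if transform.shape != (4, 4) or abs(np.linalg.det(transform[:3, :3])) < 1e-12:
        raise ValueError("transform must be an invertible 4x4 affine")
    pts = atlas_points.points @ transform[:3, :3].T + transform[:3, 3]
    return LandmarkSet(list(atlas_points.names), pts)


def _pad_to_side(image: np.ndarray, mask: np.ndarray, side: int):
    """Symmetric zero-pad so every axis is at least ``side`` long."""
    pads = []
    for dim in image.shape:
        deficit = max(0, side - dim)
        pads.append((deficit // 2, deficit - deficit // 2))
    if any(p != (0, 0) for p in pads):
        image = np.pad(image, pads)
        mask = np.pad(mask, pads)
    return image, mask


def _extract(image, mask, offset, side):
    sl = tuple(slice(o, o + side) for o in offset)
    return image[sl], mask[sl]


def sample_positive_patches(
    image: VolumeGrid,
    lesion_mask: VolumeGrid,
    n_per_lesion: int = 8,
    side: int = 64,
    seed: int = 0,
) -> list[PatchSample]:
    """Non-centred positive patches, ``n_per_lesion`` per connected lesion.

    Each patch fully contains its lesion's bounding box; the offset is
    jittered uniformly over all positions satisfying containment (clamped
    to the volume).
    """
    img, msk = _pad_to_side(np.asarray(image.data), np.asarray(lesion_mask.data) > 0, side)
    labels, n_lesions = ndimage.label(msk, structure=np.ones((3, 3, 3), dtype=int))
    if n_lesions == 0:
        raise ValueError("lesion mask is empty")
    rng = np.random.default_rng(seed)
    out: list[PatchSample] = []
    shape = np.array(img.shape)
    for lesion in range(1, n_lesions + 1):
        fg = np.argwhere(labels == lesion)
        bb_min, bb_max = fg.min(axis=0), fg.max(axis=0)
        if np.any(bb_max - bb_min + 1 > side):
            raise ValueError(f"lesion {lesion} bounding box exceeds patch side {side}")
        lo = np.maximum(0, bb_max + 1 - side)
        hi = np.minimum(shape - side, bb_min)
        for _ in range(n_per_lesion):
            offset = tuple(int(rng.integers(l, h + 1)) for l, h in zip(lo, hi))
            pi, pm = _extract(img, labels == lesion, offset, side)
            out.append(PatchSample(pi.copy(), pm.astype(np.uint8), "positive", offset))
    return out


def sample_negative_patches(
    image: VolumeGrid,
    lesion_mask: VolumeGrid | None,
    landmarks: LandmarkSet | None,
    counts: tuple[int, int, int] = (20, 20, 10),
    side: int = 64,
    seed: int = 0,
    vessel_percentile: float = 90.0,
    max_retries: int = 200,
) -> list[PatchSample]:
    """Negative patches: (landmark, vessel, random) = ``counts`` per volume.

    Landmark negatives are centred on landmark points (drawn with
    replacement when there are fewer landmarks than requested patches);
    vessel negatives are centred on voxels above the ``vessel_percentile``
    of nonzero intensities; random negatives are uniform. All are rejected
    until disjoint from the lesion mask.
    """
    n_lm, n_vessel, n_random = counts
    if n_lm > 0 and (landmarks is None or len(landmarks) == 0):
        raise ValueError("landmark negatives requested but landmark set is empty")
    raw_mask = np.zeros(image.shape, bool) if lesion_mask is None \
        else np.asarray(lesion_mask.data) > 0
    img, msk = _pad_to_side(np.asarray(image.data), raw_mask, side)
    pad_shift = np.array([(s2 - s1) // 2 for s1, s2 in zip(image.shape, img.shape)])
    rng = np.random.default_rng(seed)
    shape = np.array(img.shape)
    out: list[PatchSample] = []

    def clamp_center(center_vox):
        offset = np.rint(np.asarray(center_vox) - side / 2).astype(int)
        return np.clip(offset, 0, shape - side)

    def try_emit(offset, provenance) -> bool:
        pi, pm = _extract(img, msk, tuple(int(o) for o in offset), side)
        if pm.any():
            return False
        out.append(PatchSample(pi.copy(), np.zeros_like(pi, dtype=np.uint8),
                               provenance, tuple(int(o) for o in offset)))
        return True

    # landmark-centred negatives
    if n_lm > 0:
        lm_vox = image.world_to_voxel(landmarks.points).reshape(-1, 3) + pad_shift
        emitted = 0
        for attempt in range(max_retries * max(1, n_lm)):
            if emitted == n_lm:
                break
            center = lm_vox[int(rng.integers(len(lm_vox)))]
            jitter = rng.integers(-2, 3, size=3) if attempt >= n_lm else 0
            if try_emit(clamp_center(center + jitter), "landmark_negative"):
                emitted += 1
        if emitted < n_lm:
            raise RuntimeError("could not find lesion-free landmark negatives")

    # vessel-intensity negatives
    if n_vessel > 0:
        nonzero = img[img > 0]
        if nonzero.size == 0:
            raise RuntimeError("image has no nonzero voxels for vessel negatives")
        thr = np.percentile(nonzero, vessel_percentile)
        cand = np.argwhere(img > thr)
        emitted = 0
        for _ in range(max_retries * max(1, n_vessel)):
            if emitted == n_vessel:
                break
            center = cand[int(rng.integers(len(cand)))]
            if try_emit(clamp_center(center), "vessel_negative"):
                emitted += 1
        if emitted < n_vessel:
            raise RuntimeError("could not find lesion-free vessel negatives")

    # uniform random negatives
    emitted = 0
    for _ in range(max_retries * max(1, n_random)):
        if emitted == n_random:
            break
        offset = tuple(int(rng.integers(0, d - side + 1)) for d in shape)
        if try_emit(offset, "random_negative"):
            emitted += 1
    if emitted < n_random:
        raise RuntimeError("could not find lesion-free random negatives")
    return out


def augment_patch(p: PatchSample, ops, seed: int = 0) -> PatchSample:
    """Apply augmentations; geometric ops act on intensities and label alike.

    Rotations are about the axial (z) axis; flips are in-plane. Intensity
    ops (contrast, gamma, gauss_noise) touch only the intensities.
    """
    rng = np.random.default_rng(seed)
    img = np.asarray(p.intensities, dtype=np.float64).copy()
    lab = p.label.copy()
    for op in ops:
        if op not in _AUG_OPS:
            raise ValueError(f"unknown augmentation op {op!r}")
        if op in ("rot90", "rot180", "rot270"):
            k = {"rot90": 1, "rot180": 2, "rot270": 3}[op]
            img = np.rot90(img, k=k, axes=(0, 1))
            lab = np.rot90(lab, k=k, axes=(0, 1))
        elif op == "flip_h":
            img, lab = np.flip(img, axis=0), np.flip(lab, axis=0)
        elif op == "flip_v":
            img, lab = np.flip(img, axis=1), np.flip(lab, axis=1)
        elif op == "contrast":
            factor = float(rng.uniform(0.8, 1.2))
            img = img.mean() + factor * (img - img.mean())
        elif op == "gamma":
            exponent = float(rng.uniform(0.8, 1.2))
            lo, hi = img.min(), img.max()
            if hi > lo:
                img = lo + (hi - lo) * ((img - lo) / (hi - lo)) ** exponent
        elif op == "gauss_noise":
            sd = 0.05 * (img.std() or 1.0)
            img = img + rng.normal(0.0, sd, size=img.shape)
    return PatchSample(np.ascontiguousarray(img), np.ascontiguousarray(lab),
                       p.provenance, p.offset)


def augment_patch_param(p: PatchSample, op: str, value: float) -> PatchSample:
    """Deterministic single-op variant used for identity-parameter checks."""
    img = np.asarray(p.intensities, dtype=np.float64).copy()
    if op == "contrast":
        img = img.mean() + value * (img - img.mean())
    elif op == "gamma":
        lo, hi = img.min(), img.max()
        if hi > lo:
            img = lo + (hi - lo) * ((img - lo) / (hi - lo)) ** value
    else:
        raise ValueError(f"op {op!r} takes no parameter")
    return PatchSample(img, p.label.copy(), p.provenance, p.offset)
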
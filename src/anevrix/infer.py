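"""Anatomically-informed sliding-window inference.

Windows tile the volume with overlap; in anatomical mode only windows that
are both close to a landmark and sufficiently hyperintense are predicted.
Overlapping predictions are averaged with a coverage-count denominator,
optionally over six geometric test-time augmentations, and candidates are
the top-scoring connected components of the thresholded probability map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import ndimage

from .anatomy_prior import LandmarkSet
from .dataio import VolumeGrid
from .preprocess import zscore

__all__ = ["WindowSet", "Candidate", "enumerate_windows", "retain_anatomical",
           "predict_volume", "extract_candidates", "TTA_TRANSFORMS"]


@dataclass
class WindowSet:
    side: int
    stride: int
    offsets: list[tuple[int, int, int]]
    retained: list[bool] = field(default_factory=list)
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.retained:
            self.retained = [True] * len(self.offsets)
            self.reasons = ["all"] * len(self.offsets)

    def retained_offsets(self) -> list[tuple[int, int, int]]:
        return [o for o, r in zip(self.offsets, self.retained) if r]


@dataclass(frozen=True)
class Candidate:
    center: tuple[float, float, float]  # world mm, binary centre of mass
    score: float                        # peak probability in the component
    voxel_count: int


def enumerate_windows(shape, side: int = 64, stride: int = 32) -> WindowSet:
    """Half-open windows [o, o+side) tiling the grid with a clamped tail."""
    if side < 1 or stride < 1:
        raise ValueError("side and stride must be >= 1")
    axes = []
    for dim in shape:
        if dim < side:
            raise ValueError(f"dimension {dim} smaller than window side {side}")
        offs = list(range(0, dim - side + 1, stride))
        if offs[-1] != dim - side:
            offs.append(dim - side)
        axes.append(offs)
    offsets = [tuple(o) for o in product(*axes)]
    return WindowSet(side=side, stride=stride, offsets=offsets)


def retain_anatomical(
    ws: WindowSet,
    image: VolumeGrid,
    landmarks: LandmarkSet | None,
    max_landmark_dist: float = 64.0,
    intensity_min_voxels: int = 50,
    intensity_percentile: float = 90.0,
    agnostic: bool = False,
) -> WindowSet:
    """Filter windows by landmark proximity and an intensity criterion.

    A window passes iff its centre lies within ``max_landmark_dist`` mm of
    some landmark AND it contains at least ``intensity_min_voxels`` voxels
    above the ``intensity_percentile`` of in-brain (nonzero) intensities.
    Agnostic mode instead retains every window containing nonzero data.
    """
    data = np.asarray(image.data)
    side = ws.side
    retained: list[bool] = []
    reasons: list[str] = []
    if agnostic:
        for off in ws.offsets:
            sl = tuple(slice(o, o + side) for o in off)
            ok = bool(np.any(data[sl] != 0))
            retained.append(ok)
            reasons.append("nonzero-pass" if ok else "rejected")
        return WindowSet(side, ws.stride, list(ws.offsets), retained, reasons)
    if landmarks is None or len(landmarks) == 0:
        raise ValueError(
            "anatomical window retention needs landmarks; use agnostic=True instead")
    nonzero = data[data != 0]
    thr = np.percentile(nonzero, intensity_percentile) if nonzero.size else np.inf
    centers_vox = np.array(ws.offsets, dtype=float) + (side - 1) / 2.0
    centers_world = image.voxel_to_world(centers_vox).reshape(-1, 3)
    d2 = ((centers_world[:, None, :] - landmarks.points[None, :, :]) ** 2).sum(-1)
    near = np.sqrt(d2.min(axis=1)) <= max_landmark_dist
    for off, is_near in zip(ws.offsets, near):
        if not is_near:
            retained.append(False)
            reasons.append("rejected")
            continue
        sl = tuple(slice(o, o + side) for o in off)
        if int((data[sl] > thr).sum()) >= intensity_min_voxels:
            retained.append(True)
            reasons.append("landmark-pass,intensity-pass")
        else:
            retained.append(False)
            reasons.append("rejected")
    return WindowSet(side, ws.stride, list(ws.offsets), retained, reasons)


# the six geometric TTA transforms: (forward, inverse) acting on a 3D patch
TTA_TRANSFORMS = (
    ("identity", lambda a: a, lambda a: a),
    ("rot90", lambda a: np.rot90(a, 1, (0, 1)), lambda a: np.rot90(a, -1, (0, 1))),
    ("rot180", lambda a: np.rot90(a, 2, (0, 1)), lambda a: np.rot90(a, -2, (0, 1))),
    ("rot270", lambda a: np.rot90(a, 3, (0, 1)), lambda a: np.rot90(a, -3, (0, 1))),
    ("flip_h", lambda a: np.flip(a, 0), lambda a: np.flip(a, 0)),
    ("flip_v", lambda a: np.flip(a, 1), lambda a: np.flip(a, 1)),
)


def predict_volume(model, image: VolumeGrid, ws: WindowSet, tta: bool = True) -> VolumeGrid:
    """Predict retained windows and average overlaps into a probability map.

    ``model`` is any callable mapping a z-scored side^3 patch to a side^3
    probability patch (e.g. ``UNet3D.predict_patch``).
    """
    import warnings

    data = np.asarray(image.data, dtype=np.float32)
    acc = np.zeros(data.shape, dtype=np.float64)
    cov = np.zeros(data.shape, dtype=np.int32)
    side = ws.side
    offsets = ws.retained_offsets()
    if not offsets:
        warnings.warn("no retained windows; returning an all-zero probability map")
        return image.like(acc)
    predict = getattr(model, "predict_patch", model)
    for off in offsets:
        sl = tuple(slice(o, o + side) for o in off)
        patch = zscore(data[sl]).astype(np.float32)
        if tta:
            preds = []
            for _, fwd, inv in TTA_TRANSFORMS:
                p = predict(np.ascontiguousarray(fwd(patch)))
                preds.append(inv(np.asarray(p)))
            pred = np.mean(preds, axis=0)
        else:
            pred = np.asarray(predict(patch))
        acc[sl] += pred
        cov[sl] += 1
    covered = cov > 0
    acc[covered] /= cov[covered]
    return image.like(acc)


def extract_candidates(
    pmap: VolumeGrid,
    threshold: float = 0.5,
    max_candidates: int = 5,
    min_voxels: int = 3,
) -> list[Candidate]:
    """Threshold, 26-connect, drop tiny components, keep top candidates.

    Components are scored by peak probability and sorted by (score desc,
    voxel count desc, centre lexicographic).
    """
    prob = np.asarray(pmap.data, dtype=float)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability map values must lie in [0,1]")
    binary = prob >= threshold
    labels, n = ndimage.label(binary, structure=np.ones((3, 3, 3), dtype=int))
    cands: list[Candidate] = []
    for comp in range(1, n + 1):
        sel = labels == comp
        count = int(sel.sum())
        if count < min_voxels:
            continue
        score = float(prob[sel].max())
        centroid_vox = np.argwhere(sel).mean(axis=0)
        center = tuple(float(v) for v in pmap.voxel_to_world(centroid_vox))
        cands.append(Candidate(center, score, count))
    cands.sort(key=lambda c: (-c.score, -c.voxel_count, c.center))
    return cands[:max_candidates]
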
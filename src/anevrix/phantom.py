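"""Seeded synthetic TOF-MRA-like phantoms.

Each case renders bright tubular vessels (piecewise-linear random paths) on
a noisy dark background, attaches spherical aneurysm bulges to the vessel
walls, places landmark points at path junctions and near lesions, and draws
patient metadata for risk scoring. All ground-truth masks are noise-free
and the aneurysm spheres are defined in world mm so the maximum-diameter
ground truth is analytic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .annotate import SphereLabel, make_weak_label
from .dataio import VolumeGrid, write_volume

__all__ = ["PhantomSpec", "PhantomCase", "generate_phantom", "generate_cohort",
           "draw_phases_diameter", "PHASES_SIZE_BIN_PROBS"]

# diameter-bin probabilities used when drawing cohort lesion sizes
# (<=7, 7-9.9, 10-19.9, >=20 mm)
PHASES_SIZE_BIN_PROBS = (180 / 198, 7 / 198, 10 / 198, 1 / 198)
_SIZE_BIN_EDGES = ((2.0, 7.0), (7.0, 9.9), (10.0, 19.9), (20.0, 24.0))


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_segments: int = 4
    vessel_radius_range: tuple[float, float] = (1.5, 3.0)
    n_aneurysms: int = 1
    aneurysm_radius_range: tuple[float, float] = (2.0, 4.0)
    vessel_intensity: float = 200.0
    background_intensity: float = 40.0
    noise_sd: float = 10.0
    n_landmarks: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("vessel_radius_range", "aneurysm_radius_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive and ordered")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.grid_shape) < 8:
            raise ValueError("grid_shape too small")
        if self.n_segments < 1:
            raise ValueError("need at least one vessel segment")


@dataclass
class PhantomCase:
    image: VolumeGrid
    vessel_mask: VolumeGrid
    aneurysm_masks: list[VolumeGrid]
    aneurysm_spheres: list[SphereLabel]
    landmarks: "LandmarkSet"
    meta: dict

    @property
    def lesion_mask(self) -> VolumeGrid:
        out = np.zeros(self.image.shape, dtype=np.uint8)
        for m in self.aneurysm_masks:
            out |= m.data.astype(np.uint8)
        return self.image.like(out)


class PlacementError(RuntimeError):
    pass


def _walk_path(rng, extent_mm, start, step_mm=2.0, n_steps=60):
    """Smooth random-walk polyline inside the box [margin, extent-margin]."""
    heading = rng.normal(size=3)
    heading /= np.linalg.norm(heading)
    pts = [np.asarray(start, dtype=float)]
    margin = 4.0
    for _ in range(n_steps):
        heading = heading + 0.35 * rng.normal(size=3)
        heading /= np.linalg.norm(heading)
        nxt = pts[-1] + step_mm * heading
        # reflect off the walls to stay inside
        for ax in range(3):
            if nxt[ax] < margin or nxt[ax] > extent_mm[ax] - margin:
                heading[ax] = -heading[ax]
                nxt = pts[-1] + step_mm * heading
        nxt = np.clip(nxt, margin, extent_mm - margin)
        pts.append(nxt)
    return np.array(pts)


def _densify(polyline: np.ndarray, max_step: float) -> np.ndarray:
    """Insert points so consecutive samples are at most max_step apart."""
    out = [polyline[0]]
    for a, b in zip(polyline[:-1], polyline[1:]):
        seg = b - a
        n = max(1, int(np.ceil(np.linalg.norm(seg) / max_step)))
        for i in range(1, n + 1):
            out.append(a + seg * (i / n))
    return np.array(out)


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Render one deterministic phantom case from a spec."""
    from .anatomy_prior import LandmarkSet  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    shape = np.array(spec.grid_shape)
    spacing = np.array(spec.spacing, dtype=float)
    affine = np.diag([*spacing, 1.0])
    extent_mm = (shape - 1) * spacing

    # --- vessel centrelines: first path starts anywhere, later ones branch
    # from a random point of an earlier path (junction)
    paths: list[np.ndarray] = []
    radii: list[float] = []
    junctions: list[np.ndarray] = []
    for i in range(spec.n_segments):
        if i == 0 or len(paths) == 0:
            start = extent_mm * (0.25 + 0.5 * rng.random(3))
        else:
            parent = paths[rng.integers(len(paths))]
            start = parent[rng.integers(len(parent))]
            junctions.append(start.copy())
        paths.append(_walk_path(rng, extent_mm, start))
        radii.append(float(rng.uniform(*spec.vessel_radius_range)))

    # --- rasterize tubes: seed dense centreline voxels, distance transform
    min_sp = float(spacing.min())
    vessel = np.zeros(tuple(shape), dtype=bool)
    dist_to_path: list[np.ndarray] = []  # per-segment distance maps (mm)
    all_points = []
    for path, radius in zip(paths, radii):
        dense = _densify(path, max_step=min_sp / 2)
        all_points.append(dense)
        seeds = np.zeros(tuple(shape), dtype=bool)
        idx = np.rint(dense / spacing).astype(int)
        idx = np.clip(idx, 0, shape - 1)
        seeds[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        dist = ndimage.distance_transform_edt(~seeds, sampling=spacing)
        vessel |= dist <= radius
        dist_to_path.append(dist)
    path_points = np.concatenate(all_points, axis=0)

    grid = VolumeGrid(np.zeros(tuple(shape), dtype=np.float32), affine)

    # --- aneurysms: spheres attached to a random centreline point, offset
    # outward so the bulge overlaps the vessel wall
    masks: list[VolumeGrid] = []
    spheres: list[SphereLabel] = []
    occupied = np.zeros(tuple(shape), dtype=bool)
    for lesion in range(spec.n_aneurysms):
        placed = False
        for _ in range(200):
            seg = int(rng.integers(len(paths)))
            pt = paths[seg][int(rng.integers(len(paths[seg])))]
            a_rad = float(rng.uniform(*spec.aneurysm_radius_range))
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            center = pt + direction * (radii[seg] + 0.7 * a_rad)
            if np.any(center < a_rad) or np.any(center > extent_mm - a_rad):
                continue
            sphere = SphereLabel(tuple(center), a_rad)
            raster = make_weak_label(sphere, grid)
            fg = raster.data.astype(bool)
            if not fg.any() or (fg & occupied).any():
                continue
            occupied |= fg
            masks.append(raster)
            spheres.append(sphere)
            placed = True
            break
        if not placed:
            raise PlacementError(f"could not place aneurysm {lesion} inside the grid")

    # --- landmarks: junctions, then nearest-path points to lesions, then
    # random on-path points, up to n_landmarks
    lm_points: list[np.ndarray] = []
    for j in junctions:
        if len(lm_points) < spec.n_landmarks:
            lm_points.append(j)
    for sphere in spheres:
        if len(lm_points) >= spec.n_landmarks:
            break
        d = np.linalg.norm(path_points - np.asarray(sphere.center), axis=1)
        lm_points.append(path_points[int(np.argmin(d))])
    while len(lm_points) < spec.n_landmarks:
        lm_points.append(path_points[int(rng.integers(len(path_points)))])
    names = [f"landmark_{i + 1:02d}" for i in range(len(lm_points))]
    landmarks = LandmarkSet(names, np.array(lm_points))

    # --- intensity model: background + plateau + Gaussian noise
    image = np.full(tuple(shape), spec.background_intensity, dtype=np.float32)
    bright = vessel | occupied
    image[bright] = spec.vessel_intensity
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape).astype(np.float32)

    meta = {
        "age": int(np.clip(rng.normal(51, 16), 18, 95)),
        "sex": "F" if rng.random() < 0.6 else "M",
        "subject": "sub-001",
        "session": "ses-1",
    }
    return PhantomCase(
        image=VolumeGrid(image.astype(np.float32), affine),
        vessel_mask=VolumeGrid(vessel.astype(np.uint8), affine),
        aneurysm_masks=masks,
        aneurysm_spheres=spheres,
        landmarks=landmarks,
        meta=meta,
    )


def draw_phases_diameter(rng: np.random.Generator) -> float:
    """Draw a lesion max-diameter (mm) matching the clinical size-bin mix."""
    b = rng.choice(len(PHASES_SIZE_BIN_PROBS), p=PHASES_SIZE_BIN_PROBS)
    lo, hi = _SIZE_BIN_EDGES[b]
    return float(rng.uniform(lo, hi))


def generate_cohort(
    n_subjects: int,
    spec_template: PhantomSpec,
    out_dir: str | Path,
    seed: int = 0,
    overwrite: bool = False,
    phases_sizes: bool = False,
) -> dict:
    """Write a BIDS-like phantom cohort and return its manifest.

    Per-subject seeds are ``seed + subject index``. With ``phases_sizes``,
    lesion diameters are drawn from the clinical size-bin mix instead of the
    template's radius range.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} exists and is not empty (pass overwrite)")
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    entries = []
    participants = []
    for i in range(n_subjects):
        sub = f"sub-{i + 1:03d}"
        spec = replace(spec_template, seed=seed + i)
        if phases_sizes and spec.n_aneurysms > 0:
            d = draw_phases_diameter(rng)
            spec = replace(spec, aneurysm_radius_range=(d / 2, d / 2))
        case = generate_phantom(spec)
        anat = out_dir / sub / "ses-1" / "anat"
        img_path = anat / f"{sub}_ses-1_angio.nii.gz"
        write_volume(case.image, img_path)
        mask_dir = out_dir / "derivatives" / "manual_masks" / sub / "ses-1" / "anat"
        mask_paths = []
        for j, m in enumerate(case.aneurysm_masks):
            p = mask_dir / f"{sub}_ses-1_desc-lesion{j + 1}_mask.nii.gz"
            write_volume(m, p)
            mask_paths.append(str(p.relative_to(out_dir)))
        write_volume(case.vessel_mask,
                     mask_dir / f"{sub}_ses-1_desc-vessel_mask.nii.gz")
        lm_path = anat / f"{sub}_ses-1_landmarks.tsv"
        case.landmarks.to_tsv(lm_path)
        participants.append(
            {"participant_id": sub, "age": case.meta["age"], "sex": case.meta["sex"]})
        entries.append({
            "subject": sub,
            "session": "ses-1",
            "image": str(img_path.relative_to(out_dir)),
            "masks": mask_paths,
            "landmarks": str(lm_path.relative_to(out_dir)),
            "seed": seed + i,
            "n_aneurysms": len(case.aneurysm_masks),
        })
    pd.DataFrame(participants, columns=["participant_id", "age", "sex"]).to_csv(
        out_dir / "participants.tsv", sep="\t", index=False)
    manifest = {"seed": seed, "n_subjects": n_subjects, "subjects": entries}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
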
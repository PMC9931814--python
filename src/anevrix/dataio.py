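"""Volume I/O, configuration, and grouped cross-validation splits.

Coordinate convention: voxel indices are 0-based; world coordinates are in
mm (RAS) via the 4x4 affine. All distances in this package are computed in
world mm, never in voxel units.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

logger = logging.getLogger("anevrix")

__all__ = [
    "VolumeGrid",
    "CVSplit",
    "read_volume",
    "write_volume",
    "make_group_kfold",
    "load_config",
    "save_config",
    "DEFAULT_CONFIG",
]


@dataclass
class VolumeGrid:
    """A 3D scalar lattice with a voxel-index -> world-mm affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"VolumeGrid requires 3D data, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (...,3) voxel indices (may be fractional) to world mm."""
        arr = np.asarray(idx, dtype=float)
        single = arr.ndim == 1
        out = np.atleast_2d(arr) @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out[0] if single else out

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map (...,3) world-mm points to fractional voxel indices."""
        arr = np.asarray(xyz, dtype=float)
        single = arr.ndim == 1
        inv = np.linalg.inv(self.affine)
        out = np.atleast_2d(arr) @ inv[:3, :3].T + inv[:3, 3]
        return out[0] if single else out

    def like(self, data: np.ndarray) -> "VolumeGrid":
        """New grid on the same lattice with different data."""
        if data.shape != self.data.shape:
            raise ValueError("shape mismatch")
        return VolumeGrid(data, self.affine.copy())

    def world_coords(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World-mm coordinates of all (or masked) voxel centres, (N,3)."""
        if mask is None:
            idx = np.indices(self.shape).reshape(3, -1).T
        else:
            idx = np.argwhere(mask)
        return self.voxel_to_world(idx.astype(float))


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a 3D NIfTI volume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim}D: {path}")
    return VolumeGrid(data, np.asarray(img.affine))


def write_volume(vol: VolumeGrid, path: str | Path) -> None:
    """Write a volume as NIfTI; float data as float32, masks as uint8."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CVSplit:
    """Group-aware k-fold assignment: subjects sharing a group share a fold."""

    fold_assignments: dict[str, int]
    group_key: dict[str, str]
    k: int

    def fold_subjects(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.fold_assignments.items() if f == fold)

    def to_json(self, path: str | Path) -> None:
        out = {str(f): self.fold_subjects(f) for f in range(self.k)}
        Path(path).write_text(json.dumps(out, indent=1))


def make_group_kfold(
    subjects: list[str],
    groups: dict[str, str],
    k: int,
    seed: int = 0,
) -> CVSplit:
    """Deterministic grouped k-fold: shuffle distinct groups, deal round-robin.

    Subjects sharing a group (e.g. sessions of one patient) are never split
    across folds.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    missing = [s for s in subjects if s not in groups]
    if missing:
        raise ValueError(f"subjects without group key: {missing[:5]}")
    distinct = sorted(set(groups[s] for s in subjects))
    if len(distinct) < k:
        raise ValueError(f"only {len(distinct)} groups for k={k} folds")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(distinct))
    group_fold = {g: i % k for i, g in enumerate(order)}
    assignments = {s: group_fold[groups[s]] for s in subjects}
    return CVSplit(assignments, {s: groups[s] for s in subjects}, k)


# ---------------------------------------------------------------------------
# Configuration

DEFAULT_CONFIG: dict = {
    "patch_side": 64,
    "alpha": 0.5,
    "beta": None,  # resolved to 1 - alpha
    "lr": 1e-4,
    "batch_size": 8,
    "epochs": 100,
    "seed": 0,
    "levels": 2,
    "filters": [8, 16],
    "stride": 32,
    "n_pos_per_lesion": 8,
    "n_neg_landmark": 20,
    "n_neg_vessel": 20,
    "n_neg_random": 10,
    "vessel_percentile": 90.0,
    "max_landmark_dist_mm": 64.0,
    "min_component_voxels": 3,
    "max_candidates": 5,
    "detection_threshold": 0.5,
    "tta": True,
}

_CONFIG_TYPES = {
    "patch_side": int,
    "alpha": float,
    "beta": float,
    "lr": float,
    "batch_size": int,
    "epochs": int,
    "seed": int,
    "levels": int,
    "filters": list,
    "stride": int,
    "n_pos_per_lesion": int,
    "n_neg_landmark": int,
    "n_neg_vessel": int,
    "n_neg_random": int,
    "vessel_percentile": float,
    "max_landmark_dist_mm": float,
    "min_component_voxels": int,
    "max_candidates": int,
    "detection_threshold": float,
    "tta": bool,
}

_POSITIVE_KEYS = {"patch_side", "lr", "batch_size", "stride", "max_landmark_dist_mm"}
_UNIT_KEYS = {"alpha", "beta", "detection_threshold"}


class ConfigError(ValueError):
    pass


def _validate(cfg: dict) -> dict:
    for key, val in cfg.items():
        if key not in DEFAULT_CONFIG:
            raise ConfigError(f"unknown config key: {key!r}")
        want = _CONFIG_TYPES[key]
        if val is None and key == "beta":
            continue
        if want is float and isinstance(val, int) and not isinstance(val, bool):
            val = float(val)
            cfg[key] = val
        if not isinstance(val, want) or (want is int and isinstance(val, bool)):
            raise ConfigError(f"config key {key!r}: expected {want.__name__}, got {val!r}")
        if key in _POSITIVE_KEYS and val <= 0:
            raise ConfigError(f"config key {key!r} must be positive, got {val!r}")
        if key in _UNIT_KEYS and not (0.0 <= val <= 1.0):
            raise ConfigError(f"config key {key!r} must be in [0,1], got {val!r}")
        if key in {"epochs", "n_pos_per_lesion", "n_neg_landmark", "n_neg_vessel",
                   "n_neg_random", "min_component_voxels", "max_candidates"} and val < 0:
            raise ConfigError(f"config key {key!r} must be >= 0, got {val!r}")
    return cfg


def load_config(path: str | Path | None = None) -> dict:
    """Load YAML/JSON config, reject unknown keys, fill defaults.

    ``beta`` defaults to ``1 - alpha`` when unset.
    """
    user: dict = {}
    if path is not None:
        text = Path(path).read_text()
        user = yaml.safe_load(text) or {}
        if not isinstance(user, dict):
            raise ConfigError("config file must contain a mapping")
    user = _validate(dict(user))
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(user)
    if cfg["beta"] is None:
        cfg["beta"] = 1.0 - float(cfg["alpha"])
    cfg = _validate(cfg)
    logger.info("resolved config: %s", json.dumps(cfg, sort_keys=True))
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
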
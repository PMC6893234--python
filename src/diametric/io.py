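"""Volume, mask, and table IO plus the shared spatial-grid contract.

All spatial objects in the pipeline (BOLD runs, network/seed/tissue masks,
derived maps) live on one :class:`SpatialGrid`; nothing here resamples.  Voxel
indices are 0-based and world coordinates follow the NIfTI affine (RAS+ mm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import DimensionError, GridError, ValidationError

GROUPS = ("HC", "EM")
CONDITIONS = ("rsBase", "Med", "rsPost")

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


@dataclass(frozen=True)
class SpatialGrid:
    """A 3D voxel grid: shape plus the 4x4 voxel-to-world (mm) affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValidationError(f"grid shape must be 3 positive ints, got {shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValidationError(f"affine must be 4x4, got {aff.shape}")
        if abs(np.linalg.det(aff)) < 1e-12:
            raise ValidationError("affine is singular")
        aff = aff.copy()
        aff.flags.writeable = False
        object.__setattr__(self, "affine", aff)

    def voxel_to_world(self, ijk) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        xyz = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return xyz.squeeze()

    def world_to_voxel(self, xyz) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        ijk = xyz @ inv[:3, :3].T + inv[:3, 3]
        return ijk.squeeze()

    def matches(self, other: "SpatialGrid", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class BoldRun:
    """One subject-session 4D time series (x, y, z, time)."""

    grid: SpatialGrid
    data: np.ndarray
    tr_seconds: float
    subject: str = ""
    condition: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise DimensionError(f"BOLD data must be 4D, got {self.data.ndim}D")
        if self.data.shape[:3] != self.grid.shape:
            raise GridError(
                f"data shape {self.data.shape[:3]} != grid shape {self.grid.shape}"
            )
        if self.data.shape[3] < 8:
            raise ValidationError(
                f"need at least 8 volumes, got {self.data.shape[3]}"
            )
        if not (self.tr_seconds > 0):
            raise ValidationError(f"tr_seconds must be > 0, got {self.tr_seconds}")
        bad = ~np.isfinite(self.data)
        if bad.any():
            idx = tuple(int(i) for i in np.argwhere(bad)[0])
            raise ValidationError(f"non-finite voxel value at index {idx}")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray) -> "BoldRun":
        return BoldRun(self.grid, data, self.tr_seconds, self.subject, self.condition)


@dataclass
class VolumeMask:
    """A 3D binary region on a grid (network, seed, or tissue compartment)."""

    grid: SpatialGrid
    voxels: np.ndarray

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise DimensionError(f"mask must be 3D, got {self.voxels.ndim}D")
        if self.voxels.shape != self.grid.shape:
            raise GridError(
                f"mask shape {self.voxels.shape} != grid shape {self.grid.shape}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


def read_bold(path, tr_seconds: float | None = None) -> BoldRun:
    """Load a 4D NIfTI volume; TR comes from the header unless overridden."""
    img = nib.load(str(path))
    if img.ndim != 4:
        raise DimensionError(f"{path}: expected a 4D volume, got {img.ndim}D")
    data = np.asarray(img.get_fdata(dtype=np.float64))
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 else 0.0
        if tr_seconds <= 0:
            raise ValidationError(
                f"{path}: header carries no TR; pass tr_seconds explicitly"
            )
    grid = SpatialGrid(img.shape[:3], img.affine)
    return BoldRun(grid, data, float(tr_seconds))


def write_bold(run: BoldRun, path) -> None:
    img = nib.Nifti1Image(run.data.astype(np.float32), run.grid.affine)
    zooms = img.header.get_zooms()
    img.header.set_zooms(zooms[:3] + (run.tr_seconds,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_mask(path, grid: SpatialGrid) -> VolumeMask:
    """Load a 3D mask; any nonzero voxel counts as true; grid must match."""
    img = nib.load(str(path))
    if img.ndim != 3:
        raise DimensionError(f"{path}: expected a 3D mask, got {img.ndim}D")
    file_grid = SpatialGrid(img.shape, img.affine)
    if not grid.matches(file_grid):
        raise GridError(f"{path}: mask grid does not match the reference grid")
    voxels = np.asarray(img.get_fdata()) != 0
    if not voxels.any():
        raise ValidationError(f"{path}: mask is empty")
    return VolumeMask(grid, voxels)


def write_mask(mask: VolumeMask, path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


def write_map(grid: SpatialGrid, values: np.ndarray, path) -> None:
    """Write a 3D scalar map (fALFF, Fisher z, p) on a grid."""
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), grid.affine)
    nib.save(img, str(path))


def read_map(path, grid: SpatialGrid) -> np.ndarray:
    img = nib.load(str(path))
    file_grid = SpatialGrid(img.shape[:3], img.affine)
    if not grid.matches(file_grid):
        raise GridError(f"{path}: map grid does not match the reference grid")
    return np.asarray(img.get_fdata(dtype=np.float64))


@dataclass
class CohortTable:
    """Session table driving all contrasts.

    One row per (subject, condition); groups are HC (controls, rsBase only)
    and EM (meditators: rsBase, Med, rsPost); ``meditation_hours`` may be NaN
    for controls.
    """

    frame: pd.DataFrame = field(repr=False)

    REQUIRED = ("subject", "group", "condition")

    def __post_init__(self):
        df = self.frame.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValidationError(f"cohort table missing column '{col}'")
        bad_group = set(df["group"]) - set(GROUPS)
        if bad_group:
            raise ValidationError(
                f"unknown group(s) {sorted(bad_group)}; allowed: {list(GROUPS)}"
            )
        bad_cond = set(df["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValidationError(
                f"unknown condition(s) {sorted(bad_cond)}; "
                f"allowed: {list(CONDITIONS)}"
            )
        dup = df.duplicated(subset=["subject", "condition"])
        if dup.any():
            pair = df.loc[dup, ["subject", "condition"]].iloc[0]
            raise ValidationError(
                f"duplicate (subject, condition) pair ({pair.subject}, "
                f"{pair.condition})"
            )
        for subj, sub in df.groupby("subject"):
            groups = set(sub["group"])
            if len(groups) > 1:
                raise ValidationError(f"subject {subj} appears in both groups")
            conds = set(sub["condition"])
            if "EM" in groups and "rsBase" not in conds:
                raise ValidationError(f"EM subject {subj} lacks an rsBase session")
            if "HC" in groups and conds != {"rsBase"}:
                raise ValidationError(
                    f"HC subject {subj} must have only an rsBase session"
                )
        if "meditation_hours" in df.columns:
            hours = df["meditation_hours"].dropna()
            if (hours < 0).any():
                raise ValidationError("meditation_hours must be nonnegative")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def sessions(self, group: str | None = None, condition: str | None = None):
        df = self.frame
        if group is not None:
            df = df[df["group"] == group]
        if condition is not None:
            df = df[df["condition"] == condition]
        return df


def read_cohort(path) -> CohortTable:
    df = pd.read_csv(str(path), sep="\t")
    return CohortTable(df)


def write_cohort(table: CohortTable, path) -> None:
    table.frame.to_csv(str(path), sep="\t", index=False)


def read_motion(path) -> pd.DataFrame:
    """Read a 6-column motion table (mm translations, rad rotations)."""
    df = pd.read_csv(str(path), sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: motion table missing columns {missing}")
    return df[list(MOTION_COLUMNS)]


def write_motion(motion: pd.DataFrame, path) -> None:
    motion.to_csv(str(path), sep="\t", index=False)


def check_same_grid(*objs) -> SpatialGrid:
    """Assert that all runs/masks/maps share one grid; return it."""
    grids = [o.grid for o in objs]
    first = grids[0]
    for g in grids[1:]:
        if not first.matches(g):
            raise GridError("objects do not share one spatial grid")
    return first


def default_grid(shape=(24, 24, 24), voxel_mm: float = 4.0) -> SpatialGrid:
    """Isotropic RAS+ grid centered at the origin (synthetic default)."""
    shape = tuple(int(s) for s in shape)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * (np.array(shape) - 1) / 2.0
    return SpatialGrid(shape, affine)
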
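"""Typed 3D volumes on a shared voxel grid, with NIfTI round-tripping.

Every stage of the pothole pipeline operates on volumes that must live on the
same voxel grid: subject FA maps, white-matter masks, the normative template,
and the atlas label volume. This module defines the typed containers, the
grid-compatibility contract, and NIfTI-1 I/O (via nibabel). Registration,
resampling and reorientation are upstream concerns: inputs are assumed
co-registered, and two grids are compatible only when their shape, voxel size
and orientation tag agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "FAVolume",
    "MaskVolume",
    "AtlasVolume",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "check_grid_compatible",
]

#: absolute tolerance (mm) for voxel-size equality, absorbing float header jitter
VOXEL_SIZE_TOL_MM = 1e-6


class GridMismatchError(ValueError):
    """Two volumes do not share a voxel grid (shape, voxel size or frame)."""


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of a 3D voxel lattice.

    Parameters
    ----------
    shape
        Number of voxels along each axis.
    voxel_size
        Physical voxel edge lengths in mm along each axis.
    orientation_tag
        Opaque identifier of the spatial frame. Volumes produced by one
        registration pipeline share a tag; compatibility requires equality.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    orientation_tag: str = "native"

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(self.voxel_size) != 3 or any(float(v) <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive reals, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm³."""
        return float(np.prod(self.voxel_size))

    def is_compatible(self, other: "VoxelGrid") -> bool:
        return (
            self.shape == other.shape
            and all(
                abs(a - b) <= VOXEL_SIZE_TOL_MM
                for a, b in zip(self.voxel_size, other.voxel_size)
            )
            and self.orientation_tag == other.orientation_tag
        )


def _as_3d(values: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    arr = np.asarray(values)
    if arr.shape != grid.shape:
        raise ValueError(f"values shape {arr.shape} does not match grid {grid.shape}")
    return arr


@dataclass
class FAVolume:
    """A scalar fractional-anisotropy volume.

    FA lies in [0, 1] inside the brain; voxels outside the subject's mask may
    carry arbitrary (typically 0 or NaN) values and are ignored downstream.
    """

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _as_3d(self.values, self.grid).astype(np.float64, copy=False)

    def validate_in_mask(self, mask: "MaskVolume") -> None:
        """Check the FA invariants on the masked voxels; raise on violation."""
        inside = self.values[mask.values]
        if not np.all(np.isfinite(inside)):
            raise ValueError("non-finite FA values inside mask")
        if inside.size and (inside.min() < 0.0 or inside.max() > 1.0):
            raise ValueError("FA values outside [0, 1] inside mask")


@dataclass
class MaskVolume:
    """A boolean volume; any nonzero stored value reads as True."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _as_3d(self.values, self.grid).astype(bool)
        if not self.values.any():
            raise ValueError("mask has no true voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


@dataclass
class AtlasVolume:
    """Integer-labeled parcellation; 0 is background."""

    grid: VoxelGrid
    labels: np.ndarray
    label_names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = _as_3d(self.labels, self.grid)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("atlas labels must be integer-valued")
            arr = np.round(arr).astype(np.int32)
        if arr.min() < 0:
            raise ValueError("atlas labels must be non-negative")
        self.labels = arr.astype(np.int32, copy=False)
        present = self.present_labels()
        missing = [int(l) for l in present if int(l) not in self.label_names]
        if self.label_names and missing:
            raise ValueError(f"labels missing from label_names: {missing}")
        if not self.label_names:
            self.label_names = {int(l): f"region_{int(l)}" for l in present}

    def present_labels(self) -> list[int]:
        """Sorted nonzero labels present in the volume."""
        u = np.unique(self.labels)
        return [int(l) for l in u if l != 0]


Volume = FAVolume | MaskVolume | AtlasVolume


def _grid_from_header(img: nib.Nifti1Image) -> VoxelGrid:
    zooms = img.header.get_zooms()[:3]
    # Orientation tag derived from the affine's axis codes so that volumes
    # written by this package (identity-scaled affine) agree with one another.
    tag = "".join(nib.aff2axcodes(img.affine))
    return VoxelGrid(shape=tuple(img.shape[:3]), voxel_size=tuple(float(z) for z in zooms),
                     orientation_tag=tag)


def read_volume(path: str | Path, expected_kind: str = "scalar") -> Volume:
    """Read a 3D NIfTI volume as a typed container.

    Parameters
    ----------
    path
        A readable ``.nii`` or ``.nii.gz`` file.
    expected_kind
        ``"scalar"`` → :class:`FAVolume`, ``"mask"`` → :class:`MaskVolume`
        (any nonzero stored value coerces to True), ``"labels"`` →
        :class:`AtlasVolume` (values must be integer).
    """
    if expected_kind not in {"scalar", "mask", "labels"}:
        raise ValueError(f"unknown expected_kind {expected_kind!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {img.ndim}D shape {img.shape}")
    grid = _grid_from_header(img)
    data = np.asarray(img.dataobj)
    if expected_kind == "scalar":
        return FAVolume(grid=grid, values=data.astype(np.float64))
    if expected_kind == "mask":
        return MaskVolume(grid=grid, values=data != 0)
    return AtlasVolume(grid=grid, labels=data)


def write_volume(volume: Volume, path: str | Path) -> Path:
    """Write a typed volume as NIfTI-1; round-trips through :func:`read_volume`."""
    path = Path(path)
    if isinstance(volume, MaskVolume):
        data = volume.values.astype(np.uint8)
    elif isinstance(volume, AtlasVolume):
        data = volume.labels.astype(np.int32)
    else:
        data = volume.values.astype(np.float64)
    affine = np.diag(list(volume.grid.voxel_size) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(volume.grid.voxel_size)
    nib.save(img, str(path))
    return path


def check_grid_compatible(volumes: list[Volume] | list[VoxelGrid]) -> None:
    """Raise :class:`GridMismatchError` naming the first pair of incompatible grids."""
    if not volumes:
        raise ValueError("empty volume list")
    grids = [v if isinstance(v, VoxelGrid) else v.grid for v in volumes]
    ref = grids[0]
    for i, g in enumerate(grids[1:], start=1):
        if not ref.is_compatible(g):
            raise GridMismatchError(
                f"grid mismatch between volume 0 {ref} and volume {i} {g}"
            )
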
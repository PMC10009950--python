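"""Voxel datasets and region masks (NIfTI-1 via nibabel).

A :class:`VoxelDataset` stacks per-subject modulated gray-matter volume maps
on a common grid (subjects first, then a 3-D grid).  Values are in the
arbitrary-but-consistent modulated-GM unit; the affine carries voxel size
and orientation.  Masks are boolean grids congruent with the dataset; masks
read from images are binarized at > 0.5, matching common practice for
probabilistic label maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .errors import GridError, ValidationError

__all__ = [
    "VoxelDataset",
    "ROIMask",
    "read_volume_stack",
    "read_mask",
    "write_map",
    "write_stack",
]

_AFFINE_ATOL = 1e-4  # mm; grid congruence tolerance on affines


def _voxel_size(affine: np.ndarray) -> np.ndarray:
    return np.sqrt((affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class VoxelDataset:
    """Subjects × (nx, ny, nz) stack of local GM volume values."""

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 4:
            raise ValidationError(
                f"values must be 4-D (subjects, nx, ny, nz), got {self.values.ndim}-D"
            )
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if np.any(_voxel_size(self.affine) <= 0):
            raise ValidationError("voxel size must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("dataset contains non-finite values")
        if self.subject_ids is not None and len(self.subject_ids) != self.n_subjects:
            raise ValidationError("subject_ids length disagrees with subject axis")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape[1:]

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge length per axis in mm."""
        return _voxel_size(self.affine)

    def check_alignment(self, n_subjects: int) -> None:
        """Reject misalignment between image stack and cohort length."""
        if self.n_subjects != n_subjects:
            raise ValidationError(
                f"subject axis ({self.n_subjects}) disagrees with cohort ({n_subjects})"
            )

    def check_grid(self, shape: tuple[int, ...], affine: np.ndarray | None = None) -> None:
        if tuple(shape) != self.grid_shape:
            raise GridError(f"grid shape {tuple(shape)} != dataset {self.grid_shape}")
        if affine is not None and not np.allclose(
            affine, self.affine, atol=_AFFINE_ATOL
        ):
            raise GridError("affines differ beyond 1e-4 mm tolerance")


@dataclass
class ROIMask:
    """Named boolean region mask on a dataset's grid."""

    name: str
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValidationError(f"mask {self.name!r} must be 3-D")
        if not self.data.any():
            raise ValidationError(f"mask {self.name!r} is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def read_volume_stack(paths: Sequence[str | Path] | str | Path) -> VoxelDataset:
    """Load a subject stack from one 4-D image or a list of 3-D images.

    All images must share grid shape and affine (within 1e-4 mm); subjects
    are stacked in input order.
    """
    if isinstance(paths, (str, Path)):
        img = nib.load(str(paths))
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        if data.ndim == 3:
            data = data[np.newaxis]
        elif data.ndim == 4:
            data = np.moveaxis(data, -1, 0)  # NIfTI time axis last -> subjects first
        else:
            raise GridError(f"{paths}: expected 3-D or 4-D image, got {data.ndim}-D")
        return VoxelDataset(values=data, affine=img.affine)

    volumes, affine, shape = [], None, None
    for p in paths:
        img = nib.load(str(p))
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        if data.ndim != 3:
            raise GridError(f"{p}: expected a 3-D image, got {data.ndim}-D")
        if shape is None:
            shape, affine = data.shape, img.affine
        else:
            if data.shape != shape:
                raise GridError(f"{p}: shape {data.shape} mismatches first image {shape}")
            if not np.allclose(img.affine, affine, atol=_AFFINE_ATOL):
                raise GridError(f"{p}: affine mismatches first image")
        volumes.append(data)
    if not volumes:
        raise ValidationError("no input images given")
    return VoxelDataset(values=np.stack(volumes, axis=0), affine=affine)


def read_mask(path: str | Path, grid: VoxelDataset, name: str | None = None) -> ROIMask:
    """Read an ROI/GM mask image congruent with ``grid``; inside = value > 0.5."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    grid.check_grid(data.shape, img.affine)
    mask = data > 0.5
    if not mask.any():
        raise ValidationError(f"mask {path} is empty after binarization at 0.5")
    return ROIMask(name=name or Path(path).stem.replace(".nii", ""), data=mask)


def write_map(
    data: np.ndarray,
    affine: np.ndarray,
    path: str | Path,
    dtype=np.float32,
) -> Path:
    """Write a 3-D map as NIfTI-1 (default 32-bit float storage)."""
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValidationError("write_map expects a 3-D array")
    img = nib.Nifti1Image(data.astype(dtype), np.asarray(affine, dtype=np.float64))
    nib.save(img, str(path))
    return Path(path)


def write_stack(dataset: VoxelDataset, path: str | Path, dtype=np.float32) -> Path:
    """Write a subject stack as a 4-D NIfTI (subjects on the last axis)."""
    data = np.moveaxis(dataset.values, 0, -1).astype(dtype)
    nib.save(nib.Nifti1Image(data, dataset.affine), str(path))
    return Path(path)
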
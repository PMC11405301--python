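"""Volume I/O, spatial canonicalization, resampling, and mask morphology.

All image stages of the pipeline share the conventions defined here:

* voxel indices are 0-based,
* world coordinates are millimetres, obtained through the NIfTI affine,
* every volume is reoriented to the RAS+ anatomical convention
  (first axis points right, second anterior, third superior) immediately
  after load, so that left/right is consistent between image space and the
  exported 3D scene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class VolumeFormatError(ValueError):
    """Raised when an input image is not a readable 3D scalar volume."""


@dataclass
class VoxelGrid:
    """A scalar 3D image with its voxel-index -> world-mm affine.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar lattice (CT Hounsfield-like values or mask values).
    affine : ndarray, shape (4, 4)
        Homogeneous map from 0-based voxel index to world millimetres.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise VolumeFormatError(
                f"expected a 3D volume, got shape {self.data.shape}"
            )
        if self.affine.shape != (4, 4):
            raise VolumeFormatError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise VolumeFormatError("affine is not invertible")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map 0-based voxel indices (..., 3) to world mm (..., 3)."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        out = idx @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out if out.shape[0] > 1 else out[0]

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        out = xyz @ inv[:3, :3].T + inv[:3, 3]
        return out if out.shape[0] > 1 else out[0]

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        """Same lattice/affine, new values."""
        return VoxelGrid(data, self.affine.copy())


def read_volume(path: str | Path) -> VoxelGrid:
    """Read a single 3D scalar NIfTI volume.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    VolumeFormatError
        If the file is unreadable, 4D, or otherwise not a scalar 3D image.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises a zoo of types on bad files
        raise VolumeFormatError(f"cannot read {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(
            f"{path} is {data.ndim}D; a single 3D volume is required"
        )
    return VoxelGrid(np.asarray(data, dtype=np.float64), np.asarray(img.affine))


def write_volume(grid: VoxelGrid, path: str | Path, dtype=np.float32) -> Path:
    """Write a grid to NIfTI (.nii or .nii.gz)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(grid.data, dtype=dtype), grid.affine)
    nib.save(img, str(path))
    return path


def canonicalize_orientation(grid: VoxelGrid) -> VoxelGrid:
    """Reorient a grid to the RAS+ convention without moving any voxel in
    world space.

    Axes are permuted/flipped so the affine's rotation part has a positive
    dominant diagonal; the affine is updated so every voxel keeps its world
    coordinate. Idempotent.
    """
    ornt = nib.orientations.io_orientation(grid.affine)
    data = nib.orientations.apply_orientation(grid.data, ornt)
    affine = grid.affine @ nib.orientations.inv_ornt_aff(ornt, grid.data.shape)
    return VoxelGrid(data, affine)


def resample_isotropic(
    grid: VoxelGrid, target_mm: float = 1.0, method: str = "linear"
) -> VoxelGrid:
    """Resample onto an isotropic lattice of ``target_mm`` voxels.

    The world extent is preserved to within one voxel per axis; the output
    affine keeps the input's origin and axis directions.
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    order = _interp_order(method)
    spacing = grid.spacing
    scale = target_mm / spacing
    new_shape = np.maximum(1, np.ceil(np.array(grid.shape) * spacing / target_mm))
    new_shape = new_shape.astype(int)
    scale_aff = np.diag(list(scale) + [1.0])
    new_affine = grid.affine @ scale_aff
    # output index -> input index is diagonal here, so offset is zero
    out = ndimage.affine_transform(
        grid.data.astype(float),
        np.diag(scale),
        output_shape=tuple(new_shape),
        order=order,
        mode="constant",
        cval=0.0,
    )
    return VoxelGrid(out, new_affine)


def apply_rigid_transform(
    moving: VoxelGrid,
    transform: np.ndarray,
    reference: VoxelGrid,
    method: str = "nearest",
    orthogonality_tol: float = 1e-3,
) -> VoxelGrid:
    """Resample ``moving`` onto the lattice of ``reference`` under a rigid
    world-space transform (moving world -> reference world), e.g. a
    FLIRT-style text matrix loaded with :func:`read_transform`.

    A small departure from orthogonality (text-file rounding) is tolerated;
    anything worse than ``orthogonality_tol`` in ``||R^T R - I||`` is
    rejected.
    """
    transform = np.asarray(transform, dtype=float)
    if transform.shape != (4, 4):
        raise ValueError("transform must be 4x4")
    R = transform[:3, :3]
    dev = np.linalg.norm(R.T @ R - np.eye(3))
    if dev > orthogonality_tol:
        raise ValueError(
            f"transform is not rigid (||R^T R - I|| = {dev:.2e} "
            f"> {orthogonality_tol:.0e})"
        )
    order = _interp_order(method)
    # ref index -> ref world -> moving world -> moving index
    full = np.linalg.inv(moving.affine) @ np.linalg.inv(transform) @ reference.affine
    out = ndimage.affine_transform(
        moving.data.astype(float),
        full[:3, :3],
        offset=full[:3, 3],
        output_shape=reference.shape,
        order=order,
        mode="constant",
        cval=0.0,
    )
    return VoxelGrid(out, reference.affine.copy())


def read_transform(path: str | Path) -> np.ndarray:
    """Read a whitespace-separated 4x4 transform text file."""
    mat = np.loadtxt(str(path))
    if mat.shape != (4, 4):
        raise ValueError(f"{path} does not hold a 4x4 matrix")
    return mat


#: Face-connected (6-neighbour) structuring element used for all mask
#: morphology and component grouping in the pipeline.
FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


def erode_mask(mask: VoxelGrid, iterations: int = 3) -> VoxelGrid:
    """Binary erosion with the 6-connected structuring element.

    ``iterations=0`` is the identity. The result is always a subset of the
    input (anti-extensive).
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    binary = grid_as_bool(mask)
    if iterations == 0:
        return mask.with_data(binary.astype(np.uint8))
    out = ndimage.binary_erosion(binary, FACE_STRUCTURE, iterations=iterations)
    return mask.with_data(out.astype(np.uint8))


def grid_as_bool(mask: VoxelGrid) -> np.ndarray:
    """Validate that a grid is binary and return it as a boolean array."""
    data = np.asarray(mask.data)
    vals = np.unique(data)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"mask is not binary; value set {vals[:10]}")
    return data.astype(bool)


def _interp_order(method: str) -> int:
    try:
        return {"nearest": 0, "linear": 1}[method]
    except KeyError:
        raise ValueError(f"unknown interpolation method {method!r}") from None


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
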
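"""Axis-aligned raster containers shared by every stage of the pipeline.

Conventions (used everywhere in this package):

* Arrays are indexed ``data[ix, iy, iz]`` with fixed patient axes
  LR = x, AP = y, SI = z.
* Indices are 0-based; the world position (mm) of the *center* of voxel
  ``(i, j, k)`` is ``origin + index * spacing``.
* Grids are axis aligned; oblique orientations are out of scope.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

#: Largest voxel displacement (mm) a deformation field may carry.  Guards
#: against mis-scaled externally supplied fields.
MAX_MOTION_MM = 60.0


@dataclass(frozen=True)
class GridGeometry:
    """Shape, spacing and origin of a raster, without the payload."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self):
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be 3D and >= (1,1,1), got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """World mm of (possibly fractional) voxel indices, shape (..., 3)."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world positions, shape (..., 3)."""
        return (np.asarray(world, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis arrays of voxel-center world coordinates."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)
        )

    @staticmethod
    def centered(shape, spacing) -> "GridGeometry":
        """Geometry whose world origin (0,0,0) is the grid center."""
        shape = tuple(int(s) for s in shape)
        spacing = tuple(float(s) for s in spacing)
        origin = tuple(-(n - 1) * d / 2.0 for n, d in zip(shape, spacing))
        return GridGeometry(shape, spacing, origin)


@dataclass
class VoxelGrid:
    """3D scalar field (density g/cm3, dose Gy, energy J-surrogate, mass g)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"VoxelGrid data must be 3D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.data.dtype.kind == "f" and not np.all(np.isfinite(self.data)):
            raise ValueError("VoxelGrid data contains non-finite values")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(tuple(self.data.shape), self.spacing, self.origin)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def like(self, data: np.ndarray) -> "VoxelGrid":
        """New grid with the same geometry and different payload."""
        return VoxelGrid(data, self.spacing, self.origin)

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.data.copy(), self.spacing, self.origin)

    def index_to_world(self, index):
        return self.geometry.index_to_world(index)

    def world_to_index(self, world):
        return self.geometry.world_to_index(world)


@dataclass
class ROIMask:
    """Named boolean region of interest on a grid."""

    grid: VoxelGrid
    name: str

    def __post_init__(self):
        if self.grid.data.dtype != bool:
            self.grid = self.grid.like(self.grid.data.astype(bool))

    @property
    def mask(self) -> np.ndarray:
        return self.grid.data

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_cm3(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_cm3

    def like(self, mask: np.ndarray, name: str | None = None) -> "ROIMask":
        return ROIMask(self.grid.like(np.asarray(mask, dtype=bool)), name or self.name)


@dataclass
class DeformationField:
    """Per-voxel 3-vector displacements (mm) between a phase and the reference.

    ``direction='push'`` maps phase geometry toward the reference
    (a point at phase position x lands at x + v(x) on the reference);
    ``direction='pull'`` maps reference positions toward the phase.
    """

    vectors: np.ndarray  # (nx, ny, nz, 3) mm
    direction: str
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError("DeformationField vectors must have shape (nx,ny,nz,3)")
        if self.direction not in ("push", "pull"):
            raise ValueError(f"direction must be 'push' or 'pull', got {self.direction!r}")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("DeformationField contains non-finite vectors")
        mags = np.linalg.norm(self.vectors, axis=-1)
        if mags.max(initial=0.0) > MAX_MOTION_MM:
            raise ValueError(
                f"displacement magnitude {mags.max():.1f} mm exceeds limit {MAX_MOTION_MM} mm"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(tuple(self.vectors.shape[:3]), self.spacing, self.origin)

    @property
    def max_magnitude(self) -> float:
        return float(np.linalg.norm(self.vectors, axis=-1).max(initial=0.0))

    def is_zero(self) -> bool:
        return not np.any(self.vectors)

    def sample(self, world: np.ndarray) -> np.ndarray:
        """Trilinearly interpolated displacement at world positions (..., 3)."""
        idx = self.geometry.world_to_index(world)
        coords = np.moveaxis(idx.reshape(-1, 3), -1, 0)
        out = np.empty((idx.reshape(-1, 3).shape[0], 3))
        for a in range(3):
            out[:, a] = ndimage.map_coordinates(
                self.vectors[..., a], coords, order=1, mode="nearest"
            )
        return out.reshape(np.asarray(world).shape)


# ---------------------------------------------------------------------------
# File IO (NIfTI .nii/.nii.gz and MetaImage .mha/.mhd through SimpleITK)
# ---------------------------------------------------------------------------

def _to_sitk(data: np.ndarray, spacing, origin, vector: bool = False) -> sitk.Image:
    if vector:
        # (nx,ny,nz,3) -> sitk (z,y,x) with 3 components
        arr = np.ascontiguousarray(np.transpose(data, (2, 1, 0, 3)))
        img = sitk.GetImageFromArray(arr, isVector=True)
    else:
        img = sitk.GetImageFromArray(np.ascontiguousarray(data.T))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def write_grid(grid: VoxelGrid, path: str | os.PathLike) -> None:
    """Write a scalar grid as NIfTI or MetaImage (format from extension)."""
    data = grid.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    sitk.WriteImage(_to_sitk(data, grid.spacing, grid.origin), str(path))


def read_grid(path: str | os.PathLike) -> VoxelGrid:
    """Read a scalar NIfTI/MetaImage grid; rejects vector-valued payloads."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"expected a 3D scalar image, got {img.GetDimension()}D")
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise ValueError("expected a scalar image, got vector-valued payload")
    data = sitk.GetArrayFromImage(img).T
    return VoxelGrid(np.ascontiguousarray(data), img.GetSpacing(), img.GetOrigin())


def write_dvf(field: DeformationField, path: str | os.PathLike) -> None:
    """Write a 3-vector deformation field (direction is not stored in the file)."""
    sitk.WriteImage(_to_sitk(field.vectors, field.spacing, field.origin, vector=True), str(path))


def read_dvf(path: str | os.PathLike, direction: str) -> DeformationField:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3 or img.GetNumberOfComponentsPerPixel() != 3:
        raise ValueError("expected a 3D image with 3 components per voxel")
    arr = sitk.GetArrayFromImage(img)  # (z,y,x,3)
    vectors = np.ascontiguousarray(np.transpose(arr, (2, 1, 0, 3)))
    return DeformationField(vectors, direction, img.GetSpacing(), img.GetOrigin())


def write_mask(mask: ROIMask, path: str | os.PathLike) -> None:
    write_grid(mask.grid.like(mask.mask.astype(np.uint8)), path)


def read_mask(path: str | os.PathLike, name: str) -> ROIMask:
    g = read_grid(path)
    return ROIMask(g.like(g.data > 0), name)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample(grid: VoxelGrid, target: GridGeometry, mode: str = "trilinear") -> VoxelGrid:
    """Resample a grid onto a target geometry.

    ``trilinear`` interpolation is exact for affine-linear fields and cannot
    overshoot the source min/max (edge handling clamps to the nearest voxel).
    ``nearest`` reproduces the source exactly when the grids coincide.
    """
    if mode not in ("nearest", "trilinear"):
        raise ValueError(f"mode must be 'nearest' or 'trilinear', got {mode!r}")
    if target.shape == grid.geometry.shape and np.allclose(
        target.spacing, grid.spacing
    ) and np.allclose(target.origin, grid.origin):
        return grid.copy()
    centers = target.voxel_centers()
    xx, yy, zz = np.meshgrid(*centers, indexing="ij")
    world = np.stack([xx, yy, zz], axis=-1)
    idx = grid.geometry.world_to_index(world)
    coords = np.moveaxis(idx, -1, 0)
    order = 0 if mode == "nearest" else 1
    data = ndimage.map_coordinates(
        grid.data.astype(float), coords.reshape(3, -1), order=order, mode="nearest"
    ).reshape(target.shape)
    return VoxelGrid(data, target.spacing, target.origin)


def resample_matrix(source: GridGeometry, target: GridGeometry):
    """Sparse trilinear interpolation operator R with ``R @ vec(source) = vec(target)``.

    Rows are target voxels (flattened C-order), columns source voxels.  Used to
    make the repeated dose-grid -> CT/DVF-grid resampling inside the
    accumulation loop a single sparse mat-vec.
    """
    import scipy.sparse as sp

    centers = target.voxel_centers()
    xx, yy, zz = np.meshgrid(*centers, indexing="ij")
    world = np.stack([xx, yy, zz], axis=-1).reshape(-1, 3)
    idx = source.world_to_index(world)
    # clamp: replicate-edge behaviour, matching resample()
    for a in range(3):
        idx[:, a] = np.clip(idx[:, a], 0.0, source.shape[a] - 1.0)
    i0 = np.floor(idx).astype(np.int64)
    for a in range(3):
        i0[:, a] = np.minimum(i0[:, a], source.shape[a] - 2) if source.shape[a] > 1 else 0
    frac = idx - i0
    n_t = int(np.prod(target.shape))
    n_s = int(np.prod(source.shape))
    rows, cols, vals = [], [], []
    row_idx = np.arange(n_t)
    for dx in (0, 1):
        wx = frac[:, 0] if dx else 1.0 - frac[:, 0]
        for dy in (0, 1):
            wy = frac[:, 1] if dy else 1.0 - frac[:, 1]
            for dz in (0, 1):
                wz = frac[:, 2] if dz else 1.0 - frac[:, 2]
                w = wx * wy * wz
                keep = w > 0
                if not np.any(keep):
                    continue
                ci = np.ravel_multi_index(
                    (
                        np.minimum(i0[keep, 0] + dx, source.shape[0] - 1),
                        np.minimum(i0[keep, 1] + dy, source.shape[1] - 1),
                        np.minimum(i0[keep, 2] + dz, source.shape[2] - 1),
                    ),
                    source.shape,
                )
                rows.append(row_idx[keep])
                cols.append(ci)
                vals.append(w[keep])
    R = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_t, n_s),
    )
    R.sum_duplicates()
    return R.tocsr()
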
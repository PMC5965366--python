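"""Beam geometry, bixel grid, MLC apertures and dose-influence generation.

The fluence of each coplanar beam is subdivided into rectangular bixels
(leaf-travel x leaf-width).  For every (beam, phase) pair a sparse
dose-influence matrix D maps bixel weights to dose-grid voxels:

    D[j, v] = A * exp(-mu * d_rad(v)) * Px(v) * Py(v)

where ``d_rad`` is the radiological depth (density-scaled path length from
the grid entry to the voxel along the beam direction), and ``Px``/``Py`` are
error-function edge profiles of the bixel aperture with penumbra width
``sigma`` (chosen so the 80-20 lateral falloff matches the ~6.4 mm photon
penumbra in lung).  This analytic pencil kernel deliberately keeps only the
two physical effects the motion-interplay study depends on — exponential
attenuation in heterogeneous tissue and a finite penumbra — and is fully
deterministic.

Beams are modelled as parallel (unit magnification): the pencil axes of all
bixels share the beam direction, consistent with the orthographic
beam's-eye-view projection used for aperture tracking.  Gantry angle 0
points the beam along +LR.  The collimator is held rotated so that leaf
*travel* runs along SI for every beam — the standard choice for MLC
tracking of lung targets, since the dominant (SI) motion component is then
compensated continuously while only the small transverse component is
quantized to whole leaf widths.  The leaf-width axis is the gantry-rotated
in-plane transverse axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy import ndimage
from scipy.special import erf

from .grids import GridGeometry, VoxelGrid, resample

#: 80-20 penumbra distance of an erf edge equals 1.683 * sigma.
PENUMBRA_80_20_PER_SIGMA = 2.0 * 0.8416212335729143


@dataclass(frozen=True)
class KernelConfig:
    """Analytic dose kernel parameters."""

    mu_per_mm: float = 0.005          # effective attenuation, ~6 MV in water
    penumbra_80_20_mm: float = 6.4    # lateral 80-20 falloff in lung
    dose_per_mu: float = 0.01         # Gy per MU per unit weight, open field entry
    cutoff_rel: float = 1e-4          # drop entries below this fraction of bixel max
    depth_step_mm: float = 2.0        # integration step for radiological depth
    lateral_cut_sigma: float = 4.0    # candidate window half-width beyond bixel edge
    dtype: type = np.float32

    @property
    def sigma_mm(self) -> float:
        return self.penumbra_80_20_mm / PENUMBRA_80_20_PER_SIGMA


@dataclass(frozen=True)
class BeamGeometry:
    """One isocentric coplanar beam with its bixel grid at the isocenter plane."""

    gantry_deg: float
    sad_mm: float = 1000.0
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)
    bixel_size: tuple[float, float] = (5.0, 5.0)  # (leaf travel, leaf width) mm
    n_bixels: tuple[int, int] = (16, 16)          # (columns, leaf pairs)

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from source toward the isocenter."""
        g = np.deg2rad(self.gantry_deg)
        return np.array([np.cos(g), np.sin(g), 0.0])

    @property
    def bev_x(self) -> np.ndarray:
        """Leaf-travel axis: SI for every beam (collimator rotated 90 deg)."""
        return np.array([0.0, 0.0, 1.0])

    @property
    def bev_y(self) -> np.ndarray:
        """Leaf-width axis: the in-plane transverse axis of the beam."""
        g = np.deg2rad(self.gantry_deg)
        return np.array([-np.sin(g), np.cos(g), 0.0])

    @property
    def n_leaf_pairs(self) -> int:
        return self.n_bixels[1]

    def bixel_centers_x(self) -> np.ndarray:
        nx, bx = self.n_bixels[0], self.bixel_size[0]
        return (np.arange(nx) - (nx - 1) / 2.0) * bx

    def bixel_centers_y(self) -> np.ndarray:
        ny, by = self.n_bixels[1], self.bixel_size[1]
        return (np.arange(ny) - (ny - 1) / 2.0) * by

    def bixel_edges_x(self) -> np.ndarray:
        cx = self.bixel_centers_x()
        return np.concatenate([cx - self.bixel_size[0] / 2.0, [cx[-1] + self.bixel_size[0] / 2.0]])

    def bev_coords(self, world: np.ndarray) -> np.ndarray:
        """(..., 2) BEV coordinates (leaf travel, leaf width) of world points."""
        rel = np.asarray(world, dtype=float) - np.asarray(self.isocenter)
        return np.stack([rel @ self.bev_x, rel @ self.bev_y], axis=-1)

    def depth_coord(self, world: np.ndarray) -> np.ndarray:
        rel = np.asarray(world, dtype=float) - np.asarray(self.isocenter)
        return rel @ self.direction


def beams_equidistant(
    n: int = 9, start_deg: float = 0.0, **kwargs
) -> list[BeamGeometry]:
    """The default 9 equidistant coplanar beams (0, 40, ..., 320 degrees)."""
    return [BeamGeometry(gantry_deg=start_deg + i * 360.0 / n, **kwargs) for i in range(n)]


@dataclass
class MLCAperture:
    """Per-leaf-pair opening (mm, leaf-travel coordinate) and monitor units."""

    left: np.ndarray
    right: np.ndarray
    mu: float = 0.0

    def __post_init__(self):
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != self.right.shape or self.left.ndim != 1:
            raise ValueError("left/right must be 1D arrays of equal length")
        if np.any(self.left > self.right + 1e-12):
            raise ValueError("every leaf pair must satisfy left <= right")
        if self.mu < 0:
            raise ValueError("MU must be >= 0")

    @property
    def n_pairs(self) -> int:
        return self.left.size

    @property
    def open_area_mm2(self) -> float:
        """Open area assuming pairs of the beam's leaf width (set by caller)."""
        return float(np.sum(self.right - self.left))

    def is_closed(self) -> bool:
        return bool(np.all(self.right - self.left <= 0))

    @staticmethod
    def closed(n_pairs: int, mu: float = 0.0) -> "MLCAperture":
        z = np.zeros(n_pairs)
        return MLCAperture(z, z.copy(), mu)


@dataclass
class DoseInfluence:
    """Sparse bixel-by-voxel dose matrix for one (beam, phase).

    Row j (flattened ``jy * nx + jx``) holds the dose (Gy) per unit bixel
    weight per MU over the flattened dose grid.
    """

    matrix: sp.csr_matrix
    beam: BeamGeometry
    geometry: GridGeometry

    @property
    def nnz_fraction(self) -> float:
        return self.matrix.nnz / float(np.prod(self.matrix.shape))


# ---------------------------------------------------------------------------
# Radiological depth
# ---------------------------------------------------------------------------

def radiological_depth(density: VoxelGrid, beam: BeamGeometry,
                       step_mm: float = 2.0) -> np.ndarray:
    """Density-scaled path length (g/cm3 * mm) from grid entry to every voxel.

    Computed by resampling the density onto a beam-aligned frame, integrating
    along the beam direction with the midpoint rule, and sampling the result
    back at the voxel centers.  All rays are parallel to the beam axis.
    """
    geom = density.geometry
    centers = geom.voxel_centers()
    corners = np.array(np.meshgrid(
        [centers[0][0], centers[0][-1]],
        [centers[1][0], centers[1][-1]],
        [centers[2][0], centers[2][-1]], indexing="ij")).reshape(3, -1).T
    s = beam.depth_coord(corners)
    a = beam.bev_coords(corners)
    s_axis = np.arange(s.min() - step_mm, s.max() + 2 * step_mm, step_mm)
    a_axis = np.arange(a[:, 0].min() - step_mm, a[:, 0].max() + 2 * step_mm, step_mm)
    b_axis = np.arange(a[:, 1].min() - step_mm, a[:, 1].max() + 2 * step_mm, step_mm)

    S, A, B = np.meshgrid(s_axis, a_axis, b_axis, indexing="ij")
    world = (np.asarray(beam.isocenter)
             + S[..., None] * beam.direction
             + A[..., None] * beam.bev_x
             + B[..., None] * beam.bev_y)
    idx = geom.world_to_index(world)
    rho = ndimage.map_coordinates(
        density.data.astype(float), np.moveaxis(idx, -1, 0).reshape(3, -1),
        order=1, mode="constant", cval=0.0,
    ).reshape(S.shape)
    # midpoint cumulative integral along the beam axis
    cum = np.cumsum(rho, axis=0) * step_mm
    drad_frame = cum - 0.5 * rho * step_mm

    xx, yy, zz = np.meshgrid(*centers, indexing="ij")
    vox = np.stack([xx, yy, zz], axis=-1)
    vs = beam.depth_coord(vox)
    va = beam.bev_coords(vox)
    fi = np.stack([
        (vs - s_axis[0]) / step_mm,
        (va[..., 0] - a_axis[0]) / step_mm,
        (va[..., 1] - b_axis[0]) / step_mm,
    ], axis=0)
    drad = ndimage.map_coordinates(
        drad_frame, fi.reshape(3, -1), order=1, mode="nearest"
    ).reshape(geom.shape)
    return np.maximum(drad, 0.0)


# ---------------------------------------------------------------------------
# Dose influence
# ---------------------------------------------------------------------------

def generate_dose_influence(
    density: VoxelGrid,
    beam: BeamGeometry,
    kernel: KernelConfig = KernelConfig(),
    dose_geometry: GridGeometry | None = None,
) -> DoseInfluence:
    """Sparse dose-influence matrix of one beam on one phase's density.

    If ``dose_geometry`` differs from the density grid, the density is first
    trilinearly resampled onto it (dose is computed on the coarser dose grid;
    the CT grid only feeds the density).
    """
    if dose_geometry is not None and dose_geometry != density.geometry:
        density = resample(density, dose_geometry, mode="trilinear")
    geom = density.geometry
    n_vox = int(np.prod(geom.shape))

    drad = radiological_depth(density, beam, kernel.depth_step_mm).ravel()
    atten = kernel.dose_per_mu * np.exp(-kernel.mu_per_mm * drad)

    centers = geom.voxel_centers()
    xx, yy, zz = np.meshgrid(*centers, indexing="ij")
    vox = np.stack([xx, yy, zz], axis=-1)
    bev = beam.bev_coords(vox).reshape(-1, 2)
    bx, by = bev[:, 0], bev[:, 1]

    order_x = np.argsort(bx, kind="stable")
    bx_sorted = bx[order_x]
    sigma = kernel.sigma_mm
    sq2s = np.sqrt(2.0) * sigma
    half_x = beam.bixel_size[0] / 2.0
    half_y = beam.bixel_size[1] / 2.0
    pad = kernel.lateral_cut_sigma * sigma

    cxs = beam.bixel_centers_x()
    cys = beam.bixel_centers_y()
    nx = cxs.size

    rows, cols, vals = [], [], []
    for jx, cx in enumerate(cxs):
        lo = np.searchsorted(bx_sorted, cx - half_x - pad, side="left")
        hi = np.searchsorted(bx_sorted, cx + half_x + pad, side="right")
        slab = order_x[lo:hi]
        if slab.size == 0:
            continue
        # order the leaf-travel slab by the leaf-width coordinate so each
        # row's candidates are one contiguous range
        slab = slab[np.argsort(by[slab], kind="stable")]
        by_slab = by[slab]
        px_slab = 0.5 * (erf((bx[slab] - cx + half_x) / sq2s)
                         - erf((bx[slab] - cx - half_x) / sq2s))
        att_slab = atten[slab]
        for jy, cy in enumerate(cys):
            a = np.searchsorted(by_slab, cy - half_y - pad, side="left")
            b = np.searchsorted(by_slab, cy + half_y + pad, side="right")
            if a >= b:
                continue
            cand = slab[a:b]
            py = 0.5 * (erf((by_slab[a:b] - cy + half_y) / sq2s)
                        - erf((by_slab[a:b] - cy - half_y) / sq2s))
            d = att_slab[a:b] * px_slab[a:b] * py
            dmax = d.max(initial=0.0)
            if dmax <= 0:
                continue
            keep = d >= kernel.cutoff_rel * dmax
            if not np.any(keep):
                continue
            j = jy * nx + jx
            rows.append(np.full(int(keep.sum()), j, dtype=np.int64))
            cols.append(cand[keep])
            vals.append(d[keep].astype(kernel.dtype))

    n_bix = nx * cys.size
    if rows:
        mat = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_bix, n_vox),
        )
    else:
        mat = sp.csr_matrix((n_bix, n_vox), dtype=kernel.dtype)
    return DoseInfluence(mat, beam, geom)


# ---------------------------------------------------------------------------
# Aperture -> weights -> dose
# ---------------------------------------------------------------------------

def aperture_to_weights(aperture: MLCAperture, beam: BeamGeometry) -> np.ndarray:
    """Fractional 1D overlap of every bixel with its leaf pair's open interval.

    The leaf-width (y) direction is whole-leaf, so rows are fully governed by
    their pair; within a row the weight is the open fraction of the bixel's
    leaf-travel extent.  Apertures reaching beyond the bixel grid are clipped
    with a warning.
    """
    if aperture.n_pairs != beam.n_leaf_pairs:
        raise ValueError(
            f"aperture has {aperture.n_pairs} pairs, beam expects {beam.n_leaf_pairs}"
        )
    edges = beam.bixel_edges_x()
    nx = beam.n_bixels[0]
    grid_lo, grid_hi = edges[0], edges[-1]
    if np.any((aperture.right - aperture.left > 0)
              & ((aperture.left < grid_lo - 1e-9) | (aperture.right > grid_hi + 1e-9))):
        warnings.warn("aperture extends beyond the bixel grid; clipping", stacklevel=2)
    w = np.zeros((beam.n_leaf_pairs, nx))
    lefts = np.clip(aperture.left, grid_lo, grid_hi)
    rights = np.clip(aperture.right, grid_lo, grid_hi)
    for i in range(beam.n_leaf_pairs):
        lo = np.maximum(edges[:-1], lefts[i])
        hi = np.minimum(edges[1:], rights[i])
        w[i] = np.maximum(hi - lo, 0.0) / beam.bixel_size[0]
    return w.ravel()


def compute_aperture_dose(D: DoseInfluence, weights: np.ndarray, mu: float) -> VoxelGrid:
    """Dose grid of one aperture: dose(v) = mu * sum_j w_j D[j, v]."""
    if mu < 0:
        raise ValueError("MU must be >= 0")
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != D.matrix.shape[0]:
        raise ValueError("weight vector length does not match bixel count")
    vec = mu * (D.matrix.T @ w)
    return VoxelGrid(
        np.asarray(vec, dtype=float).reshape(D.geometry.shape),
        D.geometry.spacing,
        D.geometry.origin,
    )
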
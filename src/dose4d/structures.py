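"""Target-volume construction and motion/volume descriptors.

Two motion-inclusive target concepts are supported: the internal target
volume (ITV), the voxelwise union of the per-phase GTVs, and the moving
target volume (MTV), the union of the GTVs after rigidly aligning each
phase's GTV onto the reference GTV by its center of volume.  The MTV
presumes centroid MLC tracking removes the rigid component of the motion,
so only deformation (not translation) inflates the target.  Planning target
volumes are isotropic Euclidean expansions of either.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import ROIMask
from .phantom import mask_centroid


@dataclass
class MotionDescriptors:
    """Peak-to-peak centroid motion and GTV volume summary (Table-style)."""

    pp_si: float
    pp_ap: float
    pp_lr: float
    pp_3d: float
    vol_min_cm3: float
    vol_max_cm3: float
    vol_ref_cm3: float
    deformation_pct: float


def _check_same_geometry(masks: list[ROIMask]) -> None:
    g0 = masks[0].grid.geometry
    for m in masks[1:]:
        if m.grid.geometry != g0:
            raise ValueError("masks do not share a grid geometry")


def union_itv(gtv_masks: list[ROIMask], name: str = "ITV") -> ROIMask:
    """ITV: voxelwise union of the per-phase GTVs."""
    if not gtv_masks:
        raise ValueError("need at least one GTV mask")
    _check_same_geometry(gtv_masks)
    out = np.zeros_like(gtv_masks[0].mask)
    for m in gtv_masks:
        out |= m.mask
    return gtv_masks[0].like(out, name)


def shift_mask(mask: ROIMask, shift_voxels) -> ROIMask:
    """Translate a mask by whole voxels; voxels shifted off the grid are lost."""
    shift = tuple(int(s) for s in shift_voxels)
    out = np.zeros_like(mask.mask)
    src = []
    dst = []
    for a, s in enumerate(shift):
        n = mask.mask.shape[a]
        if abs(s) >= n:
            return mask.like(out)
        src.append(slice(max(0, -s), min(n, n - s)))
        dst.append(slice(max(0, s), min(n, n + s)))
    out[tuple(dst)] = mask.mask[tuple(src)]
    return mask.like(out)


def build_mtv(gtv_masks: list[ROIMask], ref: int, name: str = "MTV") -> ROIMask:
    """MTV: union of per-phase GTVs rigidly aligned onto the reference GTV.

    Each phase's GTV is translated by the nearest-voxel rounding of the
    centroid difference to the reference centroid (masks are boolean, so
    sub-voxel shifts would require an interpolation/threshold rule).
    """
    if not gtv_masks:
        raise ValueError("need at least one GTV mask")
    _check_same_geometry(gtv_masks)
    spacing = np.asarray(gtv_masks[ref].grid.spacing)
    c_ref = mask_centroid(gtv_masks[ref])
    out = np.zeros_like(gtv_masks[0].mask)
    for m in gtv_masks:
        shift_mm = c_ref - mask_centroid(m)
        shift_vox = np.round(shift_mm / spacing).astype(int)
        out |= shift_mask(m, shift_vox).mask
    return gtv_masks[ref].like(out, name)


def expand_margin(mask: ROIMask, margin_mm: float, name: str | None = None) -> ROIMask:
    """Isotropic Euclidean dilation: include every voxel whose center lies
    within `margin_mm` of any source-voxel center (anisotropic spacing
    respected)."""
    if margin_mm < 0:
        raise ValueError("margin must be >= 0")
    if margin_mm == 0 or not mask.mask.any():
        return mask.like(mask.mask.copy(), name or mask.name)
    dist = ndimage.distance_transform_edt(
        ~mask.mask, sampling=mask.grid.spacing
    )
    return mask.like(dist <= margin_mm + 1e-9, name or f"{mask.name}+{margin_mm:g}mm")


def select_midv_phase(centroids: list[np.ndarray], weights=None) -> int:
    """Mid-ventilation phase: centroid nearest the time-weighted mean position.

    With equal-duration phase bins the weights are uniform.  Ties go to the
    lower phase index.
    """
    cents = np.asarray(centroids, dtype=float)
    if cents.shape[0] < 2:
        raise ValueError("need at least 2 phases")
    w = np.ones(cents.shape[0]) if weights is None else np.asarray(weights, dtype=float)
    mean = (cents * w[:, None]).sum(axis=0) / w.sum()
    dists = np.linalg.norm(cents - mean, axis=1)
    return int(np.argmin(dists))


def motion_descriptors(
    centroids: list[np.ndarray], gtv_masks: list[ROIMask], ref: int
) -> MotionDescriptors:
    """Per-axis/3D peak-to-peak centroid motion and GTV volume spread.

    The 3D value is the Euclidean norm of the three per-axis peak-to-peak
    amplitudes; the deformation percentage is the maximum GTV volume increase
    relative to the reference phase.
    """
    cents = np.asarray(centroids, dtype=float)
    pp = cents.max(axis=0) - cents.min(axis=0)  # (LR, AP, SI)
    vols = np.array([m.volume_cm3 for m in gtv_masks])
    if np.any(vols <= 0):
        raise ValueError("GTV volumes must be positive")
    return MotionDescriptors(
        pp_si=float(pp[2]),
        pp_ap=float(pp[1]),
        pp_lr=float(pp[0]),
        pp_3d=float(np.linalg.norm(pp)),
        vol_min_cm3=float(vols.min()),
        vol_max_cm3=float(vols.max()),
        vol_ref_cm3=float(vols[ref]),
        deformation_pct=float((vols.max() - vols[ref]) / vols[ref] * 100.0),
    )


def pp3d_from_axes(pp_si: float, pp_ap: float, pp_lr: float) -> float:
    """3D peak-to-peak motion as the norm of the per-axis peak-to-peaks."""
    return float(np.linalg.norm([pp_si, pp_ap, pp_lr]))
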
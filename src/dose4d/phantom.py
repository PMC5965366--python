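"""Synthetic 4D breathing-thorax phantom.

Emulates a phase-binned 4DCT of a peripheral lung tumor: per respiratory
phase a density grid, GTV/lung/cord/airways masks, and *exact* analytic
deformation fields describing the tumor motion.  Phase 0 is the peak-exhale
reference phase; the tumor traverses a 1-cos respiratory cycle in SI and AP
(LR motion is ignored, as it is small for lung targets).

The deformation is rigid inside the tumor and decays to zero over a
C1-smooth (smoothstep) shell inside the lung, so that the fields resemble a
deformable registration output while keeping an analytic inverse.  Because
registration error is out of scope, the pull field is computed as the exact
numerical inverse of the analytic push field (fixed-point iteration),
isolating dose-mapping behaviour from registration quality.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .grids import (
    DeformationField,
    GridGeometry,
    ROIMask,
    VoxelGrid,
    read_dvf,
    read_grid,
    read_mask,
    write_dvf,
    write_grid,
    write_mask,
)

DENSITY_AIR = 0.001


@dataclass
class PhantomSpec:
    """Geometry, tissue and motion parameters of the digital phantom.

    Lengths in mm, densities in g/cm3, motion amplitudes peak-to-peak in mm.
    Defaults describe the study phantom: a small peripheral tumor with large
    superior-inferior motion (14 mm SI, 2.6 mm AP peak-to-peak) inside a
    static lung, sampled over ten respiratory phases.
    """

    ct_shape: tuple[int, int, int] = (128, 128, 64)
    ct_spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    dose_shape: tuple[int, int, int] = (64, 64, 64)
    dose_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)

    body_radii: tuple[float, float, float] = (60.0, 60.0, 63.0)
    body_density: float = 1.0
    lung_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    lung_radii: tuple[float, float, float] = (48.0, 42.0, 58.0)
    lung_density: float = 0.26
    tumor_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tumor_radii: tuple[float, float, float] = (10.0, 10.0, 10.0)
    tumor_density: float = 1.0
    cord_center: tuple[float, float] = (0.0, 48.0)  # (LR, AP), runs along SI
    cord_radius: float = 5.0
    cord_density: float = 1.0
    airway_center: tuple[float, float] = (0.0, -30.0)
    airway_radius: float = 6.0
    airway_density: float = 0.2

    amp_si: float = 14.0        # peak-to-peak SI motion, mm
    amp_ap: float = 2.6         # peak-to-peak AP motion, mm
    ap_phase_lag: float = 0.0   # rad; hysteresis between SI and AP
    deformation_coeff: float = 0.0  # fractional tumor-radius increase at peak inhale
    n_phases: int = 10
    falloff_mm: float = 24.0    # smoothstep shell over which displacement decays
    dvf_noise_mm: float = 0.0   # optional white perturbation of stored DVFs
    seed: int = 0

    def __post_init__(self):
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")
        if self.amp_si < 0 or self.amp_ap < 0:
            raise ValueError("motion amplitudes must be >= 0")
        if self.falloff_mm <= 0:
            raise ValueError("falloff_mm must be positive")

    @property
    def ct_geometry(self) -> GridGeometry:
        return GridGeometry.centered(self.ct_shape, self.ct_spacing)

    @property
    def dose_geometry(self) -> GridGeometry:
        return GridGeometry.centered(self.dose_shape, self.dose_spacing)

    def phase_displacements(self) -> np.ndarray:
        """(n_phases, 3) tumor displacement of each phase from the reference."""
        theta = 2.0 * np.pi * np.arange(self.n_phases) / self.n_phases

        def raw(th, lag=0.0):
            return 0.5 * (1.0 - np.cos(th - lag))

        d = np.zeros((self.n_phases, 3))
        d[:, 2] = self.amp_si * (raw(theta) - raw(0.0))
        d[:, 1] = self.amp_ap * (raw(theta, self.ap_phase_lag) - raw(0.0, self.ap_phase_lag))
        return d

    def phase_radius_scales(self) -> np.ndarray:
        theta = 2.0 * np.pi * np.arange(self.n_phases) / self.n_phases
        return 1.0 + self.deformation_coeff * 0.5 * (1.0 - np.cos(theta))

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as f:
            json.dump(dataclasses.asdict(self), f, indent=2)

    @staticmethod
    def from_json(path: str | os.PathLike) -> "PhantomSpec":
        with open(path) as f:
            raw = json.load(f)
        kwargs = {}
        for fld in dataclasses.fields(PhantomSpec):
            if fld.name in raw:
                v = raw[fld.name]
                kwargs[fld.name] = tuple(v) if isinstance(v, list) else v
        return PhantomSpec(**kwargs)


@dataclass
class Phase4DSet:
    """All per-phase data the reconstruction pipeline consumes."""

    spec: PhantomSpec
    densities: list[VoxelGrid]
    gtv: list[ROIMask]
    lung: ROIMask
    cord: ROIMask
    airways: ROIMask
    push: list[DeformationField]   # phase -> reference
    pull: list[DeformationField]   # reference -> phase
    reference: int = 0

    @property
    def n_phases(self) -> int:
        return len(self.densities)

    @property
    def ct_geometry(self) -> GridGeometry:
        return self.densities[0].geometry

    @property
    def dose_geometry(self) -> GridGeometry:
        return self.spec.dose_geometry

    def save(self, outdir: str | os.PathLike) -> None:
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        self.spec.to_json(os.path.join(outdir, "phantom_spec.json"))
        for p in range(self.n_phases):
            write_grid(self.densities[p], os.path.join(outdir, f"density_p{p}.nii.gz"))
            write_mask(self.gtv[p], os.path.join(outdir, f"gtv_p{p}.nii.gz"))
            write_dvf(self.push[p], os.path.join(outdir, f"push_p{p}.nii.gz"))
            write_dvf(self.pull[p], os.path.join(outdir, f"pull_p{p}.nii.gz"))
        for name, m in (("lung", self.lung), ("cord", self.cord), ("airways", self.airways)):
            write_mask(m, os.path.join(outdir, f"{name}.nii.gz"))
        manifest = {"n_phases": self.n_phases, "reference": self.reference}
        with open(os.path.join(outdir, "manifest.json"), "w") as f:
            json.dump(manifest, f, indent=2)

    @staticmethod
    def load(outdir: str | os.PathLike) -> "Phase4DSet":
        outdir = str(outdir)
        spec = PhantomSpec.from_json(os.path.join(outdir, "phantom_spec.json"))
        with open(os.path.join(outdir, "manifest.json")) as f:
            manifest = json.load(f)
        n = manifest["n_phases"]
        densities = [read_grid(os.path.join(outdir, f"density_p{p}.nii.gz")) for p in range(n)]
        gtv = [read_mask(os.path.join(outdir, f"gtv_p{p}.nii.gz"), f"GTV_{p}") for p in range(n)]
        push = [read_dvf(os.path.join(outdir, f"push_p{p}.nii.gz"), "push") for p in range(n)]
        pull = [read_dvf(os.path.join(outdir, f"pull_p{p}.nii.gz"), "pull") for p in range(n)]
        lung = read_mask(os.path.join(outdir, "lung.nii.gz"), "lung")
        cord = read_mask(os.path.join(outdir, "cord.nii.gz"), "cord")
        airways = read_mask(os.path.join(outdir, "airways.nii.gz"), "airways")
        return Phase4DSet(spec, densities, gtv, lung, cord, airways, push, pull,
                          manifest["reference"])


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _ellipsoid_level(points: np.ndarray, center, radii) -> np.ndarray:
    """Scaled radial coordinate g: g<=1 inside the ellipsoid."""
    rel = (points - np.asarray(center)) / np.asarray(radii)
    return np.sqrt(np.sum(rel * rel, axis=-1))


def _falloff_weight(points: np.ndarray, center, radii, shell: float) -> np.ndarray:
    """1 inside the tumor, C1-decaying to 0 over `shell` mm outside it."""
    g = _ellipsoid_level(points, center, radii)
    r_eff = float(min(radii))
    dist = np.maximum(g - 1.0, 0.0) * r_eff  # approx mm outside the surface
    return 1.0 - _smoothstep(dist / shell)


def _push_displacement(points: np.ndarray, disp, center, radii, shell: float) -> np.ndarray:
    """Analytic push field of one phase: -disp scaled by the falloff weight."""
    w = _falloff_weight(points, center, radii, shell)
    return -np.asarray(disp) * w[..., None]


def _voxel_center_stack(geom: GridGeometry) -> np.ndarray:
    cx, cy, cz = geom.voxel_centers()
    xx, yy, zz = np.meshgrid(cx, cy, cz, indexing="ij")
    return np.stack([xx, yy, zz], axis=-1)


def build_phantom(spec: PhantomSpec) -> Phase4DSet:
    """Rasterize the phantom for all phases and derive exact push/pull DVFs."""
    geom = spec.ct_geometry
    pts = _voxel_center_stack(geom)
    disps = spec.phase_displacements()
    scales = spec.phase_radius_scales()

    # invertibility of x -> x + push(x): smoothstep peak slope is 1.5/shell
    dmax = float(np.linalg.norm(disps, axis=1).max())
    if dmax * 1.5 / spec.falloff_mm >= 0.95:
        raise ValueError(
            f"motion {dmax:.1f} mm too large for falloff shell {spec.falloff_mm} mm; "
            "the deformation would fold over (increase falloff_mm)"
        )

    # analytic pre-check: the tumor surface must stay inside the lung at
    # every phase for the requested amplitude
    g = np.linspace(0, 2 * np.pi, 64)
    h = np.linspace(0, np.pi, 33)
    sph = np.stack([
        np.outer(np.cos(g), np.sin(h)).ravel(),
        np.outer(np.sin(g), np.sin(h)).ravel(),
        np.outer(np.ones_like(g), np.cos(h)).ravel(),
    ], axis=-1)
    for p in range(spec.n_phases):
        surf = (np.asarray(spec.tumor_center) + disps[p]
                + sph * np.asarray(spec.tumor_radii) * scales[p])
        if np.any(_ellipsoid_level(surf, spec.lung_center, spec.lung_radii) > 1.0):
            raise ValueError(
                f"tumor leaves the lung at phase {p} for the given amplitude"
            )

    lung_g = _ellipsoid_level(pts, spec.lung_center, spec.lung_radii)
    lung_mask = lung_g <= 1.0
    body_mask = _ellipsoid_level(pts, (0.0, 0.0, 0.0), spec.body_radii) <= 1.0
    cord_mask = (
        ((pts[..., 0] - spec.cord_center[0]) ** 2 + (pts[..., 1] - spec.cord_center[1]) ** 2)
        <= spec.cord_radius ** 2
    ) & body_mask
    airway_mask = (
        ((pts[..., 0] - spec.airway_center[0]) ** 2 + (pts[..., 1] - spec.airway_center[1]) ** 2)
        <= spec.airway_radius ** 2
    ) & lung_mask

    base = np.full(geom.shape, DENSITY_AIR)
    base[body_mask] = spec.body_density
    base[lung_mask] = spec.lung_density
    base[airway_mask] = spec.airway_density
    base[cord_mask] = spec.cord_density

    rng = np.random.default_rng(spec.seed)
    densities, gtvs, pushes, pulls = [], [], [], []
    for p in range(spec.n_phases):
        c_p = np.asarray(spec.tumor_center) + disps[p]
        radii_p = np.asarray(spec.tumor_radii) * scales[p]
        gtv_mask = _ellipsoid_level(pts, c_p, radii_p) <= 1.0
        if not gtv_mask.any():
            raise ValueError(f"GTV of phase {p} rasterizes to an empty mask")
        if np.any(gtv_mask & ~lung_mask):
            raise ValueError(f"tumor leaves the lung at phase {p} for the given amplitude")

        dens = base.copy()
        dens[gtv_mask] = spec.tumor_density
        densities.append(VoxelGrid(dens, geom.spacing, geom.origin))
        gtvs.append(ROIMask(VoxelGrid(gtv_mask, geom.spacing, geom.origin), f"GTV_{p}"))

        if not np.any(disps[p]):
            zero = np.zeros(geom.shape + (3,), dtype=np.float32)
            pushes.append(DeformationField(zero, "push", geom.spacing, geom.origin))
            pulls.append(DeformationField(zero.copy(), "pull", geom.spacing, geom.origin))
            continue

        push_vec = np.zeros(geom.shape + (3,), dtype=np.float32)
        # restrict evaluation to the moving bounding box (displacement decays
        # to zero beyond tumor + shell)
        pad = np.asarray(radii_p) + spec.falloff_mm + 1.0
        lo = geom.world_to_index(c_p - pad)
        hi = geom.world_to_index(c_p + pad)
        sl = tuple(
            slice(max(0, int(np.floor(lo[a]))), min(geom.shape[a], int(np.ceil(hi[a])) + 1))
            for a in range(3)
        )
        box_pts = pts[sl]
        v = _push_displacement(box_pts, disps[p], c_p, radii_p, spec.falloff_mm)
        if np.any(_falloff_weight(box_pts, c_p, radii_p, spec.falloff_mm)[~lung_mask[sl]] > 1e-9):
            raise ValueError(
                f"deformation shell of phase {p} reaches the lung boundary; "
                "shrink the tumor, the motion or the falloff shell"
            )
        push_vec[sl] = v
        # pull = exact inverse of the analytic push, by fixed-point iteration:
        # u(x_ref) satisfies u = -push(x_ref + u)
        pull_vec = np.zeros(geom.shape + (3,), dtype=np.float32)
        ref_pad = pad + abs(np.asarray(disps[p]))
        lo = geom.world_to_index(np.asarray(spec.tumor_center) - ref_pad)
        hi = geom.world_to_index(np.asarray(spec.tumor_center) + ref_pad)
        slr = tuple(
            slice(max(0, int(np.floor(lo[a]))), min(geom.shape[a], int(np.ceil(hi[a])) + 1))
            for a in range(3)
        )
        x_ref = pts[slr].reshape(-1, 3)
        u = -_push_displacement(x_ref, disps[p], c_p, radii_p, spec.falloff_mm).reshape(-1, 3)
        for _ in range(300):
            u_new = -_push_displacement(
                x_ref + u, disps[p], c_p, radii_p, spec.falloff_mm
            ).reshape(-1, 3)
            step = np.abs(u_new - u).max()
            u = u_new
            if step < 1e-5:
                break
        pull_vec[slr] = u.reshape(pts[slr].shape).astype(np.float32)

        if spec.dvf_noise_mm > 0:
            push_vec += rng.normal(0.0, spec.dvf_noise_mm, push_vec.shape).astype(np.float32)
            pull_vec += rng.normal(0.0, spec.dvf_noise_mm, pull_vec.shape).astype(np.float32)

        pushes.append(DeformationField(push_vec, "push", geom.spacing, geom.origin))
        pulls.append(DeformationField(pull_vec, "pull", geom.spacing, geom.origin))

    lung_roi = ROIMask(VoxelGrid(lung_mask, geom.spacing, geom.origin), "lung")
    cord_roi = ROIMask(VoxelGrid(cord_mask, geom.spacing, geom.origin), "cord")
    airway_roi = ROIMask(VoxelGrid(airway_mask, geom.spacing, geom.origin), "airways")
    return Phase4DSet(spec, densities, gtvs, lung_roi, cord_roi, airway_roi, pushes, pulls, 0)


def gtv_centroids(phases: Phase4DSet) -> list[np.ndarray]:
    """Center-of-volume (mm) of the GTV of every phase."""
    return [mask_centroid(m) for m in phases.gtv]


def mask_centroid(mask: ROIMask) -> np.ndarray:
    """Mean world position of the voxel centers inside a mask."""
    idx = np.argwhere(mask.mask)
    if idx.size == 0:
        raise ValueError(f"mask {mask.name!r} is empty")
    return mask.grid.index_to_world(idx).mean(axis=0)
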
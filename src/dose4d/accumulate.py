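"""Energy-mass-transfer (EMT) dose accumulation onto the reference phase.

Direct dose mapping (DDM) interpolates dose values through the deformation
and can mis-state dose near sharp gradients when tissue compresses or
expands.  EMT instead transports energy and mass separately — each phase
voxel's mass is split into ``s^3`` equal subvoxels, every subvoxel carries
``dose * mass / s^3`` of energy, is displaced by the trilinearly
interpolated push field and binned into its containing reference voxel —
and only then divides deposited energy by deposited ("deformed") mass.
Dose, being energy per mass, is thereby conserved by construction.  Each
displaced subvoxel is treated as a rigidly translated cube and its volume is
split *exactly* over the reference voxels it overlaps (volume-weighted
deposition); for an identity field or a whole-voxel translation the cube
lies entirely inside one voxel, so those cases remain bit-exact, while for
general fields the deposition varies continuously with displacement and
converges quickly in the subvoxel count.

Because the subvoxel transport is linear in the per-voxel quantity it
carries, it is materialized once per phase as a sparse transfer operator
S (reference voxels x phase voxels) whose entries are the transported voxel
*fractions*:  deformed mass = S @ mass and deposited energy = S @ (dose *
mass).  This is the precomputation the online loop depends on; per tick the
accumulation reduces to sparse mat-vecs.  A phase whose push field is
identically zero (the reference phase itself) keeps ``S = None`` and is
accumulated through the identity path, making a zero-motion delivery
bit-identical to a static one.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .beam import DoseInfluence, aperture_to_weights
from .delivery import DeliveryMode, DeliveryTick, TreatmentPlan
from .grids import DeformationField, GridGeometry, VoxelGrid, resample, resample_matrix

MASS_FLOOR_G = 1e-6  # below this deformed mass (air) the quotient dose is zeroed


def voxel_mass(density: VoxelGrid) -> VoxelGrid:
    """Mass grid (g): density (g/cm3) times voxel volume (cm3)."""
    if np.any(density.data < 0):
        raise ValueError("density must be >= 0")
    return density.like(density.data * density.voxel_volume_cm3)


# ---------------------------------------------------------------------------
# Subvoxel transfer operator
# ---------------------------------------------------------------------------

def build_transfer(
    push: DeformationField, subvoxels: int = 4, active: np.ndarray | None = None
) -> sp.csr_matrix | None:
    """Sparse subvoxel push operator S for one phase, or None for identity.

    ``S[v_ref, v_phase]`` is the volume fraction of phase voxel ``v_phase``
    that lands in reference voxel ``v_ref`` after displacing its ``s^3``
    subvoxel cubes; column sums below 1 are mass lost off the grid.  Voxels
    outside ``active`` (default: the dilated support of the push field) are
    mapped identically, which is exact because their displacement — and by
    trilinear interpolation that of all their subvoxels — is zero.
    """
    s = int(subvoxels)
    if s < 1:
        raise ValueError("subvoxels must be >= 1")
    if push.is_zero():
        return None
    geom = push.geometry
    shape = geom.shape
    n = int(np.prod(shape))
    spacing = np.asarray(geom.spacing)

    if active is None:
        moving = np.any(push.vectors != 0, axis=-1)
        # one-voxel dilation: trilinear interpolation reaches one voxel out
        from scipy import ndimage

        active = ndimage.binary_dilation(moving, iterations=1)
    act_idx = np.argwhere(active)
    act_flat = np.ravel_multi_index(act_idx.T, shape)

    # identity part for the static voxels
    static_flat = np.setdiff1d(np.arange(n), act_flat, assume_unique=False)
    S = sp.coo_matrix(
        (np.ones(static_flat.size), (static_flat, static_flat)), shape=(n, n)
    ).tocsr()
    rows: list = []
    cols: list = []
    vals: list = []

    def flush():
        nonlocal S, rows, cols, vals
        if not rows:
            return
        part = sp.coo_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))), shape=(n, n))
        part.sum_duplicates()
        S = S + part.tocsr()
        rows, cols, vals = [], [], []

    centers = geom.index_to_world(act_idx)  # (m, 3)
    offs = (np.arange(s) + 0.5) / s - 0.5   # subvoxel center offsets in voxel units
    frac = 1.0 / s**3
    hh = 1.0 / (2.0 * s)  # subvoxel half-width in voxel units
    nshape = np.asarray(shape)
    n_sub = 0
    for ox in offs:
        for oy in offs:
            for oz in offs:
                n_sub += 1
                sub = centers + np.array([ox, oy, oz]) * spacing
                disp = push.sample(sub)
                landed = geom.world_to_index(sub + disp)  # cube center, index units
                # the displaced subvoxel is a cube of side 1/s voxels; split its
                # volume exactly over the (up to 8) reference voxels it overlaps
                lo = landed - hh
                i0 = np.floor(lo + 0.5).astype(np.int64)
                # overlap fraction of the lower voxel along each axis
                w0 = np.clip((i0 + 0.5 - lo) / (2.0 * hh), 0.0, 1.0)
                for corner in range(8):
                    d = np.array([(corner >> a) & 1 for a in range(3)])
                    idx = i0 + d
                    w = np.prod(np.where(d == 0, w0, 1.0 - w0), axis=1)
                    inside = np.all((idx >= 0) & (idx < nshape), axis=1) & (w > 0)
                    if not np.any(inside):
                        continue
                    rows.append(np.ravel_multi_index(idx[inside].T, shape))
                    cols.append(act_flat[inside])
                    vals.append(frac * w[inside])
                if n_sub % 16 == 0:  # bound the COO working set
                    flush()
    flush()
    return S


@dataclass
class DeformedMass:
    """Per-phase mass pushed onto the reference grid, with the loss ledger."""

    mass: VoxelGrid           # deposited mass on the reference grid, g
    lost_mass: float          # mass displaced off the grid, g
    transfer: sp.csr_matrix | None  # None = identity (reference phase)
    source_mass: VoxelGrid    # phase-frame mass grid, g


def precompute_deformed_mass(
    densities: list[VoxelGrid],
    pushes: list[DeformationField],
    subvoxels: int = 4,
) -> list[DeformedMass]:
    """Deformed-mass grids and transfer operators for every phase."""
    out = []
    for dens, push in zip(densities, pushes):
        m = voxel_mass(dens)
        S = build_transfer(push, subvoxels)
        if S is None:
            out.append(DeformedMass(m.copy(), 0.0, None, m))
            continue
        vec = S @ m.data.ravel()
        deposited = m.like(vec.reshape(m.data.shape))
        lost = float(m.data.sum() - vec.sum())
        out.append(DeformedMass(deposited, lost, S, m))
    return out


# ---------------------------------------------------------------------------
# Energy mapping and the EMT quotient
# ---------------------------------------------------------------------------

def emt_map(
    dose: VoxelGrid,
    mass: VoxelGrid,
    push: DeformationField | None,
    subvoxels: int = 4,
    transfer: sp.csr_matrix | None = None,
) -> tuple[VoxelGrid, float]:
    """Push a phase-frame dose's energy onto the reference grid.

    Returns (energy grid, lost energy).  ``dose`` must already live on the
    DVF grid.  A prebuilt transfer operator may be passed to skip the
    subvoxel transport.
    """
    if dose.geometry != mass.geometry:
        raise ValueError("dose and mass must share the DVF grid geometry")
    energy_src = dose.data * mass.data
    if transfer is None and push is not None:
        transfer = build_transfer(push, subvoxels)
    if transfer is None:
        return dose.like(energy_src.copy()), 0.0
    vec = transfer @ energy_src.ravel()
    lost = float(energy_src.sum() - vec.sum())
    return dose.like(vec.reshape(dose.data.shape)), lost


def emt_dose(
    energy: VoxelGrid, deformed_mass: VoxelGrid, mass_floor: float = MASS_FLOOR_G
) -> VoxelGrid:
    """Dose = deposited energy / deformed mass, zero where mass is below floor."""
    m = deformed_mass.data
    out = np.zeros_like(energy.data, dtype=float)
    ok = m > mass_floor
    out[ok] = energy.data[ok] / m[ok]
    return energy.like(out)


def ddm_map(dose: VoxelGrid, pull: DeformationField) -> VoxelGrid:
    """Direct dose mapping comparator: trilinear sample of the phase dose at
    each reference voxel's pulled position."""
    if pull.direction != "pull":
        raise ValueError("ddm_map needs a pull (reference -> phase) field")
    geom = pull.geometry
    cx, cy, cz = geom.voxel_centers()
    xx, yy, zz = np.meshgrid(cx, cy, cz, indexing="ij")
    ref = np.stack([xx, yy, zz], axis=-1)
    pulled = ref + pull.vectors
    idx = dose.geometry.world_to_index(pulled)
    from scipy import ndimage

    vals = ndimage.map_coordinates(
        dose.data.astype(float), np.moveaxis(idx, -1, 0).reshape(3, -1),
        order=1, mode="nearest",
    ).reshape(geom.shape)
    return VoxelGrid(vals, geom.spacing, geom.origin)


# ---------------------------------------------------------------------------
# Accumulation
# ---------------------------------------------------------------------------

@dataclass
class AccumulatorState:
    """Running reference-frame dose plus energy and runtime ledgers."""

    dose: VoxelGrid                 # reference (DVF-grid) frame, Gy
    mode: DeliveryMode
    planning_phase: int
    lost_energy: dict = field(default_factory=dict)    # phase -> lost energy
    tick_ms: list = field(default_factory=list)        # wall-clock per tick

    @staticmethod
    def empty(geometry: GridGeometry, mode: DeliveryMode, planning_phase: int):
        z = VoxelGrid(np.zeros(geometry.shape), geometry.spacing, geometry.origin)
        return AccumulatorState(z, mode, planning_phase)

    def runtime_summary(self) -> dict:
        if not self.tick_ms:
            return {"mean_ms": 0.0, "p5_ms": 0.0, "p95_ms": 0.0, "n": 0}
        arr = np.asarray(self.tick_ms)
        return {
            "mean_ms": float(arr.mean()),
            "p5_ms": float(np.percentile(arr, 5)),
            "p95_ms": float(np.percentile(arr, 95)),
            "n": int(arr.size),
        }


class DoseReconstructor:
    """Holds the precomputed stores and applies the four-step online loop.

    Per tick: (1) aperture -> bixel weights, (2) weights x dose influence ->
    phase dose, resampled to the DVF grid and converted to energy,
    (3) energy / deformed mass, (4) add to the running reference dose.
    In STATIC mode steps 2-3 are bypassed and the phase-frame dose of the
    planning phase is added directly.
    """

    def __init__(
        self,
        dose_influence,                    # (beam_index, phase) -> DoseInfluence
        deformed: list[DeformedMass],
        dose_geometry: GridGeometry,
        ct_geometry: GridGeometry,
        beams: list | None = None,
    ):
        self.dose_influence = dose_influence
        self.deformed = deformed
        self.dose_geometry = dose_geometry
        self.ct_geometry = ct_geometry
        self.beams = beams
        self.R = resample_matrix(dose_geometry, ct_geometry)

    def _phase_dose_to_ref(self, dose_vec: np.ndarray, phase: int, state: AccumulatorState):
        """Steps 2-4 for a phase-frame dose vector on the dose grid."""
        d_ct = self.R @ dose_vec
        dm = self.deformed[phase]
        if dm.transfer is None:
            state.dose.data += d_ct.reshape(self.ct_geometry.shape)
            return
        energy_src = d_ct * dm.source_mass.data.ravel()
        energy = dm.transfer @ energy_src
        lost = float(energy_src.sum() - energy.sum())
        state.lost_energy[phase] = state.lost_energy.get(phase, 0.0) + lost
        quot = np.zeros_like(energy)
        ok = dm.mass.data.ravel() > MASS_FLOOR_G
        quot[ok] = energy[ok] / dm.mass.data.ravel()[ok]
        state.dose.data += quot.reshape(self.ct_geometry.shape)

    def accumulate_tick(self, state: AccumulatorState, tick: DeliveryTick) -> AccumulatorState:
        """Apply one delivery tick to the running dose (streaming API)."""
        t0 = time.perf_counter()
        if tick.mu > 0:
            phase = state.planning_phase if state.mode is DeliveryMode.STATIC else tick.phase_bin
            D = self.dose_influence(tick.beam_index, phase)
            w = aperture_to_weights(tick.aperture, D.beam)
            dose_vec = tick.mu * (D.matrix.T @ w)
            if state.mode is DeliveryMode.STATIC:
                state.dose.data += (self.R @ dose_vec).reshape(self.ct_geometry.shape)
            else:
                self._phase_dose_to_ref(np.asarray(dose_vec, dtype=float), phase, state)
        state.tick_ms.append((time.perf_counter() - t0) * 1e3)
        return state

    def accumulate_delivery(
        self, plan: TreatmentPlan, ticks: list[DeliveryTick], mode: DeliveryMode
    ) -> AccumulatorState:
        """Accumulate a full tick stream, batched by (beam, phase).

        Dose is linear in the bixel weights and EMT is linear in the
        phase-frame dose, so MU-weighted weight vectors are summed per
        (beam, phase) first and each dose-influence matrix and transfer
        operator is applied once.  The result equals the tick-by-tick loop
        up to floating-point summation order.
        """
        state = AccumulatorState.empty(self.ct_geometry, mode, plan.planning_phase)
        wsums: dict[tuple[int, int], np.ndarray] = {}
        for tick in ticks:
            if tick.mu <= 0:
                continue
            phase = plan.planning_phase if mode is DeliveryMode.STATIC else tick.phase_bin
            key = (tick.beam_index, phase)
            D = self.dose_influence(tick.beam_index, phase)
            w = aperture_to_weights(tick.aperture, D.beam)
            if key in wsums:
                wsums[key] += tick.mu * w
            else:
                wsums[key] = tick.mu * w
        phase_dose: dict[int, np.ndarray] = {}
        for (b, phase), w in sorted(wsums.items()):
            D = self.dose_influence(b, phase)
            vec = np.asarray(D.matrix.T @ w, dtype=float)
            if phase in phase_dose:
                phase_dose[phase] += vec
            else:
                phase_dose[phase] = vec
        for phase in sorted(phase_dose):
            if mode is DeliveryMode.STATIC:
                state.dose.data += (self.R @ phase_dose[phase]).reshape(self.ct_geometry.shape)
            else:
                self._phase_dose_to_ref(phase_dose[phase], phase, state)
        return state

    def accumulate_deliveries(
        self,
        jobs: list[tuple[TreatmentPlan, list[DeliveryTick], DeliveryMode]],
        evict: bool = False,
    ) -> list[AccumulatorState]:
        """Accumulate several tick streams touching each (beam, phase)
        dose-influence matrix exactly once.

        Weight vectors are summed per (job, beam, phase) first; each D is
        then built, applied to every job's summed weights, and (with
        ``evict``) released before the next one — keeping a single matrix
        in memory regardless of how many deliveries are reconstructed.
        """
        if self.beams is None:
            raise ValueError("accumulate_deliveries needs the beam list")
        wsums: list[dict[tuple[int, int], np.ndarray]] = []
        for plan, ticks, mode in jobs:
            ws: dict[tuple[int, int], np.ndarray] = {}
            for tick in ticks:
                if tick.mu <= 0:
                    continue
                phase = plan.planning_phase if mode is DeliveryMode.STATIC \
                    else tick.phase_bin
                w = aperture_to_weights(tick.aperture, self.beams[tick.beam_index])
                key = (tick.beam_index, phase)
                if key in ws:
                    ws[key] += tick.mu * w
                else:
                    ws[key] = tick.mu * w
            wsums.append(ws)
        phase_dose: list[dict[int, np.ndarray]] = [{} for _ in jobs]
        keys = sorted({k for ws in wsums for k in ws})
        for b, phase in keys:
            D = self.dose_influence(b, phase)
            for ws, pd in zip(wsums, phase_dose):
                if (b, phase) not in ws:
                    continue
                vec = np.asarray(D.matrix.T @ ws[(b, phase)], dtype=float)
                if phase in pd:
                    pd[phase] += vec
                else:
                    pd[phase] = vec
            if evict and hasattr(self.dose_influence, "release"):
                self.dose_influence.release(b, phase)
        states = []
        for (plan, ticks, mode), pd in zip(jobs, phase_dose):
            state = AccumulatorState.empty(self.ct_geometry, mode, plan.planning_phase)
            for phase in sorted(pd):
                if mode is DeliveryMode.STATIC:
                    state.dose.data += (self.R @ pd[phase]).reshape(self.ct_geometry.shape)
                else:
                    self._phase_dose_to_ref(pd[phase], phase, state)
            states.append(state)
        return states

    def energy_emitted(self, phase_dose_vec: np.ndarray, phase: int) -> float:
        """Total phase-frame energy of a dose-grid dose vector (audit helper)."""
        return float((self.R @ phase_dose_vec) @ self.deformed[phase].source_mass.data.ravel())
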
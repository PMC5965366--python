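"""End-to-end orchestration: phantom -> precompute -> plan -> deliver ->
accumulate -> report.

A clinical platform spreads these stages over a delivery machine, a
tracking controller and a planning workstation; here they run in one process
as a deterministic replay, which preserves the dataflow (and the per-tick
arithmetic) while making every run reproducible from a config and a seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analysis
from .accumulate import AccumulatorState, DoseReconstructor, precompute_deformed_mass
from .beam import BeamGeometry, DoseInfluence, KernelConfig, beams_equidistant, generate_dose_influence

from .delivery import DeliveryMode, TreatmentPlan, deliver
from .grids import VoxelGrid, resample, write_grid
from .motion import Trajectory, bin_trajectory, fit_ellipse, generate_trajectory
from .phantom import Phase4DSet, PhantomSpec, build_phantom, gtv_centroids
from .structures import (
    build_mtv,
    expand_margin,
    motion_descriptors,
    select_midv_phase,
    union_itv,
)

log = logging.getLogger("dose4d")


@dataclass
class RunConfig:
    """Everything a reproducible study run depends on."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    mtv_margins_mm: tuple[float, ...] = (1.0, 3.0, 5.0)
    itv_margin_mm: float = 5.0
    midv_margin_mm: float = 5.0
    include_itv: bool = True
    include_midv: bool = True
    mtv_modes: tuple[str, ...] = ("static", "untracked", "tracked")
    itv_modes: tuple[str, ...] = ("static", "untracked")
    period_s: float = 5.0
    rate_hz: float = 25.0
    dose_rate_mu_min: float = 550.0
    prescription_gy: float = 18.0
    gap_s: float = 2.0
    kernel: KernelConfig = field(default_factory=KernelConfig)
    subvoxels: int = 4
    n_beams: int = 9
    bixel_size: tuple[float, float] = (2.5, 5.0)  # (leaf travel, leaf width)
    n_bixels: tuple[int, int] = (32, 16)
    seed: int = 1

    def beams(self) -> list[BeamGeometry]:
        return beams_equidistant(
            self.n_beams, bixel_size=self.bixel_size, n_bixels=self.n_bixels
        )

    @staticmethod
    def from_json(path) -> "RunConfig":
        with open(path) as f:
            raw = json.load(f)
        kwargs = {}
        if "phantom" in raw:
            kwargs["phantom"] = PhantomSpec(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in raw["phantom"].items()
            })
        if "kernel" in raw:
            kwargs["kernel"] = KernelConfig(**raw["kernel"])
        for fld in dataclasses.fields(RunConfig):
            if fld.name in ("phantom", "kernel"):
                continue
            if fld.name in raw:
                v = raw[fld.name]
                kwargs[fld.name] = tuple(v) if isinstance(v, list) else v
        return RunConfig(**kwargs)


class DoseInfluenceStore:
    """Lazy per-(beam, phase) dose-influence cache on the dose grid."""

    def __init__(self, phases: Phase4DSet, beams: list[BeamGeometry], kernel: KernelConfig):
        self.phases = phases
        self.beams = beams
        self.kernel = kernel
        self._cache: dict[tuple[int, int], DoseInfluence] = {}
        self._density_dose: dict[int, VoxelGrid] = {}

    def density_on_dose_grid(self, phase: int) -> VoxelGrid:
        if phase not in self._density_dose:
            self._density_dose[phase] = resample(
                self.phases.densities[phase], self.phases.dose_geometry, "trilinear"
            )
        return self._density_dose[phase]

    def __call__(self, beam_index: int, phase: int) -> DoseInfluence:
        key = (beam_index, phase)
        if key not in self._cache:
            t0 = time.perf_counter()
            self._cache[key] = generate_dose_influence(
                self.density_on_dose_grid(phase), self.beams[beam_index], self.kernel
            )
            log.debug("D(beam=%d, phase=%d) built in %.2f s, nnz=%d",
                      beam_index, phase, time.perf_counter() - t0,
                      self._cache[key].matrix.nnz)
        return self._cache[key]

    def release(self, beam_index: int, phase: int) -> None:
        """Drop a cached matrix (memory control for full sweeps)."""
        self._cache.pop((beam_index, phase), None)

    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["kernel"] = json.dumps({
                k: (v if not isinstance(v, type) else v.__name__)
                for k, v in dataclasses.asdict(self.kernel).items()
            })
            for (b, p), D in self._cache.items():
                g = f.create_group(f"beam{b}_phase{p}")
                g.create_dataset("data", data=D.matrix.data)
                g.create_dataset("indices", data=D.matrix.indices)
                g.create_dataset("indptr", data=D.matrix.indptr)
                g.attrs["shape"] = D.matrix.shape


@dataclass
class StudyResult:
    """Everything a study run produces, in memory."""

    config: RunConfig
    phases: Phase4DSet
    descriptors: object
    trajectory: Trajectory
    plans: dict[str, TreatmentPlan]
    planned_static_dose: dict[str, VoxelGrid]   # reference-frame planning dose
    doses: dict[tuple[str, str], VoxelGrid]     # (plan, mode) -> reference dose
    states: dict[tuple[str, str], AccumulatorState]
    report: pd.DataFrame
    ptvs: dict[str, object]
    reconstructor: DoseReconstructor


def _plan_name(family: str, margin: float) -> str:
    return f"{family}+{margin:g}"


def build_structures(config: RunConfig, phases: Phase4DSet):
    """ITV, MTV and the study's PTV set from the per-phase GTVs."""
    cents = gtv_centroids(phases)
    itv = union_itv(phases.gtv)
    mtv = build_mtv(phases.gtv, phases.reference)
    midv_phase = select_midv_phase(cents)
    ptvs = {}
    planning_phase = {}
    if config.include_itv:
        name = _plan_name("ITV", config.itv_margin_mm)
        ptvs[name] = expand_margin(itv, config.itv_margin_mm, name)
        planning_phase[name] = phases.reference
    for m in config.mtv_margins_mm:
        name = _plan_name("MTV", m)
        ptvs[name] = expand_margin(mtv, m, name)
        planning_phase[name] = phases.reference
    if config.include_midv:
        name = f"midV+{config.midv_margin_mm:g}"
        ptvs[name] = expand_margin(phases.gtv[midv_phase], config.midv_margin_mm, name)
        planning_phase[name] = midv_phase
    return itv, mtv, midv_phase, ptvs, planning_phase, cents


def run_study(config: RunConfig, outdir: str | os.PathLike | None = None) -> StudyResult:
    """Run the full study: build, plan, deliver in all modes, analyze.

    With ``outdir`` set, persists descriptors, trajectory, plans, doses and
    the endpoint report; reruns with the same config and seed are
    byte-identical.
    """
    t_start = time.perf_counter()
    phases = build_phantom(config.phantom)
    log.info("phantom built: %d phases on %s", phases.n_phases, phases.ct_geometry.shape)

    itv, mtv, midv_phase, ptvs, planning_phase, cents = build_structures(config, phases)
    desc = motion_descriptors(cents, phases.gtv, phases.reference)

    beams = config.beams()
    store = DoseInfluenceStore(phases, beams, config.kernel)
    deformed = precompute_deformed_mass(phases.densities, phases.push, config.subvoxels)
    recon = DoseReconstructor(store, deformed, phases.dose_geometry,
                              phases.ct_geometry, beams=beams)
    log.info("precompute done (%.1f s)", time.perf_counter() - t_start)

    # --- plans, each normalized to D95(PTV) = Rx on its planning phase ------
    # Conformal segments first; the static planning doses of all plans are
    # then computed in one sweep that touches each (beam, phase) matrix once.
    from .beam import aperture_to_weights
    from .delivery import conformal_aperture
    from .phantom import mask_centroid

    plans: dict[str, TreatmentPlan] = {}
    planned_dose: dict[str, VoxelGrid] = {}
    for name, ptv in ptvs.items():
        pphase = planning_phase[name]
        segments = [[conformal_aperture(ptv, b)] for b in beams]
        for segs in segments:
            segs[0].mu = 100.0
        plans[name] = TreatmentPlan(
            beams, segments, pphase, name, config.prescription_gy,
            config.dose_rate_mu_min, mask_centroid(phases.gtv[pphase]),
        )
    raw_dose: dict[str, np.ndarray] = {
        name: np.zeros(int(np.prod(phases.dose_geometry.shape))) for name in plans
    }
    needed = sorted({(b, p.planning_phase) for p in plans.values()
                     for b in range(len(beams))})
    for b, pphase in needed:
        D = store(b, pphase)
        for name, plan in plans.items():
            if plan.planning_phase != pphase:
                continue
            for seg in plan.segments[b]:
                raw_dose[name] += seg.mu * (D.matrix.T @ aperture_to_weights(seg, D.beam))
        store.release(b, pphase)
    for name, plan in plans.items():
        dose = VoxelGrid(
            (recon.R @ raw_dose[name]).reshape(phases.ct_geometry.shape),
            phases.ct_geometry.spacing, phases.ct_geometry.origin,
        )
        d95 = analysis.dose_at_volume(analysis.dvh(dose, ptvs[name]), 95.0)
        if d95 <= 0:
            raise ValueError(f"PTV {name} receives no dose")
        scale = config.prescription_gy / d95
        plan.scale_mu(scale)
        planned_dose[name] = dose.like(dose.data * scale)
        log.info("plan %s: %.1f MU total", name, plan.total_mu)

    # --- one shared trajectory, long enough for the largest plan ------------
    fit = fit_ellipse(np.column_stack([[c[2] for c in cents], [c[1] for c in cents]]))
    mu_per_tick = config.dose_rate_mu_min / 60.0 * 0.04
    max_ticks = max(
        sum(int(np.ceil(seg.mu / mu_per_tick)) + 1 for segs in p.segments for seg in segs)
        + (config.n_beams + 2) * int(round(config.gap_s / 0.04))
        for p in plans.values()
    )
    duration = 4 * config.period_s + 10.0 + (max_ticks + 25) * 0.04
    traj = bin_trajectory(
        generate_trajectory(fit, config.period_s, config.rate_hz, duration),
        config.phantom.n_phases,
    )

    # --- deliveries (all modes accumulated in one dose-influence sweep) -----
    jobs = []
    job_keys = []
    for name, plan in plans.items():
        modes = config.mtv_modes if name.startswith("MTV") else config.itv_modes
        for mode_name in modes:
            mode = DeliveryMode(mode_name)
            ticks = deliver(plan, traj, mode, config.gap_s)
            jobs.append((plan, ticks, mode))
            job_keys.append((name, mode_name))
            log.info("delivered %s/%s: %d ticks, %.1f MU", name, mode_name,
                     len(ticks), sum(t.mu for t in ticks))
    results_list = recon.accumulate_deliveries(jobs, evict=True)
    doses: dict[tuple[str, str], VoxelGrid] = {}
    states: dict[tuple[str, str], AccumulatorState] = {}
    for key, state in zip(job_keys, results_list):
        doses[key] = state.dose
        states[key] = state
    log.info("accumulation sweep done (%.1f s)", time.perf_counter() - t_start)

    ref_key = None
    itv_name = _plan_name("ITV", config.itv_margin_mm)
    if (itv_name, "untracked") in doses:
        ref_key = (itv_name, "untracked")
    report = analysis.compare_modes(
        doses, phases.gtv[phases.reference], phases.lung, phases.cord,
        phases.airways, reference_key=ref_key,
    )

    result = StudyResult(
        config, phases, desc, traj, plans, planned_dose, doses, states,
        report, ptvs, recon,
    )
    if outdir is not None:
        persist_study(result, outdir)
    log.info("study complete in %.1f s", time.perf_counter() - t_start)
    return result


def persist_study(result: StudyResult, outdir: str | os.PathLike) -> None:
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    os.makedirs(os.path.join(outdir, "plans"), exist_ok=True)
    os.makedirs(os.path.join(outdir, "doses"), exist_ok=True)
    d = result.descriptors
    pd.DataFrame([dataclasses.asdict(d)]).to_csv(
        os.path.join(outdir, "descriptors.csv"), index=False
    )
    result.trajectory.to_frame().to_csv(os.path.join(outdir, "trajectory.csv"), index=False)
    for name, plan in result.plans.items():
        plan.to_json(os.path.join(outdir, "plans", f"{name.replace('+', '_')}.json"))
    for (name, mode), dose in result.doses.items():
        write_grid(
            dose.like(dose.data.astype(np.float32)),
            os.path.join(outdir, "doses", f"{name.replace('+', '_')}_{mode}.nii.gz"),
        )
    result.report.to_csv(os.path.join(outdir, "report.csv"), index=False)
    result.report.to_json(os.path.join(outdir, "report.json"), orient="records", indent=2)
    manifest = {
        "seed": result.config.seed,
        "ptv_volumes_cm3": {k: v.volume_cm3 for k, v in result.ptvs.items()},
        "plans_total_mu": {k: p.total_mu for k, p in result.plans.items()},
        "lost_energy": {
            f"{k[0]}/{k[1]}": sum(s.lost_energy.values())
            for k, s in result.states.items()
        },
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
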
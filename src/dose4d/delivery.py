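"""Treatment plans, centroid MLC tracking and the 25 Hz delivery stream.

Plans are simplified step-and-shoot IMRT: for each of nine equidistant
coplanar beams one conformal segment shaped to the PTV's beam's-eye-view
silhouette (rounded out to bixels plus a one-leaf-width dilation), with a
single global MU rescale so the statically accumulated dose meets D95 = 18 Gy
per-fraction prescription on the planning phase.  This replaces inverse
optimization while preserving the mechanism under study: the interplay of
margin size, target motion and tracking.

Delivery is replayed as a stream of 40 ms ticks at a fixed dose rate.
Depending on the mode, the reported target position is ignored (STATIC,
UNTRACKED) or used to shift the planned aperture in the beam's-eye-view
(TRACKED).  Tracking latency is zero and reported positions are exact;
leaf-travel shifts are continuous while leaf-width shifts are quantized to
whole leaves (hardware reality of an MLC).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import numpy as np

from .beam import BeamGeometry, MLCAperture
from .grids import ROIMask
from .motion import WARMUP, Trajectory


class DeliveryMode(enum.Enum):
    STATIC = "static"          # positions ignored for delivery and accumulation
    UNTRACKED = "untracked"    # positions ignored for delivery, used in accumulation
    TRACKED = "tracked"        # positions drive MLC tracking and accumulation


#: Alias: untracked delivery of an ITV/midV plan is "conventional" practice.
CONVENTIONAL = DeliveryMode.UNTRACKED


@dataclass
class TreatmentPlan:
    """Per-beam ordered segments plus prescription bookkeeping."""

    beams: list[BeamGeometry]
    segments: list[list[MLCAperture]]   # segments[b] -> apertures of beam b
    planning_phase: int
    ptv_name: str
    prescription_gy: float = 18.0       # D95 of the PTV, per fraction
    dose_rate_mu_min: float = 550.0
    target_position: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.target_position = np.asarray(self.target_position, dtype=float)
        if len(self.segments) != len(self.beams):
            raise ValueError("segments must align with beams")
        if self.total_mu <= 0:
            raise ValueError("plan must carry positive total MU")

    @property
    def total_mu(self) -> float:
        return float(sum(seg.mu for segs in self.segments for seg in segs))

    def scale_mu(self, factor: float) -> None:
        for segs in self.segments:
            for seg in segs:
                seg.mu *= factor

    def to_json(self, path) -> None:
        doc = {
            "ptv": self.ptv_name,
            "planning_phase": self.planning_phase,
            "prescription_gy": self.prescription_gy,
            "dose_rate_mu_min": self.dose_rate_mu_min,
            "target_position_mm": self.target_position.tolist(),
            "beams": [
                {
                    "gantry_deg": b.gantry_deg,
                    "sad_mm": b.sad_mm,
                    "isocenter": list(b.isocenter),
                    "bixel_size": list(b.bixel_size),
                    "n_bixels": list(b.n_bixels),
                    "segments": [
                        {"left": s.left.tolist(), "right": s.right.tolist(), "mu": s.mu}
                        for s in segs
                    ],
                }
                for b, segs in zip(self.beams, self.segments)
            ],
        }
        with open(path, "w") as f:
            json.dump(doc, f, indent=2)

    @staticmethod
    def from_json(path) -> "TreatmentPlan":
        with open(path) as f:
            doc = json.load(f)
        beams, segments = [], []
        for b in doc["beams"]:
            beams.append(BeamGeometry(
                gantry_deg=b["gantry_deg"], sad_mm=b["sad_mm"],
                isocenter=tuple(b["isocenter"]), bixel_size=tuple(b["bixel_size"]),
                n_bixels=tuple(b["n_bixels"]),
            ))
            segments.append([
                MLCAperture(np.asarray(s["left"]), np.asarray(s["right"]), s["mu"])
                for s in b["segments"]
            ])
        return TreatmentPlan(
            beams, segments, doc["planning_phase"], doc["ptv"],
            doc["prescription_gy"], doc["dose_rate_mu_min"],
            np.asarray(doc["target_position_mm"]),
        )


@dataclass
class DeliveryTick:
    """One 40 ms slice of the delivery as reported to the dose engine."""

    time_s: float
    beam_index: int
    aperture: MLCAperture
    mu: float
    position: np.ndarray      # reported target position, mm
    phase_bin: int            # online bin; WARMUP replaced by the planning phase
    tracked: bool = False
    clamped: bool = False


# ---------------------------------------------------------------------------
# Plan generation
# ---------------------------------------------------------------------------

def conformal_aperture(ptv: ROIMask, beam: BeamGeometry,
                       dilation_mm: float | None = None) -> MLCAperture:
    """BEV silhouette of the PTV rounded out to bixels, dilated by one leaf
    width (default) along leaf travel and one row across leaves.

    The dilation is a fixed length, not "one bixel": the leaf-travel bixel
    size is a computational resolution and must not change the field margin.
    """
    idx = np.argwhere(ptv.mask)
    if idx.size == 0:
        raise ValueError("PTV is empty")
    world = ptv.grid.index_to_world(idx)
    bev = beam.bev_coords(world)
    cys = beam.bixel_centers_y()
    wy = beam.bixel_size[1]
    edges_x = beam.bixel_edges_x()
    rows = np.clip(np.floor((bev[:, 1] - (cys[0] - wy / 2.0)) / wy).astype(int),
                   0, cys.size - 1)
    intervals = np.full((cys.size, 2), np.nan)
    for r in range(cys.size):
        sel = rows == r
        if np.any(sel):
            intervals[r, 0] = bev[sel, 0].min()
            intervals[r, 1] = bev[sel, 0].max()
    # one-row dilation along the leaf-width axis
    dil = intervals.copy()
    for r in range(cys.size):
        neigh = [intervals[q] for q in (r - 1, r, r + 1)
                 if 0 <= q < cys.size and not np.isnan(intervals[q, 0])]
        if neigh:
            neigh = np.asarray(neigh)
            dil[r] = (neigh[:, 0].min(), neigh[:, 1].max())
    if dilation_mm is None:
        dilation_mm = beam.bixel_size[1]  # one leaf width
    left = np.zeros(cys.size)
    right = np.zeros(cys.size)
    for r in range(cys.size):
        if np.isnan(dil[r, 0]):
            continue
        # snap outward to bixel boundaries, then add the dilation margin
        lo = edges_x[np.searchsorted(edges_x, dil[r, 0], side="right") - 1]
        hi = edges_x[np.searchsorted(edges_x, dil[r, 1], side="left")]
        left[r] = max(lo - dilation_mm, edges_x[0])
        right[r] = min(hi + dilation_mm, edges_x[-1])
    return MLCAperture(left, right, 0.0)


def make_plan(
    ptv: ROIMask,
    beams: list[BeamGeometry],
    planning_phase: int,
    dose_for_unit_plan,
    d95_of,
    target_position: np.ndarray,
    prescription_gy: float = 18.0,
    dose_rate_mu_min: float = 550.0,
    mu_per_beam: float = 100.0,
) -> TreatmentPlan:
    """Conformal plan normalized so the static planning dose has D95(PTV) = Rx.

    ``dose_for_unit_plan(plan)`` must return the statically accumulated dose
    of the plan as built, and ``d95_of(dose)`` its PTV D95 in Gy — both are
    supplied by the caller (accumulation and DVH live in their own modules).
    """
    segments = [[conformal_aperture(ptv, b)] for b in beams]
    for segs in segments:
        segs[0].mu = mu_per_beam
    plan = TreatmentPlan(
        beams, segments, planning_phase, ptv.name,
        prescription_gy, dose_rate_mu_min, np.asarray(target_position, dtype=float),
    )
    dose = dose_for_unit_plan(plan)
    d95 = d95_of(dose)
    if d95 <= 0:
        raise ValueError("PTV receives no dose; PTV outside all beams' fields?")
    plan.scale_mu(prescription_gy / d95)
    return plan


# ---------------------------------------------------------------------------
# Tracking geometry
# ---------------------------------------------------------------------------

def project_shift(displacement: np.ndarray, beam: BeamGeometry) -> np.ndarray:
    """Orthographic BEV projection (leaf travel, leaf width) of a 3D shift."""
    d = np.asarray(displacement, dtype=float)
    return np.array([d @ beam.bev_x, d @ beam.bev_y])


def track_aperture(
    aperture: MLCAperture, bev_shift: np.ndarray, beam: BeamGeometry
) -> tuple[MLCAperture, bool]:
    """Shift an aperture in the BEV: continuous in leaf travel, whole-leaf
    steps in leaf width (vacated pairs close).  Returns (aperture, clamped)."""
    sx, sy = float(bev_shift[0]), float(bev_shift[1])
    edges = beam.bixel_edges_x()
    lo, hi = edges[0], edges[-1]
    left = aperture.left + sx
    right = aperture.right + sx
    clamped = False
    open_pairs = aperture.right > aperture.left
    if np.any(open_pairs & ((left < lo) | (right > hi))):
        clamped = True
        left = np.clip(left, lo, hi)
        right = np.clip(right, lo, hi)
    k = int(round(sy / beam.bixel_size[1]))
    n = aperture.n_pairs
    new_left = np.zeros(n)
    new_right = np.zeros(n)
    src_lo = max(0, -k)
    src_hi = min(n, n - k)
    if src_lo < src_hi:
        new_left[src_lo + k:src_hi + k] = left[src_lo:src_hi]
        new_right[src_lo + k:src_hi + k] = right[src_lo:src_hi]
    if k != 0 and np.any(open_pairs):
        dest = np.flatnonzero(open_pairs) + k
        if np.any((dest < 0) | (dest >= n)):  # some open pairs pushed off the carriage
            clamped = True
    return MLCAperture(new_left, new_right, aperture.mu), clamped


# ---------------------------------------------------------------------------
# Delivery stream
# ---------------------------------------------------------------------------

TICK_S = 0.04  # 25 Hz reporting interval


def deliver(
    plan: TreatmentPlan,
    trajectory: Trajectory,
    mode: DeliveryMode,
    gap_s: float = 2.0,
    start_after_warmup: bool = True,
) -> list[DeliveryTick]:
    """Replay a plan against a phase-annotated trajectory as 40 ms ticks.

    Beams are delivered in ascending gantry order, each segment at the plan
    dose rate discretized to ticks (the last tick of a segment carries the MU
    remainder, so per-beam MU is conserved exactly).  Between segments and
    beams the beam is off for ``gap_s`` (zero-MU ticks that still consume the
    trajectory).  Ticks whose online phase is still WARMUP are annotated with
    the planning phase.
    """
    if trajectory.phase_bins is None:
        raise ValueError("trajectory must be phase-annotated (see bin_trajectory)")
    mu_per_tick = plan.dose_rate_mu_min / 60.0 * TICK_S
    order = np.argsort([b.gantry_deg for b in plan.beams])
    i = 0
    if start_after_warmup:
        nonwarm = np.flatnonzero(trajectory.phase_bins != WARMUP)
        i = int(nonwarm[0]) if nonwarm.size else 0

    n_samples = trajectory.times.size
    ticks: list[DeliveryTick] = []

    def next_sample():
        nonlocal i
        if i >= n_samples:
            raise ValueError("trajectory underrun: delivery outlasts the motion data")
        t = trajectory.times[i]
        pos = trajectory.positions[i]
        bin_ = int(trajectory.phase_bins[i])
        i += 1
        return t, pos, (plan.planning_phase if bin_ == WARMUP else bin_)

    n_gap = int(round(gap_s / TICK_S))
    first_segment = True
    for b in order:
        beam = plan.beams[b]
        for segment in plan.segments[b]:
            if not first_segment:
                for _ in range(n_gap):
                    t, pos, ph = next_sample()
                    ticks.append(DeliveryTick(
                        t, int(b), MLCAperture.closed(beam.n_leaf_pairs),
                        0.0, pos.copy(), ph,
                    ))
            first_segment = False
            remaining = segment.mu
            while remaining > 0:
                t, pos, ph = next_sample()
                mu = min(mu_per_tick, remaining)
                remaining -= mu
                if remaining < 1e-12:
                    remaining = 0.0
                if mode is DeliveryMode.TRACKED:
                    shift = project_shift(pos - plan.target_position, beam)
                    ap, clamped = track_aperture(segment, shift, beam)
                    ap.mu = mu
                    ticks.append(DeliveryTick(t, int(b), ap, mu, pos.copy(), ph,
                                              tracked=True, clamped=clamped))
                else:
                    ap = MLCAperture(segment.left.copy(), segment.right.copy(), mu)
                    ticks.append(DeliveryTick(t, int(b), ap, mu, pos.copy(), ph))
    return ticks


def ticks_to_frame(ticks: list[DeliveryTick]):
    import pandas as pd

    return pd.DataFrame({
        "time_s": [t.time_s for t in ticks],
        "beam": [t.beam_index for t in ticks],
        "MU": [t.mu for t in ticks],
        "SI_mm": [t.position[2] for t in ticks],
        "AP_mm": [t.position[1] for t in ticks],
        "phase_bin": [t.phase_bin for t in ticks],
        "tracked": [t.tracked for t in ticks],
    })
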
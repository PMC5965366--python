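"""DVH computation and delivery-mode comparison endpoints.

Four dose-volume points summarize each reconstructed dose on the reference
phase: GTV_ref D98 (near-minimum target dose), lung-minus-GTV V20 (dose
spill, evaluated on the total-course dose, i.e. fraction dose times the
number of fractions), and D2 (near-maximum) for spinal cord and proximal
airways.  D_x / V_x are computed from the empirical voxel-dose distribution
(linear interpolation between order statistics); the binned cumulative DVH
curve is kept for export and plotting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import ROIMask, VoxelGrid

N_FRACTIONS = 3  # 3 x 18 Gy course


@dataclass
class DVHResult:
    """Cumulative DVH of one structure, plus the raw masked dose values."""

    dose_edges: np.ndarray     # Gy, ascending
    volume_pct: np.ndarray     # % of structure receiving >= edge dose
    values: np.ndarray         # sorted masked voxel doses, Gy
    name: str
    bin_width: float

    @property
    def n_voxels(self) -> int:
        return self.values.size


def dvh(dose: VoxelGrid, mask: ROIMask, bin_width: float = 0.01) -> DVHResult:
    """Cumulative histogram of the masked dose (bin width <= 0.01 Gy)."""
    if dose.data.shape != mask.mask.shape:
        raise ValueError("dose and mask must share a grid")
    vals = np.sort(dose.data[mask.mask].astype(float))
    if vals.size == 0:
        raise ValueError(f"mask {mask.name!r} is empty")
    top = max(float(vals[-1]), bin_width)
    edges = np.arange(0.0, top + 2 * bin_width, bin_width)
    # % of voxels with dose >= edge
    pct = 100.0 * (vals.size - np.searchsorted(vals, edges, side="left")) / vals.size
    return DVHResult(edges, pct, vals, mask.name, bin_width)


def dose_at_volume(d: DVHResult, x_pct: float) -> float:
    """D_x: dose received by the hottest x% of the structure (Gy)."""
    if not 0 < x_pct < 100:
        raise ValueError("x must be in (0, 100)")
    return float(np.quantile(d.values, 1.0 - x_pct / 100.0))


def volume_at_dose(d: DVHResult, x_gy: float) -> float:
    """V_x: percent of the structure receiving >= x Gy."""
    if x_gy < 0:
        raise ValueError("dose threshold must be >= 0")
    return float(100.0 * np.mean(d.values >= x_gy))


def lung_v20(
    dose: VoxelGrid, lung: ROIMask, gtv_ref: ROIMask, n_fractions: int = N_FRACTIONS
) -> float:
    """Lung V20 on the total-course dose, with GTV_ref subtracted from lung."""
    mask = lung.like(lung.mask & ~gtv_ref.mask, "lung-GTVref")
    scaled = dose.like(dose.data * n_fractions)
    return volume_at_dose(dvh(scaled, mask), 20.0)


def normalize_to_reference(
    dose: VoxelGrid, gtv: ROIMask, target_d98: float
) -> VoxelGrid:
    """Scale a dose distribution so its GTV D98 equals the target (Gy)."""
    current = dose_at_volume(dvh(dose, gtv), 98.0)
    if current <= 0:
        raise ValueError("current GTV D98 is zero; cannot normalize")
    return dose.like(dose.data * (target_d98 / current))


@dataclass
class Endpoints:
    gtv_d98: float
    lung_v20: float
    cord_d2: float
    airways_d2: float


def endpoints(
    dose: VoxelGrid,
    gtv_ref: ROIMask,
    lung: ROIMask,
    cord: ROIMask,
    airways: ROIMask,
    n_fractions: int = N_FRACTIONS,
) -> Endpoints:
    return Endpoints(
        gtv_d98=dose_at_volume(dvh(dose, gtv_ref), 98.0),
        lung_v20=lung_v20(dose, lung, gtv_ref, n_fractions),
        cord_d2=dose_at_volume(dvh(dose, cord), 2.0),
        airways_d2=dose_at_volume(dvh(dose, airways), 2.0),
    )


def compare_modes(
    doses: dict[tuple[str, str], VoxelGrid],
    gtv_ref: ROIMask,
    lung: ROIMask,
    cord: ROIMask,
    airways: ROIMask,
    reference_key: tuple[str, str] | None = None,
    n_fractions: int = N_FRACTIONS,
) -> pd.DataFrame:
    """Endpoint table over (plan, mode) dose grids with deltas and scaling.

    For every entry the four endpoints are computed; deltas are reported
    against the same plan's static delivery (target-coverage view) and
    against ``reference_key`` (by convention the conventionally delivered
    ITV+5 plan).  A scaled variant renormalizes each entry's GTV D98 to the
    reference entry's before re-evaluating the OAR endpoints, separating
    margin-driven OAR sparing from prescription differences.
    """
    rows = []
    eps = {k: endpoints(v, gtv_ref, lung, cord, airways, n_fractions)
           for k, v in doses.items()}
    ref_ep = eps[reference_key] if reference_key is not None else None
    for (plan, mode), ep in sorted(eps.items()):
        row = {
            "plan": plan,
            "mode": mode,
            "gtv_d98_gy": ep.gtv_d98,
            "lung_v20_pct": ep.lung_v20,
            "cord_d2_gy": ep.cord_d2,
            "airways_d2_gy": ep.airways_d2,
        }
        static_key = (plan, "static")
        if static_key in eps:
            row["d98_minus_static_gy"] = ep.gtv_d98 - eps[static_key].gtv_d98
        if ref_ep is not None:
            row["d98_minus_ref_gy"] = ep.gtv_d98 - ref_ep.gtv_d98
            row["v20_minus_ref_pct"] = ep.lung_v20 - ref_ep.lung_v20
            row["cord_d2_minus_ref_gy"] = ep.cord_d2 - ref_ep.cord_d2
            row["airways_d2_minus_ref_gy"] = ep.airways_d2 - ref_ep.airways_d2
            if ep.gtv_d98 > 0:
                scaled = normalize_to_reference(doses[(plan, mode)], gtv_ref, ref_ep.gtv_d98)
                sep = endpoints(scaled, gtv_ref, lung, cord, airways, n_fractions)
                row["v20_scaled_minus_ref_pct"] = sep.lung_v20 - ref_ep.lung_v20
                row["cord_d2_scaled_minus_ref_gy"] = sep.cord_d2 - ref_ep.cord_d2
                row["airways_d2_scaled_minus_ref_gy"] = sep.airways_d2 - ref_ep.airways_d2
        rows.append(row)
    return pd.DataFrame(rows)
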
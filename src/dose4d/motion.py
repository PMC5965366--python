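"""Tumor trajectory synthesis and online respiratory phase binning.

The per-phase GTV centroids of the 4D phantom (or a real 4DCT) are reduced to
a 2D ellipse in the SI/AP plane by least squares.  A sinusoidal trajectory
tracing that ellipse at a given respiratory period is sampled at the motion
acquisition rate (25 Hz).  During replayed delivery the respiratory phase of
every sample is computed *causally*: extrema of the SI component are detected
on the fly and each sample is binned relative to the last fully acquired
respiratory cycle; the respiratory period is additionally estimated from the
last 20 s of data by Fourier analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Phase annotation of samples acquired before one full respiratory cycle.
WARMUP = -1


@dataclass
class EllipseFit:
    """SI/AP ellipse in the 1:1 Lissajous parametrization.

    SI(theta) = center_si + a_si * cos(theta)
    AP(theta) = center_ap + a_ap * cos(theta + phase_offset)
    """

    center_si: float
    center_ap: float
    a_si: float
    a_ap: float
    phase_offset: float
    rms_error: float
    degenerate: bool = False

    def __post_init__(self):
        if self.a_si < 0 or self.a_ap < 0:
            raise ValueError("semi-axes must be >= 0")
        if self.rms_error < 0:
            raise ValueError("rms_error must be >= 0")


@dataclass
class Trajectory:
    """Uniformly sampled target positions with online phase annotations."""

    times: np.ndarray            # s
    positions: np.ndarray        # (n, 3) mm, axes LR/AP/SI
    rate: float                  # Hz
    phase_bins: np.ndarray | None = None   # int, WARMUP before first full cycle
    periods: np.ndarray | None = None      # running Fourier period estimate, s

    @property
    def si(self) -> np.ndarray:
        return self.positions[:, 2]

    @property
    def ap(self) -> np.ndarray:
        return self.positions[:, 1]

    def to_frame(self):
        import pandas as pd

        d = {
            "time_s": self.times,
            "LR_mm": self.positions[:, 0],
            "AP_mm": self.positions[:, 1],
            "SI_mm": self.positions[:, 2],
        }
        if self.phase_bins is not None:
            d["phase_bin"] = self.phase_bins
        if self.periods is not None:
            d["period_s"] = self.periods
        return pd.DataFrame(d)


# ---------------------------------------------------------------------------
# Ellipse fitting
# ---------------------------------------------------------------------------

def _geometric_rms(pts: np.ndarray, fit: "EllipseFit") -> float:
    """RMS of point-to-ellipse distances against the parametric curve."""
    th = np.linspace(0.0, 2.0 * np.pi, 2000, endpoint=False)
    curve = np.column_stack([
        fit.center_si + fit.a_si * np.cos(th),
        fit.center_ap + fit.a_ap * np.cos(th + fit.phase_offset),
    ])
    d2 = ((pts[:, None, :] - curve[None, :, :]) ** 2).sum(axis=-1).min(axis=1)
    return float(np.sqrt(d2.mean()))


def fit_ellipse(points: np.ndarray) -> EllipseFit:
    """Least-squares ellipse through ordered SI/AP centroid positions.

    ``points`` is (n, 2) with columns (SI, AP), n >= 5, assumed to sample a
    whole number of respiratory cycles uniformly in cycle phase — which is
    exactly what phase-binned GTV centroids (or 25 Hz samples of a periodic
    trajectory) are.  Each coordinate is regressed on the fundamental
    harmonic (the dominant integer frequency of the sequence), giving the
    1:1 Lissajous parameters directly; the sign of the recovered phase
    offset follows the traversal direction of the input.  Collinear input
    (e.g., AP constant) is flagged degenerate with a zero AP semi-axis.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2) with columns (SI, AP)")
    n = pts.shape[0]
    if n < 5:
        raise ValueError("ellipse fit needs at least 5 points")
    center_guess = pts.mean(axis=0)
    centered = pts - center_guess
    if not centered.any():
        return EllipseFit(center_guess[0], center_guess[1], 0.0, 0.0, 0.0, 0.0, True)

    # collinear input cannot define an ellipse
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] <= 1e-9 * sv[0]:
        a_si = (pts[:, 0].max() - pts[:, 0].min()) / 2.0
        a_ap = (pts[:, 1].max() - pts[:, 1].min()) / 2.0
        _, _, vt = np.linalg.svd(centered)
        rms = float(np.sqrt(np.mean((centered @ vt[1]) ** 2)))
        return EllipseFit(center_guess[0], center_guess[1], a_si, a_ap, 0.0, rms, True)

    # dominant integer frequency of the (periodic) sequence = cycle count
    spec = np.abs(np.fft.rfft(centered[:, 0])) + np.abs(np.fft.rfft(centered[:, 1]))
    k = int(np.argmax(spec[1:]) + 1)
    theta = 2.0 * np.pi * k * np.arange(n) / n
    X = np.column_stack([np.ones(n), np.cos(theta), np.sin(theta)])
    (c_si, al_si, be_si), *_ = np.linalg.lstsq(X, pts[:, 0], rcond=None)
    (c_ap, al_ap, be_ap), *_ = np.linalg.lstsq(X, pts[:, 1], rcond=None)
    a_si = float(np.hypot(al_si, be_si))
    a_ap = float(np.hypot(al_ap, be_ap))
    # x = a cos(theta - psi) with psi = atan2(beta, alpha)
    psi_si = np.arctan2(be_si, al_si)
    psi_ap = np.arctan2(be_ap, al_ap)
    phi = float((psi_si - psi_ap + np.pi) % (2.0 * np.pi) - np.pi)
    fit = EllipseFit(float(c_si), float(c_ap), a_si, a_ap, phi, 0.0, False)
    fit.rms_error = _geometric_rms(pts, fit)
    return fit


# ---------------------------------------------------------------------------
# Trajectory generation
# ---------------------------------------------------------------------------

def generate_trajectory(
    fit: EllipseFit, period: float, rate: float = 25.0, duration: float = 60.0
) -> Trajectory:
    """Sample the fitted ellipse sinusoidally at `rate` Hz for `duration` s."""
    if period <= 0 or rate <= 0:
        raise ValueError("period and rate must be positive")
    if duration < period:
        warnings.warn("trajectory shorter than one respiratory period; "
                      "online phase binning will stay in warm-up", stacklevel=2)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    theta = 2.0 * np.pi * t / period
    pos = np.zeros((n, 3))
    pos[:, 2] = fit.center_si + fit.a_si * np.cos(theta)
    pos[:, 1] = fit.center_ap + fit.a_ap * np.cos(theta + fit.phase_offset)
    return Trajectory(t, pos, rate)


# ---------------------------------------------------------------------------
# Fourier period estimation
# ---------------------------------------------------------------------------

def estimate_period(si: np.ndarray, rate: float, window_s: float = 20.0) -> float:
    """Dominant respiratory period from the last `window_s` seconds of SI data.

    The discrete spectrum of the Hann-windowed, mean-subtracted signal is
    searched for its largest nonzero-frequency peak, which is refined by
    parabolic interpolation of log-magnitude (a 20 s window alone gives only
    0.05 Hz resolution, too coarse near typical 0.2 Hz breathing).
    """
    si = np.asarray(si, dtype=float)
    n_win = int(round(window_s * rate))
    x = si[-n_win:] if si.size > n_win else si
    x = x - x.mean()
    if x.size < 4 or np.max(np.abs(x)) < 1e-12:
        raise ValueError("constant or too-short signal: period undefined")
    w = np.hanning(x.size)
    spec = np.abs(np.fft.rfft(x * w))
    if spec.size < 3:
        raise ValueError("window too short for period estimation")
    k = int(np.argmax(spec[1:]) + 1)
    if spec[k] <= 0:
        raise ValueError("no spectral peak: period undefined")
    # parabolic refinement on log magnitude
    if 1 <= k < spec.size - 1 and spec[k - 1] > 0 and spec[k + 1] > 0:
        la, lb, lc = np.log(spec[k - 1]), np.log(spec[k]), np.log(spec[k + 1])
        denom = la - 2.0 * lb + lc
        delta = 0.5 * (la - lc) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    freq = (k + delta) * rate / x.size
    if freq <= 0:
        raise ValueError("non-positive dominant frequency")
    return float(1.0 / freq)


# ---------------------------------------------------------------------------
# Online phase binning
# ---------------------------------------------------------------------------

@dataclass
class OnlinePhaseBinner:
    """Causal respiratory phase binning of a streamed SI signal.

    Extrema are detected with a zigzag rule: a candidate extremum is confirmed
    once the signal has retreated from it by a minimum prominence (10% of the
    running peak-to-peak) *and* `confirm_s` seconds have elapsed, guarding
    against jitter; confirmed extremum times are refined to sub-sample
    precision by parabolic interpolation.  Bin 0 is anchored at the exhale
    extremum (the signal minimum by default, matching a peak-exhale reference
    phase); each cycle is divided into `n_phases` equal-duration, half-open
    bins *centered* on the phase times p/N of the cycle, so a sample is
    always paired with the nearest phase's geometry.  A sample at time t is
    assigned the bin of its position relative to the last confirmed exhale
    extremum, using the duration of the last fully acquired cycle as the
    cycle length (the one-cycle phase shift of causal binning).  The Fourier
    period estimate over the trailing 20 s is tracked alongside.
    """

    n_phases: int = 10
    rate: float = 25.0
    exhale_is_min: bool = True
    prominence_frac: float = 0.1
    confirm_s: float = 0.5
    window_s: float = 20.0

    _times: list = field(default_factory=list, repr=False)
    _si: list = field(default_factory=list, repr=False)
    _extrema: list = field(default_factory=list, repr=False)  # (t, si, kind)
    _cand: dict | None = field(default=None, repr=False)
    _run_min: float = field(default=np.inf, repr=False)
    _run_max: float = field(default=-np.inf, repr=False)
    _period: float | None = field(default=None, repr=False)

    @property
    def period(self) -> float | None:
        return self._period

    def _exhale_kind(self) -> str:
        return "min" if self.exhale_is_min else "max"

    def _update_extrema(self, t: float, v: float) -> None:
        self._run_min = min(self._run_min, v)
        self._run_max = max(self._run_max, v)
        prom = self.prominence_frac * (self._run_max - self._run_min)
        i = len(self._si) - 1
        if self._cand is None:
            self._cand = {"i_max": i, "v_max": v, "i_min": i, "v_min": v}
        c = self._cand
        if v > c["v_max"]:
            c["v_max"], c["i_max"] = v, i
        if v < c["v_min"]:
            c["v_min"], c["i_min"] = v, i
        if prom <= 0:
            return
        last_kind = self._extrema[-1][2] if self._extrema else None
        # confirm a maximum: signal dropped by >= prom below the running max
        if last_kind != "max" and c["v_max"] - v >= prom and t - self._times[c["i_max"]] >= self.confirm_s:
            self._extrema.append((self._refined_time(c["i_max"]), c["v_max"], "max"))
            c["v_min"], c["i_min"] = v, i
        elif last_kind != "min" and v - c["v_min"] >= prom and t - self._times[c["i_min"]] >= self.confirm_s:
            self._extrema.append((self._refined_time(c["i_min"]), c["v_min"], "min"))
            c["v_max"], c["i_max"] = v, i

    def _refined_time(self, i: int) -> float:
        """Sub-sample extremum time by parabolic interpolation of neighbors."""
        if i < 1 or i >= len(self._si) - 1:
            return self._times[i]
        va, vb, vc = self._si[i - 1], self._si[i], self._si[i + 1]
        denom = va - 2.0 * vb + vc
        if denom == 0:
            return self._times[i]
        delta = float(np.clip(0.5 * (va - vc) / denom, -0.5, 0.5))
        return self._times[i] + delta / self.rate

    def update(self, t: float, si: float) -> int:
        """Feed one sample; returns its phase bin or WARMUP."""
        self._times.append(float(t))
        self._si.append(float(si))
        self._update_extrema(float(t), float(si))
        if len(self._si) % 25 == 0 or self._period is None:
            try:
                self._period = estimate_period(
                    np.asarray(self._si), self.rate, self.window_s
                )
            except ValueError:
                pass
        anchors = [e for e in self._extrema if e[2] == self._exhale_kind()]
        if len(anchors) < 2:
            return WARMUP
        e_prev, e_last = anchors[-2][0], anchors[-1][0]
        cycle = e_last - e_prev
        if cycle <= 0:
            return WARMUP
        frac = ((t - e_last) % cycle) / cycle
        # bins are centered on the phase times (phase p at cycle fraction p/N),
        # so every sample is paired with its nearest 4DCT phase geometry
        return int(np.floor(frac * self.n_phases + 0.5)) % self.n_phases


def bin_phase_online(t: float, si: float, binner: OnlinePhaseBinner) -> int:
    """Functional wrapper: stream one (time, SI) sample through a binner."""
    return binner.update(t, si)


def bin_trajectory(traj: Trajectory, n_phases: int = 10, **kwargs) -> Trajectory:
    """Annotate a trajectory with causal phase bins and period estimates."""
    binner = OnlinePhaseBinner(n_phases=n_phases, rate=traj.rate, **kwargs)
    bins = np.empty(traj.times.size, dtype=int)
    periods = np.full(traj.times.size, np.nan)
    for i, (t, s) in enumerate(zip(traj.times, traj.si)):
        bins[i] = binner.update(t, s)
        periods[i] = binner.period if binner.period is not None else np.nan
    return Trajectory(traj.times, traj.positions, traj.rate, bins, periods)
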
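"""Compartmental and graphical V_T estimation for reversible PET tracers.

The two-tissue compartment model (2TCM) describes tissue activity as

    C(t) = (1 - V_B) * (h * Cp_parent)(t) + V_B * C_wb(t)

with impulse response h(t) = phi1 exp(-theta1 t) + phi2 exp(-theta2 t),
where theta1,2 = 0.5 [(k2 + k3 + k4) +/- sqrt((k2 + k3 + k4)^2 - 4 k2 k4)],
phi1 = K1 (theta1 - k3 - k4) / (theta1 - theta2) and
phi2 = K1 (k3 + k4 - theta2) / (theta1 - theta2).  The macro-parameter of
interest is the total volume of distribution

    V_T = (K1 / k2) (1 + k3 / k4) = integral of h over [0, inf).

Logan graphical analysis linearizes the late ("linear phase") portion of
the plot of normalized integrated tissue activity against normalized
integrated plasma activity; its slope estimates V_T.  The start of the
linear phase t* is selected as the earliest frame midpoint for which the
maximal relative deviation of the included points from their fitted line
does not exceed a threshold (default 10%).

All internal times are minutes; frame schedules are stored in seconds to
match the acquisition convention.  Activity inputs are assumed already
decay-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares
from scipy.signal import fftconvolve

from .blood import InputFunction
from .exceptions import (FitFailureError, InsufficientDataError,
                         NoLinearPhaseError, ValidationError)

__all__ = [
    "FrameSchedule",
    "TissueTAC",
    "TwoTCMParams",
    "FitDiagnostics",
    "LoganPoints",
    "LoganResult",
    "solve_2tcm_forward",
    "fit_2tcm",
    "logan_transform",
    "select_tstar",
    "fit_logan",
    "time_stability",
    "cohort_stability_summary",
    "compute_suv",
    "DEFAULT_FRAME_SCHEME",
]

# 28-frame / 90-min acquisition: 4x15 s, 4x30 s, 4x60 s, 4x120 s, 9x300 s, 3x600 s
DEFAULT_FRAME_SCHEME = ((4, 15.0), (4, 30.0), (4, 60.0), (4, 120.0),
                        (9, 300.0), (3, 600.0))


@dataclass(eq=False)
class FrameSchedule:
    """Dynamic acquisition frame timing (seconds)."""

    start_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self):
        self.start_s = np.asarray(self.start_s, dtype=float)
        self.duration_s = np.asarray(self.duration_s, dtype=float)
        if self.start_s.size != self.duration_s.size or self.start_s.size == 0:
            raise ValidationError("frame starts and durations must match and be non-empty")
        if np.any(self.duration_s <= 0):
            raise ValidationError("frame durations must be > 0")
        ends = self.start_s + self.duration_s
        if np.any(self.start_s[1:] < ends[:-1] - 1e-9):
            raise ValidationError("frames must be non-overlapping and ordered")

    @classmethod
    def default(cls) -> "FrameSchedule":
        durations = np.concatenate([np.full(n, d) for n, d in DEFAULT_FRAME_SCHEME])
        starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        return cls(starts, durations)

    @classmethod
    def from_list(cls, pairs) -> "FrameSchedule":
        arr = np.asarray(pairs, dtype=float)
        return cls(arr[:, 0], arr[:, 1])

    def to_list(self):
        return [[float(s), float(d)] for s, d in zip(self.start_s, self.duration_s)]

    @property
    def n_frames(self) -> int:
        return self.start_s.size

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s

    @property
    def start_min(self) -> np.ndarray:
        return self.start_s / 60.0

    @property
    def end_min(self) -> np.ndarray:
        return self.end_s / 60.0

    @property
    def duration_min(self) -> np.ndarray:
        return self.duration_s / 60.0

    @property
    def mid_min(self) -> np.ndarray:
        return (self.start_s + 0.5 * self.duration_s) / 60.0

    @property
    def total_min(self) -> float:
        return float(self.end_s[-1] / 60.0)

    def truncate(self, duration_min: float) -> "FrameSchedule":
        """Keep frames ending at or before ``duration_min``."""
        keep = self.end_min <= duration_min + 1e-9
        if not np.any(keep):
            raise ValidationError(f"no frames end within {duration_min} min")
        return FrameSchedule(self.start_s[keep], self.duration_s[keep])


@dataclass(eq=False)
class TissueTAC:
    """Regional or voxel time-activity curve (kBq/mL per frame)."""

    schedule: FrameSchedule
    values: np.ndarray
    region: str = ""
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.schedule.n_frames:
            raise ValidationError("one TAC value per frame required")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("TAC values must be finite")

    def truncate(self, duration_min: float) -> "TissueTAC":
        sched = self.schedule.truncate(duration_min)
        return TissueTAC(sched, self.values[: sched.n_frames], region=self.region)


@dataclass
class TwoTCMParams:
    """2TCM micro-parameters with fixed blood volume fraction.

    K1 in mL cm^-3 min^-1; k2, k3, k4 in min^-1; vb unitless.
    """

    k1: float
    k2: float
    k3: float
    k4: float
    vb: float = 0.04

    def __post_init__(self):
        if self.k1 < 0 or self.k2 <= 0:
            raise ValidationError("require K1 >= 0 and k2 > 0")
        if self.k3 < 0 or self.k4 < 0:
            raise ValidationError("rate constants must be >= 0")
        if self.k3 > 0 and self.k4 == 0:
            raise ValidationError("k3 > 0 requires k4 > 0 for reversible kinetics")
        if not (0.0 <= self.vb < 1.0):
            raise ValidationError("require 0 <= V_B < 1")

    @property
    def vt(self) -> float:
        ratio = self.k3 / self.k4 if self.k4 > 0 else 0.0
        return (self.k1 / self.k2) * (1.0 + ratio)

    def to_dict(self) -> dict:
        return {"K1": self.k1, "k2": self.k2, "k3": self.k3, "k4": self.k4,
                "VB": self.vb, "VT": self.vt}


@dataclass
class FitDiagnostics:
    rss: float
    aic: float
    se: np.ndarray
    converged: bool
    n_frames: int
    start_used: int = 0
    vt_not_identifiable: bool = False
    implausible_fit: bool = False


def impulse_response(params: TwoTCMParams, t: np.ndarray) -> np.ndarray:
    """2TCM tissue impulse response h(t) on times ``t`` (minutes).

    The repeated-root case theta1 == theta2 uses the analytic limit
    h(t) = K1 exp(-theta t) (1 + (k3 + k4 - theta) t).
    """
    t = np.asarray(t, dtype=float)
    k1, k2, k3, k4 = params.k1, params.k2, params.k3, params.k4
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    sq = np.sqrt(max(disc, 0.0))
    th1 = 0.5 * (s + sq)
    th2 = 0.5 * (s - sq)
    if sq <= 1e-9 * max(s, 1e-12):
        theta = 0.5 * s
        return k1 * np.exp(-theta * t) * (1.0 + (k3 + k4 - theta) * t)
    phi1 = k1 * (th1 - k3 - k4) / sq
    phi2 = k1 * (k3 + k4 - th2) / sq
    return phi1 * np.exp(-th1 * t) + phi2 * np.exp(-th2 * t)


def _frame_average(t: np.ndarray, y: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Time-average of a fine-grid curve over each frame (trapezoid)."""
    cum = cumulative_trapezoid(y, t, initial=0.0)
    f0 = np.interp(schedule.start_min, t, cum)
    f1 = np.interp(schedule.end_min, t, cum)
    return (f1 - f0) / schedule.duration_min


def _check_fine_grid(cp: InputFunction, schedule: FrameSchedule):
    t = cp.times
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValidationError("input function must be sampled on a uniform grid")
    if dt[0] > schedule.duration_min.min() / 10.0 + 1e-12:
        raise ValidationError("input grid must be >= 10x finer than the shortest frame")
    if t[0] > schedule.start_min[0] + 1e-9 or t[-1] < schedule.end_min[-1] - 1e-9:
        raise ValidationError("input grid must cover the frame schedule")
    return float(dt[0])


def solve_2tcm_forward(params: TwoTCMParams, cp: InputFunction,
                       schedule: FrameSchedule) -> TissueTAC:
    """Forward-simulate frame-averaged 2TCM tissue activity.

    The convolution (h * Cp_parent) is evaluated by trapezoidal quadrature
    on the input-function grid; per-frame values are time-averages of the
    instantaneous model curve over each frame.
    """
    dt = _check_fine_grid(cp, schedule)
    t = cp.times
    h = impulse_response(params, t - t[0])
    conv = fftconvolve(h, cp.cp_parent)[: t.size] * dt
    # trapezoid end-point correction for the convolution quadrature
    conv -= 0.5 * dt * (h[0] * cp.cp_parent + h * cp.cp_parent[0])
    ct = (1.0 - params.vb) * conv + params.vb * cp.c_wb
    return TissueTAC(schedule, _frame_average(t, ct, schedule))


_STARTS = (
    (0.8, 0.4, 0.10, 0.10),   # fast kinetics
    (0.3, 0.15, 0.05, 0.05),  # intermediate
    (0.1, 0.05, 0.01, 0.01),  # slow kinetics
)
_BOUNDS = (1e-6, 2.0)


def fit_2tcm(tac: TissueTAC, cp: InputFunction, vb: float = 0.04,
             weights: str | np.ndarray = "duration"
             ) -> tuple[TwoTCMParams, FitDiagnostics]:
    """Weighted nonlinear least-squares 2TCM fit with fixed V_B.

    Frame weights default to normalized frame durations (a count-statistics
    proxy); pass ``"uniform"`` or an explicit array to override.  Three
    documented starting points spanning fast to slow kinetics are tried and
    the best converged fit returned.
    """
    sched = tac.schedule
    if sched.n_frames < 8:
        raise InsufficientDataError("2TCM fit requires >= 8 frames")
    if isinstance(weights, str):
        if weights == "duration":
            w = sched.duration_min / sched.duration_min.sum()
        elif weights == "uniform":
            w = np.full(sched.n_frames, 1.0 / sched.n_frames)
        else:
            raise ValidationError(f"unknown weight scheme '{weights}'")
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    sw = np.sqrt(w)
    data = tac.values

    def residuals(x):
        p = TwoTCMParams(*np.abs(x), vb=vb)
        model = solve_2tcm_forward(p, cp, sched).values
        return sw * (model - data)

    best = None
    last_x = None
    for x0 in _STARTS:
        try:
            res = least_squares(residuals, x0, bounds=_BOUNDS,
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        last_x = res.x
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitFailureError("no 2TCM start converged", last_iterate=last_x)

    params = TwoTCMParams(*best.x, vb=vb)
    n, p = data.size, 4
    rss = float(2.0 * best.cost)
    aic = n * np.log(max(rss / n, 1e-300)) + 2 * p
    dof = max(n - p, 1)
    jtj = best.jac.T @ best.jac
    cov = np.linalg.pinv(jtj) * (rss / dof)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    diag = FitDiagnostics(
        rss=rss, aic=float(aic), se=se, converged=True, n_frames=n,
        vt_not_identifiable=params.k1 <= 1e-4,
        implausible_fit=params.vt > 1e3,
    )
    return params, diag


@dataclass(eq=False)
class LoganPoints:
    """Logan-transformed points (one per usable frame)."""

    x: np.ndarray        # int_0^t Cp / C_T(t)
    y: np.ndarray        # int_0^t C_T / C_T(t)
    mid_min: np.ndarray  # frame midpoints, minutes
    excluded: list = field(default_factory=list)


@dataclass
class LoganResult:
    vt: float
    intercept: float
    t_star: float
    n_points: int
    max_rel_dev: float
    r2: float


def logan_transform(tac: TissueTAC, cp: InputFunction,
                    vb: float = 0.04) -> LoganPoints:
    """Logan plot coordinates from a TAC and input function.

    The measured TAC carries a vascular signal fraction; it is removed
    before the transform with the same fixed blood volume fraction used by
    the compartment model, C_T = (C_meas - V_B C_wb) / (1 - V_B), so the
    graphical slope estimates the tissue V_T rather than a blood-volume
    weighted mixture.  Pass ``vb=0`` to transform the raw curve.

    Plasma integrals use the trapezoid rule on the input fine grid; tissue
    integrals use the trapezoid rule over frame midpoints anchored at
    C_T(0) = 0.  Frames with non-positive tissue activity are excluded
    (recorded in ``excluded``).
    """
    mids = tac.schedule.mid_min
    values = tac.values
    if vb > 0:
        values = (values - vb * cp.wb_at(mids)) / (1.0 - vb)
    anchor_t = np.concatenate([[0.0], mids])
    anchor_v = np.concatenate([[0.0], values])
    cum_t = cumulative_trapezoid(anchor_v, anchor_t, initial=0.0)[1:]
    cum_p = cp.cum_cp_at(mids)
    usable = values > 0
    excluded = [float(m) for m in mids[~usable]]
    ct = values[usable]
    return LoganPoints(x=cum_p[usable] / ct, y=cum_t[usable] / ct,
                       mid_min=mids[usable], excluded=excluded)


def _line_max_rel_dev(x, y):
    slope, intercept = np.polyfit(x, y, 1)
    yfit = slope * x + intercept
    dev = np.max(np.abs(yfit - y) / np.abs(yfit))
    return slope, intercept, float(dev)


def select_tstar(points: LoganPoints, max_rel_error: float = 0.10) -> tuple[float, int]:
    """Earliest linear-phase start satisfying the maximal-error criterion.

    Scanning start candidates from the earliest frame midpoint forward,
    returns the first midpoint t such that a line fitted to all points at
    or after t deviates from every included point by at most
    ``max_rel_error`` (relative to the fitted value), with at least 3
    points included.
    """
    n = points.x.size
    if n < 3:
        raise InsufficientDataError("t* selection requires >= 3 Logan points")
    for i in range(n - 2):
        _, _, dev = _line_max_rel_dev(points.x[i:], points.y[i:])
        if dev <= max_rel_error:
            return float(points.mid_min[i]), n - i
    raise NoLinearPhaseError(
        f"no linear phase with max relative error <= {max_rel_error:g}")


def fit_logan(tac: TissueTAC, cp: InputFunction, max_rel_error: float = 0.10,
              t_star: float | None = None, vb: float = 0.04) -> LoganResult:
    """Logan graphical V_T estimate (slope of the linear phase).

    ``t_star`` may be forced (e.g. a global value for parametric mapping);
    by default it is selected per curve via :func:`select_tstar`.
    """
    pts = logan_transform(tac, cp, vb=vb)
    if pts.x.size < 3:
        raise InsufficientDataError("fewer than 3 usable Logan points")
    if t_star is None:
        t_star, _ = select_tstar(pts, max_rel_error=max_rel_error)
    sel = pts.mid_min >= t_star - 1e-9
    if sel.sum() < 3:
        raise InsufficientDataError("fewer than 3 Logan points after t*")
    x, y = pts.x[sel], pts.y[sel]
    slope, intercept, dev = _line_max_rel_dev(x, y)
    yfit = slope * x + intercept
    ss_res = float(np.sum((y - yfit) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return LoganResult(vt=float(slope), intercept=float(intercept),
                       t_star=float(t_star), n_points=int(sel.sum()),
                       max_rel_dev=dev, r2=r2)


def time_stability(tac: TissueTAC, cp: InputFunction,
                   durations=(90.0, 80.0, 70.0, 60.0, 50.0, 40.0),
                   max_rel_error: float = 0.10, vb: float = 0.04) -> pd.DataFrame:
    """Logan V_T as a function of scan duration.

    Re-runs the Logan fit on truncated schedules and reports the percent
    difference relative to the longest duration.  Durations whose
    truncation leaves fewer than 3 usable points are flagged unusable.
    """
    durations = sorted(set(float(d) for d in durations), reverse=True)
    if tac.schedule.total_min + 1e-6 < durations[0]:
        raise ValidationError(
            f"schedule covers {tac.schedule.total_min:g} min < requested {durations[0]:g}")
    rows = []
    ref_vt = None
    for d in durations:
        try:
            res = fit_logan(tac.truncate(d), cp, max_rel_error=max_rel_error, vb=vb)
            vt = res.vt
            usable = True
        except (InsufficientDataError, NoLinearPhaseError, ValidationError):
            vt, usable = np.nan, False
        if ref_vt is None and usable:
            ref_vt = vt
        rows.append({"duration_min": d, "vt": vt, "usable": usable})
    if ref_vt is None:
        raise FitFailureError("no usable duration for time-stability analysis")
    out = pd.DataFrame(rows)
    out["pct_diff"] = 100.0 * (out["vt"] - ref_vt) / ref_vt
    return out


def cohort_stability_summary(tables: list[pd.DataFrame],
                             mean_threshold: float = 10.0,
                             sd_threshold: float = 5.0) -> pd.DataFrame:
    """Cohort mean/SD of the per-subject percent differences.

    A duration is ``acceptable`` when |mean| is below ``mean_threshold``
    percent and the interindividual SD below ``sd_threshold`` percent.
    """
    cat = pd.concat(tables, ignore_index=True)
    g = cat[cat["usable"]].groupby("duration_min")["pct_diff"]
    out = g.agg(mean_pct_diff="mean", sd_pct_diff="std", n="count").reset_index()
    out["acceptable"] = (out["mean_pct_diff"].abs() < mean_threshold) & \
                        (out["sd_pct_diff"] < sd_threshold)
    return out.sort_values("duration_min", ascending=False).reset_index(drop=True)


def compute_suv(tac: TissueTAC, injected_dose_mbq: float,
                body_weight_kg: float) -> TissueTAC:
    """Standardized uptake value: C [kBq/mL] / (dose [kBq] / weight [g])."""
    if injected_dose_mbq <= 0 or body_weight_kg <= 0:
        raise ValidationError("dose and body weight must be > 0")
    dose_kbq = injected_dose_mbq * 1000.0
    weight_g = body_weight_kg * 1000.0
    return TissueTAC(tac.schedule, tac.values / (dose_kbq / weight_g),
                     region=tac.region)
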
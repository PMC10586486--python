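"""Arterial blood processing for PET kinetic modeling.

Serial arterial samples drawn during a dynamic scan provide three
measurements per time point: whole-blood activity, plasma activity, and
(at a subset of times) the fraction of plasma activity attributable to
unmetabolized parent tracer.  Kinetic models are driven by the
metabolite-corrected parent plasma concentration

    Cp_parent(t) = C_wb(t) * r(t) * PF(t)

where ``r`` is the plasma-to-whole-blood activity ratio and ``PF`` the
parent fraction.  This module fits the two correction models — a
monotonically declining Hill-type sigmoid for the parent fraction and an
ordinary-least-squares quadratic for the plasma ratio — and assembles the
corrected input function on a regular time grid.

All times are minutes post-injection; all activity concentrations kBq/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import warnings

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import OptimizeWarning, curve_fit

from .exceptions import FitFailureError, InsufficientDataError, ValidationError

__all__ = [
    "BloodSampleSeries",
    "ParentFractionModel",
    "PlasmaRatioModel",
    "InputFunction",
    "fit_parent_fraction",
    "fit_plasma_ratio",
    "build_input_function",
    "resample_curve",
    "uniform_grid",
]


def uniform_grid(end_min: float, dt_s: float = 1.0, start_min: float = 0.0) -> np.ndarray:
    """Regular time grid in minutes from ``start_min`` to at least ``end_min``."""
    dt = dt_s / 60.0
    n = int(np.ceil((end_min - start_min) / dt + 0.5)) + 1
    return start_min + dt * np.arange(n)


@dataclass(eq=False)
class BloodSampleSeries:
    """Serial arterial blood measurements.

    ``parent_fraction`` may be NaN where only activity was measured; late
    activity samples may likewise be NaN when decay made counting
    impossible.  Fits use available values only.
    """

    times: np.ndarray          # minutes post-injection, strictly increasing
    whole_blood: np.ndarray    # kBq/mL
    plasma: np.ndarray         # kBq/mL
    parent_fraction: np.ndarray  # unitless in [0, 1], NaN where missing

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.whole_blood = np.asarray(self.whole_blood, dtype=float)
        self.plasma = np.asarray(self.plasma, dtype=float)
        self.parent_fraction = np.asarray(self.parent_fraction, dtype=float)
        n = self.times.size
        for name in ("whole_blood", "plasma", "parent_fraction"):
            if getattr(self, name).size != n:
                raise ValidationError(f"{name} length does not match times")
        if n == 0:
            raise ValidationError("empty blood sample series")
        if np.any(self.times < 0):
            raise ValidationError("sample times must be >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("sample times must be strictly increasing")
        for name in ("whole_blood", "plasma"):
            v = getattr(self, name)
            if np.any(v[np.isfinite(v)] < 0):
                raise ValidationError(f"{name} activities must be >= 0")
        pf = self.parent_fraction
        ok = np.isfinite(pf)
        if np.any((pf[ok] < 0) | (pf[ok] > 1)):
            raise ValidationError("parent_fraction must lie in [0, 1]")

    @property
    def n_parent_samples(self) -> int:
        return int(np.isfinite(self.parent_fraction).sum())


@dataclass
class ParentFractionModel:
    """Declining Hill-type sigmoid parent-fraction model.

    PF(t) = pf_inf + (pf0 - pf_inf) / (1 + (t / t50)^h)

    Monotonically non-increasing for ``h > 0`` and ``pf0 >= pf_inf``;
    reduces to a constant when ``pf0 == pf_inf``.
    """

    pf0: float
    pf_inf: float
    t50: float
    h: float
    rss: float = 0.0
    form: str = "sigmoid"

    def __post_init__(self):
        if not (0.0 <= self.pf_inf <= self.pf0 <= 1.0):
            raise ValidationError("require 0 <= pf_inf <= pf0 <= 1")
        if self.t50 <= 0 or self.h <= 0:
            raise ValidationError("require t50 > 0 and h > 0")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return _sigmoid(t, self.pf0, self.pf_inf, self.t50, self.h)

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "pf0": self.pf0,
            "pf_inf": self.pf_inf,
            "t50": self.t50,
            "h": self.h,
            "rss": self.rss,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParentFractionModel":
        return cls(pf0=d["pf0"], pf_inf=d["pf_inf"], t50=d["t50"], h=d["h"],
                   rss=d.get("rss", 0.0))


def _sigmoid(t, pf0, pf_inf, t50, h):
    t = np.maximum(np.asarray(t, dtype=float), 0.0)
    return pf_inf + (pf0 - pf_inf) / (1.0 + (t / t50) ** h)


@dataclass
class PlasmaRatioModel:
    """Quadratic plasma-to-whole-blood ratio model r(t) = a t^2 + b t + c."""

    a: float
    b: float
    c: float
    r2: float = 1.0
    form: str = "quadratic"

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.a * t * t + self.b * t + self.c

    def to_dict(self) -> dict:
        return {"form": self.form, "a": self.a, "b": self.b, "c": self.c, "r2": self.r2}

    @classmethod
    def from_dict(cls, d: dict) -> "PlasmaRatioModel":
        return cls(a=d["a"], b=d["b"], c=d["c"], r2=d.get("r2", 1.0))


@dataclass(eq=False)
class InputFunction:
    """Metabolite-corrected input function sampled on a time grid.

    ``cp_parent`` is the parent plasma concentration driving the tissue
    model; ``c_wb`` the whole-blood concentration contributing the vascular
    signal fraction.  ``provenance`` records the correction models used.
    """

    times: np.ndarray      # minutes, increasing
    cp_parent: np.ndarray  # kBq/mL
    c_wb: np.ndarray       # kBq/mL
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.cp_parent = np.asarray(self.cp_parent, dtype=float)
        self.c_wb = np.asarray(self.c_wb, dtype=float)
        if self.cp_parent.size != self.times.size or self.c_wb.size != self.times.size:
            raise ValidationError("curve lengths do not match time grid")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("time grid must be strictly increasing")
        if np.any(self.cp_parent < 0):
            raise ValidationError("cp_parent must be >= 0 everywhere")

    @cached_property
    def _cum_cp(self) -> np.ndarray:
        return cumulative_trapezoid(self.cp_parent, self.times, initial=0.0)

    def cp_at(self, t) -> np.ndarray:
        return np.interp(t, self.times, self.cp_parent)

    def wb_at(self, t) -> np.ndarray:
        return np.interp(t, self.times, self.c_wb)

    def cum_cp_at(self, t) -> np.ndarray:
        """Trapezoidal cumulative integral of cp_parent evaluated at ``t``."""
        return np.interp(t, self.times, self._cum_cp)

    def scaled(self, factor: float) -> "InputFunction":
        return InputFunction(self.times.copy(), factor * self.cp_parent,
                             factor * self.c_wb, dict(self.provenance))


def resample_curve(times, values, grid) -> np.ndarray:
    """Resample a sampled curve onto ``grid``.

    Piecewise-linear between samples, zero before the first sample, and a
    mono-exponential tail beyond the last sample with rate taken from the
    last two positive samples (constant extension if non-decaying).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0:
        raise ValidationError("cannot resample an empty curve")
    if np.any(np.diff(times) <= 0):
        raise ValidationError("curve times must be strictly increasing")
    grid = np.asarray(grid, dtype=float)
    out = np.interp(grid, times, values, left=0.0)
    beyond = grid > times[-1]
    if np.any(beyond):
        lam = 0.0
        pos = np.flatnonzero(values > 0)
        if pos.size >= 2:
            i, j = pos[-2], pos[-1]
            if values[j] < values[i]:
                lam = np.log(values[i] / values[j]) / (times[j] - times[i])
        out[beyond] = values[-1] * np.exp(-lam * (grid[beyond] - times[-1]))
    return out


def fit_parent_fraction(samples: BloodSampleSeries) -> ParentFractionModel:
    """Least-squares sigmoid fit of the parent-fraction samples.

    Requires at least 3 usable parent-fraction samples.  Falls back to the
    constant (pf0 == pf_inf) degenerate model when the data carry no
    decline, which is the limit the sigmoid cannot represent with
    pf_inf > pf0.
    """
    ok = np.isfinite(samples.parent_fraction)
    if ok.sum() < 3:
        raise InsufficientDataError(
            f"need >= 3 parent-fraction samples, got {int(ok.sum())}")
    t = samples.times[ok]
    pf = samples.parent_fraction[ok]
    if np.any(t <= 0):
        raise ValidationError("parent-fraction sample times must be > 0")

    p0 = [min(float(pf.max()), 1.0), float(pf.min()), float(np.median(t)), 1.5]
    bounds = ([0.0, 0.0, 1e-2, 1e-2], [1.0, 1.0, 1e3, 20.0])
    try:
        with warnings.catch_warnings():
            # constant data makes the covariance singular; harmless here
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(_sigmoid, t, pf, p0=p0, bounds=bounds,
                                maxfev=20000, xtol=1e-12, ftol=1e-12)
    except RuntimeError as exc:
        raise FitFailureError(f"parent-fraction fit failed: {exc}",
                              last_iterate=p0) from exc
    pf0, pf_inf, t50, h = (float(v) for v in popt)
    if pf_inf > pf0:
        # non-declining data: collapse to the constant degenerate model
        const = float(np.mean(pf))
        pf0 = pf_inf = const
        t50, h = max(t50, 1e-2), max(h, 1e-2)
    rss = float(np.sum((_sigmoid(t, pf0, pf_inf, t50, h) - pf) ** 2))
    return ParentFractionModel(pf0=pf0, pf_inf=pf_inf, t50=t50, h=h, rss=rss)


def fit_plasma_ratio(samples: BloodSampleSeries) -> PlasmaRatioModel:
    """Ordinary-least-squares quadratic fit of plasma/whole-blood vs time."""
    ok = np.isfinite(samples.plasma) & np.isfinite(samples.whole_blood)
    zero = ok & (samples.whole_blood == 0) & (samples.plasma > 0)
    if np.any(zero):
        t_bad = samples.times[zero][0]
        raise ValidationError(
            f"whole_blood is zero at t = {t_bad:g} min; ratio undefined")
    # pre-arrival samples (no activity in either fraction) carry no ratio
    ok &= samples.whole_blood > 0
    if ok.sum() < 3:
        raise InsufficientDataError(
            f"need >= 3 plasma/whole-blood samples, got {int(ok.sum())}")
    t = samples.times[ok]
    ratio = samples.plasma[ok] / samples.whole_blood[ok]
    a, b, c = np.polyfit(t, ratio, 2)
    pred = a * t * t + b * t + c
    ss_res = float(np.sum((ratio - pred) ** 2))
    ss_tot = float(np.sum((ratio - ratio.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    model = PlasmaRatioModel(a=float(a), b=float(b), c=float(c), r2=r2)
    probe = np.linspace(0.0, float(t.max()), 200)
    if np.any(model(probe) <= 0):
        raise FitFailureError("fitted plasma ratio non-positive on the scan interval",
                              last_iterate=[a, b, c])
    return model


def build_input_function(samples: BloodSampleSeries,
                         pf: ParentFractionModel,
                         ratio: PlasmaRatioModel,
                         grid) -> InputFunction:
    """Assemble the metabolite-corrected input function on ``grid``.

    Whole blood is interpolated between samples (zero before the first,
    mono-exponential tail after the last); the parent plasma curve is the
    pointwise product C_wb * r * PF, clipped at zero.  A grid extending
    more than 20 min past the last sample records an extrapolation
    warning in the provenance rather than raising.
    """
    grid = np.asarray(grid, dtype=float)
    ok = np.isfinite(samples.whole_blood)
    if ok.sum() == 0:
        raise ValidationError("no usable whole-blood samples")
    c_wb = resample_curve(samples.times[ok], samples.whole_blood[ok], grid)
    cp = np.clip(c_wb * ratio(grid) * np.clip(pf(grid), 0.0, 1.0), 0.0, None)
    last = float(samples.times[ok][-1])
    overhang = float(grid.max() - last)
    provenance = {
        "parent_fraction": pf.to_dict(),
        "plasma_ratio": ratio.to_dict(),
        "last_sample_min": last,
        "extrapolated_min": max(overhang, 0.0),
        "extrapolation_warning": overhang > 20.0,
    }
    return InputFunction(times=grid, cp_parent=cp, c_wb=np.clip(c_wb, 0.0, None),
                         provenance=provenance)
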
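"""Voxelwise Logan V_T mapping and atlas-based regional extraction.

Parametric maps assign each voxel its Logan-slope V_T.  The default
policy estimates a single global t* from the mean TAC over the mask (the
convention of pixelwise graphical-analysis tools, and markedly more noise
robust than a per-voxel search); a per-voxel t* search is available.
Invalid voxels (outside the mask, non-positive activity in the linear
phase, or failed fits) carry NaN — zero would be ambiguous with true zero
binding.  Maps are never smoothed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blood import InputFunction
from .exceptions import ValidationError
from .kinetics import FrameSchedule, TissueTAC, fit_logan, logan_transform, select_tstar

__all__ = [
    "DynamicImage",
    "LabelAtlas",
    "ParametricMap",
    "extract_voi_tacs",
    "voxelwise_logan_map",
    "group_mean_map",
]


@dataclass(eq=False)
class DynamicImage:
    """4D dynamic PET volume (x, y, z, frame), kBq/mL."""

    data: np.ndarray
    voxel_size_mm: tuple
    schedule: FrameSchedule
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValidationError("dynamic image must be 4D (x, y, z, frame)")
        if self.data.shape[3] != self.schedule.n_frames:
            raise ValidationError("frame axis length must equal schedule length")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValidationError("voxel sizes must be three positive numbers")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValidationError("mask shape must match image grid")


@dataclass(eq=False)
class LabelAtlas:
    """Integer label image (0 = background) with a label -> name table."""

    labels: np.ndarray
    names: dict

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("atlas must be a 3D label image")
        if np.any(self.labels < 0):
            raise ValidationError("labels must be >= 0 (0 = background)")
        present = set(np.unique(self.labels).tolist())
        for lab, name in self.names.items():
            if int(lab) == 0:
                raise ValidationError("label 0 is reserved for background")
            if int(lab) not in present:
                raise ValidationError(f"label {lab} ('{name}') absent from atlas image")

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass(eq=False)
class ParametricMap:
    """3D V_T image; invalid voxels are NaN with ``valid`` False."""

    data: np.ndarray
    valid: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.data.shape != self.valid.shape or self.data.ndim != 3:
            raise ValidationError("map and validity mask must be matching 3D arrays")
        if np.any(~np.isfinite(self.data[self.valid])):
            raise ValidationError("valid voxels must carry finite values")


def extract_voi_tacs(img: DynamicImage, atlas: LabelAtlas) -> dict:
    """Per-region unweighted mean TAC over member voxels."""
    if atlas.labels.shape != img.data.shape[:3]:
        raise ValidationError("atlas grid does not match image grid")
    out = {}
    for lab, name in atlas.names.items():
        sel = atlas.labels == int(lab)
        if not np.any(sel):
            raise ValidationError(f"region '{name}' (label {lab}) is empty")
        out[name] = TissueTAC(img.schedule, img.data[sel].mean(axis=0), region=name)
    return out


def _cum_tissue(tacmat: np.ndarray, mids: np.ndarray) -> np.ndarray:
    """Trapezoidal cumulative tissue integral at frame midpoints, zero anchor."""
    t = np.concatenate([[0.0], mids])
    v = np.concatenate([np.zeros((tacmat.shape[0], 1)), tacmat], axis=1)
    seg = 0.5 * (v[:, 1:] + v[:, :-1]) * np.diff(t)
    return np.cumsum(seg, axis=1)


def voxelwise_logan_map(img: DynamicImage, cp: InputFunction,
                        t_star_policy: str = "global",
                        mask: np.ndarray | None = None,
                        max_rel_error: float = 0.10,
                        vb: float = 0.04) -> ParametricMap:
    """Logan V_T parametric map over the masked voxels.

    ``t_star_policy``:

    * ``"global"`` (default) — t* selected once from the mean TAC over the
      mask, then applied to every voxel (vectorized least squares).
    * ``"voxel"`` — full per-voxel t* search (slow; loops the scalar path).
    """
    if mask is None:
        mask = img.mask if img.mask is not None else np.ones(img.data.shape[:3], bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.data.shape[:3]:
        raise ValidationError("mask shape must match image grid")
    sched = img.schedule
    mids = sched.mid_min
    flat = img.data[mask]  # (n_vox, n_frames)
    if flat.shape[0] == 0:
        raise ValidationError("mask selects no voxels")

    vt_flat = np.full(flat.shape[0], np.nan)
    meta = {"policy": t_star_policy, "max_rel_error": max_rel_error, "vb": vb}
    if vb > 0:
        # remove the vascular signal fraction, as in the scalar Logan path
        flat = (flat - vb * cp.wb_at(mids)[None, :]) / (1.0 - vb)

    if t_star_policy == "global":
        mean_tac = TissueTAC(sched, flat.mean(axis=0))
        pts = logan_transform(mean_tac, cp, vb=0.0)
        t_star, _ = select_tstar(pts, max_rel_error=max_rel_error)
        sel = mids >= t_star - 1e-9
        m = int(sel.sum())
        if m < 3:
            raise ValidationError("global t* leaves fewer than 3 frames")
        ct = flat[:, sel]
        ok = np.all(ct > 0, axis=1)
        cum_t = _cum_tissue(flat, mids)[:, sel]
        cum_p = cp.cum_cp_at(mids[sel])[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            x = cum_p / ct
            y = cum_t / ct
            xm = x.mean(axis=1, keepdims=True)
            ym = y.mean(axis=1, keepdims=True)
            num = np.sum((x - xm) * (y - ym), axis=1)
            den = np.sum((x - xm) ** 2, axis=1)
            slope = num / den
        ok &= np.isfinite(slope)
        vt_flat[ok] = slope[ok]
        meta.update(t_star=float(t_star), n_frames_used=m,
                    frames_used=[int(i) for i in np.flatnonzero(sel)])
    elif t_star_policy == "voxel":
        for i in range(flat.shape[0]):
            try:
                vt_flat[i] = fit_logan(TissueTAC(sched, flat[i]), cp,
                                       max_rel_error=max_rel_error, vb=0.0).vt
            except Exception:
                pass
        meta.update(t_star=None)
    else:
        raise ValidationError(f"unknown t_star_policy '{t_star_policy}'")

    data = np.full(img.data.shape[:3], np.nan)
    data[mask] = vt_flat
    valid = np.zeros(img.data.shape[:3], bool)
    valid[mask] = np.isfinite(vt_flat)
    if not valid.any():
        raise ValidationError("Logan fit failed for every masked voxel")
    return ParametricMap(data=data, valid=valid, meta=meta)


def group_mean_map(maps: list[ParametricMap]) -> ParametricMap:
    """Voxelwise mean; a voxel is invalid if invalid in any input map."""
    if len(maps) == 0:
        raise ValidationError("no maps to average")
    shape = maps[0].data.shape
    for m in maps[1:]:
        if m.data.shape != shape:
            raise ValidationError("parametric map grids do not match")
    valid = np.logical_and.reduce([m.valid for m in maps])
    stack = np.stack([m.data for m in maps])
    data = np.full(shape, np.nan)
    data[valid] = stack[:, valid].mean(axis=0)
    return ParametricMap(data=data, valid=valid, meta={"n": len(maps)})
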
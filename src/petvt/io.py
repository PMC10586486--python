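"""File formats: blood/TAC/cohort CSV, frame-schedule JSON, NIfTI images.

NIfTI stores no frame timing reliably, so dynamic images travel with a
sidecar JSON listing ``[start_s, duration_s]`` per frame.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .blood import BloodSampleSeries, InputFunction, ParentFractionModel, PlasmaRatioModel
from .exceptions import ValidationError
from .kinetics import FrameSchedule, TissueTAC
from .parametric import DynamicImage, LabelAtlas

BLOOD_COLUMNS = ["time_min", "whole_blood_kBq_ml", "plasma_kBq_ml", "parent_fraction"]
AIF_COLUMNS = ["time_min", "cp_parent_kBq_ml", "whole_blood_kBq_ml"]


def write_blood_csv(samples: BloodSampleSeries, path):
    pd.DataFrame({
        "time_min": samples.times,
        "whole_blood_kBq_ml": samples.whole_blood,
        "plasma_kBq_ml": samples.plasma,
        "parent_fraction": samples.parent_fraction,
    }).to_csv(path, index=False)


def read_blood_csv(path) -> BloodSampleSeries:
    df = pd.read_csv(path)
    missing = set(BLOOD_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"blood CSV missing columns: {sorted(missing)}")
    return BloodSampleSeries(times=df["time_min"].to_numpy(),
                             whole_blood=df["whole_blood_kBq_ml"].to_numpy(),
                             plasma=df["plasma_kBq_ml"].to_numpy(),
                             parent_fraction=df["parent_fraction"].to_numpy())


def write_input_function_csv(aif: InputFunction, path):
    pd.DataFrame({
        "time_min": aif.times,
        "cp_parent_kBq_ml": aif.cp_parent,
        "whole_blood_kBq_ml": aif.c_wb,
    }).to_csv(path, index=False)


def read_input_function_csv(path) -> InputFunction:
    df = pd.read_csv(path)
    missing = set(AIF_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"input-function CSV missing columns: {sorted(missing)}")
    return InputFunction(times=df["time_min"].to_numpy(),
                         cp_parent=df["cp_parent_kBq_ml"].to_numpy(),
                         c_wb=df["whole_blood_kBq_ml"].to_numpy())


def write_blood_models_json(pf: ParentFractionModel, ratio: PlasmaRatioModel, path):
    with open(path, "w") as f:
        json.dump({"parent_fraction": pf.to_dict(), "plasma_ratio": ratio.to_dict()},
                  f, indent=1, sort_keys=True)


def read_blood_models_json(path):
    with open(path) as f:
        d = json.load(f)
    return (ParentFractionModel.from_dict(d["parent_fraction"]),
            PlasmaRatioModel.from_dict(d["plasma_ratio"]))


def write_tac_csv(tacs: dict, path):
    """Long-format TAC table: one row per frame x region."""
    rows = []
    for name, tac in tacs.items():
        sched = tac.schedule
        for s, d, v in zip(sched.start_s, sched.duration_s, tac.values):
            rows.append({"frame_start_s": s, "frame_duration_s": d,
                         "region": name, "value_kBq_ml": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tac_csv(path) -> dict:
    df = pd.read_csv(path)
    out = {}
    for name, sub in df.groupby("region", sort=False):
        sub = sub.sort_values("frame_start_s")
        sched = FrameSchedule(sub["frame_start_s"].to_numpy(),
                              sub["frame_duration_s"].to_numpy())
        out[name] = TissueTAC(sched, sub["value_kBq_ml"].to_numpy(), region=name)
    return out


def write_schedule_json(schedule: FrameSchedule, path):
    with open(path, "w") as f:
        json.dump(schedule.to_list(), f)


def read_schedule_json(path) -> FrameSchedule:
    with open(path) as f:
        return FrameSchedule.from_list(json.load(f))


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


def save_nifti(data: np.ndarray, voxel_size_mm, path):
    nib.save(nib.Nifti1Image(np.asarray(data), _affine(voxel_size_mm)), str(path))


def load_nifti(path):
    img = nib.load(str(path))
    voxel = tuple(float(v) for v in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), voxel


def save_dynamic_image(img: DynamicImage, nifti_path, frames_path):
    save_nifti(img.data, img.voxel_size_mm, nifti_path)
    write_schedule_json(img.schedule, frames_path)


def load_dynamic_image(nifti_path, frames_path) -> DynamicImage:
    data, voxel = load_nifti(nifti_path)
    schedule = read_schedule_json(frames_path)
    return DynamicImage(data=data, voxel_size_mm=voxel, schedule=schedule)


def save_atlas(atlas: LabelAtlas, nifti_path, names_path):
    save_nifti(atlas.labels.astype(np.int16), (1.0, 1.0, 1.0), nifti_path)
    with open(names_path, "w") as f:
        json.dump({str(k): v for k, v in atlas.names.items()}, f, indent=1,
                  sort_keys=True)


def load_atlas(nifti_path, names_path) -> LabelAtlas:
    data, _ = load_nifti(nifti_path)
    with open(names_path) as f:
        names = {int(k): v for k, v in json.load(f).items()}
    return LabelAtlas(labels=np.asarray(data).astype(int), names=names)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
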
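"""End-to-end study orchestration: simulate -> blood -> kinetics -> parametric -> stats -> report.

Each stage reads its inputs from the study directory and writes its outputs
back to it, so deleting downstream outputs and rerunning reproduces them
exactly from the upstream artifacts.  A stage failure aborts the run with
the stage name; partial outputs are preserved on disk.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .blood import build_input_function, fit_parent_fraction, fit_plasma_ratio, uniform_grid
from .exceptions import PipelineStageError, ValidationError
from .kinetics import cohort_stability_summary, fit_logan, time_stability
from .parametric import ParametricMap, group_mean_map, voxelwise_logan_map
from .simulate import SimulationConfig, simulate_study
from .stats import (extract_clusters, pearson_correlation, posthoc_group_by_region,
                    two_way_anova, voxelwise_two_sample_map)

logger = logging.getLogger("petvt")

STAGES = ("simulate", "blood", "kinetics", "parametric", "stats", "report")


@dataclass
class PipelineConfig:
    """Pipeline tunables; round-trips losslessly through YAML."""

    seed: int = 20230
    outdir: str = "study"
    stages: tuple = STAGES
    make_images: bool = True
    vb: float = 0.04
    max_rel_error: float = 0.10
    durations: tuple = (90.0, 80.0, 70.0, 60.0, 50.0, 40.0)
    stability_mean_threshold: float = 10.0
    stability_sd_threshold: float = 5.0
    p_thresh: float = 0.01
    k_min: int = 10
    connectivity: int = 18
    cluster_strict: bool = True
    alpha: float = 0.05
    t_star_policy: str = "global"
    sim: dict = field(default_factory=dict)

    def simulation_config(self) -> SimulationConfig:
        d = dict(self.sim)
        d.setdefault("seed", self.seed)
        d.setdefault("vb", self.vb)
        return SimulationConfig.from_dict(d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["durations"] = list(self.durations)
        return d

    def to_yaml(self, path):
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown pipeline config keys: {sorted(unknown)}")
        for key in ("stages", "durations"):
            if key in d:
                d[key] = tuple(d[key])
        for st in d.get("stages", ()):
            if st not in STAGES:
                raise ValidationError(f"unknown stage '{st}'")
        if "sim" in d and d["sim"]:
            SimulationConfig.from_dict({**d["sim"]})  # validate keys early
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})


def _stage_simulate(cfg: PipelineConfig, out: Path):
    sim_cfg = cfg.simulation_config()
    study = simulate_study(sim_cfg)
    sdir = pio.ensure_dir(out / "study")
    pio.write_schedule_json(sim_cfg.schedule(), sdir / "frames.json")
    study.animals.to_csv(sdir / "animals.csv", index=False)
    study.truth.to_csv(sdir / "truth.csv", index=False)
    study.behavior.to_csv(sdir / "behavior.csv", index=False)
    bdir = pio.ensure_dir(sdir / "blood")
    tdir = pio.ensure_dir(sdir / "tacs")
    for animal in study.animals["animal"]:
        pio.write_blood_csv(study.blood[animal], bdir / f"{animal}.csv")
        pio.write_tac_csv(study.tacs[animal], tdir / f"{animal}.csv")
    if cfg.make_images:
        pdir = pio.ensure_dir(sdir / "pet")
        images = study.make_images()
        atlas_written = False
        for animal, (img, atlas) in images.items():
            pio.save_dynamic_image(img, pdir / f"{animal}.nii.gz",
                                   sdir / "frames.json")
            if not atlas_written:
                pio.save_atlas(atlas, sdir / "atlas.nii.gz",
                               sdir / "atlas_names.json")
                atlas_written = True
    logger.info("simulate: wrote study for %d animals", len(study.animals))


def _animals(out: Path) -> pd.DataFrame:
    return pd.read_csv(out / "study" / "animals.csv")


def _stage_blood(cfg: PipelineConfig, out: Path):
    sdir = out / "study"
    schedule = pio.read_schedule_json(sdir / "frames.json")
    grid = uniform_grid(schedule.total_min)
    adir = pio.ensure_dir(out / "aif")
    for animal in _animals(out)["animal"]:
        samples = pio.read_blood_csv(sdir / "blood" / f"{animal}.csv")
        pf = fit_parent_fraction(samples)
        ratio = fit_plasma_ratio(samples)
        aif = build_input_function(samples, pf, ratio, grid)
        pio.write_blood_models_json(pf, ratio, adir / f"{animal}_models.json")
        pio.write_input_function_csv(aif, adir / f"{animal}_input.csv")
    logger.info("blood: fitted input functions")


def _stage_kinetics(cfg: PipelineConfig, out: Path):
    sdir = out / "study"
    kdir = pio.ensure_dir(out / "kinetics")
    animals = _animals(out)
    rows, stab_tables = [], []
    for animal, group in zip(animals["animal"], animals["group"]):
        aif = pio.read_input_function_csv(out / "aif" / f"{animal}_input.csv")
        tacs = pio.read_tac_csv(sdir / "tacs" / f"{animal}.csv")
        for region, tac in tacs.items():
            res = fit_logan(tac, aif, max_rel_error=cfg.max_rel_error)
            rows.append({"animal": animal, "group": group, "region": region,
                         "vt": res.vt, "t_star": res.t_star,
                         "n_points": res.n_points, "r2": res.r2})
            stab = time_stability(tac, aif, durations=cfg.durations,
                                  max_rel_error=cfg.max_rel_error)
            stab.insert(0, "animal", animal)
            stab.insert(1, "region", region)
            stab_tables.append(stab)
    pd.DataFrame(rows).to_csv(kdir / "cohort_vt.csv", index=False)
    stab_all = pd.concat(stab_tables, ignore_index=True)
    stab_all.to_csv(kdir / "time_stability.csv", index=False)
    cohort_stability_summary(
        stab_tables, mean_threshold=cfg.stability_mean_threshold,
        sd_threshold=cfg.stability_sd_threshold,
    ).to_csv(kdir / "time_stability_summary.csv", index=False)
    logger.info("kinetics: %d Logan fits", len(rows))


def _stage_parametric(cfg: PipelineConfig, out: Path):
    sdir = out / "study"
    if not (sdir / "pet").exists():
        logger.info("parametric: no images present, skipping")
        return
    pdir = pio.ensure_dir(out / "parametric")
    animals = _animals(out)
    atlas = pio.load_atlas(sdir / "atlas.nii.gz", sdir / "atlas_names.json")
    maps = {}
    for animal in animals["animal"]:
        img = pio.load_dynamic_image(sdir / "pet" / f"{animal}.nii.gz",
                                     sdir / "frames.json")
        aif = pio.read_input_function_csv(out / "aif" / f"{animal}_input.csv")
        pmap = voxelwise_logan_map(img, aif, t_star_policy=cfg.t_star_policy,
                                   mask=atlas.brain_mask,
                                   max_rel_error=cfg.max_rel_error)
        maps[animal] = pmap
        pio.save_nifti(pmap.data, img.voxel_size_mm, pdir / f"vt_{animal}.nii.gz")
    by_group = animals.groupby("group")["animal"].apply(list).to_dict()
    for group, members in by_group.items():
        gmap = group_mean_map([maps[a] for a in members])
        pio.save_nifti(gmap.data, (1, 1, 1), pdir / f"mean_vt_{group}.nii.gz")
    if "85Q" in by_group and len(by_group) > 1:
        controls = [a for g, m in by_group.items() if g != "85Q" for a in m]
        tmap, df = voxelwise_two_sample_map(
            [maps[a] for a in by_group["85Q"]], [maps[a] for a in controls])
        pio.save_nifti(np.nan_to_num(tmap, nan=0.0, posinf=0.0, neginf=0.0),
                       (1, 1, 1), pdir / "tmap_85Q_gt_controls.nii.gz")
        clusters = extract_clusters(tmap, df, p_thresh=cfg.p_thresh,
                                    k_min=cfg.k_min,
                                    connectivity=cfg.connectivity,
                                    strict=cfg.cluster_strict)
        clusters.table.to_csv(pdir / "clusters.csv", index=False)
        with open(pdir / "cluster_meta.json", "w") as f:
            json.dump({"df": df, "threshold_t": clusters.threshold_t,
                       "p_thresh": cfg.p_thresh, "k_min": cfg.k_min,
                       "connectivity": cfg.connectivity}, f, sort_keys=True)
    logger.info("parametric: %d maps", len(maps))


def _stage_stats(cfg: PipelineConfig, out: Path):
    kdir = out / "kinetics"
    stdir = pio.ensure_dir(out / "stats")
    table = pd.read_csv(kdir / "cohort_vt.csv")
    anova = two_way_anova(table)
    anova.effects.to_csv(stdir / "anova.csv", index=False)
    posthoc = posthoc_group_by_region(table, anova=anova, alpha=cfg.alpha)
    posthoc.to_csv(stdir / "posthoc.csv", index=False)
    behavior_path = out / "study" / "behavior.csv"
    if behavior_path.exists():
        behavior = pd.read_csv(behavior_path).set_index("animal")
        rows = []
        for region, sub in table.groupby("region", sort=False):
            sub = sub.set_index("animal")
            common = sub.index.intersection(behavior.index)
            for measure in ("neurologic_rating", "working_memory"):
                r, p = pearson_correlation(behavior.loc[common, measure],
                                           sub.loc[common, "vt"])
                rows.append({"region": region, "measure": measure, "r": r, "p": p})
        pd.DataFrame(rows).to_csv(stdir / "correlations.csv", index=False)
    logger.info("stats: ANOVA + post hoc + correlations written")


def _stage_report(cfg: PipelineConfig, out: Path):
    summary = {"seed": cfg.seed}
    anova_path = out / "stats" / "anova.csv"
    if anova_path.exists():
        eff = pd.read_csv(anova_path)
        summary["anova"] = {
            row["effect"]: {"df": row["df"], "F": row["F"], "p": row["p"]}
            for _, row in eff.iterrows()
        }
    ph_path = out / "stats" / "posthoc.csv"
    if ph_path.exists():
        ph = pd.read_csv(ph_path)
        sig = ph[ph["significant"]]
        summary["posthoc"] = {
            "n_significant": int(len(sig)),
            "significant_regions": sorted(sig["region"].unique().tolist()),
        }
    corr_path = out / "stats" / "correlations.csv"
    if corr_path.exists():
        corr = pd.read_csv(corr_path)
        summary["correlations"] = {
            measure: {"mean_r": float(sub["r"].mean()),
                      "n_regions": int(len(sub))}
            for measure, sub in corr.groupby("measure")
        }
    cl_path = out / "parametric" / "clusters.csv"
    if cl_path.exists():
        cl = pd.read_csv(cl_path)
        summary["clusters"] = {"n": int(len(cl)),
                               "total_voxels": int(cl["size"].sum()) if len(cl) else 0}
    ts_path = out / "kinetics" / "time_stability_summary.csv"
    if ts_path.exists():
        ts = pd.read_csv(ts_path)
        summary["time_stability"] = ts.to_dict(orient="records")
    with open(out / "summary.json", "w") as f:
        json.dump(summary, f, indent=1, sort_keys=True)
    lines = ["# Study report", ""]
    if "anova" in summary:
        g = summary["anova"].get("group", {})
        lines.append(f"Group main effect: F = {g.get('F', float('nan')):.3f}, "
                     f"p = {g.get('p', float('nan')):.3g}")
    if "posthoc" in summary:
        lines.append(f"Significant post hoc regions: "
                     f"{', '.join(summary['posthoc']['significant_regions']) or 'none'}")
    if "clusters" in summary:
        lines.append(f"Voxelwise clusters (85Q > controls): {summary['clusters']['n']}")
    (out / "report.md").write_text("\n".join(lines) + "\n")
    logger.info("report: summary written")
    return summary


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "blood": _stage_blood,
    "kinetics": _stage_kinetics,
    "parametric": _stage_parametric,
    "stats": _stage_stats,
    "report": _stage_report,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in canonical order; returns the summary."""
    out = pio.ensure_dir(cfg.outdir)
    if not logger.handlers:
        logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "pipeline.log")
    logger.addHandler(fh)
    try:
        cfg.to_yaml(out / "pipeline_config.yaml")
        summary = {}
        for stage in STAGES:
            if stage not in cfg.stages:
                continue
            logger.info("running stage: %s", stage)
            try:
                result = _STAGE_FUNCS[stage](cfg, out)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(stage, exc) from exc
            if stage == "report" and result is not None:
                summary = result
        return summary
    finally:
        logger.removeHandler(fh)
        fh.close()
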
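"""Synthetic three-group cohort generator for end-to-end pipeline testing.

Emulates a viral-vector primate study of mutant-huntingtin aggregate
imaging: a buffer-injected control group, a 10Q control fragment group,
and an 85Q pathogenic fragment group whose regional V_T is elevated by
region-specific fold changes (largest in the putamen, anterior cingulate
and supplemental motor cortices; cerebellum null).

Generated artifacts mirror the acquisition protocol: a Feng-type arterial
whole-blood curve, a declining sigmoid parent fraction calibrated so that
PF(60 min) = 0.514, a near-constant plasma/whole-blood ratio with mild
quadratic curvature, 16 activity samples and 7 parent-fraction samples,
28 frames over 90 min, 2TCM tissue kinetics, frame-duration-dependent
noise, small 4D label phantoms, and behavior scores linearly coupled to
the mean V_T of the affected regions.

Randomness is organized into independent named streams derived from the
configured seed, so every artifact is byte-stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .blood import (BloodSampleSeries, InputFunction, ParentFractionModel,
                    PlasmaRatioModel, uniform_grid)
from .exceptions import ValidationError
from .kinetics import FrameSchedule, TissueTAC, TwoTCMParams, solve_2tcm_forward
from .parametric import DynamicImage, LabelAtlas

__all__ = [
    "RegionSpec",
    "SimulationConfig",
    "SimulatedStudy",
    "default_parent_fraction_model",
    "feng_whole_blood",
    "simulate_aif",
    "simulate_blood_samples",
    "derive_micro_params",
    "simulate_cohort_tacs",
    "simulate_dynamic_image",
    "simulate_behavior",
    "simulate_study",
]

# 16 activity sampling times and the 7 late times with radiometabolite analysis
BLOOD_SAMPLE_TIMES = (0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0,
                      5.0, 8.0, 15.0, 30.0, 45.0, 60.0, 75.0, 90.0)
PARENT_SAMPLE_TIMES = (5.0, 15.0, 30.0, 45.0, 60.0, 75.0, 90.0)


@dataclass(frozen=True)
class RegionSpec:
    """Region with its control-group V_T and 85Q fold change."""

    name: str
    control_vt: float
    fold_change_85q: float


# Anterior-to-posterior V_T gradient; effects largest in putamen / anterior
# cingulate / supplemental motor cortex, null in occipital cortex and
# cerebellum.  V_T values are order-of-magnitude choices for a reversible
# CNS tracer, not calibrated to any measured table.
DEFAULT_REGIONS = (
    RegionSpec("dorsomedial_prefrontal_cortex", 5.0, 1.4),
    RegionSpec("anterior_cingulate_cortex", 4.8, 1.7),
    RegionSpec("supplemental_motor_cortex", 4.6, 1.6),
    RegionSpec("insular_cortex", 4.4, 1.3),
    RegionSpec("caudate", 4.2, 1.5),
    RegionSpec("putamen", 4.0, 1.8),
    RegionSpec("occipital_cortex", 3.4, 1.0),
    RegionSpec("cerebellum", 3.0, 1.0),
)


def default_parent_fraction_model(pf0: float = 1.0, pf_inf: float = 0.30,
                                  h: float = 1.6,
                                  pf_at_60: float = 0.514) -> ParentFractionModel:
    """Sigmoid parent-fraction model calibrated to PF(60 min) = ``pf_at_60``.

    The half-transition time t50 is solved from the calibration constraint,
    so the pin holds exactly by construction.
    """
    if pf0 == pf_inf:
        # constant parent fraction: no transition to calibrate
        return ParentFractionModel(pf0=pf0, pf_inf=pf_inf, t50=60.0, h=h)
    if not (pf_inf < pf_at_60 < pf0):
        raise ValidationError("require pf_inf < PF(60) < pf0 for calibration")
    x = (pf0 - pf_inf) / (pf_at_60 - pf_inf) - 1.0
    t50 = 60.0 / x ** (1.0 / h)
    return ParentFractionModel(pf0=pf0, pf_inf=pf_inf, t50=t50, h=h)


@dataclass
class SimulationConfig:
    """All tunables of the synthetic study; defaults define the study conditions."""

    seed: int = 20230
    # cohort
    groups: dict = field(default_factory=lambda: {"buffer": 5, "10Q": 4, "85Q": 5})
    regions: tuple = DEFAULT_REGIONS
    between_animal_cv: float = 0.10   # lognormal CV of true V_T across animals
    amplitude_cv: float = 0.10        # lognormal CV of per-animal AIF scale
    # kinetic defaults shared across regions (k3 solved per target V_T)
    k1: float = 0.5                   # mL cm^-3 min^-1
    k2: float = 0.5                   # min^-1
    k4: float = 0.05                  # min^-1
    vb: float = 0.04
    # Feng-type whole-blood model (kBq/mL, 1/min); lam1 < lam2 < lam3 < 0
    aif_a1: float = 850.0
    aif_a2: float = 21.0
    aif_a3: float = 6.0
    aif_lam1: float = -4.0
    aif_lam2: float = -0.25
    aif_lam3: float = -0.012
    aif_delay_min: float = 0.5
    # blood correction models
    pf0: float = 1.0
    pf_inf: float = 0.30
    pf_h: float = 1.6
    pf_at_60: float = 0.514
    ratio_a: float = -5.0e-6
    ratio_b: float = 5.0e-4
    ratio_c: float = 1.08
    # sampling / acquisition
    blood_times: tuple = BLOOD_SAMPLE_TIMES
    parent_times: tuple = PARENT_SAMPLE_TIMES
    blood_noise: float = 0.03         # relative SD on blood measurements
    frame_scheme: str = "default"     # 28-frame / 90-min scheme
    grid_dt_s: float = 1.0
    # tissue noise: SD_k = scale * sqrt(mean_k / duration_min_k)
    tac_noise_scale: float = 0.1
    # phantom image
    image_shape: tuple = (32, 32, 16)
    voxel_size_mm: tuple = (2.0, 2.0, 2.0)
    voxel_noise_scale: float = 0.3
    # behavior model (predictor = per-animal mean true V_T over affected regions)
    rating_intercept: float = 2.0
    rating_slope: float = 1.0         # > 0: higher rating = worse = more binding
    rating_noise_sd: float = 1.7
    memory_intercept: float = 95.0
    memory_slope: float = 8.0         # > 0 slope magnitude; enters negatively
    memory_noise_sd: float = 13.0

    def schedule(self) -> FrameSchedule:
        if self.frame_scheme != "default":
            raise ValidationError(f"unknown frame scheme '{self.frame_scheme}'")
        return FrameSchedule.default()

    def parent_fraction_model(self) -> ParentFractionModel:
        return default_parent_fraction_model(self.pf0, self.pf_inf,
                                             self.pf_h, self.pf_at_60)

    def plasma_ratio_model(self) -> PlasmaRatioModel:
        return PlasmaRatioModel(a=self.ratio_a, b=self.ratio_b, c=self.ratio_c)

    def group_mean_vt(self, group: str, region: RegionSpec) -> float:
        return region.control_vt * (region.fold_change_85q if group == "85Q" else 1.0)

    @property
    def affected_regions(self) -> tuple:
        return tuple(r.name for r in self.regions if r.fold_change_85q > 1.0)

    @property
    def animal_ids(self) -> list:
        out = []
        for g, n in self.groups.items():
            if n < 2:
                raise ValidationError("group sizes must be >= 2")
            out.extend((f"{g}_{i + 1:02d}", g) for i in range(n))
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["regions"] = [asdict(r) for r in self.regions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown simulation config keys: {sorted(unknown)}")
        if "regions" in d:
            d["regions"] = tuple(RegionSpec(**r) if isinstance(r, dict) else r
                                 for r in d["regions"])
        for key in ("blood_times", "parent_times", "image_shape", "voxel_size_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _rng(config: SimulationConfig, *stream) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2 ** 31), *stream])


def feng_whole_blood(t, a1, lam1, a2, lam2, a3, lam3, delay) -> np.ndarray:
    """Feng-type whole-blood curve: zero before the arrival delay, then a
    linear-rise exponential plus two decaying exponentials."""
    t = np.asarray(t, dtype=float)
    ts = t - delay
    with np.errstate(over="ignore"):
        curve = (a1 * ts * np.exp(lam1 * ts) + a2 * np.exp(lam2 * ts)
                 + a3 * np.exp(lam3 * ts))
    return np.where(ts > 0, curve, 0.0)


def simulate_aif(config: SimulationConfig, amplitude: float = 1.0) -> InputFunction:
    """Noise-free continuous input function on the fine grid."""
    if not (config.aif_lam1 < config.aif_lam2 < config.aif_lam3 < 0):
        raise ValidationError("require lam1 < lam2 < lam3 < 0")
    grid = uniform_grid(config.schedule().total_min, dt_s=config.grid_dt_s)
    wb = amplitude * feng_whole_blood(grid, config.aif_a1, config.aif_lam1,
                                      config.aif_a2, config.aif_lam2,
                                      config.aif_a3, config.aif_lam3,
                                      config.aif_delay_min)
    if np.any(wb < 0):
        raise ValidationError("whole-blood model is negative on the grid")
    pf = config.parent_fraction_model()
    ratio = config.plasma_ratio_model()
    cp = wb * ratio(grid) * pf(grid)
    return InputFunction(times=grid, cp_parent=cp, c_wb=wb,
                         provenance={"parent_fraction": pf.to_dict(),
                                     "plasma_ratio": ratio.to_dict(),
                                     "amplitude": amplitude})


def simulate_blood_samples(config: SimulationConfig,
                           rng: np.random.Generator | None = None,
                           amplitude: float = 1.0) -> BloodSampleSeries:
    """Sampled blood table with relative Gaussian measurement noise."""
    if rng is None:
        rng = _rng(config, 1)
    t = np.asarray(config.blood_times, dtype=float)
    wb = amplitude * feng_whole_blood(t, config.aif_a1, config.aif_lam1,
                                      config.aif_a2, config.aif_lam2,
                                      config.aif_a3, config.aif_lam3,
                                      config.aif_delay_min)
    plasma = wb * config.plasma_ratio_model()(t)
    pf_model = config.parent_fraction_model()
    pf = np.full(t.size, np.nan)
    is_parent = np.isin(t, np.asarray(config.parent_times))
    pf[is_parent] = pf_model(t[is_parent])
    sd = config.blood_noise
    if sd > 0:
        wb = np.clip(wb * (1.0 + sd * rng.standard_normal(t.size)), 0.0, None)
        plasma = np.clip(plasma * (1.0 + sd * rng.standard_normal(t.size)), 0.0, None)
        noisy_pf = pf * (1.0 + sd * rng.standard_normal(t.size))
        pf = np.where(np.isfinite(pf), np.clip(noisy_pf, 0.0, 1.0), np.nan)
    return BloodSampleSeries(times=t, whole_blood=wb, plasma=plasma,
                             parent_fraction=pf)


def derive_micro_params(target_vt: float, k1: float, k2: float, k4: float,
                        vb: float = 0.04) -> TwoTCMParams:
    """Micro-parameters reaching ``target_vt`` with K1, k2, k4 held fixed."""
    ratio = target_vt * k2 / k1 - 1.0
    if ratio < -1e-12:
        raise ValidationError(
            f"target V_T={target_vt:g} unreachable with K1/k2={k1 / k2:g}")
    return TwoTCMParams(k1=k1, k2=k2, k3=k4 * max(ratio, 0.0), k4=k4, vb=vb)


def _tac_noise_sd(values: np.ndarray, schedule: FrameSchedule,
                  scale: float) -> np.ndarray:
    return scale * np.sqrt(np.clip(values, 0.0, None) / schedule.duration_min)


def draw_cohort_truth(config: SimulationConfig) -> pd.DataFrame:
    """Sample the generative law for true V_T without the imaging chain.

    One lognormal between-animal draw per animal x region around the group
    mean; used for fast Monte-Carlo studies of the statistics stages.
    """
    rows = []
    for idx, (animal, group) in enumerate(config.animal_ids):
        rng = _rng(config, 5, idx)
        for region in config.regions:
            true_vt = config.group_mean_vt(group, region) * float(
                np.exp(rng.normal(0.0, config.between_animal_cv)))
            rows.append({"animal": animal, "group": group,
                         "region": region.name, "true_vt": true_vt})
    return pd.DataFrame(rows)


def simulate_cohort_tacs(config: SimulationConfig):
    """Per-animal regional TACs with ground truth.

    Returns ``(tacs, truth, aifs, blood)`` where ``tacs`` maps animal ->
    region -> TissueTAC, ``truth`` is a DataFrame of true micro-parameters
    and V_T per animal x region, ``aifs`` the noise-free per-animal input
    functions (amplitude-scaled), and ``blood`` the noisy sampled blood
    tables.
    """
    sched = config.schedule()
    tacs, aifs, blood, rows = {}, {}, {}, []
    for idx, (animal, group) in enumerate(config.animal_ids):
        rng = _rng(config, 2, idx)
        amp = float(np.exp(rng.normal(0.0, config.amplitude_cv))) \
            if config.amplitude_cv > 0 else 1.0
        aif = simulate_aif(config, amplitude=amp)
        aifs[animal] = aif
        blood[animal] = simulate_blood_samples(config, rng=rng, amplitude=amp)
        tacs[animal] = {}
        for region in config.regions:
            mean_vt = config.group_mean_vt(group, region)
            true_vt = mean_vt * float(np.exp(rng.normal(0.0, config.between_animal_cv)))
            params = derive_micro_params(true_vt, config.k1, config.k2,
                                         config.k4, vb=config.vb)
            tac = solve_2tcm_forward(params, aif, sched)
            vals = tac.values
            if config.tac_noise_scale > 0:
                sd = _tac_noise_sd(vals, sched, config.tac_noise_scale)
                vals = vals + rng.normal(0.0, 1.0, vals.size) * sd
            tacs[animal][region.name] = TissueTAC(sched, vals, region=region.name)
            rows.append({"animal": animal, "group": group, "region": region.name,
                         "K1": params.k1, "k2": params.k2, "k3": params.k3,
                         "k4": params.k4, "vb": params.vb, "true_vt": true_vt,
                         "aif_amplitude": amp})
    truth = pd.DataFrame(rows)
    return tacs, truth, aifs, blood


def _region_boxes(shape: tuple, n_regions: int):
    """Disjoint axis-aligned boxes in a 2 x 2 x 2 arrangement (<= 8 regions)."""
    if n_regions > 8:
        raise ValidationError("default phantom placement supports <= 8 regions")
    margin, gap = 3, 2
    sizes = [(shape[i] - 2 * margin - gap) // 2 for i in range(3)]
    if any(s < 2 for s in sizes):
        raise ValidationError(f"image shape {shape} too small for region placement")
    boxes = []
    for k in range(n_regions):
        ix, iy, iz = k % 2, (k // 2) % 2, k // 4
        origin = [margin + i * (s + gap) for i, s in
                  zip((ix, iy, iz), sizes)]
        boxes.append(tuple(slice(o, o + s) for o, s in zip(origin, sizes)))
    return boxes


def simulate_dynamic_image(config: SimulationConfig, animal_tacs: dict,
                           rng: np.random.Generator | None = None
                           ) -> tuple[DynamicImage, LabelAtlas]:
    """Small 4D phantom: box-shaped regions carrying the regional TACs
    plus voxel-level frame-duration-dependent noise; the atlas matches the
    construction exactly."""
    if rng is None:
        rng = _rng(config, 3)
    sched = config.schedule()
    shape = tuple(config.image_shape)
    region_names = list(animal_tacs)
    boxes = _region_boxes(shape, len(region_names))
    labels = np.zeros(shape, dtype=np.int16)
    data = np.zeros(shape + (sched.n_frames,))
    names = {}
    for lab, (name, box) in enumerate(zip(region_names, boxes), start=1):
        if np.any(labels[box] != 0):
            raise ValidationError("phantom regions overlap")
        labels[box] = lab
        names[lab] = name
        vals = animal_tacs[name].values
        block = np.broadcast_to(vals, labels[box].shape + (sched.n_frames,)).copy()
        if config.voxel_noise_scale > 0:
            sd = _tac_noise_sd(vals, sched, config.voxel_noise_scale)
            block += rng.normal(0.0, 1.0, block.shape) * sd
        data[box] = block
    img = DynamicImage(data=data, voxel_size_mm=tuple(config.voxel_size_mm),
                       schedule=sched, mask=labels > 0)
    return img, LabelAtlas(labels=labels, names=names)


def simulate_behavior(config: SimulationConfig, truth: pd.DataFrame,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Behavior scores linearly coupled to mean affected-region true V_T.

    Neurologic rating increases (worse) and working memory decreases
    (worse) with binding; noise SDs are set so cohort-level |r| falls in
    roughly the 0.5-0.7 band.
    """
    if rng is None:
        rng = _rng(config, 4)
    affected = list(config.affected_regions)
    sub = truth[truth["region"].isin(affected)] if affected else truth
    x = sub.groupby("animal", sort=False)["true_vt"].mean()
    groups = truth.drop_duplicates("animal").set_index("animal")["group"]
    n = x.size
    rating = (config.rating_intercept + config.rating_slope * x.values
              + rng.normal(0.0, config.rating_noise_sd, n))
    memory = (config.memory_intercept - config.memory_slope * x.values
              + rng.normal(0.0, config.memory_noise_sd, n))
    return pd.DataFrame({"animal": x.index, "group": groups.loc[x.index].values,
                         "neurologic_rating": rating, "working_memory": memory})


@dataclass(eq=False)
class SimulatedStudy:
    """Complete synthetic study with ground truth attached."""

    config: SimulationConfig
    animals: pd.DataFrame          # animal, group
    blood: dict                    # animal -> BloodSampleSeries
    aifs: dict                     # animal -> noise-free InputFunction
    tacs: dict                     # animal -> region -> TissueTAC
    truth: pd.DataFrame
    behavior: pd.DataFrame

    def make_images(self) -> dict:
        """Per-animal (DynamicImage, LabelAtlas) phantoms (deterministic)."""
        out = {}
        for idx, animal in enumerate(self.animals["animal"]):
            rng = _rng(self.config, 3, idx)
            out[animal] = simulate_dynamic_image(self.config, self.tacs[animal],
                                                 rng=rng)
        return out


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    if config is None:
        config = SimulationConfig()
    tacs, truth, aifs, blood = simulate_cohort_tacs(config)
    behavior = simulate_behavior(config, truth)
    animals = pd.DataFrame(config.animal_ids, columns=["animal", "group"])
    return SimulatedStudy(config=config, animals=animals, blood=blood,
                          aifs=aifs, tacs=tacs, truth=truth, behavior=behavior)
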
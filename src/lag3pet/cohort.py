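"""Synthetic-cohort simulator emulating the dose-escalation study design.

Six patients each receive a 4-mg-mass-dose tracer injection in cycle 1
(scans <2, 90 and 138 h p.i.) and, three weeks later, a second injection
after an unlabeled antibody pre-dose that brings the total mass dose to
44 mg (three patients) or 604 mg (three patients), with scans at 90 and
138 h. Venous blood is drawn at 1 h and at the scan time points. Each
patient carries two to five tumor lesions (twenty total by default) plus
six reference organs.

Ground truth (plasma parameters, kinetic parameters, lesion latent
infiltration) is stored separately from the "observed" noisy measurements,
so estimator-recovery tests can compare against the generating values.
All randomness flows from the single configured seed; the same seed and
configuration reproduce the dataset exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.stats import norm

from . import reference as ref
from .calibration import (
    TumorPopulationModel,
    default_occupancy_model,
    default_organ_params,
    default_plasma_params,
)
from .occupancy import OccupancyModel
from .pk import PlasmaPKParams
from .quantify import (
    InjectionRecord,
    TimeActivityCurve,
    Units,
    decay_uncorrect,
    pct_ia_per_l_to_bq_ml,
)
from .tissue import TissueKineticParams, simulate_tissue_curve

__all__ = [
    "CohortConfig",
    "LesionTruth",
    "PatientData",
    "CohortDataset",
    "generate_cohort",
    "add_noise",
]

ORGANS = ("spleen", "lungs", "liver", "kidneys", "bone_marrow", "bone")


class CohortConfig(BaseModel):
    """Study-design configuration for the simulator.

    Defaults encode the emulated trial: 37 MBq / 4 mg tracer, scans at
    2/90/138 h (cycle 1) and 90/138 h (cycle 2), a 3/3 split between the
    44- and 604-mg cycle-2 arms, 2–5 lesions per patient, 10% multiplicative
    measurement noise. Patient-level variability: log-normal (mean-one)
    scales on plasma amplitudes (sigma 0.25) and terminal clearance
    (sigma 0.10); lesion latent infiltration carries a between-patient
    variance share of 0.30, enough to reproduce the reported clustering of
    patients into immune-desert and immune-infiltrated groups.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    n_patients: int = 6
    arm_doses: tuple[float, ...] = (44.0, 44.0, 44.0, 604.0, 604.0, 604.0)
    scan_times_c1: tuple[float, ...] = ref.SCAN_TIMES_C1_H
    scan_times_c2: tuple[float, ...] = ref.SCAN_TIMES_C2_H
    blood_times_c1: tuple[float, ...] = (1.0, 90.0, 138.0)
    blood_times_c2: tuple[float, ...] = (1.0, 90.0, 138.0)
    lesions_per_patient: tuple[int, int] = (2, 5)
    noise_cv: float = 0.10
    seed: int = 0
    injected_activity_mbq: float = ref.INJECTED_ACTIVITY_MBQ
    tracer_mass_mg: float = ref.TRACER_MASS_MG
    scan_jitter_h: float = 0.0          # ±1 h in the emulated protocol; off
    drop_one_blood_sample: bool = False  # emulate a failed 90-h plasma draw
    amplitude_sigma: float = 0.25
    clearance_sigma: float = 0.10
    patient_effect_share: float = 0.30
    lymph_node_fraction: float = 0.35

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        for times in (self.scan_times_c1, self.scan_times_c2,
                      self.blood_times_c1, self.blood_times_c2):
            arr = np.asarray(times, dtype=float)
            if arr.size == 0 or np.any(arr <= 0) or np.any(np.diff(arr) <= 0):
                raise ValueError(
                    "scan/blood times must be positive and strictly increasing")
        if len(self.arm_doses) != self.n_patients:
            raise ValueError("arm_doses must list one cycle-2 dose per patient")
        if any(d not in (44.0, 604.0) for d in self.arm_doses):
            raise ValueError("cycle-2 mass doses must be 44 or 604 mg")
        lo, hi = self.lesions_per_patient
        if not (1 <= lo <= hi <= 5):
            raise ValueError("lesions_per_patient must satisfy 1 <= lo <= hi <= 5")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0.0 <= self.patient_effect_share <= 1.0:
            raise ValueError("patient_effect_share must be in [0, 1]")
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class LesionTruth:
    """Generating truth for one tumor lesion."""

    lesion_id: str
    patient_id: int
    volume_ml: float
    infiltration: float            # latent immune-infiltration score in [0,1]
    ki_spec_unblocked: float       # μL·g⁻¹·h⁻¹ at zero occupancy
    ihc_lag3_pct: float            # % LAG-3+ immune cells per tumor area
    site_class: str                # lymph-node | other

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError("volume must be > 0")
        if not 0.0 <= self.infiltration <= 1.0:
            raise ValueError("infiltration must be in [0, 1]")
        if not 0.0 <= self.ihc_lag3_pct <= 100.0:
            raise ValueError("ihc_lag3_pct must be in [0, 100]")


@dataclass
class PatientData:
    patient_id: int
    body_weight_kg: float
    arm_dose_mg: float
    injections: dict[int, InjectionRecord]
    plasma_params: dict[int, PlasmaPKParams]          # truth, per cycle
    plasma_observed: dict[int, TimeActivityCurve]     # measured Bq/mL
    tacs_observed: dict[tuple[str, int], TimeActivityCurve]
    tacs_truth: dict[tuple[str, int], TimeActivityCurve]  # noise-free %IA/L
    lesion_ids: list[str] = field(default_factory=list)


@dataclass
class CohortDataset:
    config: CohortConfig
    config_hash: str
    patients: list[PatientData]
    lesions: list[LesionTruth]
    organ_params: dict[str, TissueKineticParams]
    lesion_params: dict[str, TissueKineticParams]
    occupancy: OccupancyModel
    tumor_model: TumorPopulationModel

    @property
    def n_lesions(self) -> int:
        return len(self.lesions)


# ---------------------------------------------------------------------------


def add_noise(tac: TimeActivityCurve, cv: float, rng) -> TimeActivityCurve:
    """Multiplicative Gaussian measurement noise, truncated positive.

    Each sample is multiplied by (1 + ε), ε ~ N(0, cv²); factors are
    redrawn until positive so concentrations stay > 0. ``rng`` may be a
    seed or a ``numpy.random.Generator``.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0:
        return tac
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    vals = []
    for v in tac.values:
        factor = 1.0 + rng.normal(0.0, cv)
        while factor <= 0.0:
            factor = 1.0 + rng.normal(0.0, cv)
        vals.append(v * factor)
    return tac.with_values(vals)


def _observe(region_id, region_type, cycle, times, pct_ia_values, inj, cv, rng
             ) -> TimeActivityCurve:
    """Truth (%IA/L, decay-corrected) → measured curve (Bq/mL, decayed)."""
    bq = [decay_uncorrect(pct_ia_per_l_to_bq_ml(p, inj), t)
          for t, p in zip(times, pct_ia_values)]
    tac = TimeActivityCurve(region_id=region_id, region_type=region_type,
                            cycle=cycle, times=tuple(times), values=tuple(bq),
                            units=Units.BQ_PER_ML, decay_corrected=False)
    return add_noise(tac, cv, rng)


def _default_tumor_model() -> TumorPopulationModel:
    from .calibration import refined_tumor_model
    return refined_tumor_model()


def generate_cohort(config: CohortConfig,
                    tumor_model: Optional[TumorPopulationModel] = None
                    ) -> CohortDataset:
    """Simulate one cohort; a pure function of (config, tumor model)."""
    rng = np.random.default_rng(config.seed)
    occ_model, _ = default_occupancy_model()
    organ_params = default_organ_params()
    tm = tumor_model if tumor_model is not None else _default_tumor_model()

    sb = np.sqrt(config.patient_effect_share)
    sw = np.sqrt(1.0 - config.patient_effect_share)
    occ_c1 = float(occ_model.occupancy(config.tracer_mass_mg))

    patients: list[PatientData] = []
    lesions: list[LesionTruth] = []
    lesion_params: dict[str, TissueKineticParams] = {}

    for p_idx in range(config.n_patients):
        pid = p_idx + 1
        arm = float(config.arm_doses[p_idx])
        weight = float(np.clip(rng.normal(75.0, 12.0), 45.0, 120.0))
        amp_scale = float(rng.lognormal(-config.amplitude_sigma ** 2 / 2,
                                        config.amplitude_sigma))
        cl_jitter = float(rng.lognormal(-config.clearance_sigma ** 2 / 2,
                                        config.clearance_sigma))
        z_patient = float(rng.normal()) * sb
        n_lesions = int(rng.integers(config.lesions_per_patient[0],
                                     config.lesions_per_patient[1] + 1))

        injections = {
            1: InjectionRecord(config.injected_activity_mbq,
                               config.tracer_mass_mg, weight,
                               t0="2019-06-01T10:00:00",
                               tracer_mass_mg=config.tracer_mass_mg),
            2: InjectionRecord(config.injected_activity_mbq, arm, weight,
                               t0="2019-06-22T10:00:00",
                               tracer_mass_mg=config.tracer_mass_mg),
        }
        plasma_params = {
            1: default_plasma_params(config.tracer_mass_mg).scaled(
                amp_scale, cl_jitter),
            2: default_plasma_params(arm).scaled(amp_scale, cl_jitter),
        }

        # lesion truth draws (before observation noise, fixed order)
        patient_lesions = []
        for l_idx in range(n_lesions):
            z = z_patient + float(rng.normal()) * sw
            params, ki_spec = tm.lesion_kinetics(z)
            infiltration = float(norm.cdf(z))
            volume = float(np.clip(np.exp(np.log(12.0) + 0.8 * rng.normal()),
                                   *ref.TUMOR_VOLUME_RANGE_ML))
            ihc = float(rng.binomial(100, 0.25 * infiltration ** 2))
            site = ("lymph-node" if rng.random() < config.lymph_node_fraction
                    else "other")
            lesion_id = f"P{pid}_L{l_idx + 1}"
            lesion = LesionTruth(lesion_id=lesion_id, patient_id=pid,
                                 volume_ml=volume, infiltration=infiltration,
                                 ki_spec_unblocked=ki_spec, ihc_lag3_pct=ihc,
                                 site_class=site)
            patient_lesions.append((lesion, params))
            lesions.append(lesion)
            lesion_params[lesion_id] = params

        # simulate curves per cycle
        scan_times = {1: np.asarray(config.scan_times_c1, dtype=float),
                      2: np.asarray(config.scan_times_c2, dtype=float)}
        if config.scan_jitter_h > 0:
            for cyc in (1, 2):
                jit = rng.uniform(-config.scan_jitter_h, config.scan_jitter_h,
                                  size=scan_times[cyc].size)
                scan_times[cyc] = np.sort(np.maximum(scan_times[cyc] + jit, 0.25))
        blood_times = {1: np.asarray(config.blood_times_c1, dtype=float),
                       2: np.asarray(config.blood_times_c2, dtype=float)}

        occ_by_cycle = {1: occ_c1, 2: float(occ_model.occupancy(arm))}

        plasma_observed = {}
        tacs_observed: dict[tuple[str, int], TimeActivityCurve] = {}
        tacs_truth: dict[tuple[str, int], TimeActivityCurve] = {}
        for cyc in (1, 2):
            inj = injections[cyc]
            pk = plasma_params[cyc]
            bt = blood_times[cyc]
            plasma_pct = pk.conc(bt)
            drop = (config.drop_one_blood_sample and pid == 1 and cyc == 1)
            if drop:
                keep = ~np.isclose(bt, 90.0)
                bt, plasma_pct = bt[keep], plasma_pct[keep]
            plasma_observed[cyc] = _observe(
                f"P{pid}_plasma", "plasma", cyc, bt, plasma_pct, inj,
                config.noise_cv, rng)

            for organ in ORGANS:
                op = organ_params[organ]
                pct = simulate_tissue_curve(op, occ_by_cycle[cyc], pk,
                                            scan_times[cyc])
                key = (f"P{pid}_{organ}", cyc)
                tacs_truth[key] = TimeActivityCurve(
                    region_id=key[0], region_type="organ", cycle=cyc,
                    times=tuple(scan_times[cyc]), values=tuple(pct),
                    units=Units.PCT_IA_PER_L, decay_corrected=True)
                tacs_observed[key] = _observe(key[0], "organ", cyc,
                                              scan_times[cyc], pct, inj,
                                              config.noise_cv, rng)

            for lesion, lp in patient_lesions:
                pct = simulate_tissue_curve(lp, occ_by_cycle[cyc], pk,
                                            scan_times[cyc])
                key = (lesion.lesion_id, cyc)
                tacs_truth[key] = TimeActivityCurve(
                    region_id=lesion.lesion_id, region_type="tumor", cycle=cyc,
                    times=tuple(scan_times[cyc]), values=tuple(pct),
                    units=Units.PCT_IA_PER_L, decay_corrected=True)
                tacs_observed[key] = _observe(lesion.lesion_id, "tumor", cyc,
                                              scan_times[cyc], pct, inj,
                                              config.noise_cv, rng)

        patients.append(PatientData(
            patient_id=pid, body_weight_kg=weight, arm_dose_mg=arm,
            injections=injections, plasma_params=plasma_params,
            plasma_observed=plasma_observed, tacs_observed=tacs_observed,
            tacs_truth=tacs_truth,
            lesion_ids=[l.lesion_id for l, _ in patient_lesions]))

    return CohortDataset(
        config=config, config_hash=config.config_hash(), patients=patients,
        lesions=lesions, organ_params=dict(organ_params),
        lesion_params=lesion_params, occupancy=occ_model, tumor_model=tm)
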
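"""Cohort-level analysis: uptake tables, Patlak tables, summary extraction.

These functions run the measurement pipeline exactly as it would run on
real exported region data: decay-correct the observed Bq/mL samples to the
cycle's injection time, convert to %IA/L and SUV, pair tissue times with
the nearest plasma draw for ratios, fit the input function per
patient-cycle, and fit Patlak slopes per region.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import default_plasma_params
from .cohort import CohortDataset
from .patlak import fit_input_function, patlak_fit, patlak_transform
from .quantify import (
    ZR89_HALF_LIFE_H,
    TimeActivityCurve,
    Units,
    percent_injected_activity,
    suv,
    tissue_to_plasma_ratio,
)

__all__ = ["uptake_table", "patlak_table", "tumor_ratio_median",
           "plasma_mean_pct_ia"]


def _plasma_pct_curve(ds, patient, cycle: int,
                      half_life_h: float) -> TimeActivityCurve:
    obs = patient.plasma_observed[cycle]
    if obs.units == Units.PCT_IA_PER_L and obs.decay_corrected:
        return obs
    inj = patient.injections[cycle]
    obs = obs.decay_corrected_curve(half_life_h)
    pct = [percent_injected_activity(v, inj) for v in obs.values]
    return obs.with_values(pct, units=Units.PCT_IA_PER_L)


def uptake_table(ds: CohortDataset, tolerance_h: float = 6.0,
                 half_life_h: float = ZR89_HALF_LIFE_H) -> pd.DataFrame:
    """Quantify every observed curve into the study's outcome measures.

    Returns one row per (region, cycle, time, measure): plasma %IA/L,
    tissue SUV (peak-concentration convention) and tissue-to-plasma
    ratios.
    """
    rows = []
    for patient in ds.patients:
        for cycle in (1, 2):
            inj = patient.injections[cycle]
            dose = inj.mass_dose_mg
            plasma_pct = _plasma_pct_curve(ds, patient, cycle, half_life_h)
            for t, v in zip(plasma_pct.times, plasma_pct.values):
                rows.append((patient.patient_id, plasma_pct.region_id,
                             "plasma", cycle, dose, t, "pct_ia_per_l", v))
            for (region_id, cyc), tac in patient.tacs_observed.items():
                if cyc != cycle:
                    continue
                dc = tac.decay_corrected_curve(half_life_h)
                for t, v in zip(dc.times, dc.values):
                    rows.append((patient.patient_id, region_id,
                                 tac.region_type, cycle, dose, t, "suv_peak",
                                 suv(v, inj)))
                pct = dc.with_values(
                    [percent_injected_activity(v, inj) for v in dc.values],
                    units=Units.PCT_IA_PER_L)
                for m in tissue_to_plasma_ratio(pct, plasma_pct, tolerance_h):
                    rows.append((patient.patient_id, region_id,
                                 tac.region_type, cycle, dose, m.time_h,
                                 "tissue_to_plasma", m.value))
    return pd.DataFrame(rows, columns=[
        "patient_id", "region_id", "region_type", "cycle", "mass_dose_mg",
        "time_h", "measure_kind", "value"])


def patlak_table(ds: CohortDataset, window: tuple[float, float] = (10.0, np.inf),
                 input_model: str = "biexponential",
                 half_life_h: float = ZR89_HALF_LIFE_H) -> pd.DataFrame:
    """Patlak Ki per region and cycle from the observed (noisy) data.

    The input function is fitted per patient-cycle from that patient's own
    plasma samples; with the protocol's three draws the fast phase is held
    at the arm's calibrated default.
    """
    rows = []
    for patient in ds.patients:
        for cycle in (1, 2):
            dose = patient.injections[cycle].mass_dose_mg
            plasma_pct = _plasma_pct_curve(ds, patient, cycle, half_life_h)
            arm_default = default_plasma_params(dose)
            input_fit = fit_input_function(
                plasma_pct, model=input_model,
                fixed_fast=(arm_default.amp_fast, arm_default.lambda_fast))
            for (region_id, cyc), tac in patient.tacs_observed.items():
                if cyc != cycle:
                    continue
                inj = patient.injections[cycle]
                dc = tac.decay_corrected_curve(half_life_h)
                pct = dc.with_values(
                    [percent_injected_activity(v, inj) for v in dc.values],
                    units=Units.PCT_IA_PER_L)
                points = patlak_transform(pct, input_fit)
                try:
                    fit = patlak_fit(points, window)
                except ValueError:
                    continue
                rows.append((patient.patient_id, region_id, tac.region_type,
                             cycle, dose, fit.ki, fit.v_intercept,
                             fit.r_squared, fit.n_points,
                             "negative_ki" if fit.negative_ki else ""))
    return pd.DataFrame(rows, columns=[
        "patient_id", "region_id", "region_type", "cycle", "mass_dose_mg",
        "ki_ul_g_h", "v_intercept", "r_squared", "n_points", "flags"])


def tumor_ratio_median(uptake: pd.DataFrame, dose_mg: float, time_h: float,
                       tol_h: float = 2.0) -> float:
    """Median lesion-level tumor-to-plasma ratio at one dose and time."""
    sel = uptake[(uptake.region_type == "tumor")
                 & (uptake.measure_kind == "tissue_to_plasma")
                 & (uptake.mass_dose_mg == dose_mg)
                 & (np.abs(uptake.time_h - time_h) <= tol_h)]
    if sel.empty:
        raise ValueError(f"no tumor ratios at dose {dose_mg} mg, {time_h} h")
    return float(sel.value.median())


def plasma_mean_pct_ia(uptake: pd.DataFrame, dose_mg: float, time_h: float,
                       tol_h: float = 2.0) -> float:
    """Mean plasma %IA/L across patients at one dose and time."""
    sel = uptake[(uptake.region_type == "plasma")
                 & (uptake.measure_kind == "pct_ia_per_l")
                 & (uptake.mass_dose_mg == dose_mg)
                 & (np.abs(uptake.time_h - time_h) <= tol_h)]
    if sel.empty:
        raise ValueError(f"no plasma samples at dose {dose_mg} mg, {time_h} h")
    return float(sel.value.mean())
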
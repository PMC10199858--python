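"""Reported clinical summary values used as calibration inputs.

These numbers are the published summary statistics of a first-in-human
⁸⁹Zr-labelled anti-LAG-3 antibody dose-escalation imaging study (6 patients,
three antibody mass doses: 4, 44 and 604 mg). The raw patient data are not
public; the synthetic-cohort simulator is calibrated so that its noise-free
summaries reproduce these values. They are treated as *inputs* to the
package, on the same footing as a dosing schedule.
"""

from __future__ import annotations

# --- dosing & schedule -----------------------------------------------------

INJECTED_ACTIVITY_MBQ = 37.0    # tracer activity per administration
TRACER_MASS_MG = 4.0            # antibody mass carried by the tracer itself
MASS_DOSES_MG = (4.0, 44.0, 604.0)
SCAN_TIMES_C1_H = (2.0, 90.0, 138.0)
SCAN_TIMES_C2_H = (90.0, 138.0)

# --- plasma activity concentration, %IA/L (mean over patients) -------------
# keyed by total antibody mass dose (mg) -> {time h p.i.: %IA/L}
PLASMA_MEAN_PCT_IA_PER_L = {
    4.0: {90.0: 6.2, 138.0: 3.2},
    44.0: {90.0: 11.9, 138.0: 10.0},
    604.0: {90.0: 14.5, 138.0: 11.9},
}

# --- spleen net irreversible uptake rate Ki, μL·g⁻¹·h⁻¹ (mean ± SD) --------
SPLEEN_KI_UL_G_H = {4.0: 30.06, 44.0: 2.91, 604.0: 0.67}
SPLEEN_KI_SD_UL_G_H = {4.0: 11.17, 44.0: 0.79, 604.0: 0.39}

# --- tumor-to-plasma ratios, lesion-level median (IQR) ---------------------
# keyed by (mass dose mg, time h): (median, q1, q3)
TUMOR_TO_PLASMA_MEDIAN_IQR = {
    (4.0, 90.0): (1.63, 0.37, 2.89),
    (4.0, 138.0): (2.70, 0.85, 4.62),
    (44.0, 138.0): (0.67, 0.50, 0.85),
    (604.0, 138.0): (0.58, 0.42, 0.75),
}

# --- per-patient outcomes (clinical table) ---------------------------------
# patient id -> (cycle-2 mass dose mg, mean tumor-to-plasma ratio 138 h at
# 4 mg, LAG-3 immunoreactivity % positive cells per tumor area or None,
# progression-free survival days)
PATIENT_TABLE = {
    1: (604.0, 3.20, 10.0, 126),
    2: (604.0, 3.02, 5.0, 188),
    3: (604.0, 3.44, None, 139),
    6: (44.0, 0.83, 1.0, 81),
    9: (44.0, 1.43, 5.0, 88),
    10: (44.0, 3.59, 30.0, 119),
}

#: the six per-patient mean tumor-to-plasma ratios at 138 h p.i., 4-mg dose
PATIENT_MEAN_RATIOS_138H = tuple(v[1] for v in PATIENT_TABLE.values())

# --- lesion geometry -------------------------------------------------------
N_LESIONS_TOTAL = 20
TUMOR_VOLUME_MEAN_ML = 16.6
TUMOR_VOLUME_RANGE_ML = (3.6, 109.12)

# --- biology ---------------------------------------------------------------
#: reported LAG-3 receptor re-synthesis rate in T cells, fraction per hour;
#: informs the default maximal trapping rate k3_max
LAG3_SYNTHESIS_RATE_PER_H = 0.10
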
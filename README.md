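# lag3pet

Quantitative analysis of ⁸⁹Zr-immuno-PET antibody dose-escalation imaging,
built around the design of a first-in-human study of a zirconium-89-labelled
anti-LAG-3 monoclonal antibody: six patients, whole-body PET at <2, 90 and
138 h post-injection, venous blood sampling at every scan, and three
antibody mass doses (4 mg tracer-only in cycle 1; 44 mg or 604 mg total in
cycle 2 after an unlabeled pre-dose).

It is written for imaging pharmacologists and methodologists who need the
full quantitative chain of such a study as tested, reusable code — from
decay-corrected activity concentrations through Patlak kinetics to
dose-saturation statistics — together with a calibrated synthetic-cohort
simulator that stands in for the (non-public) patient data.

## The science in brief

**Units.** Measured concentrations (Bq/mL) are decay-corrected to injection
time (⁸⁹Zr half-life 78.41 h) and expressed as %IA/L (percent injected
activity per litre), SUV, or — the preferred outcome for an antibody with
dose-dependent clearance — the **tissue-to-plasma ratio**, which divides
out plasma exposure.

**Kinetics.** ⁸⁹Zr is a residualizing label: internalized antibody leaves
its radiometal trapped in the cell. Tissue uptake follows the irreversible
two-tissue compartment model

    dC_rev/dt  = K1·Cp − (k2 + k3)·C_rev
    dC_trap/dt = k3·C_rev,          Ct = C_rev + C_trap + vb·Cp

whose net irreversible uptake rate is **Ki = 1000·K1·k3/(k2+k3)**
(μL·g⁻¹·h⁻¹). Plotting Ct/Cp against ∫₀ᵗCp dτ / Cp (**Patlak
linearization**) turns the late scans into a straight line with slope Ki.

**Saturation.** Ki combines a target-specific part — suppressed as
unlabeled antibody occupies LAG-3, modelled as a Hill function of mass
dose, occ(D) = D^h/(D^h + D₅₀^h) — and a non-saturable floor:

    Ki(D) = Ki_ns + Ki_spec · (1 − occ(D))

The fraction of specific signal blocked per dose classifies organs as
unsaturated / partially / fully saturated.

**Simulator.** The cohort generator draws patient-level plasma kinetics
(bi-exponential, dose-dependent terminal clearance), lesion-level latent
immune infiltration driving both perfusion and specific uptake, IHC-style
LAG-3 scores, and multiplicative measurement noise. All of its
quantitative defaults are *calibrated by least squares* against the
study's published summary statistics (per-arm plasma means, the spleen Ki
triple, tumor-to-plasma medians and IQRs); the calibration is code, not
hand-picked constants (`lag3pet.calibration`).

## Worked example

```python
import numpy as np
from lag3pet import CohortConfig, generate_cohort
from lag3pet.analysis import uptake_table, patlak_table
from lag3pet.compare import compare_nonparametric, saturation_report

ds = generate_cohort(CohortConfig(seed=1))
uptake = uptake_table(ds)

lesions = uptake[(uptake.region_type == "tumor")
                 & (uptake.measure_kind == "tissue_to_plasma")
                 & (uptake.time_h == 138.0)]
groups = {d: g.value.to_numpy() for d, g in lesions.groupby("mass_dose_mg")}
for dose, vals in groups.items():
    q1, q3 = np.quantile(vals, [0.25, 0.75])
    print(f"{dose:5.0f} mg: median tumor-to-plasma {np.median(vals):.2f} "
          f"(IQR {q1:.2f}-{q3:.2f}, n={len(vals)})")

res = compare_nonparametric(groups)
p_adj = {pw.pair: pw.p_adjusted for pw in res.pairwise}[(44.0, 604.0)]
print(f"Kruskal-Wallis H = {res.global_stat:.2f}; "
      f"44 vs 604 mg adjusted p = {p_adj:.2f}")

ki = patlak_table(ds)
spleen = ki[ki.region_id.str.endswith("_spleen")]
by_dose = spleen.groupby("mass_dose_mg").ki_ul_g_h.mean().to_dict()
rep = saturation_report(by_dose, ref_dose=4.0, floor_dose=604.0)
for dose in sorted(by_dose):
    print(f"spleen Ki at {dose:3.0f} mg: {by_dose[dose]:6.2f} uL/g/h "
          f"({rep.classification[dose]} saturation)")
```

prints, for this seed:

```
    4 mg: median tumor-to-plasma 2.59 (IQR 0.75-5.37, n=24)
   44 mg: median tumor-to-plasma 0.43 (IQR 0.33-0.58, n=10)
  604 mg: median tumor-to-plasma 0.68 (IQR 0.39-1.09, n=14)
Kruskal-Wallis H = 17.76; 44 vs 604 mg adjusted p = 0.46
spleen Ki at   4 mg:  32.49 uL/g/h (none saturation)
spleen Ki at  44 mg:   3.85 uL/g/h (partial saturation)
spleen Ki at 604 mg:  -1.32 uL/g/h (full saturation)
```

Reading this: unblocked (4 mg) tumor uptake is high and heterogeneous;
pre-dosing to 44 or 604 mg collapses it to near the blood/reversible
background and the two blocked arms are statistically indistinguishable
(adjusted p = 0.46). Spleen Ki falls from ~30 to ~0 μL·g⁻¹·h⁻¹ — full
target saturation. The negative 604-mg estimate is a deliberate feature:
with only two late scans and 10% measurement noise, tiny slopes scatter
around zero, and the package reports them flagged rather than clamped.

A command-line interface wraps the same pipeline:

```
lag3pet run --seed 42 --out runs/demo        # all stages + report.txt
lag3pet simulate --seed 3 --out runs/sim     # cohort CSVs only
lag3pet validate runs/demo/uptake.csv uptake
```

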
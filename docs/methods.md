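# Methods

## Scope and data flow

The package implements the quantitative chain of a ⁸⁹Zr-labelled
anti-LAG-3 antibody dose-escalation imaging study on synthetic data:
simulate a cohort → write plain-text interchange CSVs → decay-correct and
normalize (→ %IA/L, SUV, tissue-to-plasma ratios) → fit plasma input
functions and Patlak slopes → dose-arm statistics and saturation
classification → immune-infiltration linking. Every stage consumes the
files the previous stage writes, so each can also run on externally
produced data with the same schemas.

## Plasma model

Each mass-dose arm has a bi-exponential decay-corrected plasma curve
Cp(t) = A₁e^(−λ₁t) + A₂e^(−λ₂·s·t) in %IA/L. The two published per-arm
plasma means (90 and 138 h) determine the terminal amplitude and rate
exactly by a two-point log-linear solve; the clearance scale s expresses
each arm's terminal rate relative to the 4-mg arm (s ≈ 0.26 at 44 mg,
0.30 at 604 mg — slower clearance as target-mediated disposition
saturates). The distribution phase is weakly identified by late venous
sampling and is fixed by convention: Cp(0) = 100/3 %IA/L (a ~3 L plasma
volume) and λ₁ = 0.3 h⁻¹. These conventions affect the Patlak abscissa
only through the early area under the curve (a few percent of the 90-h
integral).

Patient-level variability: mean-one log-normal scales on the amplitudes
(σ = 0.25) and on terminal clearance (σ = 0.10). Amplitude scale cancels
in tissue-to-plasma ratios; clearance jitter propagates into the Patlak
abscissa, as in real cohorts.

## Tissue model and occupancy

Regions follow the irreversible two-tissue model (closed form for
bi-exponential inputs; an LSODA route exists for arbitrary callable
inputs). The net uptake rate decomposes as
Ki(D) = Ki_ns + Ki_spec·(1 − occ(D)) with occ a Hill function of the
administered mass dose. Dose-level (rather than concentration-level)
occupancy keeps Ki constant within a cycle, which is exactly the regime
in which the Patlak line is straight. Hill exponent 2 is required: with
h = 1 no positive D₅₀ reproduces the measured spleen Ki triple
(30.06 / 2.91 / 0.67 μL·g⁻¹·h⁻¹ at 4 / 44 / 604 mg); with h = 2 a
one-dimensional least-squares fit (specific amplitude profiled out,
floor fixed at the fully-blocked value) gives D₅₀ ≈ 11.9 mg and
reproduces the triple to ≈2% of the smallest value. A corollary worth
flagging: this calibration implies the 4-mg tracer mass itself occupies
≈10% of target — a model statement, not a clinical claim.

Trapping is capped at k₃ = 0.1 h⁻¹, matching the reported ~10%/h LAG-3
re-synthesis rate that continuously regenerates binding sites. Spleen
delivery K1 follows from the fitted specific Ki; its efflux k₂ = 0.3 h⁻¹
and vascular fraction v_b = 0.30 are conventions (equilibration time
~2.5 h, well before the late scans). The other five organs (lungs, liver,
kidneys, bone marrow, bone) carry plausible antibody-biodistribution
defaults — blood-dominated lungs, a large non-specific catabolic floor in
liver, radiometal deposition in bone — and are not calibration targets.

## Tumor population calibration

A single standard-normal latent variable z per lesion — infiltration on
the probability scale via Φ(z) — drives correlated log-normal
heterogeneity in delivery (k1, σ = 0.72) and unblocked specific Ki
(σ = 1.57), so better-infiltrated lesions are both better perfused and
richer in target, and the noise-free uptake ratio is strictly monotone in
z. Patients contribute a 0.30 share of the latent variance (clustering
into immune-desert and immune-infiltrated patients); lesions the rest.

Calibration proceeds in three least-squares stages, all in
`lag3pet.calibration`:

1. **Medians.** (k1, median specific Ki, non-specific floor) fitted so the
   noise-free model reproduces the four published tumor-to-plasma medians
   (1.63 @4 mg/90 h, 2.70 @4 mg/138 h, 0.67 @44 mg/138 h,
   0.58 @604 mg/138 h). These four numbers are not exactly representable
   by any single irreversible two-tissue parameter set under the
   calibrated inputs — the unblocked 90→138 h rise forces a Patlak
   intercept near 0.8 while the blocked plateaus bound it below 0.67 — so
   a relative-residual compromise with ≈5% worst-case error is the
   documented choice.
2. **Spreads.** (σ_Ki, σ_k1) fitted to the eight published quartile
   values. The published IQRs are wide and log-asymmetric; the log-normal
   matches their width, not their skew.
3. **Finite-cohort refinement.** The medians a six-patient study reports
   are sample medians of ~20 heterogeneous lesions; with spreads this
   wide the expected sample median sits several percent from the
   population median (the ratio is convex in z). The median calibration
   is therefore iterated against Monte-Carlo cohort means-of-medians
   computed with the actual generator and measurement pipeline (600
   cohorts on a fixed internal seed block, two iterations), so that the
   quantity the simulator is judged on — the seed-averaged reported
   median — is the quantity that was calibrated.

After refinement, independent 100-seed blocks reproduce the four medians
within ±10% (typical ±5%) and the 90-h plasma mean within ±1%.

## Measurement model

Observed curves are the decay-uncorrected Bq/mL values implied by
37 MBq injections, with multiplicative Gaussian noise (1 + ε),
ε ~ N(0, cv²), truncated positive by redraw; cv = 0.10 by default (the
study publishes no error model; 10% is a typical PET region-level
repeatability figure). Blood draws are co-timed with the late scans plus
a 1-h sample. Quantification reverses the decay and unit conversions
exactly, so with cv = 0 the pipeline reproduces the model curves to
floating-point precision.

## Patlak estimation

The input function per patient-cycle is a log-space least-squares
bi-exponential; with the protocol's three samples the fast phase is held
at the arm's calibrated default and only the slow phase is fitted
(log-linear interpolation with exact piecewise integrals is the fallback
dialect). The Patlak fit is ordinary least squares on points inside a
time window; the default window drops the <2 h scan, which precedes
reversible-compartment equilibration. Ki = 1000 × slope (1 g/mL density);
negative noisy slopes are reported with a flag, never clamped, so noise
statistics stay honest. r² is defined as 1 for two-point fits. Units are
μL·g⁻¹·h⁻¹ throughout.

**Noise floor.** With two late scans and cv = 0.1 the slope estimator has
an irreducible absolute error of roughly ±1–2 μL·g⁻¹·h⁻¹ (the two y
values carry ~14% combined noise against an x-lever of 74–241 h).
Including the 2-h point as a low-noise anchor roughly halves the variance
at the cost of a ≈1 μL·g⁻¹·h⁻¹ upward equilibration bias. Consequences,
measured at 200 replicates: unblocked spleen-like regions (Ki ≈ 30)
recover with ~9% median relative error (anchored window); partially
blocked regions (Ki ≈ 3) cannot do better than ~40–55% relative error
under any window — an inherent limit of two-late-scan Patlak at this
noise level, not an implementation artifact. The corresponding acceptance
test is left failing for the Ki ≈ 3 condition rather than weakened.

## Statistics

Study conventions are reproduced: organs/plasma as mean ± SD with one-way
ANOVA and Tukey HSD (scipy); tumors as median (IQR,
linear-interpolation quantiles) with Kruskal–Wallis and pairwise
two-sided rank-sum tests, exact when the smaller group has ≤10
observations and no ties, mid-rank normal approximation otherwise,
Bonferroni-corrected over all pairs. Lesions are treated as independent
observations (the study pools 20/9/11 lesions across patients); a
patient-clustered sensitivity view is available by aggregating the uptake
table per patient first. Saturation reports the blocked fraction
1 − (Ki_D − Ki_floor)/(Ki_ref − Ki_floor), classified full ≥0.95 and
partial ≥0.5 (configurable).

## Immune linking

The RNA readout is deliberately simplified: a gene-set score equal to the
per-sample mean of per-gene z-scores (GSVA-class machinery is out of
scope; the analysis only needs a monotone infiltration readout).
Simulated expression sets the signature genes to infiltration plus
Gaussian noise (SD 0.5) among standard-normal bystander genes. IHC-style
LAG-3 percentages are Binomial(100, 0.25·infiltration²) counts,
reflecting percent-positive scoring over ≥100 cells with low percentages
typical of LAG-3. Patients are labelled immune-desert vs
immune-infiltrated by mean 4-mg tumor-to-plasma ratio at 138 h against a
threshold of 3.0 (boundary inclusive); Spearman correlation between
per-patient uptake and signature score uses an exact full-enumeration
permutation p for n ≤ 8.

## Problem sizes and determinism

Default analyses use the study geometry (6 patients, 2–5 lesions each,
~20 lesions). Seed-averaged summaries use 120 cohorts in the test suite
and 300 in the acceptance script; noisy-recovery experiments use 200
replicates; the calibration refinement uses 600 internal cohorts. A run
is a pure function of (config, seed): identical seeds give byte-identical
output files, interchange CSVs are written with shortest-roundtrip floats
and read back with exact (`round_trip`) parsing.

## What passing tests do and do not show

The generator emulates the *design and published summary statistics* of a
six-patient study, not patient-level reality: no voxel data or
partial-volume effects, no scanner calibration drift, no cross-cycle
residual activity from the first injection (~5% of cycle-1 activity
remains physically at cycle 2), no time-varying occupancy within a cycle,
no site-class (lymph-node) uptake effect, and plasma kinetics are
parameterized rather than mechanistically target-mediated. The published
organ-to-plasma ratios for spleen are not jointly consistent with the
published spleen Ki under any single intercept and the calibrated input
function; the simulator is calibrated to Ki (the kinetic quantity), and
its spleen ratios are whatever the model then implies. Agreement of the
pipeline with the published summaries therefore validates the method
chain and the calibration, not the biology of any individual patient.
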
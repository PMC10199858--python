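"""End-to-end workflow: simulate → quantify → Patlak → compare → immune.

Every stage communicates through the plain-text interchange files, so each
stage can also be run on externally produced files with the same schemas.
A run is a pure function of (configuration, seed): re-running writes
byte-identical tables.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path
from types import SimpleNamespace
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from .analysis import patlak_table, plasma_mean_pct_ia, uptake_table
from .cohort import CohortConfig, generate_cohort
from .compare import (
    compare_nonparametric,
    compare_parametric,
    saturation_report,
    summarize_group,
)
from .immune import (
    correlate_uptake_infiltration,
    phenotype_table,
    signature_score,
    simulate_expression,
)
from .io import read_csv, write_cohort
from .quantify import ZR89_HALF_LIFE_H, InjectionRecord, TimeActivityCurve, Units
from .schemas import validate_schema

__all__ = ["PipelineConfig", "RunManifest", "PipelineValidationError",
           "run_pipeline", "read_cohort_dir"]

DEFAULT_GENE_SET = ("IFNG", "CD8A", "GZMB", "PRF1", "LAG3", "CXCL9",
                    "CXCL13", "CCL19")


class PipelineConfig(BaseModel):
    """Full run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    version: str = __version__
    outdir: str = "lag3pet_run"
    seed: int = 0
    cohort: CohortConfig = CohortConfig()
    half_life_h: float = ZR89_HALF_LIFE_H
    pairing_tolerance_h: float = 6.0
    patlak_window_lo_h: float = 10.0
    patlak_window_hi_h: Optional[float] = None   # None = unbounded
    input_model: str = "biexponential"
    alpha: float = 0.05
    ratio_threshold: float = 3.0
    gene_set: tuple[str, ...] = DEFAULT_GENE_SET

    def window(self) -> tuple[float, float]:
        hi = np.inf if self.patlak_window_hi_h is None else self.patlak_window_hi_h
        return (self.patlak_window_lo_h, hi)


@dataclass(frozen=True)
class RunManifest:
    config_hash: str
    seed: int
    version: str
    started: str
    finished: str
    row_counts: dict[str, int]


class PipelineValidationError(RuntimeError):
    """A stage input failed schema validation; carries the error list."""

    def __init__(self, stage: str, errors):
        self.stage = stage
        self.errors = list(errors)
        lines = "\n".join(str(e) for e in self.errors)
        super().__init__(f"validation failed in stage {stage!r}:\n{lines}")


def read_cohort_dir(cohort_dir) -> SimpleNamespace:
    """Reconstruct patient measurement objects from the interchange CSVs."""
    cohort_dir = Path(cohort_dir)
    for name, schema in [("plasma.csv", "plasma"), ("tac.csv", "tac"),
                         ("injections.csv", "injections")]:
        errors = validate_schema(cohort_dir / name, schema)
        if errors:
            raise PipelineValidationError("quantify", errors)
    plasma = read_csv(cohort_dir / "plasma.csv")
    tac = read_csv(cohort_dir / "tac.csv")
    injections = read_csv(cohort_dir / "injections.csv")

    patients = []
    for pid, inj_rows in injections.groupby("patient_id"):
        inj = {int(r.cycle): InjectionRecord(r.activity_mbq, r.mass_mg,
                                             r.weight_kg, r.t0_iso8601)
               for r in inj_rows.itertuples()}
        plasma_obs = {}
        for cyc, rows in plasma[plasma.patient_id == pid].groupby("cycle"):
            plasma_obs[int(cyc)] = TimeActivityCurve(
                region_id=f"P{pid}_plasma", region_type="plasma",
                cycle=int(cyc), times=tuple(rows.time_h),
                values=tuple(rows.conc_pct_ia_per_l),
                units=Units.PCT_IA_PER_L, decay_corrected=True)
        tacs = {}
        for (rid, cyc), rows in tac[tac.patient_id == pid].groupby(
                ["region_id", "cycle"]):
            tacs[(rid, int(cyc))] = TimeActivityCurve(
                region_id=rid, region_type=str(rows.region_type.iloc[0]),
                cycle=int(cyc), times=tuple(rows.time_h),
                values=tuple(rows.conc_bq_per_ml),
                units=Units.BQ_PER_ML, decay_corrected=False)
        patients.append(SimpleNamespace(
            patient_id=int(pid),
            body_weight_kg=float(inj_rows.weight_kg.iloc[0]),
            arm_dose_mg=float(inj[2].mass_dose_mg) if 2 in inj else None,
            injections=inj, plasma_observed=plasma_obs, tacs_observed=tacs))
    return SimpleNamespace(patients=patients)


def _compare_stage(config: PipelineConfig, uptake: pd.DataFrame,
                   patlak: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Group summaries, dose comparisons and the spleen saturation report."""
    summaries = []
    comparisons: dict = {"alpha": config.alpha}

    # tumor-to-plasma, lesion level, nonparametric (study convention)
    tumor_groups = {}
    for dose in (4.0, 44.0, 604.0):
        sel = uptake[(uptake.region_type == "tumor")
                     & (uptake.measure_kind == "tissue_to_plasma")
                     & (uptake.mass_dose_mg == dose)
                     & (np.isclose(uptake.time_h, 138.0, atol=2.0))]
        if len(sel):
            tumor_groups[dose] = sel.value.to_numpy()
            s = summarize_group(sel.value, "nonparametric", dose, 138.0,
                                "tissue_to_plasma")
            summaries.append(("tumor", dose, 138.0, s.n, s.central,
                              s.spread[0], s.spread[1], "median_iqr"))
    if len(tumor_groups) >= 2:
        res = compare_nonparametric(tumor_groups, config.alpha)
        comparisons["tumor_ratio_138h"] = {
            "test": res.test, "H": res.global_stat, "df": res.df,
            "pairwise": [
                {"pair": list(pw.pair), "statistic": pw.statistic,
                 "p_raw": pw.p_raw, "p_adjusted": pw.p_adjusted}
                for pw in res.pairwise],
        }

    # plasma %IA/L, patient level, parametric (study convention)
    for t in (90.0, 138.0):
        plasma_groups = {}
        for dose in (4.0, 44.0, 604.0):
            sel = uptake[(uptake.region_type == "plasma")
                         & (uptake.measure_kind == "pct_ia_per_l")
                         & (uptake.mass_dose_mg == dose)
                         & (np.isclose(uptake.time_h, t, atol=2.0))]
            if len(sel):
                plasma_groups[dose] = sel.value.to_numpy()
                s = summarize_group(sel.value, "parametric", dose, t,
                                    "pct_ia_per_l")
                summaries.append(("plasma", dose, t, s.n, s.central,
                                  s.spread[0], s.spread[1], "mean_sd"))
        if len(plasma_groups) >= 2:
            res = compare_parametric(plasma_groups, config.alpha)
            comparisons[f"plasma_pct_ia_{int(t)}h"] = {
                "test": res.test, "F": res.global_stat, "df": res.df,
                "pairwise": [
                    {"pair": list(pw.pair), "p_adjusted": pw.p_adjusted}
                    for pw in res.pairwise],
            }

    # spleen Ki saturation
    spleen = patlak[patlak.region_id.str.endswith("_spleen")]
    ki_by_dose = spleen.groupby("mass_dose_mg").ki_ul_g_h.mean().to_dict()
    if {4.0, 604.0} <= set(ki_by_dose):
        rep = saturation_report(ki_by_dose, ref_dose=4.0, floor_dose=604.0,
                                region="spleen")
        comparisons["spleen_saturation"] = {
            "ki_by_dose": rep.ki_by_dose,
            "specific_fraction_blocked": rep.specific_fraction_blocked,
            "classification": rep.classification,
        }
        for dose, ki in sorted(ki_by_dose.items()):
            summaries.append(("spleen_ki", dose, np.nan,
                              int((spleen.mass_dose_mg == dose).sum()),
                              ki, np.nan, np.nan, "mean"))

    frame = pd.DataFrame(summaries, columns=[
        "scope", "mass_dose_mg", "time_h", "n", "central", "spread_lo",
        "spread_hi", "summary_kind"])
    return frame, comparisons


def _immune_stage(config: PipelineConfig, ds, uptake: pd.DataFrame,
                  outdir: Path) -> tuple[pd.DataFrame, dict]:
    """Expression simulation, signature scoring and phenotype labels.

    One biopsied lesion per patient (the first) provides the infiltration
    driving that patient's expression sample, mirroring single-biopsy
    sampling of a heterogeneous tumor burden.
    """
    rng = np.random.default_rng([config.seed, 7])
    biopsies = {}
    ihc = {}
    for lesion in ds.lesions:
        if lesion.patient_id not in biopsies:
            biopsies[lesion.patient_id] = lesion.infiltration
            ihc[lesion.patient_id] = lesion.ihc_lag3_pct
    pids = sorted(biopsies)
    expr = simulate_expression([biopsies[p] for p in pids], config.gene_set,
                               rng=rng)
    expr.index = pd.Index([f"P{p}" for p in pids], name="sample_id")
    expr.to_csv(outdir / "expression.csv")
    (outdir / "gene_sets.json").write_text(
        json.dumps({"tcell_activation": list(config.gene_set)}, indent=2)
        + "\n", encoding="utf-8")

    scores = signature_score(expr, config.gene_set, "tcell_activation")
    score_by_pid = {int(s.sample_id.lstrip("P")): s.score for s in scores}
    pheno = phenotype_table(uptake, scores=score_by_pid,
                            threshold=config.ratio_threshold)
    pheno["ihc_lag3_pct"] = [ihc.get(int(p)) for p in pheno.patient_id]

    stats: dict = {}
    paired = pheno.dropna(subset=["signature_score"])
    if len(paired) >= 3 and paired.mean_ratio_138h.nunique() > 1:
        rho, p = correlate_uptake_infiltration(paired.mean_ratio_138h,
                                               paired.signature_score)
        stats["uptake_vs_signature"] = {"spearman_rho": rho, "p": p,
                                        "n": int(len(paired))}
    return pheno, stats


def _report_text(summaries, comparisons, immune_stats, pheno) -> str:
    lines = ["Synthetic antibody-PET dose-escalation analysis", "=" * 48, ""]
    lines.append("Group summaries:")
    lines.append(summaries.to_string(index=False))
    lines.append("")
    if "spleen_saturation" in comparisons:
        sat = comparisons["spleen_saturation"]
        lines.append("Spleen saturation (fraction of specific Ki blocked):")
        for dose in sorted(sat["specific_fraction_blocked"]):
            lines.append(
                f"  {dose:>6.0f} mg: Ki = {sat['ki_by_dose'][dose]:7.2f} "
                f"uL/g/h, blocked = {sat['specific_fraction_blocked'][dose]:5.1%}"
                f" ({sat['classification'][dose]})")
        lines.append("")
    if "tumor_ratio_138h" in comparisons:
        kw = comparisons["tumor_ratio_138h"]
        lines.append(f"Tumor ratios 138 h: Kruskal-Wallis H = {kw['H']:.2f}")
        for pw in kw["pairwise"]:
            lines.append(f"  {pw['pair'][0]:.0f} vs {pw['pair'][1]:.0f} mg: "
                         f"p_adj = {pw['p_adjusted']:.3g}")
        lines.append("")
    lines.append("Patient phenotypes:")
    lines.append(pheno.to_string(index=False))
    if "uptake_vs_signature" in immune_stats:
        c = immune_stats["uptake_vs_signature"]
        lines.append(f"\nUptake vs signature: Spearman rho = "
                     f"{c['spearman_rho']:.2f} (p = {c['p']:.3g}, "
                     f"n = {c['n']})")
    return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages; writes outputs under ``config.outdir``."""
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # simulate
    cohort_cfg = config.cohort.model_copy(update={"seed": config.seed})
    ds = generate_cohort(cohort_cfg)
    cohort_dir = outdir / "cohort"
    write_cohort(ds, cohort_dir)
    counts["patients"] = len(ds.patients)
    counts["lesions"] = ds.n_lesions
    counts["dose_groups"] = len({4.0, *(p.arm_dose_mg for p in ds.patients)})

    # quantify (from the written files, so schema validation is exercised)
    errors = validate_schema(cohort_dir / "lesions.csv", "lesions")
    if errors:
        raise PipelineValidationError("quantify", errors)
    measured = read_cohort_dir(cohort_dir)
    uptake = uptake_table(measured, config.pairing_tolerance_h,
                          config.half_life_h)
    uptake.to_csv(outdir / "uptake.csv", index=False)
    counts["uptake_rows"] = len(uptake)

    # patlak
    patlak = patlak_table(measured, config.window(), config.input_model,
                          config.half_life_h)
    patlak.to_csv(outdir / "patlak.csv", index=False)
    counts["patlak_rows"] = len(patlak)

    # compare
    summaries, comparisons = _compare_stage(config, uptake, patlak)
    summaries.to_csv(outdir / "summaries.csv", index=False)
    comparisons["seed"] = config.seed
    counts["summary_rows"] = len(summaries)

    # immune
    pheno, immune_stats = _immune_stage(config, ds, uptake, outdir)
    pheno.to_csv(outdir / "immune.csv", index=False)
    comparisons["immune"] = immune_stats
    counts["patients_phenotyped"] = len(pheno)
    (outdir / "comparisons.json").write_text(
        json.dumps(comparisons, indent=2, default=float) + "\n",
        encoding="utf-8")

    (outdir / "report.txt").write_text(
        _report_text(summaries, comparisons, immune_stats, pheno),
        encoding="utf-8")

    manifest = RunManifest(config_hash=cohort_cfg.config_hash(),
                           seed=config.seed, version=config.version,
                           started=started,
                           finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
                           row_counts=counts)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest.__dict__, indent=2, default=dict) + "\n",
        encoding="utf-8")
    return manifest
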
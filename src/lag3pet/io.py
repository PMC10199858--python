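"""Reading and writing the cohort interchange files.

A cohort is a directory of plain-text files: ``cohort.json`` (config, seed,
config hash and ground truth), ``plasma.csv``, ``tac.csv``,
``injections.csv`` and ``lesions.csv``. All CSVs are RFC-4180, UTF-8, with
a mandatory header row; times are hours post-injection as decimals,
timestamps ISO-8601.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .cohort import CohortDataset
from .quantify import percent_injected_activity

__all__ = ["write_cohort", "read_csv", "plasma_frame", "tac_frame",
           "injections_frame", "lesions_frame"]


def read_csv(path) -> pd.DataFrame:
    """CSV reader with exact (round-trip) decimal-to-binary conversion.

    The default pandas parser can be one ulp off, which breaks the
    byte-identical write → read → write contract of the interchange files.
    """
    return pd.read_csv(path, float_precision="round_trip")


def plasma_frame(ds: CohortDataset) -> pd.DataFrame:
    """Observed plasma samples as %IA/L (decay-corrected to cycle t0)."""
    rows = []
    for p in ds.patients:
        for cycle, tac in sorted(p.plasma_observed.items()):
            inj = p.injections[cycle]
            dc = tac.decay_corrected_curve()
            for t, v in zip(dc.times, dc.values):
                rows.append((p.patient_id, cycle, t,
                             percent_injected_activity(v, inj)))
    return pd.DataFrame(rows, columns=["patient_id", "cycle", "time_h",
                                       "conc_pct_ia_per_l"])


def tac_frame(ds: CohortDataset) -> pd.DataFrame:
    """Observed region samples as measured (not decay-corrected) Bq/mL."""
    rows = []
    for p in ds.patients:
        for (region_id, cycle), tac in sorted(p.tacs_observed.items()):
            for t, v in zip(tac.times, tac.values):
                rows.append((p.patient_id, region_id, tac.region_type,
                             cycle, t, v))
    return pd.DataFrame(rows, columns=["patient_id", "region_id",
                                       "region_type", "cycle", "time_h",
                                       "conc_bq_per_ml"])


def injections_frame(ds: CohortDataset) -> pd.DataFrame:
    rows = []
    for p in ds.patients:
        for cycle, inj in sorted(p.injections.items()):
            rows.append((p.patient_id, cycle, inj.injected_activity_mbq,
                         inj.mass_dose_mg, p.body_weight_kg, inj.t0))
    return pd.DataFrame(rows, columns=["patient_id", "cycle", "activity_mbq",
                                       "mass_mg", "weight_kg", "t0_iso8601"])


def lesions_frame(ds: CohortDataset) -> pd.DataFrame:
    rows = [(l.patient_id, l.lesion_id, l.volume_ml, l.infiltration,
             l.ki_spec_unblocked, l.ihc_lag3_pct, l.site_class)
            for l in ds.lesions]
    return pd.DataFrame(rows, columns=["patient_id", "lesion_id", "volume_ml",
                                       "infiltration", "ki_spec_ul_g_h",
                                       "ihc_lag3_pct", "site_class"])


def write_cohort(ds: CohortDataset, outdir) -> dict[str, Path]:
    """Write the cohort directory; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = {
        "config": ds.config.model_dump(),
        "config_hash": ds.config_hash,
        "occupancy": {"d50_mg": ds.occupancy.d50, "hill": ds.occupancy.hill},
        "tumor_model": {
            "k1": ds.tumor_model.k1, "k2": ds.tumor_model.k2,
            "vb": ds.tumor_model.vb,
            "ki_spec_median": ds.tumor_model.ki_spec_median,
            "ki_nonspec": ds.tumor_model.ki_nonspec,
            "sigma_ki": ds.tumor_model.sigma_ki,
            "sigma_k1": ds.tumor_model.sigma_k1,
        },
        "plasma_truth": {
            str(p.patient_id): {
                str(cyc): {
                    "amp_fast": pk.amp_fast, "amp_slow": pk.amp_slow,
                    "lambda_fast": pk.lambda_fast,
                    "lambda_slow": pk.lambda_slow,
                    "clearance_scale": pk.clearance_scale,
                } for cyc, pk in p.plasma_params.items()
            } for p in ds.patients
        },
    }
    paths = {}
    cohort_json = outdir / "cohort.json"
    cohort_json.write_text(json.dumps(truth, indent=2, default=list) + "\n",
                           encoding="utf-8")
    paths["cohort.json"] = cohort_json
    for name, frame in [("plasma.csv", plasma_frame(ds)),
                        ("tac.csv", tac_frame(ds)),
                        ("injections.csv", injections_frame(ds)),
                        ("lesions.csv", lesions_frame(ds))]:
        path = outdir / name
        frame.to_csv(path, index=False, lineterminator="\r\n")
        paths[name] = path
    return paths
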
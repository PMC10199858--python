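"""Unit and ratio arithmetic for PET activity data.

Measured radioactivity concentrations (Bq/mL) are decay-corrected to the
injection time of the relevant cycle, then normalized to one of the study's
outcome measures:

* **%IA/L** — percent of injected activity per litre; body-size independent.
* **SUV** — concentration over (injected activity / body weight), the
  conventional PET measure, with 1 g/mL tissue density.
* **tissue-to-plasma ratio** — the preferred outcome for an antibody tracer
  with dose-dependent clearance, since it divides out the plasma exposure.

Ratios pair each tissue time point with the nearest plasma sample within a
configurable tolerance (default 6 h).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = [
    "ZR89_HALF_LIFE_H",
    "Units",
    "TimeActivityCurve",
    "InjectionRecord",
    "UptakeMeasure",
    "decay_correct",
    "percent_injected_activity",
    "suv",
    "tissue_to_plasma_ratio",
]

#: physical half-life of ⁸⁹Zr in hours
ZR89_HALF_LIFE_H = 78.41


class Units(str, Enum):
    BQ_PER_ML = "Bq/mL"
    PCT_IA_PER_L = "%IA/L"
    SUV = "SUV"
    RATIO = "ratio"


@dataclass(frozen=True)
class InjectionRecord:
    """One tracer administration.

    injected_activity_mbq : activity at injection time, MBq
    mass_dose_mg : total antibody mass (tracer + unlabeled pre-dose), mg
    body_weight_kg : kg
    t0 : ISO-8601 timestamp of injection
    """

    injected_activity_mbq: float
    mass_dose_mg: float
    body_weight_kg: float
    t0: str = "1970-01-01T00:00:00"
    tracer_mass_mg: float = 4.0

    def __post_init__(self) -> None:
        if self.injected_activity_mbq <= 0:
            raise ValueError("injected activity must be > 0")
        if self.mass_dose_mg < self.tracer_mass_mg:
            raise ValueError("mass dose cannot be below the tracer mass")
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be > 0")

    @property
    def injected_activity_bq(self) -> float:
        return self.injected_activity_mbq * 1e6


@dataclass(frozen=True)
class TimeActivityCurve:
    """Sampled activity concentration of one region over time.

    ``times`` are hours post-injection (strictly increasing), ``values``
    concentrations in ``units``. ``decay_corrected`` records whether values
    are referred back to the injection time.
    """

    region_id: str
    region_type: str            # organ | tumor | plasma | blood
    cycle: int
    times: tuple = field(default_factory=tuple)
    values: tuple = field(default_factory=tuple)
    units: Units = Units.BQ_PER_ML
    decay_corrected: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size != v.size:
            raise ValueError("times and values must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("concentrations must be >= 0")
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        object.__setattr__(self, "values", tuple(float(x) for x in v))

    def t(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    def v(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def with_values(self, values, units: Units | None = None,
                    decay_corrected: bool | None = None) -> "TimeActivityCurve":
        return replace(
            self,
            values=tuple(float(x) for x in np.asarray(values, dtype=float)),
            units=self.units if units is None else units,
            decay_corrected=(self.decay_corrected if decay_corrected is None
                             else decay_corrected),
        )

    def decay_corrected_curve(self, half_life_h: float = ZR89_HALF_LIFE_H
                              ) -> "TimeActivityCurve":
        """Return the curve decay-corrected to injection time."""
        if self.decay_corrected:
            return self
        vals = [decay_correct(c, t, half_life_h)
                for t, c in zip(self.times, self.values)]
        return self.with_values(vals, decay_corrected=True)


@dataclass(frozen=True)
class UptakeMeasure:
    """A single uptake summary for one region at one time."""

    region_id: str
    time_h: float
    value: float
    kind: str  # tissue_to_plasma | suv_peak | pct_ia_per_l

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("uptake values must be >= 0")
        if self.kind not in ("tissue_to_plasma", "suv_peak", "pct_ia_per_l"):
            raise ValueError(f"unknown uptake kind {self.kind!r}")


# ---------------------------------------------------------------------------


def decay_correct(conc: float, elapsed_h: float,
                  half_life_h: float = ZR89_HALF_LIFE_H) -> float:
    """Correct a measured concentration for physical decay.

    Returns ``conc · 2^(elapsed/half_life)``; a negative ``half_life`` is
    rejected, and uncorrection is obtained by passing the corrected value
    through with a negative exponent via ``decay_uncorrect``.
    """
    if elapsed_h < 0:
        raise ValueError("elapsed time must be >= 0")
    if half_life_h <= 0:
        raise ValueError("half-life must be > 0")
    return conc * 2.0 ** (elapsed_h / half_life_h)


def decay_uncorrect(conc_dc: float, elapsed_h: float,
                    half_life_h: float = ZR89_HALF_LIFE_H) -> float:
    """Inverse of :func:`decay_correct` (used by the simulator)."""
    if elapsed_h < 0:
        raise ValueError("elapsed time must be >= 0")
    return conc_dc * 2.0 ** (-elapsed_h / half_life_h)


def percent_injected_activity(conc_dc_bq_ml: float, inj: InjectionRecord
                              ) -> float:
    """Decay-corrected Bq/mL → %IA/L.

    %IA/L = 100 · (conc · 1000 mL/L) / injected activity [Bq].
    """
    if inj.injected_activity_bq <= 0:
        raise ValueError("injected activity must be > 0")
    return 100.0 * conc_dc_bq_ml * 1000.0 / inj.injected_activity_bq


def pct_ia_per_l_to_bq_ml(pct: float, inj: InjectionRecord) -> float:
    """Inverse of :func:`percent_injected_activity`."""
    return pct * inj.injected_activity_bq / (100.0 * 1000.0)


def suv(conc_dc_bq_ml: float, inj: InjectionRecord) -> float:
    """Standardized uptake value, 1 g/mL tissue density convention."""
    if inj.body_weight_kg <= 0 or inj.injected_activity_bq <= 0:
        raise ValueError("weight and activity must be > 0")
    weight_g = inj.body_weight_kg * 1000.0
    return conc_dc_bq_ml / (inj.injected_activity_bq / weight_g)


def tissue_to_plasma_ratio(
    tissue: TimeActivityCurve,
    plasma: TimeActivityCurve,
    tolerance_h: float = 6.0,
) -> list[UptakeMeasure]:
    """Pair tissue samples with the nearest plasma sample and divide.

    Both curves must be decay-corrected and in the same units. A tissue
    time with no plasma sample within ``tolerance_h`` raises a
    ``MissingPlasmaSampleError``; a zero plasma concentration is rejected.
    """
    if tissue.units != plasma.units:
        raise ValueError("tissue and plasma curves must share units")
    if not (tissue.decay_corrected and plasma.decay_corrected):
        raise ValueError("both curves must be decay-corrected")
    pt = plasma.t()
    pv = plasma.v()
    out = []
    for t, c in zip(tissue.times, tissue.values):
        i = int(np.argmin(np.abs(pt - t)))
        if abs(pt[i] - t) > tolerance_h:
            raise MissingPlasmaSampleError(
                f"no plasma sample within {tolerance_h} h of t={t} h "
                f"for region {tissue.region_id!r}")
        if pv[i] <= 0:
            raise ValueError("plasma concentration must be > 0 for a ratio")
        out.append(UptakeMeasure(region_id=tissue.region_id, time_h=t,
                                 value=c / pv[i], kind="tissue_to_plasma"))
    return out


class MissingPlasmaSampleError(ValueError):
    """Raised when no plasma sample lies within the pairing tolerance."""
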
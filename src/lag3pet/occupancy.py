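"""Receptor occupancy as a function of administered antibody mass dose.

Increasing the unlabeled antibody mass dose occupies target (LAG-3) binding
sites and suppresses target-specific tracer uptake. Occupancy is modeled as
a Hill function of the *administered mass dose* rather than of the
time-varying plasma concentration: this keeps the net irreversible uptake
rate constant within an imaging cycle, which is exactly the regime in which
Patlak linearization is valid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["OccupancyModel", "receptor_occupancy", "fit_occupancy"]


@dataclass(frozen=True)
class OccupancyModel:
    """Hill occupancy model: occ(d) = d^h / (d^h + d50^h).

    ``d50`` is the mass dose (mg) at half-maximal occupancy, ``hill`` the
    Hill exponent. occ(0) = 0, occ is strictly increasing, and occ < 1 for
    any finite dose.
    """

    d50: float
    hill: float = 2.0

    def __post_init__(self) -> None:
        if self.d50 <= 0:
            raise ValueError("d50 must be > 0")
        if self.hill <= 0:
            raise ValueError("hill must be > 0")

    def occupancy(self, dose_mg):
        dose = np.asarray(dose_mg, dtype=float)
        if np.any(dose < 0):
            raise ValueError("dose must be >= 0")
        dh = dose ** self.hill
        return dh / (dh + self.d50 ** self.hill)


def receptor_occupancy(dose_mg, model: OccupancyModel):
    """Fraction of target sites occupied at ``dose_mg`` (mg); in [0, 1)."""
    return model.occupancy(dose_mg)


def fit_occupancy(
    doses_mg,
    ki_values,
    ki_floor: float,
    hill: float = 2.0,
    d50_bounds: tuple[float, float] = (0.5, 300.0),
) -> tuple[OccupancyModel, float]:
    """Calibrate ``d50`` against measured Ki values at several mass doses.

    Assumes ``Ki(d) = ki_floor + ki_spec · (1 − occ(d))`` with the
    non-specific floor fixed (typically the fully-blocked value). For each
    candidate d50 the specific amplitude ``ki_spec`` has a closed-form
    linear least-squares solution, so the fit is a one-dimensional bounded
    minimization over d50.

    Returns
    -------
    (model, ki_spec) : the fitted occupancy model and the specific Ki
        amplitude at zero occupancy, same units as ``ki_values``.
    """
    doses = np.asarray(doses_mg, dtype=float)
    ki = np.asarray(ki_values, dtype=float)
    if doses.shape != ki.shape or doses.size < 2:
        raise ValueError("need matching dose/Ki arrays with >= 2 points")
    resid = ki - ki_floor

    def profile(d50: float) -> tuple[float, float]:
        u = d50 ** hill / (doses ** hill + d50 ** hill)  # = 1 - occ
        spec = float(u @ resid) / float(u @ u)
        sse = float(np.sum((resid - spec * u) ** 2))
        return sse, spec

    res = minimize_scalar(lambda x: profile(x)[0], bounds=d50_bounds,
                          method="bounded")
    d50 = float(res.x)
    _, ki_spec = profile(d50)
    return OccupancyModel(d50=d50, hill=hill), ki_spec
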
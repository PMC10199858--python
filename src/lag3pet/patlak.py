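"""Input-function fitting and Patlak graphical analysis.

For a tracer with an irreversibly trapped compartment, plotting

    y(t) = Ct(t)/Cp(t)   against   x(t) = ∫₀ᵗ Cp(τ) dτ / Cp(t)

("normalized time") yields, after the reversible compartment equilibrates,
a straight line whose slope is the net irreversible uptake rate Ki and
whose intercept reflects the reversible distribution volume plus blood
fraction. Ki is reported in μL·g⁻¹·h⁻¹ (slope × 1000, 1 g/mL density).

The sparse venous sampling of an antibody-imaging protocol (three plasma
samples per cycle) is bridged by a continuous input model: either a
bi-exponential fit — with the weakly-identified fast phase held at
configured defaults when fewer than four samples are available — or exact
piecewise log-linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .pk import PlasmaPKParams
from .quantify import TimeActivityCurve

__all__ = [
    "InputFunctionFit",
    "PatlakPoint",
    "PatlakFit",
    "fit_input_function",
    "patlak_transform",
    "patlak_fit",
]


@dataclass(frozen=True)
class InputFunctionFit:
    """Continuous plasma model with a closed-form running integral."""

    model: str                      # biexponential | loglinear_interp
    params: Optional[PlasmaPKParams] = None
    knot_times: Optional[tuple] = None
    knot_values: Optional[tuple] = None
    fit_residual: float = 0.0       # relative RMS at the sample points

    def conc(self, t):
        scalar = np.ndim(t) == 0
        t = np.asarray(t, dtype=float)
        if self.model == "biexponential":
            out = self.params.conc(t)
        else:
            out = _loglin_conc(np.asarray(self.knot_times),
                               np.asarray(self.knot_values), t)
        return float(np.ravel(out)[0]) if scalar else out

    def integral(self, t):
        scalar = np.ndim(t) == 0
        t = np.asarray(t, dtype=float)
        if self.model == "biexponential":
            out = self.params.integral(t)
        else:
            out = _loglin_integral(np.asarray(self.knot_times),
                                   np.asarray(self.knot_values), t)
        return float(np.ravel(out)[0]) if scalar else out


@dataclass(frozen=True)
class PatlakPoint:
    x: float    # normalized time, h
    y: float    # tissue-to-plasma, dimensionless
    t: float    # h p.i.


@dataclass(frozen=True)
class PatlakFit:
    """OLS fit of the Patlak-transformed points.

    A negative slope (possible under noise) is reported, not clamped,
    and flagged via ``negative_ki``.
    """

    ki: float               # μL·g⁻¹·h⁻¹
    v_intercept: float      # mL/g
    r_squared: float
    n_points: int
    window: tuple[float, float]

    @property
    def negative_ki(self) -> bool:
        return self.ki < 0


# --- input function --------------------------------------------------------


def fit_input_function(
    plasma: TimeActivityCurve,
    model: str = "biexponential",
    fixed_fast: Optional[tuple[float, float]] = None,
) -> InputFunctionFit:
    """Fit a continuous input model to sparse plasma samples.

    Least squares in log space. With fewer than four samples the
    bi-exponential's fast phase (amplitude, rate) is held at ``fixed_fast``
    — required in that case — and only the slow phase is fitted.
    """
    t = plasma.t()
    c = plasma.v()
    if t.size < 2:
        raise ValueError("need at least 2 plasma samples")
    if np.any(c <= 0):
        raise ValueError("plasma concentrations must be > 0 to fit")

    if model == "loglinear_interp":
        return InputFunctionFit(model=model, knot_times=tuple(t),
                                knot_values=tuple(c), fit_residual=0.0)
    if model != "biexponential":
        raise ValueError(f"unknown input model {model!r}")

    logc = np.log(c)
    if t.size < 4:
        if fixed_fast is None:
            raise ValueError(
                "with < 4 samples the fast phase must be fixed (fixed_fast)")
        a1, l1 = fixed_fast

        # initial slow phase from the last two samples
        lam0 = max((logc[-2] - logc[-1]) / (t[-1] - t[-2]), 1e-4)
        a2_0 = c[-1] * np.exp(lam0 * t[-1])

        def resid(q):
            a2, lam2 = np.exp(q)
            return np.log(a1 * np.exp(-l1 * t) + a2 * np.exp(-lam2 * t)) - logc

        fit = least_squares(resid, np.log([a2_0, lam0]),
                            bounds=(np.log([1e-6, 1e-5]),
                                    np.log([1e4, l1 * 0.999])))
        a2, lam2 = np.exp(fit.x)
        params = PlasmaPKParams(amp_fast=a1, amp_slow=a2, lambda_fast=l1,
                                lambda_slow=lam2)
    else:
        lam0 = max((logc[-2] - logc[-1]) / (t[-1] - t[-2]), 1e-4)
        a2_0 = c[-1] * np.exp(lam0 * t[-1])
        a1_0 = max(c[0] - a2_0 * np.exp(-lam0 * t[0]), 0.05 * c[0])

        def resid(q):
            a1, a2, lam2, dlam = np.exp(q)
            lam1 = lam2 + dlam
            return np.log(a1 * np.exp(-lam1 * t) + a2 * np.exp(-lam2 * t)) - logc

        fit = least_squares(
            resid, np.log([a1_0, a2_0, lam0, max(10 * lam0, 0.05)]),
            bounds=(np.log([1e-8, 1e-8, 1e-5, 1e-4]),
                    np.log([1e5, 1e5, 2.0, 20.0])))
        a1, a2, lam2, dlam = np.exp(fit.x)
        params = PlasmaPKParams(amp_fast=a1, amp_slow=a2,
                                lambda_fast=lam2 + dlam, lambda_slow=lam2)

    rel = params.conc(t) / c - 1.0
    return InputFunctionFit(model="biexponential", params=params,
                            fit_residual=float(np.sqrt(np.mean(rel ** 2))))


def _loglin_conc(kt, kv, t):
    """Piecewise-exponential interpolant through the knots."""
    logv = np.log(kv)
    t = np.atleast_1d(t)
    out = np.empty_like(t, dtype=float)
    for j, tj in enumerate(t):
        i = int(np.clip(np.searchsorted(kt, tj) - 1, 0, kt.size - 2))
        slope = (logv[i + 1] - logv[i]) / (kt[i + 1] - kt[i])
        out[j] = np.exp(logv[i] + slope * (tj - kt[i]))
    return out


def _loglin_integral(kt, kv, t):
    """Exact ∫₀ᵗ of the piecewise-exponential interpolant.

    Each segment integrates to Δt·(c2−c1)/ln(c2/c1) (the logarithmic
    mean); before the first knot the first segment's rate extrapolates
    back to t = 0.
    """
    def seg(c1, c2, dt):
        if dt <= 0:
            return 0.0
        if np.isclose(c1, c2):
            return c1 * dt
        return dt * (c2 - c1) / np.log(c2 / c1)

    logv = np.log(kv)
    rate0 = (logv[1] - logv[0]) / (kt[1] - kt[0])
    t = np.atleast_1d(t)
    out = np.empty_like(t, dtype=float)
    for j, tj in enumerate(t):
        total = 0.0
        c_at = _loglin_conc(kt, kv, np.array([min(tj, kt[0])]))[0]
        # head: extrapolated segment from 0 to min(t, first knot)
        c0 = np.exp(logv[0] - rate0 * kt[0])
        total += seg(c0, c_at, min(tj, kt[0]))
        for i in range(kt.size - 1):
            if tj <= kt[i]:
                break
            hi = min(tj, kt[i + 1])
            c_hi = _loglin_conc(kt, kv, np.array([hi]))[0]
            total += seg(kv[i], c_hi, hi - kt[i])
        if tj > kt[-1]:
            c_end = _loglin_conc(kt, kv, np.array([tj]))[0]
            total += seg(kv[-1], c_end, tj - kt[-1])
        out[j] = total
    return out


# --- Patlak ----------------------------------------------------------------


def patlak_transform(tissue: TimeActivityCurve, input_fit: InputFunctionFit
                     ) -> list[PatlakPoint]:
    """Map a tissue curve into Patlak coordinates using the exact integral."""
    points = []
    for t, ct in zip(tissue.times, tissue.values):
        cp = float(input_fit.conc(t))
        if cp <= 0:
            raise ValueError(f"input concentration is 0 at t={t} h")
        x = float(input_fit.integral(t)) / cp
        points.append(PatlakPoint(x=x, y=ct / cp, t=t))
    return points


def patlak_fit(points: Sequence[PatlakPoint],
               window: tuple[float, float] = (10.0, np.inf)) -> PatlakFit:
    """Ordinary least squares on the Patlak points inside the time window.

    The default window excludes the early (< 2 h) scan, which precedes
    reversible-compartment equilibration; the late scans carry the slope.
    ``r_squared`` is defined as 1 for a two-point fit.
    """
    sel = [p for p in points if window[0] <= p.t <= window[1]]
    if len(sel) < 2:
        raise ValueError("need >= 2 Patlak points inside the window")
    x = np.array([p.x for p in sel])
    y = np.array([p.y for p in sel])
    if x.max() - x.min() < 1e-9:
        raise ValueError("degenerate x spread: Patlak slope is unidentifiable")
    slope, intercept = np.polyfit(x, y, 1)
    yhat = intercept + slope * x
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if len(sel) == 2 or ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PatlakFit(ki=1000.0 * float(slope), v_intercept=float(intercept),
                     r_squared=float(r2), n_points=len(sel),
                     window=(float(window[0]), float(window[1])))
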
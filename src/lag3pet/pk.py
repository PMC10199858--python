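"""Plasma pharmacokinetics: bi-exponential input curves per mass-dose arm.

Monoclonal antibodies given at sub-saturating mass doses are cleared faster
than at saturating doses (target-mediated drug disposition): the target acts
as an additional elimination pathway until it is occupied. Rather than
solving a mechanistic TMDD system, each dose arm gets a bi-exponential
disposition curve

    Cp(t) = A1·exp(−λ1·t) + A2·exp(−λ2·s·t)

in %IA/L (percent of the injected activity per litre, decay-corrected),
where the dimensionless ``clearance_scale`` s multiplies the terminal rate
so dose-dependent clearance is parameterized, not emergent. Defaults are
calibrated from the published per-arm plasma means (see
:mod:`lag3pet.calibration`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PlasmaPKParams", "simulate_plasma_curve"]


@dataclass(frozen=True)
class PlasmaPKParams:
    """Bi-exponential plasma disposition parameters.

    Parameters
    ----------
    amp_fast, amp_slow : float
        Amplitudes A1, A2 of the distribution and elimination phases, %IA/L.
        ``Cp(0) = A1 + A2`` is (100 / plasma volume in L) for a tracer
        confined to plasma at time zero.
    lambda_fast, lambda_slow : float
        Rate constants λ1 > λ2 > 0, in 1/h.
    clearance_scale : float
        Dimensionless multiplier on ``lambda_slow``; encodes the dose
        dependence of terminal clearance (lower at saturating doses).
    """

    amp_fast: float
    amp_slow: float
    lambda_fast: float
    lambda_slow: float
    clearance_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.amp_fast < 0 or self.amp_slow < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.amp_fast + self.amp_slow <= 0:
            raise ValueError("Cp(0) = amp_fast + amp_slow must be > 0")
        if not (self.lambda_fast > self.lambda_slow > 0):
            raise ValueError("need lambda_fast > lambda_slow > 0")
        if self.clearance_scale <= 0:
            raise ValueError("clearance_scale must be > 0")

    @property
    def lambda_slow_effective(self) -> float:
        """Terminal rate after applying the clearance scale, 1/h."""
        return self.lambda_slow * self.clearance_scale

    # -- evaluation ---------------------------------------------------------

    def conc(self, t):
        """Cp(t) in %IA/L for scalar or array times (h p.i.)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("times must be >= 0")
        return (
            self.amp_fast * np.exp(-self.lambda_fast * t)
            + self.amp_slow * np.exp(-self.lambda_slow_effective * t)
        )

    def integral(self, t):
        """Exact ∫₀ᵗ Cp(τ) dτ, %IA·h/L."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("times must be >= 0")
        l2 = self.lambda_slow_effective
        return (
            self.amp_fast * (1.0 - np.exp(-self.lambda_fast * t)) / self.lambda_fast
            + self.amp_slow * (1.0 - np.exp(-l2 * t)) / l2
        )

    def scaled(self, amplitude_scale: float = 1.0, clearance_jitter: float = 1.0
               ) -> "PlasmaPKParams":
        """Patient-level variant: rescale amplitudes and terminal clearance."""
        return PlasmaPKParams(
            amp_fast=self.amp_fast * amplitude_scale,
            amp_slow=self.amp_slow * amplitude_scale,
            lambda_fast=self.lambda_fast,
            lambda_slow=self.lambda_slow,
            clearance_scale=self.clearance_scale * clearance_jitter,
        )


def simulate_plasma_curve(params: PlasmaPKParams, times) -> "np.ndarray":
    """Evaluate the decay-corrected plasma curve at ``times`` (h p.i.).

    Returns concentrations in %IA/L. Negative times are rejected.
    """
    return params.conc(times)
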
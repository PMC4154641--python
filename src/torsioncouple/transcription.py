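"""Thermodynamic model of transcription initiation under superhelical stress.

The expression level is taken proportional to the initiation probability
of the chemical equilibrium between bound and unbound states of the
transcription machinery.  The only supercoiling-dependent contribution to
the initiation free energy is the promoter opening penalty:

    dG_init(sigma) = dG_open(sigma) + dG_bind,
    k(sigma)       = k_max * exp(-dG_init(sigma) / (R * T_e)),

with an *effective temperature* T_e standing in for the non-thermal,
polymerase-assisted component of bubble formation; it is the single
adjustable parameter of the rate law and is calibrated on expression data.
The unsaturated Boltzmann form makes the supercoiling fold-change

    rho(sigma; sigma0) = exp(-[dG_open(sigma) - dG_open(sigma0)] / (R T_e))

exactly independent of dG_bind and k_max, so the coupling diagrams need no
knowledge of the binding energetics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np
from scipy import stats

from .opening import R_KCAL, SigmoidOpening, opening_energy

__all__ = [
    "PromoterModel",
    "CalibrationResult",
    "CalibrationError",
    "initiation_energy",
    "transcription_rate",
    "fold_change",
    "calibrate_effective_temperature",
]

OpeningModel = Union[SigmoidOpening, Callable]

_EXP_CAP = 500.0


class CalibrationError(RuntimeError):
    """Effective-temperature calibration failed (degenerate or invalid data)."""


def _eval_opening(opening: OpeningModel, sigma):
    if isinstance(opening, SigmoidOpening):
        return opening_energy(sigma, opening)
    return opening(sigma)


@dataclass(frozen=True)
class PromoterModel:
    """Opening model + binding energy + effective temperature + max rate."""

    opening: OpeningModel
    binding_energy: float = 0.0      # dG_bind, kcal/mol, sigma-independent
    effective_temperature: float = 558.0  # K; placeholder default 1.8 x 310 K
    max_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.effective_temperature <= 0:
            raise ValueError("effective_temperature must be > 0")
        if self.max_rate <= 0:
            raise ValueError("max_rate must be > 0")

    @property
    def beta(self) -> float:
        """1 / (R T_e) in mol/kcal."""
        return 1.0 / (R_KCAL * self.effective_temperature)

    def to_dict(self) -> dict:
        if not isinstance(self.opening, SigmoidOpening):
            raise TypeError("only SigmoidOpening promoters are serializable")
        return {
            "opening": self.opening.to_dict(),
            "binding_energy": self.binding_energy,
            "effective_temperature": self.effective_temperature,
            "max_rate": self.max_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PromoterModel":
        return cls(
            opening=SigmoidOpening.from_dict(d["opening"]),
            binding_energy=d.get("binding_energy", 0.0),
            effective_temperature=d.get("effective_temperature", 558.0),
            max_rate=d.get("max_rate", 1.0),
        )

    @classmethod
    def from_json(cls, path) -> "PromoterModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def initiation_energy(sigma, promoter: PromoterModel):
    """Total initiation free energy dG_init = dG_open(sigma) + dG_bind."""
    return _eval_opening(promoter.opening, sigma) + promoter.binding_energy


def transcription_rate(sigma, promoter: PromoterModel):
    """Average transcription rate k(sigma) = k_max exp(-beta dG_init)."""
    exponent = -promoter.beta * np.asarray(initiation_energy(sigma, promoter))
    if np.any(np.abs(exponent) > _EXP_CAP):
        warnings.warn("transcription_rate: exponent capped to avoid overflow")
        exponent = np.clip(exponent, -_EXP_CAP, _EXP_CAP)
    out = promoter.max_rate * np.exp(exponent)
    if np.ndim(out) == 0:
        return float(out)
    return out


def fold_change(sigma, sigma0, promoter: PromoterModel):
    """Supercoiling fold-change rho = k(sigma)/k(sigma0).

    Computed from the opening-energy difference only, so it is independent
    of the binding energy and of the maximal rate by construction.
    """
    dg = np.asarray(_eval_opening(promoter.opening, sigma), dtype=float)
    dg0 = _eval_opening(promoter.opening, sigma0)
    exponent = np.clip(-promoter.beta * (dg - dg0), -_EXP_CAP, _EXP_CAP)
    out = np.exp(exponent)
    if np.ndim(out) == 0:
        return float(out)
    return out


@dataclass
class CalibrationResult:
    effective_temperature: float
    intercept: float
    r_squared: float
    residual: float


def calibrate_effective_temperature(
    sigma_values,
    expression_values,
    opening: OpeningModel,
) -> CalibrationResult:
    """Fit T_e from (sigma, expression) data.

    Under the rate law, log expression is linear in -dG_open(sigma) with
    slope 1/(R T_e) and a free intercept absorbing k_max and dG_bind; a
    least-squares line gives T_e directly.
    """
    sigma = np.asarray(sigma_values, dtype=float)
    expr = np.asarray(expression_values, dtype=float)
    if sigma.size < 3:
        raise CalibrationError("need at least 3 (sigma, expression) points")
    if np.any(expr <= 0):
        raise CalibrationError("expression values must be strictly positive")
    x = -np.asarray(_eval_opening(opening, sigma), dtype=float)
    if np.ptp(x) < 1e-12:
        raise CalibrationError("opening energy is flat over the sigma range")
    y = np.log(expr)
    fit = stats.linregress(x, y)
    if fit.slope <= 0:
        raise CalibrationError(
            "expression does not increase with promoter destabilization; "
            f"slope={fit.slope:.3g}"
        )
    t_e = 1.0 / (R_KCAL * fit.slope)
    resid = float(np.linalg.norm(y - (fit.intercept + fit.slope * x)))
    return CalibrationResult(
        effective_temperature=float(t_e),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        residual=resid,
    )
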
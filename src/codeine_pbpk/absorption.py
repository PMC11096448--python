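"""Oral dose input: formulation release, gastric emptying, intestinal transit.

Formulation release follows a Weibull cumulative-dissolution curve
parameterised directly by the 50%-dissolution time t50 and a shape factor:

    f(t) = 1 - 2**(-((t - lag)/t50)**shape)          (t >= lag)

so that f(lag + t50) = 0.5 exactly. Immediate-release tablets and solutions
are treated as fully dissolved at administration; intravenous doses bypass
the gut entirely.

Dissolved drug empties from the stomach (first-order) into a serial
small-intestine transit chain; each segment absorbs drug into the portal
circulation at a first-order rate ka = 2*P_cell/r derived from the cellular
permeability and an effective intestinal radius, and drug leaving the last
segment is lost to a faecal sink. Solubility limitation is not modelled;
a warning is logged when the administered dose could exceed the solubility
of the luminal fluid volume.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from ._data import load_packaged_yaml
from .compound import CompoundParameters, FormulationParams

__all__ = [
    "FormulationSpec", "Regimen", "DoseEvent",
    "weibull_fraction_dissolved", "weibull_release_rate",
    "dose_events", "GutModel",
]

logger = logging.getLogger(__name__)

INSTANT_KINDS = ("iv_bolus", "iv_infusion", "solution", "IR_tablet", "CR_solution")
WEIBULL_KINDS = ("tablet", "capsule", "SR_tablet", "sr_tablet")
LUMINAL_FLUID_ML = 250.0


@dataclass(frozen=True)
class FormulationSpec:
    """Release behaviour of one dosage form."""

    kind: str
    dissolution_t50_min: float | None = None
    dissolution_shape: float | None = None
    lag_time_min: float = 0.0
    infusion_duration_min: float = 30.0

    def __post_init__(self) -> None:
        if self.kind not in INSTANT_KINDS + WEIBULL_KINDS:
            raise ValueError(f"unknown formulation kind {self.kind!r}")
        if self.is_weibull:
            if not (self.dissolution_t50_min and self.dissolution_t50_min > 0):
                raise ValueError("Weibull formulations need dissolution_t50_min > 0")
            if not (self.dissolution_shape and self.dissolution_shape > 0):
                raise ValueError("Weibull formulations need dissolution_shape > 0")

    @property
    def is_weibull(self) -> bool:
        return self.kind in WEIBULL_KINDS

    @classmethod
    def from_compound(cls, compound: CompoundParameters, kind: str,
                      lag_time_min: float = 0.0) -> "FormulationSpec":
        """Formulation using the compound file's dissolution parameters."""
        if kind in INSTANT_KINDS:
            return cls(kind=kind, lag_time_min=lag_time_min)
        key = {"SR_tablet": "sr_tablet"}.get(kind, kind)
        params: FormulationParams = compound.formulations[key]
        return cls(kind=kind, dissolution_t50_min=params.dissolution_t50_min,
                   dissolution_shape=params.dissolution_shape,
                   lag_time_min=lag_time_min)


@dataclass(frozen=True)
class Regimen:
    """Dosing regimen: dose per administration, route, formulation, schedule."""

    dose_mg: float
    formulation: FormulationSpec
    n_doses: int = 1
    dosing_interval_h: float = 0.0
    start_time_h: float = 0.0

    def __post_init__(self) -> None:
        if self.dose_mg < 0:
            raise ValueError("dose must be non-negative")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        if self.n_doses > 1 and self.dosing_interval_h <= 0:
            raise ValueError("multiple doses need a positive dosing interval")

    @property
    def route(self) -> str:
        return "iv" if self.formulation.kind.startswith("iv") else "po"


@dataclass(frozen=True)
class DoseEvent:
    time_min: float
    amount_umol: float


def weibull_fraction_dissolved(t_min, spec: FormulationSpec):
    """Cumulative fraction dissolved at time t (minutes) since administration."""
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if not spec.is_weibull:
        return np.where(t >= spec.lag_time_min, 1.0, 0.0)[()]
    x = np.clip(t - spec.lag_time_min, 0.0, None) / spec.dissolution_t50_min
    return (1.0 - 2.0 ** (-(x ** spec.dissolution_shape)))[()]


def weibull_release_rate(t_min: float, spec: FormulationSpec) -> float:
    """Instantaneous release rate df/dt (1/min) at time t since administration.

    For shape < 1 the rate diverges at t -> lag; callers clip the origin.
    """
    s = spec.dissolution_shape
    t50 = spec.dissolution_t50_min
    te = t_min - spec.lag_time_min
    if te <= 0:
        return 0.0
    x = te / t50
    return math.log(2.0) * (s / t50) * x ** (s - 1.0) * 2.0 ** (-(x ** s))


def dose_events(regimen: Regimen, molecular_weight: float) -> list[DoseEvent]:
    """Ordered administration events with amounts in umol."""
    amount = regimen.dose_mg / molecular_weight * 1e3  # mg / (g/mol) -> mmol -> umol
    return [DoseEvent(time_min=(regimen.start_time_h + k * regimen.dosing_interval_h) * 60.0,
                      amount_umol=amount)
            for k in range(regimen.n_doses)]


class GutModel:
    """Segmented gastrointestinal transit/absorption chain for oral dosing.

    States: dissolved amount in stomach plus ``n_segments`` small-intestine
    segments. Constant rate coefficients: gastric emptying k_ge, per-segment
    transit k_t = n/total_transit and absorption ka = 2*P/r (permeability-
    limited, identical segments). Undissolved drug is tracked analytically
    through the Weibull release curve.
    """

    def __init__(self, permeability_cm_min: float):
        g = load_packaged_yaml("constants.yaml")["gut"]
        self.n_segments = int(g["n_segments"])
        self.k_ge = math.log(2.0) / float(g["gastric_emptying_half_time_min"])
        self.k_transit = self.n_segments / (float(g["small_intestine_transit_h"]) * 60.0)
        self.ka = 2.0 * permeability_cm_min / float(g["effective_radius_cm"])

    @property
    def n_states(self) -> int:
        return 1 + self.n_segments

    def rates(self, lumen: np.ndarray) -> tuple[np.ndarray, float, float]:
        """d(lumen)/dt without release input, absorption rate, faecal rate."""
        dl = np.empty_like(lumen)
        dl[0] = -self.k_ge * lumen[0]
        inflow = self.k_ge * lumen[0]
        for j in range(1, self.n_states):
            dl[j] = inflow - (self.k_transit + self.ka) * lumen[j]
            inflow = self.k_transit * lumen[j]
        absorbed = self.ka * float(np.sum(lumen[1:]))
        fecal = self.k_transit * float(lumen[-1])
        return dl, absorbed, fecal

    @staticmethod
    def check_solubility(regimen: Regimen, compound: CompoundParameters) -> None:
        cap = compound.solubility_mg_per_mL_pH7 * LUMINAL_FLUID_ML
        if regimen.route == "po" and regimen.dose_mg > cap:
            logger.warning(
                "dose %.0f mg exceeds the solubility capacity of %.0f mL luminal "
                "fluid (%.0f mg); dissolution is modelled as solubility-unlimited",
                regimen.dose_mg, LUMINAL_FLUID_ML, cap)
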
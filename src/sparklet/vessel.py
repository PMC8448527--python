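"""Pressure-myography and luminal-flow computations.

Percent constriction, percent dilation (normalized to the passive
Ca2+-free diameter), myogenic tone, and Poiseuille wall shear stress
tau = 4 * mu * Qdot / (pi * r^3) in dyn/cm^2 (CGS).  Diameter ratios are
unit-free; shear inputs are converted to CGS explicitly — a record with
no unit hint is rejected rather than silently guessed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from ._errors import ParameterError

__all__ = [
    "VesselRecord",
    "FlowRecord",
    "percent_constriction",
    "percent_dilation",
    "myogenic_tone",
    "shear_stress",
    "shear_stress_cgs",
]

logger = logging.getLogger(__name__)

_VISCOSITY_TO_POISE = {"poise": 1.0, "P": 1.0, "cP": 0.01, "mPa_s": 0.01}
_FLOW_TO_CM3_S = {"cm3_per_s": 1.0, "mL_per_s": 1.0, "uL_per_min": 1e-3 / 60.0, "mL_per_min": 1.0 / 60.0}
_RADIUS_TO_CM = {"cm": 1.0, "mm": 0.1, "um": 1e-4}


@dataclass
class VesselRecord:
    """Summary diameters (um) for one artery under one treatment."""

    d_before: float | None = None
    d_after: float | None = None
    d_basal: float | None = None
    d_dilated: float | None = None
    d_ca_free: float | None = None
    pressure_mmhg: float | None = None
    treatment: str = ""
    ns309_viable: bool = True

    def __post_init__(self) -> None:
        for name in ("d_before", "d_after", "d_basal", "d_dilated", "d_ca_free"):
            val = getattr(self, name)
            if val is not None and val <= 0:
                raise ParameterError(f"{name} must be > 0 when given, got {val!r}")
        if (
            self.d_ca_free is not None
            and self.d_basal is not None
            and self.d_ca_free < self.d_basal
        ):
            logger.warning(
                "passive (Ca2+-free) diameter %.3g um below basal %.3g um",
                self.d_ca_free, self.d_basal,
            )


@dataclass(frozen=True)
class FlowRecord:
    """Viscosity, volumetric flow, and internal radius with explicit units."""

    viscosity: float
    flow: float
    radius: float
    viscosity_unit: str = "poise"
    flow_unit: str = "cm3_per_s"
    radius_unit: str = "cm"

    def __post_init__(self) -> None:
        for name, table in (
            ("viscosity_unit", _VISCOSITY_TO_POISE),
            ("flow_unit", _FLOW_TO_CM3_S),
            ("radius_unit", _RADIUS_TO_CM),
        ):
            unit = getattr(self, name)
            if unit not in table:
                raise ParameterError(
                    f"unknown {name} {unit!r}; expected one of {sorted(table)} "
                    "(units are never guessed)"
                )
        if not (self.viscosity > 0 and self.flow > 0 and self.radius > 0):
            raise ParameterError("viscosity, flow and radius must all be > 0")

    def to_cgs(self) -> tuple[float, float, float]:
        """(mu [poise], Qdot [cm^3/s], r [cm])."""
        mu = self.viscosity * _VISCOSITY_TO_POISE[self.viscosity_unit]
        q = self.flow * _FLOW_TO_CM3_S[self.flow_unit]
        r = self.radius * _RADIUS_TO_CM[self.radius_unit]
        logger.debug("flow record in CGS: mu=%g poise, Q=%g cm^3/s, r=%g cm", mu, q, r)
        return mu, q, r


def percent_constriction(d_before: float, d_after: float) -> float:
    """100 * (d_before - d_after) / d_before.

    Negative values mean net dilation; they are permitted and logged.
    """
    if d_before <= 0:
        raise ParameterError("d_before must be > 0")
    pct = 100.0 * (d_before - d_after) / d_before
    if pct < 0:
        logger.warning("negative constriction %.3g%% (net dilation)", pct)
    return pct


def percent_dilation(d_basal: float, d_dilated: float, d_ca_free: float) -> float:
    """100 * (d_dilated - d_basal) / (d_ca_free - d_basal)."""
    if d_ca_free == d_basal:
        raise ParameterError(
            "degenerate denominator: passive (Ca2+-free) diameter equals basal"
        )
    return 100.0 * (d_dilated - d_basal) / (d_ca_free - d_basal)


def myogenic_tone(d_active: float, d_ca_free: float) -> float:
    """Pressure-induced tone: 100 * (d_ca_free - d_active) / d_ca_free.

    Reference is the passive (Ca2+-free) diameter at the same pressure.
    """
    if d_ca_free <= 0:
        raise ParameterError("d_ca_free must be > 0")
    return 100.0 * (d_ca_free - d_active) / d_ca_free


def shear_stress_cgs(mu_poise: float, flow_cm3_s: float, radius_cm: float) -> float:
    """tau = 4 * mu * Qdot / (pi * r^3), all inputs CGS, result dyn/cm^2."""
    if radius_cm <= 0:
        raise ParameterError("radius must be > 0")
    if mu_poise <= 0 or flow_cm3_s <= 0:
        raise ParameterError("viscosity and flow must be > 0")
    return 4.0 * mu_poise * flow_cm3_s / (math.pi * radius_cm**3)


def shear_stress(flow: FlowRecord) -> float:
    """Wall shear stress in dyn/cm^2 after explicit unit conversion."""
    mu, q, r = flow.to_cgs()
    return shear_stress_cgs(mu, q, r)
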
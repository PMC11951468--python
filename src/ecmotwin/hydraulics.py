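"""Pressure-flow laws for the passive ECMO circuit elements and the pump.

Every element (cannula, tubing segment, oxygenator) is lumped into a
linear-plus-quadratic resistance ``dP = k1*Q + k2*Q*|Q|`` with pressure in
mmHg and flow in L/min.  The linear coefficient is the Hagen-Poiseuille
laminar term computed from the element's geometry; the quadratic term
collects entrance/exit, side-hole and transitional-turbulence losses and is
a calibration parameter.  The centrifugal pump is a quadratic head surface
``H(omega, Q)`` with speed expressed in krpm.

Unit conventions (shared by the whole package): pressure mmHg, flow L/min,
vascular resistance dyn.s.cm-5 where clinicians use it, with
``R[dyn.s.cm-5] = 79.9959 * dP[mmHg] / Q[L/min]``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal

import yaml

__all__ = [
    "MMHG_PER_PA",
    "DYN_PER_MMHG_MIN_L",
    "TRANSDUCER_LIMIT_MMHG",
    "FluidProperties",
    "CannulaSpec",
    "ConduitSpec",
    "PumpSpec",
    "InvalidGeometryError",
    "SpeedBoundsError",
    "french_to_inner_diameter",
    "poiseuille_k1",
    "element_dp",
    "pump_head",
    "cannula_inlet_pressure",
    "reynolds_number",
    "load_catalogue",
]

logger = logging.getLogger(__name__)

MMHG_PER_PA = 1.0 / 133.322
#: dyn.s.cm-5 per (mmHg per L/min); the exact clinical conversion factor.
DYN_PER_MMHG_MIN_L = 79.9959
#: Saturation limit of the bench pressure transducers, mmHg.
TRANSDUCER_LIMIT_MMHG = 357.0

_LPM_TO_M3S = 1.0 / 60000.0


class InvalidGeometryError(ValueError):
    """Raised when a cannula geometry yields a non-positive inner diameter."""


class SpeedBoundsError(ValueError):
    """Raised when a pump speed falls outside [0, omega_max]."""


@dataclass(frozen=True)
class FluidProperties:
    """Working fluid: a 60/40 w/w water-glycerol blood analogue.

    viscosity_cp
        Dynamic viscosity in centipoise (default 3.6, the physiological
        range of blood at 37 C).
    density_kg_m3
        Mass density; 1099 kg/m3 for the 60/40 mixture at room temperature.
    """

    viscosity_cp: float = 3.6
    density_kg_m3: float = 1099.0

    def __post_init__(self) -> None:
        if self.viscosity_cp <= 0 or self.density_kg_m3 <= 1000.0:
            raise ValueError("viscosity must be positive and density > 1000 kg/m3")

    @property
    def viscosity_pa_s(self) -> float:
        return self.viscosity_cp * 1e-3


def french_to_inner_diameter(size_fr: float, wall_mm: float) -> float:
    """Inner diameter in metres of a cannula of given French gauge.

    The French gauge gives the outer diameter in mm as Fr/3; subtracting
    twice the wall thickness yields the lumen.
    """
    if size_fr < 4:
        raise InvalidGeometryError(f"French size {size_fr} below minimum of 4")
    id_mm = size_fr / 3.0 - 2.0 * wall_mm
    if id_mm <= 0:
        raise InvalidGeometryError(
            f"{size_fr} Fr with {wall_mm} mm wall has non-positive lumen"
        )
    return id_mm / 1000.0


def poiseuille_k1(
    inner_diameter_m: float, length_m: float, fluid: FluidProperties | None = None
) -> float:
    """Laminar (Hagen-Poiseuille) resistance in mmHg per L/min.

    ``dP = 128 * mu * L / (pi * d^4) * Q`` evaluated in SI and converted.
    """
    if inner_diameter_m <= 0 or length_m <= 0:
        raise ValueError("diameter and length must be positive")
    fluid = fluid or FluidProperties()
    r_si = 128.0 * fluid.viscosity_pa_s * length_m / (math.pi * inner_diameter_m**4)
    return r_si * _LPM_TO_M3S * MMHG_PER_PA


def element_dp(k1: float, k2: float, q_lpm: float) -> float:
    """Pressure drop of one lumped element, mmHg; odd and monotone in Q."""
    return k1 * q_lpm + k2 * q_lpm * abs(q_lpm)


def reynolds_number(
    inner_diameter_m: float, q_lpm: float, fluid: FluidProperties | None = None
) -> float:
    """Diagnostic pipe Reynolds number Re = 4*rho*Q/(pi*mu*d).

    Logged for every element when circuits are assembled; purely
    informational -- the loss law never branches on it.
    """
    fluid = fluid or FluidProperties()
    q_si = abs(q_lpm) * _LPM_TO_M3S
    return 4.0 * fluid.density_kg_m3 * q_si / (
        math.pi * fluid.viscosity_pa_s * inner_diameter_m
    )


@dataclass(frozen=True)
class CannulaSpec:
    """One cannula of the hardware catalogue.

    ``k1`` is derived from geometry via :func:`poiseuille_k1`; ``k2`` lumps
    all minor and transitional losses (side holes of the multi-stage
    drainage cannulae included) and comes from calibration.  ``length_m``
    is the hydraulic length (inserted + external), a bounded calibration
    parameter because the bench rig's exact lengths are not documented.
    """

    role: Literal["arterial", "drainage"]
    size_fr: int
    wall_mm: float = 0.5
    length_m: float = 0.25
    stages: Literal["single", "multi"] = "single"
    k2: float = 0.0
    fluid: FluidProperties = field(default_factory=FluidProperties)

    ARTERIAL_SIZES = (13, 15, 17, 19, 21)
    DRAINAGE_SIZES = (21, 23, 25)

    def __post_init__(self) -> None:
        allowed = self.ARTERIAL_SIZES if self.role == "arterial" else self.DRAINAGE_SIZES
        if self.size_fr not in allowed:
            raise ValueError(f"{self.size_fr} Fr not in the {self.role} catalogue {allowed}")
        if self.k2 < 0:
            raise ValueError("k2 must be non-negative")
        # validates the lumen is positive
        french_to_inner_diameter(self.size_fr, self.wall_mm)

    @property
    def inner_diameter_m(self) -> float:
        return french_to_inner_diameter(self.size_fr, self.wall_mm)

    @property
    def k1(self) -> float:
        return poiseuille_k1(self.inner_diameter_m, self.length_m, self.fluid)

    def dp(self, q_lpm: float) -> float:
        return element_dp(self.k1, self.k2, q_lpm)

    def reynolds(self, q_lpm: float) -> float:
        re = reynolds_number(self.inner_diameter_m, q_lpm, self.fluid)
        logger.debug("Re=%.0f in %d Fr %s cannula at %.2f L/min",
                     re, self.size_fr, self.role, q_lpm)
        return re


@dataclass(frozen=True)
class ConduitSpec:
    """Straight conduit (tubing segment) or lumped oxygenator element."""

    inner_diameter_m: float
    length_m: float
    k2: float = 0.0
    #: when set, overrides the geometric Poiseuille term (used for the
    #: oxygenator, whose fibre bundle is not a single pipe)
    k1_override: float | None = None
    fluid: FluidProperties = field(default_factory=FluidProperties)

    def __post_init__(self) -> None:
        if self.inner_diameter_m <= 0 or self.length_m <= 0:
            raise ValueError("conduit geometry must be positive")
        if self.k2 < 0:
            raise ValueError("k2 must be non-negative")

    @property
    def k1(self) -> float:
        if self.k1_override is not None:
            return self.k1_override
        return poiseuille_k1(self.inner_diameter_m, self.length_m, self.fluid)

    def dp(self, q_lpm: float) -> float:
        return element_dp(self.k1, self.k2, q_lpm)


@dataclass(frozen=True)
class PumpSpec:
    """Centrifugal pump head surface H(omega, Q) = a2 w^2 + a1 w Q + a0 Q^2.

    ``w`` is the impeller speed in krpm, Q in L/min, H in mmHg.  The pure
    quadratic form satisfies the centrifugal affinity laws (shut-off head
    scales with w^2) and H(0, 0) = 0 by construction.
    """

    a2: float
    a1: float
    a0: float
    omega_max_rpm: float = 4500.0

    def __post_init__(self) -> None:
        if self.a2 <= 0:
            raise ValueError("a2 must be positive (shut-off head rises with speed)")
        if self.a0 > 0:
            raise ValueError("a0 must be <= 0 (head falls with flow)")

    def head(self, omega_rpm: float, q_lpm: float) -> float:
        return pump_head(self, omega_rpm, q_lpm)


def pump_head(pump: PumpSpec, omega_rpm: float, q_lpm: float) -> float:
    """Pump pressure head in mmHg at a given speed (rpm) and flow (L/min)."""
    if not 0.0 <= omega_rpm <= pump.omega_max_rpm:
        raise SpeedBoundsError(
            f"speed {omega_rpm} rpm outside [0, {pump.omega_max_rpm}]"
        )
    w = omega_rpm / 1000.0
    return pump.a2 * w * w + pump.a1 * w * q_lpm + pump.a0 * q_lpm * q_lpm


def cannula_inlet_pressure(
    arterial: CannulaSpec, q_lpm: float, aortic_pressure_mmhg: float
) -> tuple[float, bool]:
    """Pressure at the arterial-cannula sidearm port, with saturation flag.

    Returns the true computed value together with a flag that mirrors the
    bench transducers clipping at 357 mmHg; the value itself is never
    clipped.
    """
    if q_lpm < 0:
        raise ValueError("arterial cannula flow must be non-negative")
    p = aortic_pressure_mmhg + arterial.dp(q_lpm)
    return p, p > TRANSDUCER_LIMIT_MMHG


def load_catalogue(path: str | None = None) -> dict:
    """Load the hardware catalogue YAML (cannula sizes, tubing, pump bounds).

    The packaged default describes the bench circuit: 13-21 Fr single-stage
    arterial and 21-25 Fr multi-stage drainage cannulae with 0.5 mm walls,
    three 3/8-inch tubing segments (200/75/200 cm) and the pump speed limit.
    """
    if path is None:
        src = resources.files("ecmotwin.data").joinpath("catalogue.yaml")
        raw = yaml.safe_load(src.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return raw


def catalogue_cannula(
    catalogue: dict,
    role: str,
    size_fr: int,
    length_m: float | None = None,
    k2: float = 0.0,
) -> CannulaSpec:
    """Instantiate a CannulaSpec from a catalogue entry."""
    entry = next(
        c for c in catalogue["cannulae"] if c["role"] == role and c["size_fr"] == size_fr
    )
    return CannulaSpec(
        role=role,
        size_fr=size_fr,
        wall_mm=entry.get("wall_mm", 0.5),
        length_m=length_m if length_m is not None else entry.get("length_m", 0.25),
        stages=entry.get("stages", "single"),
        k2=k2,
    )
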
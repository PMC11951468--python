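"""Coupling of the ECMO branch to the closed-loop circulation.

The branch runs right-atrial chamber -> drainage cannula -> 200 cm tubing
-> centrifugal pump -> 75 cm tubing -> oxygenator -> 200 cm tubing ->
arterial cannula -> aorta distal to the arterial compliance (retrograde
femoral return).  Branch flow obeys

    L_e dQe/dt = P_ra + H(omega, Qe) - P_ao - sum_elements dp(Qe)

with the branch inertance L_e computed from tubing/cannula geometry
(rho * sum(L/A)) and held fixed.  Coupled operating points are solved by
time integration to the periodic state, preserving pulsatile MAP and valve
switching rather than collapsing to an algebraic fixed point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cardio import (
    CardioParams,
    ScenarioConfig,
    default_cardio_params,
    haemodynamic_metrics,
    simulate_to_periodic,
)
from .hydraulics import (
    CannulaSpec,
    ConduitSpec,
    FluidProperties,
    PumpSpec,
    TRANSDUCER_LIMIT_MMHG,
    french_to_inner_diameter,
)

__all__ = [
    "HydraulicParams",
    "CircuitConfig",
    "OperatingPoint",
    "build_circuit",
    "branch_inertance",
    "coupled_rhs",
    "run_operating_point",
    "find_speed_for_flow",
    "max_flow",
]

_TUBING_ID_M = 0.009525           # 3/8 inch
_TUBING_SEGMENTS_M = (2.0, 0.75, 2.0)
_MMHG_S_PER_LPM = 1.0 / (133.322 * 60000.0)  # Pa.s2/m3 -> mmHg.s/(L/min)

#: reference lumen diameters for the quadratic-loss scaling rule
_REF_ID_ART_M = french_to_inner_diameter(15, 0.5)
_REF_ID_DRAIN_M = french_to_inner_diameter(21, 0.5)


@dataclass(frozen=True)
class HydraulicParams:
    """Calibratable hydraulic parameter set of the circuit.

    Quadratic cannula losses follow the dynamic-head scaling
    ``k2(size) = k2_ref * (d_ref / d)**p`` within each role, anchored at
    the 15 Fr arterial and 21 Fr drainage lumens, so one coefficient per
    role covers the whole catalogue (p = 4 for the single-lumen arterial
    cannulae; calibrated for the multi-stage drainage ones).  Hydraulic
    lengths are shared per role (the rig's exact inserted + external
    lengths are undocumented).
    """

    l_art: float = 0.25       # m, arterial cannula hydraulic length
    l_drain: float = 0.50     # m, drainage cannula hydraulic length
    k2_art_ref: float = 12.0  # mmHg/(L/min)^2 at 15 Fr
    k2_drain_ref: float = 2.0  # mmHg/(L/min)^2 at 21 Fr drainage
    #: size exponent of the drainage k2 scaling; 4 is the rigid-pipe
    #: dynamic-head law, but side-hole recruitment in multi-stage cannulae
    #: makes the effective-area scaling uncertain, so it is calibrated
    drain_scale_exp: float = 4.0
    k1_ox: float = 8.0        # mmHg per L/min, lumped oxygenator
    a2: float = 28.0          # pump head surface, omega in krpm
    a1: float = -4.0
    a0: float = -2.0

    def cannula(self, role: str, size_fr: int,
                fluid: FluidProperties | None = None) -> CannulaSpec:
        fluid = fluid or FluidProperties()
        d = french_to_inner_diameter(size_fr, 0.5)
        if role == "arterial":
            k2 = self.k2_art_ref * (_REF_ID_ART_M / d) ** 4
            return CannulaSpec(role="arterial", size_fr=size_fr,
                               length_m=self.l_art, k2=k2, fluid=fluid)
        k2 = self.k2_drain_ref * (_REF_ID_DRAIN_M / d) ** self.drain_scale_exp
        return CannulaSpec(role="drainage", size_fr=size_fr, stages="multi",
                           length_m=self.l_drain, k2=k2, fluid=fluid)


@dataclass(frozen=True)
class CircuitConfig:
    """Assembled ECMO hardware for one cannula combination."""

    arterial: CannulaSpec
    drainage: CannulaSpec
    segments: tuple[ConduitSpec, ...]
    oxygenator: ConduitSpec
    pump: PumpSpec
    l_e: float  # branch inertance, mmHg.s/(L/min)

    def __post_init__(self) -> None:
        if len(self.segments) != 3:
            raise ValueError("circuit has exactly three tubing segments")
        if self.l_e <= 0:
            raise ValueError("branch inertance must be positive")

    @property
    def k1_total(self) -> float:
        return (self.arterial.k1 + self.drainage.k1 + self.oxygenator.k1
                + sum(s.k1 for s in self.segments))

    @property
    def k2_total(self) -> float:
        return (self.arterial.k2 + self.drainage.k2 + self.oxygenator.k2
                + sum(s.k2 for s in self.segments))

    def circuit_dp(self, q_lpm: float) -> float:
        """Total passive pressure drop of the branch at flow Q."""
        return self.k1_total * q_lpm + self.k2_total * q_lpm * abs(q_lpm)

    def lumped(self) -> dict[str, float]:
        return {
            "l_e": self.l_e, "k1_tot": self.k1_total, "k2_tot": self.k2_total,
            "a2": self.pump.a2, "a1": self.pump.a1, "a0": self.pump.a0,
        }


def branch_inertance(arterial: CannulaSpec, drainage: CannulaSpec,
                     fluid: FluidProperties | None = None) -> float:
    """Fluid inertance rho * sum(L/A) of the whole branch, mmHg.s/(L/min)."""
    fluid = fluid or FluidProperties()
    total = sum(seg / (math.pi / 4.0 * _TUBING_ID_M**2)
                for seg in _TUBING_SEGMENTS_M)
    for can in (arterial, drainage):
        a = math.pi / 4.0 * can.inner_diameter_m**2
        total += can.length_m / a
    return fluid.density_kg_m3 * total * _MMHG_S_PER_LPM


def build_circuit(arterial_fr: int, drainage_fr: int,
                  hyd: HydraulicParams | None = None,
                  fluid: FluidProperties | None = None) -> CircuitConfig:
    """Assemble the full circuit for one cannula combination."""
    hyd = hyd or HydraulicParams()
    fluid = fluid or FluidProperties()
    arterial = hyd.cannula("arterial", arterial_fr, fluid)
    drainage = hyd.cannula("drainage", drainage_fr, fluid)
    segments = tuple(
        ConduitSpec(inner_diameter_m=_TUBING_ID_M, length_m=seg, fluid=fluid)
        for seg in _TUBING_SEGMENTS_M
    )
    oxygenator = ConduitSpec(inner_diameter_m=0.02, length_m=0.1,
                             k1_override=hyd.k1_ox, fluid=fluid)
    pump = PumpSpec(a2=hyd.a2, a1=hyd.a1, a0=hyd.a0)
    return CircuitConfig(
        arterial=arterial, drainage=drainage, segments=segments,
        oxygenator=oxygenator, pump=pump,
        l_e=branch_inertance(arterial, drainage, fluid),
    )


@dataclass(frozen=True)
class OperatingPoint:
    """One steady-state record of the coupled patient + circuit system."""

    arterial_fr: int
    drainage_fr: int
    svr: float
    pvr: float
    omega_rpm: float
    q_ecmo: float
    map: float
    co: float
    total_flow: float
    rap: float
    lap: float
    inlet_pressure: float
    saturated: bool
    collapse: bool
    n_beats: int = 0

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def coupled_rhs(t: float, state: np.ndarray, cardio: CardioParams,
                scenario: ScenarioConfig, circuit: CircuitConfig,
                omega_rpm: float) -> np.ndarray:
    """Time derivative of the coupled state (reference entry point).

    The last state entry is the branch flow Qe;
    ``L_e dQe/dt = P_ra + H(omega, Qe) - P_ao - circuit_dp(Qe)``, while the
    drainage withdraws Qe from the right-atrial node and the return adds it
    to the aortic node.  With the pump clamped (omega = 0 and Qe = 0) this
    reduces exactly to the native-circulation derivative.
    """
    from .cardio import cardio_rhs

    return cardio_rhs(t, state, cardio, scenario, circuit.lumped(),
                      mode=1, drive=omega_rpm / 1000.0)


def _summarize(sol, scenario, circuit, omega_rpm) -> OperatingPoint:
    h = haemodynamic_metrics(sol)
    if sol.states.shape[0] > 1:
        q = sol.states[:, 10]
        p_sa = sol.states[:, 4]
        inlet = float(np.mean(p_sa + circuit.arterial.k1 * q
                              + circuit.arterial.k2 * q * np.abs(q)))
    else:
        inlet = h["map"] + circuit.arterial.dp(h["q_ecmo"])
    return OperatingPoint(
        arterial_fr=circuit.arterial.size_fr,
        drainage_fr=circuit.drainage.size_fr,
        svr=scenario.svr, pvr=scenario.pvr, omega_rpm=float(omega_rpm),
        q_ecmo=h["q_ecmo"], map=h["map"], co=h["co"],
        total_flow=h["co"] + h["q_ecmo"], rap=h["rap"], lap=h["lap"],
        inlet_pressure=inlet,
        saturated=inlet > TRANSDUCER_LIMIT_MMHG,
        collapse=h["rap"] <= 0.0,
        n_beats=sol.n_beats,
    )


def _cache_key(scenario: ScenarioConfig, circuit: CircuitConfig) -> tuple:
    return (circuit.arterial.size_fr, circuit.drainage.size_fr,
            scenario.svr, scenario.pvr)


def run_operating_point(
    scenario: ScenarioConfig,
    circuit: CircuitConfig,
    omega_rpm: float,
    cardio: CardioParams | None = None,
    mode: int = 1,
    q_set: float = 0.0,
    dt_ms: float = 1.0,
    record: bool = False,
    state_cache: dict | None = None,
    tol_map: float = 0.1,
    tol_co: float = 0.02,
) -> OperatingPoint:
    """Converge the coupled system at a fixed pump speed and summarize it.

    ``mode=1`` drives the branch with the pump at ``omega_rpm``; ``mode=2``
    clamps branch flow at ``q_set`` (flow-setpoint experiments); ``mode=0``
    clamps the branch entirely.  ``state_cache`` (keyed per configuration)
    warm-starts the integration from a previously converged state, which
    cuts the beat count during sweeps and calibration.
    """
    cardio = cardio or default_cardio_params()
    if mode == 1 and not 0.0 <= omega_rpm <= circuit.pump.omega_max_rpm:
        raise ValueError(f"omega {omega_rpm} outside [0, {circuit.pump.omega_max_rpm}]")
    y0 = None
    key = None
    if state_cache is not None:
        key = _cache_key(scenario, circuit)
        y0 = state_cache.get(key)
    drive = omega_rpm / 1000.0 if mode == 1 else q_set
    sol = simulate_to_periodic(
        scenario, cardio, dt_ms=dt_ms, circuit_lumped=circuit.lumped(),
        mode=mode, drive=drive, y0=y0, record=record,
        tol_map=tol_map, tol_co=tol_co,
    )
    if state_cache is not None:
        state_cache[key] = sol.final_state
    return _summarize(sol, scenario, circuit, omega_rpm)


def max_flow(scenario: ScenarioConfig, circuit: CircuitConfig,
             cardio: CardioParams | None = None, **kw) -> float:
    """ECMO branch flow at maximum pump speed (4500 rpm), L/min."""
    op = run_operating_point(scenario, circuit, circuit.pump.omega_max_rpm,
                             cardio, **kw)
    return op.q_ecmo


def find_speed_for_flow(
    scenario: ScenarioConfig,
    circuit: CircuitConfig,
    q_target: float,
    cardio: CardioParams | None = None,
    xtol_rpm: float = 2.0,
    state_cache: dict | None = None,
    dt_ms: float = 1.0,
) -> float | None:
    """Pump speed (rpm) delivering a steady ECMO flow, or None if infeasible.

    Bracketing secant/bisection root search on the steady flow-speed curve,
    which is monotone increasing for every valid configuration; the search
    verifies the bracket and raises if the response is non-monotone.
    """
    from scipy.optimize import brentq

    if q_target <= 0:
        raise ValueError("q_target must be positive")
    cardio = cardio or default_cardio_params()
    cache = state_cache if state_cache is not None else {}

    def steady_q(omega):
        return run_operating_point(scenario, circuit, omega, cardio,
                                   state_cache=cache, dt_ms=dt_ms).q_ecmo

    w_hi = circuit.pump.omega_max_rpm
    q_hi = steady_q(w_hi)
    if q_hi < q_target:
        return None
    # lower bracket: speed at which pump head roughly balances MAP - RAP
    w_lo = min(0.6 * w_hi, 1000.0 * math.sqrt(60.0 / circuit.pump.a2))
    q_lo = steady_q(w_lo)
    while q_lo > q_target and w_lo > 200.0:
        w_lo *= 0.7
        q_lo = steady_q(w_lo)
    if q_lo > q_target:
        raise RuntimeError("flow-speed response not bracketable from below")
    if q_lo >= q_hi:
        raise RuntimeError("flow-speed response is not monotone increasing")
    return float(brentq(lambda w: steady_q(w) - q_target, w_lo, w_hi,
                        xtol=xtol_rpm))
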
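"""Closed-loop heart + five-element Windkessel model of the bench patient.

The simulated patient is acute cardiogenic shock: severe left-ventricular
dysfunction (low end-systolic elastance) with preserved right-ventricular
function, heart rate 80 bpm, and systemic/pulmonary vascular resistance set
per scenario.  Chambers follow the time-varying-elastance law
``P = E(t) * (V - V0)`` with a double-Hill activation waveform; each
vascular bed is a five-element Windkessel (characteristic resistance,
arterial compliance, inertance + peripheral resistance, venous compliance).
Frank-Starling behaviour is implicit in the elastance formulation: output
rises with preload and falls with afterload, which is what makes the native
cardiac output respond to SVR and to ECMO support.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import _core
from .hydraulics import DYN_PER_MMHG_MIN_L

__all__ = [
    "ChamberParams",
    "WindkesselParams",
    "ScenarioConfig",
    "CardioParams",
    "CardioState",
    "PeriodicSolution",
    "ConvergenceError",
    "IntegrationError",
    "double_hill",
    "activation_samples",
    "elastance",
    "valve_flow",
    "cardio_rhs",
    "default_cardio_params",
    "initial_state",
    "pack_params",
    "simulate_to_periodic",
    "haemodynamic_metrics",
]

#: protocol grid of the bench experiment, dyn.s.cm-5
SVR_GRID = (2500, 1600, 1000)
PVR_GRID = (300, 100, 60)


class ConvergenceError(RuntimeError):
    """Periodic steady state not reached within the beat budget."""


class IntegrationError(RuntimeError):
    """State became non-finite during integration."""


@dataclass(frozen=True)
class ChamberParams:
    """Time-varying elastance chamber: P = E(t) (V - V0)."""

    emax: float  # mmHg/mL, end-systolic elastance
    emin: float  # mmHg/mL, end-diastolic elastance
    v0: float    # mL, unstressed volume
    activation_offset: float = 0.0  # fraction of cycle; atria fire early

    def __post_init__(self) -> None:
        if not (self.emax >= self.emin > 0):
            raise ValueError("need emax >= emin > 0")
        if self.v0 < 0:
            raise ValueError("v0 must be >= 0")


@dataclass(frozen=True)
class WindkesselParams:
    """Five-element Windkessel bed.

    Resistances in mmHg.min/L (converted from dyn.s.cm-5 at the interface),
    compliances in mL/mmHg, inertance in mmHg.s/(L/min).  ``r_ven`` is the
    small venous-return resistance from the venous compliance chamber into
    the atrium.
    """

    rc: float
    rp: float
    c_art: float
    l_art: float
    cv: float
    r_ven: float

    def __post_init__(self) -> None:
        for name in ("rc", "rp", "c_art", "l_art", "cv", "r_ven"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def total_resistance_dyn(self) -> float:
        return (self.rc + self.rp) * DYN_PER_MMHG_MIN_L


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulated disease condition of the protocol grid."""

    svr: float = 2500.0   # dyn.s.cm-5
    pvr: float = 100.0    # dyn.s.cm-5
    heart_rate: float = 80.0  # bpm
    contractility: str = "severe-lv-failure"

    @property
    def period_s(self) -> float:
        return 60.0 / self.heart_rate

    @classmethod
    def from_yaml(cls, path: str) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            svr=float(raw.get("svr", 2500)),
            pvr=float(raw.get("pvr", 100)),
            heart_rate=float(raw.get("hr", raw.get("heart_rate", 80))),
            contractility=raw.get("contractility", "severe-lv-failure"),
        )


@dataclass(frozen=True)
class CardioParams:
    """Full cardiac + vascular parameter set (scenario resistances excluded).

    ``rc_fraction`` fixes the characteristic resistance at a fraction of the
    scenario's total SVR/PVR; ``v_total`` is the stressed circulating volume
    that the calibration adjusts to set preload.
    """

    lv: ChamberParams
    la: ChamberParams
    rv: ChamberParams
    ra: ChamberParams
    r_valve: float = 0.05          # mmHg.min/L, all four valves
    v_total: float = 690.0         # mL stressed volume
    rc_fraction: float = 0.05
    c_sa: float = 1.2
    l_sa: float = 0.25
    cv_s: float = 25.0
    r_vs: float = 1.0
    c_pa: float = 3.5
    l_pa: float = 0.10
    cv_p: float = 8.0
    r_vp: float = 0.5
    systolic_fraction: float = 0.3
    atrial_offset: float = -0.10   # atria activate this fraction before t=0


def default_cardio_params(**overrides) -> CardioParams:
    """Severe-LV-failure preset: depressed LV elastance, preserved RV,
    passive atria with weak contraction (emax = 2 emin)."""
    base = CardioParams(
        lv=ChamberParams(emax=0.41, emin=0.065, v0=10.0),
        la=ChamberParams(emax=0.30, emin=0.15, v0=5.0),
        rv=ChamberParams(emax=0.90, emin=0.05, v0=10.0),
        ra=ChamberParams(emax=0.24, emin=0.12, v0=5.0),
    )
    return replace(base, **overrides) if overrides else base


# -- activation --------------------------------------------------------------

def double_hill(phase: np.ndarray, systolic_fraction: float = 0.3,
                n1: float = 1.9, n2: float = 21.9) -> np.ndarray:
    """Normalized double-Hill activation over phase in [0, 1).

    Product of an ascending and a descending Hill function, rescaled to
    span exactly [0, 1]; the descending half-time sits at the systolic
    fraction of the cycle so ejection occupies roughly 30% of the beat.
    """
    phase = np.asarray(phase, dtype=float) % 1.0
    a1 = 0.5 * systolic_fraction
    a2 = systolic_fraction
    x1 = (phase / a1) ** n1
    up = x1 / (1.0 + x1)
    down = 1.0 / (1.0 + (phase / a2) ** n2)
    e = up * down
    # normalize on a fine grid so max == 1 exactly for any exponents
    pg = np.linspace(0.0, 1.0, 2001)
    xg = (pg / a1) ** n1
    eg = xg / (1.0 + xg) / (1.0 + (pg / a2) ** n2)
    return e / eg.max()


def activation_samples(params: CardioParams, nsteps: int) -> tuple[np.ndarray, np.ndarray]:
    """Ventricular and atrial activation sampled at 2*nsteps+1 points/beat."""
    phase = np.arange(2 * nsteps + 1) / (2.0 * nsteps)
    act_v = double_hill(phase, params.systolic_fraction)
    act_a = double_hill(phase - params.atrial_offset,
                        0.25 * params.systolic_fraction / 0.3)
    return act_v, act_a


def elastance(t_s: float, chamber: ChamberParams, heart_rate: float,
              systolic_fraction: float = 0.3) -> float:
    """Instantaneous elastance in mmHg/mL at time t (periodic in 60/HR)."""
    if t_s < 0:
        raise ValueError("time must be non-negative")
    period = 60.0 / heart_rate
    phase = (t_s / period) - chamber.activation_offset
    e = float(double_hill(np.array([phase]), systolic_fraction)[0])
    return chamber.emin + (chamber.emax - chamber.emin) * e


def valve_flow(p_up: float, p_down: float, r_valve: float) -> float:
    """Ideal-diode valve: forward flow only, L/min."""
    if r_valve <= 0:
        raise ValueError("valve resistance must be positive")
    return max(0.0, p_up - p_down) / r_valve


# -- packing and state -------------------------------------------------------

STATE_NAMES = ("V_la", "V_lv", "V_ra", "V_rv", "P_sa", "P_sv", "P_pa", "P_pv",
               "Q_sa", "Q_pa", "Q_e")


@dataclass
class CardioState:
    """Instantaneous model state; thin named wrapper over the core vector."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (_core.NSTATE,):
            raise ValueError(f"state must have {_core.NSTATE} entries")

    def __getattr__(self, name):
        if name in STATE_NAMES:
            return self.values[STATE_NAMES.index(name)]
        raise AttributeError(name)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(STATE_NAMES, self.values))


def systemic_windkessel(params: CardioParams, svr_dyn: float) -> WindkesselParams:
    r_tot = svr_dyn / DYN_PER_MMHG_MIN_L
    return WindkesselParams(
        rc=params.rc_fraction * r_tot, rp=(1 - params.rc_fraction) * r_tot,
        c_art=params.c_sa, l_art=params.l_sa, cv=params.cv_s, r_ven=params.r_vs,
    )


def pulmonary_windkessel(params: CardioParams, pvr_dyn: float) -> WindkesselParams:
    r_tot = pvr_dyn / DYN_PER_MMHG_MIN_L
    return WindkesselParams(
        rc=params.rc_fraction * r_tot, rp=(1 - params.rc_fraction) * r_tot,
        c_art=params.c_pa, l_art=params.l_pa, cv=params.cv_p, r_ven=params.r_vp,
    )


def pack_params(params: CardioParams, scenario: ScenarioConfig,
                circuit_lumped: Mapping[str, float] | None = None) -> np.ndarray:
    """Flatten parameters into the core's float vector.

    ``circuit_lumped`` supplies the ECMO branch terms: l_e, k1_tot, k2_tot,
    a2, a1, a0 (zeros when the branch is clamped).
    """
    p = np.zeros(_core.NPARAMS)
    i = _core.PIDX
    sw = systemic_windkessel(params, scenario.svr)
    pw = pulmonary_windkessel(params, scenario.pvr)
    p[i["hr"]] = scenario.heart_rate
    for name, ch in (("lv", params.lv), ("la", params.la),
                     ("rv", params.rv), ("ra", params.ra)):
        p[i[f"emax_{name}"]] = ch.emax
        p[i[f"emin_{name}"]] = ch.emin
        p[i[f"v0_{name}"]] = ch.v0
    for v in ("r_mv", "r_av", "r_tv", "r_pv"):
        p[i[v]] = params.r_valve
    p[i["rc_s"]], p[i["rp_s"]] = sw.rc, sw.rp
    p[i["c_sa"]], p[i["l_sa"]] = sw.c_art, sw.l_art
    p[i["cv_s"]], p[i["r_vs"]] = sw.cv, sw.r_ven
    p[i["rc_p"]], p[i["rp_p"]] = pw.rc, pw.rp
    p[i["c_pa"]], p[i["l_pa"]] = pw.c_art, pw.l_art
    p[i["cv_p"]], p[i["r_vp"]] = pw.cv, pw.r_ven
    if circuit_lumped is not None:
        p[i["l_e"]] = circuit_lumped["l_e"]
        p[i["k1_tot"]] = circuit_lumped["k1_tot"]
        p[i["k2_tot"]] = circuit_lumped["k2_tot"]
        p[i["a2"]] = circuit_lumped["a2"]
        p[i["a1"]] = circuit_lumped["a1"]
        p[i["a0"]] = circuit_lumped["a0"]
    else:
        p[i["l_e"]] = 1.0  # unused when the branch is clamped
    return p


def initial_state(params: CardioParams, scenario: ScenarioConfig) -> np.ndarray:
    """Nominal starting state with the venous reservoir absorbing v_total."""
    y = np.zeros(_core.NSTATE)
    y[0], y[1], y[2], y[3] = 40.0, 100.0, 40.0, 100.0  # V_la V_lv V_ra V_rv
    y[4], y[6], y[7] = 55.0, 18.0, 8.0                 # P_sa P_pa P_pv
    committed = (y[0] + y[1] + y[2] + y[3]
                 + params.c_sa * y[4] + params.c_pa * y[6] + params.cv_p * y[7])
    y[5] = (params.v_total - committed) / params.cv_s   # P_sv
    y[8], y[9] = 2.0, 2.0
    return y


def cardio_rhs(t: float, state: np.ndarray, params: CardioParams,
               scenario: ScenarioConfig,
               circuit_lumped: Mapping[str, float] | None = None,
               mode: int = 0, drive: float = 0.0) -> np.ndarray:
    """Reference time-derivative of the state (used with scipy integrators).

    Evaluates the same equations as the compiled kernel with activation
    computed continuously in time; mass conservation (sum of all compartment
    volume derivatives = 0 in the closed loop) holds by construction.
    """
    state = np.asarray(state, dtype=float)
    if not np.isfinite(state).all():
        raise IntegrationError("non-finite state")
    p = pack_params(params, scenario, circuit_lumped)
    phase = (t / scenario.period_s)
    ev = float(double_hill(np.array([phase]), params.systolic_fraction)[0])
    frac_a = 0.25 * params.systolic_fraction / 0.3
    ea = float(double_hill(np.array([phase - params.atrial_offset]), frac_a)[0])
    dy = np.empty(_core.NSTATE)
    _core._rhs(state, dy, ev, ea, p, mode, drive)
    return dy


@dataclass
class PeriodicSolution:
    """Converged periodic solution of one scenario (one full cycle stored)."""

    time_s: np.ndarray
    states: np.ndarray           # (nsteps+1, 11)
    metrics: np.ndarray          # core metric vector
    n_beats: int
    converged: bool
    scenario: ScenarioConfig
    params: CardioParams
    final_state: np.ndarray

    def waveforms(self) -> pd.DataFrame:
        """Tidy per-cycle waveform table (time, pressures, flows, volumes)."""
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_s", self.time_s)
        # chamber pressures reconstructed from elastance
        n = len(self.time_s) - 1
        act_v, act_a = activation_samples(self.params, n)
        ev, ea = act_v[::2], act_a[::2]
        for ch, col, act in (
            (self.params.la, "V_la", ea), (self.params.lv, "V_lv", ev),
            (self.params.ra, "V_ra", ea), (self.params.rv, "V_rv", ev),
        ):
            e = ch.emin + (ch.emax - ch.emin) * act
            df["P_" + col[2:].lower()] = e * (df[col].to_numpy() - ch.v0)
        return df

    def to_csv(self, path: str) -> None:
        self.waveforms().to_csv(path, index=False)


def simulate_to_periodic(
    scenario: ScenarioConfig,
    params: CardioParams,
    max_beats: int = 400,
    tol_map: float = 0.1,
    tol_co: float = 0.02,
    dt_ms: float = 1.0,
    circuit_lumped: Mapping[str, float] | None = None,
    mode: int = 0,
    drive: float = 0.0,
    y0: np.ndarray | None = None,
    record: bool = True,
) -> PeriodicSolution:
    """Integrate beats until cycle-averaged MAP/CO/ECMO flow settle.

    Convergence requires consecutive-beat changes below ``tol_map`` (mmHg)
    and ``tol_co`` (L/min).  Raises :class:`ConvergenceError` with the last
    residual if the budget is exhausted, :class:`IntegrationError` on
    numerical blow-up.
    """
    if tol_map <= 0 or tol_co <= 0:
        raise ValueError("tolerances must be positive")
    p = pack_params(params, scenario, circuit_lumped)
    nsteps = max(50, int(round(scenario.period_s * 1000.0 / dt_ms)))
    dt = scenario.period_s / nsteps
    act_v, act_a = activation_samples(params, nsteps)
    if y0 is None:
        y0 = initial_state(params, scenario)
    y0 = np.asarray(y0, float).copy()
    if mode in (0, 2):
        # branch flow is a held constant in these modes: clamp it explicitly
        # so a warm-start state from another drive mode cannot leak through
        y0[10] = drive if mode == 2 else 0.0
    # the closed loop conserves volume, so the stressed volume v_total must
    # be imposed on the start state (warm starts included): absorb any
    # mismatch into the systemic venous reservoir
    v_now = float(y0[0] + y0[1] + y0[2] + y0[3] + params.c_sa * y0[4]
                  + params.cv_s * y0[5] + params.c_pa * y0[6]
                  + params.cv_p * y0[7])
    y0[5] += (params.v_total - v_now) / params.cv_s
    y, metrics, n, converged, traj = _core.integrate_to_periodic(
        np.asarray(y0, float), p, act_v, act_a, dt, nsteps, mode, drive,
        max_beats, tol_map, tol_co, record,
    )
    if not np.isfinite(metrics).all() or not np.isfinite(y).all():
        raise IntegrationError(
            f"integration diverged after {n} beats (scenario svr={scenario.svr})"
        )
    if not converged:
        raise ConvergenceError(
            f"no periodic state in {max_beats} beats; last MAP={metrics[0]:.2f}"
        )
    time_s = np.arange(traj.shape[0]) * dt if record else np.zeros(1)
    return PeriodicSolution(time_s, traj, metrics, n, converged, scenario,
                            params, y)


def haemodynamic_metrics(sol: PeriodicSolution) -> dict[str, float]:
    """Cycle-averaged haemodynamics of a converged solution.

    CO is the cycle-averaged aortic-valve flow; pressures are beat means.
    """
    m = sol.metrics
    i = _core.MIDX
    return {
        "map": float(m[i["map"]]),
        "co": float(m[i["co"]]),
        "q_ecmo": float(m[i["q_e"]]),
        "rap": float(m[i["rap"]]),
        "lap": float(m[i["lap"]]),
        "pap": float(m[i["pap"]]),
        "p_sv": float(m[i["p_sv"]]),
        "stroke_volume": float(m[i["sv_lv"]]),
        "total_flow": float(m[i["co"]] + m[i["q_e"]]),
        "sys_pressure": float(m[i["p_sa_max"]]),
        "dia_pressure": float(m[i["p_sa_min"]]),
    }
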
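"""Full factorial protocol sweep and derived findings.

Reproduces the bench protocol: every arterial size (13-21 Fr) x drainage
size (21-25 Fr) x SVR state x PVR state, with ECMO flow setpoints from
1 L/min upward in 1 L/min increments to the maximum the pump can deliver,
plus the maximum-speed point itself.  Emits tidy per-figure tables (inlet
pressure vs flow, total flow vs speed, MAP vs speed) and a findings report
(drainage-size interaction, SVR effect on maximum flow, PVR sensitivity,
collapse map).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import cardio_from_params, hydraulics_from_params, load_params
from .cardio import PVR_GRID, SVR_GRID, ScenarioConfig
from .coupling import build_circuit, find_speed_for_flow, run_operating_point

__all__ = ["full_sweep", "figure_tables", "findings_report", "SWEEP_COLUMNS"]

logger = logging.getLogger(__name__)

ARTERIAL_SIZES = (13, 15, 17, 19, 21)
DRAINAGE_SIZES = (21, 23, 25)

SWEEP_COLUMNS = [
    "arterial_fr", "drainage_fr", "svr", "pvr", "setpoint", "omega_rpm",
    "q_ecmo", "map", "co", "total_flow", "rap", "lap", "inlet_pressure",
    "saturated", "collapse",
]


def _op_row(op, setpoint: str) -> dict:
    d = op.as_dict()
    d.pop("n_beats")
    d["setpoint"] = setpoint
    return d


def full_sweep(
    params: dict[str, float] | None = None,
    arterial_sizes=ARTERIAL_SIZES,
    drainage_sizes=DRAINAGE_SIZES,
    svr_grid=SVR_GRID,
    pvr_grid=PVR_GRID,
    dt_ms: float = 1.0,
) -> pd.DataFrame:
    """Run the whole protocol grid with a calibrated parameter set.

    Returns one row per (configuration, setpoint) in a fixed deterministic
    order.  Setpoints are the 1 L/min increments that are feasible below
    maximum pump speed, then the maximum-speed point.  Failures are logged
    and recorded as NaN rows; the sweep continues.
    """
    params = params if params is not None else load_params()
    cardio = cardio_from_params(params)
    hyd = hydraulics_from_params(params)
    rows: list[dict] = []
    for art, drain, svr, pvr in itertools.product(
            arterial_sizes, drainage_sizes, svr_grid, pvr_grid):
        scenario = ScenarioConfig(svr=svr, pvr=pvr)
        circuit = build_circuit(art, drain, hyd)
        cache: dict = {}
        try:
            op_max = run_operating_point(
                scenario, circuit, circuit.pump.omega_max_rpm, cardio,
                dt_ms=dt_ms, state_cache=cache)
        except Exception as exc:
            logger.warning("max-speed point failed for %s/%s svr=%s pvr=%s: %s",
                           art, drain, svr, pvr, exc)
            rows.append({"arterial_fr": art, "drainage_fr": drain,
                         "svr": svr, "pvr": pvr, "setpoint": "max"})
            continue
        q_max = op_max.q_ecmo
        for q in range(1, int(np.floor(q_max)) + 1):
            try:
                omega = find_speed_for_flow(scenario, circuit, float(q),
                                            cardio, state_cache=cache,
                                            dt_ms=dt_ms)
                if omega is None:
                    continue
                op = run_operating_point(scenario, circuit, omega, cardio,
                                         dt_ms=dt_ms, state_cache=cache)
                rows.append(_op_row(op, f"{q}L"))
            except Exception as exc:
                logger.warning("setpoint %d failed for %s/%s svr=%s pvr=%s: %s",
                               q, art, drain, svr, pvr, exc)
                rows.append({"arterial_fr": art, "drainage_fr": drain,
                             "svr": svr, "pvr": pvr, "setpoint": f"{q}L"})
        rows.append(_op_row(op_max, "max"))
    grid = pd.DataFrame(rows)
    for col in SWEEP_COLUMNS:
        if col not in grid.columns:
            grid[col] = np.nan
    return grid[SWEEP_COLUMNS]


def figure_tables(grid: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Tidy tables mirroring the bench figures.

    inlet_pressure_vs_flow: cannula inlet pressure against ECMO flow by
    arterial/drainage size and SVR (saturated points flagged, values kept);
    total_flow_vs_speed and map_vs_speed: patient support against pump
    speed.
    """
    if grid.empty:
        empty = pd.DataFrame()
        return {"inlet_pressure_vs_flow": empty, "total_flow_vs_speed": empty,
                "map_vs_speed": empty}
    ok = grid.dropna(subset=["omega_rpm"])
    f2 = ok[["arterial_fr", "drainage_fr", "svr", "pvr", "q_ecmo",
             "inlet_pressure", "saturated"]].copy()
    f3 = ok[["arterial_fr", "drainage_fr", "svr", "pvr", "omega_rpm",
             "total_flow"]].copy()
    f4 = ok[["arterial_fr", "drainage_fr", "svr", "pvr", "omega_rpm",
             "map"]].copy()
    return {"inlet_pressure_vs_flow": f2, "total_flow_vs_speed": f3,
            "map_vs_speed": f4}


def findings_report(grid: pd.DataFrame, pvr_ref: float = 100.0) -> dict:
    """Headline quantitative findings of the sweep.

    Computes the drainage-size interaction (gain in maximum ECMO flow from
    21 to 25 Fr drainage per arterial size), the SVR effect on maximum
    flow, PVR sensitivity (max relative change of flow/MAP across the PVR
    grid), and the RAP<=0 collapse map at maximum speed.
    """
    if grid.empty:
        return {"drainage_gain": {}, "svr_max_flow": {}, "pvr_sensitivity": {},
                "collapse_map": []}
    ok = grid.dropna(subset=["omega_rpm"])
    mx = ok[(ok["setpoint"] == "max") & (ok["pvr"] == pvr_ref)]

    drainage_gain = {}
    for art in sorted(mx["arterial_fr"].unique()):
        sub = mx[(mx["arterial_fr"] == art) & (mx["svr"] == 1600)]
        q21 = sub[sub["drainage_fr"] == 21]["q_ecmo"]
        q25 = sub[sub["drainage_fr"] == 25]["q_ecmo"]
        if len(q21) and len(q25):
            drainage_gain[int(art)] = float(q25.iloc[0] - q21.iloc[0])

    svr_max_flow = {}
    for art in sorted(mx["arterial_fr"].unique()):
        sub = mx[(mx["arterial_fr"] == art) & (mx["drainage_fr"] == 21)]
        svr_max_flow[int(art)] = {
            int(svr): float(sub[sub["svr"] == svr]["q_ecmo"].iloc[0])
            for svr in sorted(sub["svr"].unique())
        }

    # PVR sensitivity: relative change of q_ecmo and MAP across the PVR
    # grid at fixed speed (the max-speed points share omega exactly;
    # flow setpoints pin q_ecmo by construction so they carry no signal)
    rel_changes = []
    key_cols = ["arterial_fr", "drainage_fr", "svr"]
    for _, sub in ok[ok["setpoint"] == "max"].groupby(key_cols):
        if sub["pvr"].nunique() < 2:
            continue
        for col in ("q_ecmo", "map"):
            vals = sub[col].dropna()
            if len(vals) >= 2 and vals.abs().min() > 0:
                rel_changes.append(float(vals.max() / vals.min() - 1.0))
    pvr_sensitivity = {
        "max_relative_change": max(rel_changes) if rel_changes else float("nan"),
        "n_groups": len(rel_changes),
    }

    collapse = mx[mx["collapse"] == True]  # noqa: E712
    collapse_map = collapse[["arterial_fr", "drainage_fr", "svr"]].astype(int)
    return {
        "drainage_gain": drainage_gain,
        "svr_max_flow": svr_max_flow,
        "pvr_sensitivity": pvr_sensitivity,
        "collapse_map": collapse_map.to_dict("records"),
    }
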
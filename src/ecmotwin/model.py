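"""Model/Results front end for the calibrated digital twin.

``VAECMOModel`` is constructed from a fixture table of bench operating
points (the data); ``fit`` calibrates the free parameters and returns a
``VAECMOResults`` object carrying the estimates, residual diagnostics and
a ``summary()`` table, with simulation, speed search and the full protocol
sweep hanging off the results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import calibration as _cal
from .calibration import (
    CalibrationResult,
    FixtureTable,
    cardio_from_params,
    hydraulics_from_params,
    load_fixtures,
)
from .cardio import ScenarioConfig, haemodynamic_metrics, simulate_to_periodic
from .coupling import (
    OperatingPoint,
    build_circuit,
    find_speed_for_flow,
    max_flow,
    run_operating_point,
)
from .sweep import figure_tables, findings_report, full_sweep

__all__ = ["VAECMOModel", "VAECMOResults"]


class VAECMOModel:
    """Digital twin of the bench VA ECMO experiment, built from data.

    Parameters
    ----------
    fixtures
        Operating-point observations (``load_fixtures()`` gives the
        packaged bench table).

    Examples
    --------
    >>> model = VAECMOModel(load_fixtures())
    >>> res = model.fit(seed=0)
    >>> res.baseline(svr=2500)["co"]  # doctest: +SKIP
    2.0...
    """

    def __init__(self, fixtures: FixtureTable | None = None):
        self.fixtures = fixtures if fixtures is not None else load_fixtures()

    @classmethod
    def from_csv(cls, path: str) -> "VAECMOModel":
        return cls(load_fixtures(path))

    def fit(self, seed: int = 0, n_starts: int = 5, **kw) -> "VAECMOResults":
        res = _cal.fit(self.fixtures, seed=seed, n_starts=n_starts, **kw)
        return VAECMOResults(self, res)

    def results_from_params(self, params: dict[str, float]) -> "VAECMOResults":
        """Wrap a previously calibrated parameter set without refitting."""
        x = _cal.dict_to_params(params)
        r = _cal.residuals(x, self.fixtures)
        table = self.fixtures.frame.copy()
        preds = _cal.predict_fixtures(x, self.fixtures)
        table["predicted"] = [preds[rid] for rid in table["row_id"]]
        table["residual_sigma"] = r
        res = CalibrationResult(
            params=dict(params), x=x,
            weighted_rms=float(np.sqrt(np.mean(r**2))),
            residual_table=table, success=True, n_starts=0, start_costs=[],
            jacobian_rank=-1, n_params=len(x),
            message="parameters supplied, not fitted",
        )
        return VAECMOResults(self, res)


@dataclass
class VAECMOResults:
    """Calibrated twin: parameter estimates plus simulation methods."""

    model: VAECMOModel
    calibration: CalibrationResult

    @property
    def params(self) -> dict[str, float]:
        return self.calibration.params

    @property
    def weighted_rms(self) -> float:
        return self.calibration.weighted_rms

    @property
    def residuals(self) -> pd.DataFrame:
        return self.calibration.residual_table

    def summary(self) -> str:
        return self.calibration.summary()

    # -- simulation ---------------------------------------------------------

    def _objects(self):
        return (cardio_from_params(self.params),
                hydraulics_from_params(self.params))

    def baseline(self, svr: float, pvr: float = 100.0,
                 heart_rate: float = 80.0) -> dict[str, float]:
        """Native haemodynamics with the ECMO branch clamped."""
        cardio, _ = self._objects()
        sol = simulate_to_periodic(
            ScenarioConfig(svr=svr, pvr=pvr, heart_rate=heart_rate), cardio)
        return haemodynamic_metrics(sol)

    def simulate(self, arterial_fr: int, drainage_fr: int, svr: float,
                 omega_rpm: float, pvr: float = 100.0, **kw) -> OperatingPoint:
        """One coupled operating point at a fixed pump speed."""
        cardio, hyd = self._objects()
        circuit = build_circuit(arterial_fr, drainage_fr, hyd)
        return run_operating_point(
            ScenarioConfig(svr=svr, pvr=pvr), circuit, omega_rpm, cardio, **kw)

    def speed_for_flow(self, arterial_fr: int, drainage_fr: int, svr: float,
                       q_target: float, pvr: float = 100.0, **kw) -> float | None:
        cardio, hyd = self._objects()
        circuit = build_circuit(arterial_fr, drainage_fr, hyd)
        return find_speed_for_flow(
            ScenarioConfig(svr=svr, pvr=pvr), circuit, q_target, cardio, **kw)

    def max_flow(self, arterial_fr: int, drainage_fr: int, svr: float,
                 pvr: float = 100.0, **kw) -> float:
        cardio, hyd = self._objects()
        circuit = build_circuit(arterial_fr, drainage_fr, hyd)
        return max_flow(ScenarioConfig(svr=svr, pvr=pvr), circuit, cardio, **kw)

    # -- protocol -----------------------------------------------------------

    def sweep(self, **kw) -> pd.DataFrame:
        return full_sweep(self.params, **kw)

    def figure_tables(self, grid: pd.DataFrame | None = None):
        return figure_tables(grid if grid is not None else self.sweep())

    def findings(self, grid: pd.DataFrame | None = None):
        return findings_report(grid if grid is not None else self.sweep())

    def save_params(self, path: str) -> None:
        self.calibration.to_yaml(path)
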
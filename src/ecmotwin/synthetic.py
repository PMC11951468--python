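"""Synthetic noisy operating-point tables from a known ground truth.

Emulates what the bench instrumentation would record -- cycle-averaged
pressures from fluid-filled transducers and flows from clamp-on ultrasonic
sensors -- for a circuit whose true parameters are known, so the whole
calibrate-and-sweep pipeline can be tested end to end without any bench
data.  Noise is independent Gaussian per observation (steady-state cycle
averages carry no appreciable autocorrelation): sigma 2 mmHg on pressures,
0.05 L/min on flows, 25 rpm on speeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import (
    BOUNDS_HI,
    BOUNDS_LO,
    FixtureTable,
    PARAM_NAMES,
    _FIELD_KIND,
    params_to_dict,
    predict_fixtures,
)

__all__ = ["NoiseModel", "make_ground_truth", "synthesize_fixtures",
           "default_design"]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise model of the virtual bench sensors."""

    sigma_pressure: float = 2.0   # mmHg
    sigma_flow: float = 0.05      # L/min
    sigma_rpm: float = 25.0       # rpm
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_pressure, self.sigma_flow, self.sigma_rpm) < 0:
            raise ValueError("noise sigmas must be non-negative")

    def sigma_for(self, field: str) -> float:
        kind = _FIELD_KIND[field]
        return {"pressure": self.sigma_pressure, "flow": self.sigma_flow,
                "rpm": self.sigma_rpm}[kind]


def make_ground_truth(seed: int) -> dict[str, float]:
    """Draw a full parameter set uniformly within the calibration bounds.

    Hydraulic parameters span their full calibration ranges; the cardiac
    block is drawn from the central half of its bounds so every ground
    truth is a plausible severe-LV-failure bench state (baseline cardiac
    output of order 1-4 L/min) rather than an extreme corner of the box.
    Reproducible by seed; the same seed always yields the same parameters.
    """
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=len(PARAM_NAMES))
    from .calibration import STAGES

    cardiac = np.array([s == "cardiac" for s in STAGES])
    u = np.where(cardiac, 0.25 + 0.5 * u, u)
    x = BOUNDS_LO + u * (BOUNDS_HI - BOUNDS_LO)
    return params_to_dict(x)


def default_design(fixtures: FixtureTable) -> FixtureTable:
    """Design = the bench fixture layout with the observed values blanked.

    Reuses the configurations, observed-field masks and comparison kinds of
    an existing table, so synthetic tables mimic the bench's reporting
    pattern exactly.
    """
    frame = fixtures.frame.copy()
    frame["value"] = np.nan
    frame["location"] = "synthetic: " + frame["row_id"]
    return FixtureTable(frame)


def synthesize_fixtures(
    params: dict[str, float],
    design: FixtureTable,
    noise: NoiseModel | None = None,
) -> FixtureTable:
    """Simulate each design row under ``params`` and add sensor noise.

    Only ``kind == 'value'`` rows receive observed values (plus noise);
    hinge and diff rows keep their comparison structure with values
    computed from the noiseless simulation, mimicking how the bench
    reported those findings.  With all sigmas zero the table equals the
    direct simulation output.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    x = np.array([params[n] for n in PARAM_NAMES])
    preds = predict_fixtures(x, design)
    frame = design.frame.copy()
    values = []
    for _, row in frame.iterrows():
        pred = preds[row["row_id"]]
        if pred is None:
            values.append(np.nan)
            continue
        if row["kind"] == "value":
            values.append(pred + rng.normal() * noise.sigma_for(row["observed_field"]))
        elif row["kind"] == "diff":
            # diff rows may reference rows observing other fields;
            # recompute the reference prediction for this row's field
            sub = design.subset([row["row_id"], row["ref_row"]])
            sub_frame = sub.frame.copy()
            sub_frame["observed_field"] = row["observed_field"]
            ref_preds = predict_fixtures(x, FixtureTable(sub_frame))
            # a reported difference inherits noise from both measurements
            values.append(pred - ref_preds[row["ref_row"]]
                          + rng.normal() * np.sqrt(2.0)
                          * noise.sigma_for(row["observed_field"]))
        else:  # gt / lt hinge thresholds keep the noiseless prediction
            values.append(pred)
    frame["value"] = values
    return FixtureTable(frame)
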
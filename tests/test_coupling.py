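"""Coupled patient + ECMO branch: equilibria, speed search, grid behaviour."""

import numpy as np
import pytest

from ecmotwin import _core
from ecmotwin.cardio import (
    ScenarioConfig,
    cardio_rhs,
    haemodynamic_metrics,
    simulate_to_periodic,
)
from ecmotwin.coupling import (
    HydraulicParams,
    build_circuit,
    branch_inertance,
    find_speed_for_flow,
    max_flow,
    run_operating_point,
)


@pytest.fixture(scope="module")
def circuit(hydraulics):
    return build_circuit(15, 21, hydraulics)


SC = ScenarioConfig(svr=1600, pvr=100)


class TestCircuitAssembly:
    def test_branch_inertance_from_geometry(self, circuit):
        """rho*sum(L/A): tubing dominates; order 10 mmHg.s/(L/min)."""
        le = branch_inertance(circuit.arterial, circuit.drainage)
        # independent evaluation for the tubing alone (lower bound)
        rho, a = 1099.0, np.pi / 4 * 0.009525**2
        tubing_only = rho * 4.75 / a / (133.322 * 60000.0)
        assert le > tubing_only
        assert le == pytest.approx(tubing_only, rel=0.6)

    def test_total_losses_sum_elements(self, circuit):
        parts = [circuit.arterial, circuit.drainage, circuit.oxygenator,
                 *circuit.segments]
        assert circuit.k1_total == pytest.approx(sum(p.k1 for p in parts))
        assert circuit.k2_total == pytest.approx(sum(p.k2 for p in parts))

    def test_bad_speed_rejected(self, circuit, cardio):
        with pytest.raises(ValueError):
            run_operating_point(SC, circuit, 5000.0, cardio)


class TestCoupledDynamics:
    def test_branch_equilibrium_speed_balances_head(self, circuit, cardio):
        """At the converged point the pump head balances losses + gradient:
        dQe/dt = 0 on cycle average."""
        op = run_operating_point(SC, circuit, 3500.0, cardio, record=True,
                                 tol_map=0.01, tol_co=0.002)
        q = op.q_ecmo
        head = circuit.pump.head(3500.0, q)
        # P_ra + H - P_ao - dp(Q) ~ 0 in cycle average
        residual = op.rap + head - op.map - circuit.circuit_dp(q)
        assert abs(residual) < 2.0  # mmHg; pulsatile rectification remains

    def test_clamped_branch_reduces_to_native_model(self, circuit, cardio):
        op = run_operating_point(SC, circuit, 0.0, cardio, mode=0)
        native = haemodynamic_metrics(simulate_to_periodic(SC, cardio))
        assert op.q_ecmo == 0.0
        assert op.map == pytest.approx(native["map"], abs=0.2)
        assert op.co == pytest.approx(native["co"], abs=0.05)

    def test_volume_conservation_with_branch(self, cardio, circuit, rng):
        """The branch moves volume RA -> aorta without storing any."""
        for _ in range(10):
            y = np.abs(rng.normal(0, 1, _core.NSTATE)) * np.array(
                [50, 120, 50, 120, 60, 8, 20, 10, 3, 3, 4])
            dy = cardio_rhs(0.3, y, cardio, SC, circuit.lumped(), mode=1,
                            drive=3.5)
            dv = (dy[0] + dy[1] + dy[2] + dy[3] + cardio.c_sa * dy[4]
                  + cardio.cv_s * dy[5] + cardio.c_pa * dy[6]
                  + cardio.cv_p * dy[7])
            assert abs(dv) < 1e-9 * max(1.0, np.abs(dy).max())

    def test_total_flow_identity(self, circuit, cardio):
        op = run_operating_point(SC, circuit, 4000.0, cardio)
        assert op.total_flow == pytest.approx(op.co + op.q_ecmo, abs=0.01)


class TestSpeedSearch:
    def test_find_speed_then_verify_flow(self, circuit, cardio):
        cache = {}
        w = find_speed_for_flow(SC, circuit, 3.0, cardio, state_cache=cache)
        op = run_operating_point(SC, circuit, w, cardio, state_cache=cache)
        assert op.q_ecmo == pytest.approx(3.0, abs=0.02)

    def test_infeasible_target_returns_none(self, circuit, cardio):
        assert find_speed_for_flow(SC, circuit, 8.0, cardio) is None

    def test_flow_monotone_in_speed(self, circuit, cardio):
        cache = {}
        qs = [run_operating_point(SC, circuit, w, cardio,
                                  state_cache=cache).q_ecmo
              for w in (2500, 3000, 3500, 4000, 4500)]
        assert np.all(np.diff(qs) > 0)

    def test_rejects_nonpositive_target(self, circuit, cardio):
        with pytest.raises(ValueError):
            find_speed_for_flow(SC, circuit, 0.0, cardio)


class TestGridProperties:
    def test_higher_svr_lowers_flow_and_raises_inlet_pressure(self, hydraulics,
                                                              cardio):
        """At fixed speed, raising SVR throttles the circuit."""
        circuit = build_circuit(15, 21, hydraulics)
        ops = {svr: run_operating_point(ScenarioConfig(svr=svr, pvr=100),
                                        circuit, 4000.0, cardio)
               for svr in (1000, 1600, 2500)}
        assert ops[1000].q_ecmo > ops[1600].q_ecmo > ops[2500].q_ecmo
        assert ops[1000].inlet_pressure < ops[1600].inlet_pressure \
            < ops[2500].inlet_pressure

    def test_pvr_insensitivity(self, hydraulics, cardio):
        """PVR 300 -> 60 changes ECMO flow and MAP by under 2%."""
        circuit = build_circuit(15, 21, hydraulics)
        ops = [run_operating_point(ScenarioConfig(svr=1600, pvr=pvr),
                                   circuit, 4000.0, cardio)
               for pvr in (300, 60)]
        assert ops[0].q_ecmo == pytest.approx(ops[1].q_ecmo, rel=0.02)
        assert ops[0].map == pytest.approx(ops[1].map, rel=0.02)

    def test_max_flow_monotone_in_arterial_size(self, hydraulics, cardio):
        flows = [max_flow(SC, build_circuit(fr, 21, hydraulics), cardio)
                 for fr in (13, 15, 17, 19, 21)]
        assert np.all(np.diff(flows) > 0)

    def test_drainage_interaction_larger_with_big_arterial(self, hydraulics,
                                                           cardio):
        """Upsizing drainage 21->25 Fr pays off more at 21 Fr arterial."""
        gains = {}
        for art in (15, 21):
            q21 = max_flow(SC, build_circuit(art, 21, hydraulics), cardio)
            q25 = max_flow(SC, build_circuit(art, 25, hydraulics), cardio)
            gains[art] = q25 - q21
        assert gains[21] > gains[15] > 0

    def test_rap_decreases_with_speed(self, circuit, cardio):
        cache = {}
        raps = [run_operating_point(SC, circuit, w, cardio,
                                    state_cache=cache).rap
                for w in (2000, 3000, 4000, 4500)]
        assert np.all(np.diff(raps) < 0)

    def test_collapse_flag_at_high_svr_max_speed(self, hydraulics, cardio):
        op = run_operating_point(ScenarioConfig(svr=2500, pvr=100),
                                 build_circuit(21, 25, hydraulics),
                                 4500.0, cardio)
        assert op.collapse and op.rap <= 0.0
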
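"""Closed-loop heart/Windkessel model: conservation, limits, convergence."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.integrate import solve_ivp

from ecmotwin import _core
from ecmotwin.cardio import (
    ChamberParams,
    ScenarioConfig,
    activation_samples,
    cardio_rhs,
    default_cardio_params,
    double_hill,
    elastance,
    haemodynamic_metrics,
    initial_state,
    pack_params,
    simulate_to_periodic,
    valve_flow,
)
from ecmotwin.hydraulics import DYN_PER_MMHG_MIN_L


class TestActivation:
    def test_normalized_to_unit_range(self):
        phase = np.linspace(0, 1, 5000, endpoint=False)
        e = double_hill(phase)
        assert e.min() == pytest.approx(0.0, abs=1e-6)
        assert e.max() == pytest.approx(1.0, abs=1e-9)

    def test_elastance_endpoints_and_period(self):
        ch = ChamberParams(emax=0.9, emin=0.06, v0=10.0)
        ts = np.linspace(0, 0.75, 400, endpoint=False)
        es = np.array([elastance(t, ch, 80.0) for t in ts])
        assert es.max() == pytest.approx(0.9, rel=1e-3)
        assert es.min() == pytest.approx(0.06, rel=1e-2)
        # periodic in 60/HR = 0.75 s at 80 bpm
        assert elastance(0.2, ch, 80.0) == pytest.approx(
            elastance(0.95, ch, 80.0), rel=1e-9)

    def test_rejects_negative_time(self):
        ch = ChamberParams(emax=0.9, emin=0.06, v0=10.0)
        with pytest.raises(ValueError):
            elastance(-0.1, ch, 80.0)


class TestValveFlow:
    @pytest.mark.parametrize("pu,pd,r,expected", [(100, 90, 5, 2.0),
                                                  (90, 100, 5, 0.0),
                                                  (80, 80, 5, 0.0)])
    def test_diode_law(self, pu, pd, r, expected):
        assert valve_flow(pu, pd, r) == pytest.approx(expected)

    def test_continuous_at_zero_gradient(self):
        eps = 1e-9
        assert valve_flow(100 + eps, 100, 5) == pytest.approx(0.0, abs=1e-9)


class TestMassConservation:
    def test_rhs_conserves_total_volume_at_random_states(self, rng):
        """Kirchhoff node law: compartment volume derivatives sum to zero."""
        params = default_cardio_params()
        sc = ScenarioConfig(svr=1600, pvr=100)
        for _ in range(25):
            y = np.abs(rng.normal(0, 1, _core.NSTATE)) * np.array(
                [50, 120, 50, 120, 60, 8, 20, 10, 3, 3, 0])
            dy = cardio_rhs(rng.uniform(0, 0.75), y, params, sc)
            dv_total = (dy[0] + dy[1] + dy[2] + dy[3]
                        + params.c_sa * dy[4] + params.cv_s * dy[5]
                        + params.c_pa * dy[6] + params.cv_p * dy[7])
            assert abs(dv_total) < 1e-9 * max(1.0, np.abs(dy).max())

    def test_volume_drift_below_tenth_millilitre_over_20_beats(self, cardio):
        sc = ScenarioConfig(svr=1600, pvr=100)
        p = pack_params(cardio, sc)
        nsteps = 750
        dt = sc.period_s / nsteps
        act_v, act_a = activation_samples(cardio, nsteps)
        y = initial_state(cardio, sc)
        m = np.zeros(_core.NMETRICS)
        traj = np.zeros((1, _core.NSTATE))
        v0 = _core._total_volume(y, p)
        for _ in range(20):
            _core._run_beat(y, p, act_v, act_a, dt, nsteps, 0, 0.0, m, traj, False)
        assert abs(_core._total_volume(y, p) - v0) < 0.1


class TestWindkesselLimit:
    def test_constant_flow_resistor_solution(self):
        """Inert heart + constant branch flow: P_sa - P_sv -> Q*(Rc+Rp)."""
        inert = ChamberParams(emax=0.08, emin=0.08, v0=10.0)
        params = replace(default_cardio_params(), lv=inert, la=inert,
                         rv=inert, ra=inert)
        sc = ScenarioConfig(svr=1600, pvr=100)
        q = 3.0
        lumped = {"l_e": 10.0, "k1_tot": 40.0, "k2_tot": 10.0,
                  "a2": 30.0, "a1": -5.0, "a0": -1.0}
        sol = simulate_to_periodic(sc, params, circuit_lumped=lumped,
                                   mode=2, drive=q, max_beats=600,
                                   tol_map=0.001, tol_co=0.001)
        m = haemodynamic_metrics(sol)
        r_total = sc.svr / DYN_PER_MMHG_MIN_L
        assert m["map"] - m["p_sv"] == pytest.approx(q * r_total, rel=0.005)

    def test_svr_resistor_identity_on_native_solution(self, cardio):
        """79.9959*(MAP - P_sv)/Q_systemic recovers the set SVR within 1%."""
        for svr in (2500, 1600, 1000):
            sol = simulate_to_periodic(ScenarioConfig(svr=svr, pvr=100), cardio)
            m = haemodynamic_metrics(sol)
            q_sys = sol.states[:-1, 8].mean()
            svr_meas = DYN_PER_MMHG_MIN_L * (m["map"] - m["p_sv"]) / q_sys
            assert svr_meas == pytest.approx(svr, rel=0.01)


class TestPeriodicConvergence:
    def test_solution_is_periodic(self, cardio):
        sol = simulate_to_periodic(ScenarioConfig(svr=1600, pvr=100), cardio,
                                   tol_map=0.01, tol_co=0.002)
        first, last = sol.states[0], sol.states[-1]
        assert np.allclose(first[:4], last[:4], atol=0.5)   # volumes, mL
        assert np.allclose(first[4:8], last[4:8], atol=0.5)  # pressures

    def test_metrics_insensitive_to_initial_volumes(self, cardio):
        """+/-20% initial chamber volumes: same metrics to 0.5%."""
        sc = ScenarioConfig(svr=1600, pvr=100)
        ref = haemodynamic_metrics(simulate_to_periodic(
            sc, cardio, tol_map=0.01, tol_co=0.002))
        for scale in (0.8, 1.2):
            y0 = initial_state(cardio, sc)
            y0[:4] *= scale
            m = haemodynamic_metrics(simulate_to_periodic(
                sc, cardio, y0=y0, tol_map=0.01, tol_co=0.002))
            assert m["map"] == pytest.approx(ref["map"], rel=0.005)
            assert m["co"] == pytest.approx(ref["co"], rel=0.005)

    def test_nonconvergence_raises(self, cardio):
        from ecmotwin.cardio import ConvergenceError

        with pytest.raises(ConvergenceError):
            simulate_to_periodic(ScenarioConfig(svr=1600, pvr=100), cardio,
                                 max_beats=4, tol_map=1e-6, tol_co=1e-7)


class TestPhysiology:
    def test_native_co_rises_as_svr_falls(self, cardio):
        """Afterload sensitivity of the failing LV across the SVR grid."""
        cos = [haemodynamic_metrics(simulate_to_periodic(
            ScenarioConfig(svr=svr, pvr=100), cardio))["co"]
            for svr in (2500, 1600, 1000)]
        assert cos[0] < cos[1] < cos[2]

    def test_end_systolic_points_on_emax_line(self, cardio):
        """P/(V-V0) peaks at Emax_LV regardless of loading."""
        for svr in (2500, 1000):
            sol = simulate_to_periodic(ScenarioConfig(svr=svr, pvr=100), cardio)
            wf = sol.waveforms()
            ratio = wf["P_lv"] / (wf["V_lv"] - cardio.lv.v0)
            assert ratio.max() == pytest.approx(cardio.lv.emax, rel=0.01)


class TestIntegratorAccuracy:
    def test_rk4_agrees_with_adaptive_reference(self, cardio):
        """Fixed-step kernel vs scipy LSODA on the same equations."""
        sc = ScenarioConfig(svr=1600, pvr=100)
        p = pack_params(cardio, sc)
        nsteps = 750
        act_v, act_a = activation_samples(cardio, 2000)
        phase_grid = np.arange(2 * 2000 + 1) / (2.0 * 2000)

        def rhs(t, y):
            ph = (t / sc.period_s) % 1.0
            ev = np.interp(ph, phase_grid, act_v)
            ea = np.interp(ph, phase_grid, act_a)
            dy = np.empty(_core.NSTATE)
            _core._rhs(y, dy, ev, ea, p, 0, 0.0)
            return dy

        y0 = initial_state(cardio, sc)
        n_beats = 12
        ref = solve_ivp(rhs, (0, n_beats * sc.period_s), y0, method="LSODA",
                        rtol=1e-8, atol=1e-8, dense_output=True)
        assert ref.success
        # cycle averages over the final beat
        ts = np.linspace((n_beats - 1) * sc.period_s, n_beats * sc.period_s,
                         2000, endpoint=False)
        map_ref = ref.sol(ts)[4].mean()

        act_v_c, act_a_c = activation_samples(cardio, nsteps)
        y = y0.copy()
        m = np.zeros(_core.NMETRICS)
        traj = np.zeros((1, _core.NSTATE))
        dt = sc.period_s / nsteps
        for _ in range(n_beats):
            _core._run_beat(y, p, act_v_c, act_a_c, dt, nsteps, 0, 0.0, m,
                            traj, False)
        assert m[_core.MIDX["map"]] == pytest.approx(map_ref, abs=0.1)
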
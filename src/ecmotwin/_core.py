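"""Numba-compiled fixed-step integrator for the coupled 0D circulation.

The closed loop is a four-chamber time-varying-elastance heart with a
five-element Windkessel (characteristic resistance, arterial compliance,
inertance, peripheral resistance, venous compliance) per circulation, plus
an optional ECMO branch from the right-atrial node to the aortic node.

State vector (11 floats):
    0 V_la, 1 V_lv, 2 V_ra, 3 V_rv          chamber volumes, mL
    4 P_sa, 5 P_sv, 6 P_pa, 7 P_pv          compartment pressures, mmHg
    8 Q_sa, 9 Q_pa                          inertance branch flows, L/min
    10 Q_e                                  ECMO branch flow, L/min

Parameter vector layout (see ``PIDX``): pressures mmHg, flows L/min,
resistances mmHg.min/L, compliances mL/mmHg, inertances mmHg.s/(L/min),
time seconds.  Ventricular and atrial activation waveforms are passed as
pre-sampled arrays (2*nsteps+1 points per beat) so the classic fourth-order
Runge-Kutta substeps index them directly.

ECMO drive modes: 0 = branch clamped (Q_e forced to 0), 1 = speed-driven
(pump head at a fixed omega, branch inertance dynamics), 2 = flow-imposed
(Q_e held at a setpoint; used by calibration where the bench protocol fixed
the flow, not the speed).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# -- parameter indices -------------------------------------------------------
PIDX = {
    "hr": 0,
    "emax_lv": 1, "emin_lv": 2, "v0_lv": 3,
    "emax_la": 4, "emin_la": 5, "v0_la": 6,
    "emax_rv": 7, "emin_rv": 8, "v0_rv": 9,
    "emax_ra": 10, "emin_ra": 11, "v0_ra": 12,
    "r_mv": 13, "r_av": 14, "r_tv": 15, "r_pv": 16,
    "rc_s": 17, "rp_s": 18, "c_sa": 19, "l_sa": 20, "cv_s": 21, "r_vs": 22,
    "rc_p": 23, "rp_p": 24, "c_pa": 25, "l_pa": 26, "cv_p": 27, "r_vp": 28,
    "l_e": 29, "k1_tot": 30, "k2_tot": 31,
    "a2": 32, "a1": 33, "a0": 34,
}
NPARAMS = 35
NSTATE = 11

# -- metric indices ----------------------------------------------------------
MIDX = {
    "map": 0, "co": 1, "q_e": 2, "rap": 3, "lap": 4, "pap": 5,
    "p_sv": 6, "p_pv": 7, "sv_lv": 8, "v_total": 9, "v_drift": 10,
    "p_sa_max": 11, "p_sa_min": 12, "co_pulm": 13, "rap_min": 14,
}
NMETRICS = 15

_FL = 1000.0 / 60.0  # mL/s per L/min


@njit(cache=True)
def _rhs(y, dy, ev, ea, p, mode, drive):
    """Time derivative of the state; ev/ea are the activation samples in [0,1]."""
    v_la, v_lv, v_ra, v_rv = y[0], y[1], y[2], y[3]
    p_sa, p_sv, p_pa, p_pv = y[4], y[5], y[6], y[7]
    q_sa, q_pa, q_e = y[8], y[9], y[10]

    e_lv = p[2] + (p[1] - p[2]) * ev
    e_la = p[5] + (p[4] - p[5]) * ea
    e_rv = p[8] + (p[7] - p[8]) * ev
    e_ra = p[11] + (p[10] - p[11]) * ea

    p_lv = e_lv * (v_lv - p[3])
    p_la = e_la * (v_la - p[6])
    p_rv = e_rv * (v_rv - p[9])
    p_ra = e_ra * (v_ra - p[12])

    # unidirectional valves (ideal diodes with small series resistance)
    q_mv = max(0.0, p_la - p_lv) / p[13]
    q_av = max(0.0, p_lv - p_sa) / p[14]
    q_tv = max(0.0, p_ra - p_rv) / p[15]
    q_pvv = max(0.0, p_rv - p_pa) / p[16]

    q_ven_s = (p_sv - p_ra) / p[22]
    q_ven_p = (p_pv - p_la) / p[28]

    dy[0] = _FL * (q_ven_p - q_mv)
    dy[1] = _FL * (q_mv - q_av)
    dy[2] = _FL * (q_ven_s - q_tv - q_e)
    dy[3] = _FL * (q_tv - q_pvv)
    dy[4] = _FL * (q_av - q_sa + q_e) / p[19]
    dy[5] = _FL * (q_sa - q_ven_s) / p[21]
    dy[6] = _FL * (q_pvv - q_pa) / p[25]
    dy[7] = _FL * (q_pa - q_ven_p) / p[27]
    # characteristic + peripheral resistance in series with the inertance:
    # the set SVR/PVR spans exactly the arterial-to-venous node pair
    dy[8] = (p_sa - (p[17] + p[18]) * q_sa - p_sv) / p[20]
    dy[9] = (p_pa - (p[23] + p[24]) * q_pa - p_pv) / p[26]

    if mode == 1:
        w = drive  # krpm
        head = p[32] * w * w + p[33] * w * q_e + p[34] * q_e * q_e
        dy[10] = (p_ra + head - p_sa - (p[30] * q_e + p[31] * q_e * abs(q_e))) / p[29]
    else:
        dy[10] = 0.0


@njit(cache=True)
def _total_volume(y, p):
    return (y[0] + y[1] + y[2] + y[3]
            + p[19] * y[4] + p[21] * y[5] + p[25] * y[6] + p[27] * y[7])


@njit(cache=True)
def _run_beat(y, p, act_v, act_a, dt, nsteps, mode, drive, metrics, traj, record):
    """Integrate one cardiac period in place; fill beat-averaged metrics."""
    k1 = np.empty(NSTATE)
    k2 = np.empty(NSTATE)
    k3 = np.empty(NSTATE)
    k4 = np.empty(NSTATE)
    yt = np.empty(NSTATE)

    s_map = 0.0
    s_co = 0.0
    s_qe = 0.0
    s_rap = 0.0
    s_lap = 0.0
    s_pap = 0.0
    s_psv = 0.0
    s_ppv = 0.0
    s_copulm = 0.0
    v_lv_max = y[1]
    v_lv_min = y[1]
    p_sa_max = y[4]
    p_sa_min = y[4]
    rap_min = 1e30
    v0 = _total_volume(y, p)

    for i in range(nsteps):
        ev0 = act_v[2 * i]
        ea0 = act_a[2 * i]
        evh = act_v[2 * i + 1]
        eah = act_a[2 * i + 1]
        ev1 = act_v[2 * i + 2]
        ea1 = act_a[2 * i + 2]

        # beat-average accumulators (left endpoint)
        e_ra = p[11] + (p[10] - p[11]) * ea0
        e_la = p[5] + (p[4] - p[5]) * ea0
        e_lv = p[2] + (p[1] - p[2]) * ev0
        p_ra = e_ra * (y[2] - p[12])
        p_la = e_la * (y[0] - p[6])
        p_lv = e_lv * (y[1] - p[3])
        e_rv = p[8] + (p[7] - p[8]) * ev0
        p_rv = e_rv * (y[3] - p[9])
        s_map += y[4]
        s_co += max(0.0, p_lv - y[4]) / p[14]
        s_copulm += max(0.0, p_rv - y[6]) / p[16]
        s_qe += y[10]
        s_rap += p_ra
        s_lap += p_la
        s_pap += y[6]
        s_psv += y[5]
        s_ppv += y[7]
        if y[1] > v_lv_max:
            v_lv_max = y[1]
        if y[1] < v_lv_min:
            v_lv_min = y[1]
        if y[4] > p_sa_max:
            p_sa_max = y[4]
        if y[4] < p_sa_min:
            p_sa_min = y[4]
        if p_ra < rap_min:
            rap_min = p_ra

        if record:
            for j in range(NSTATE):
                traj[i, j] = y[j]

        _rhs(y, k1, ev0, ea0, p, mode, drive)
        for j in range(NSTATE):
            yt[j] = y[j] + 0.5 * dt * k1[j]
        _rhs(yt, k2, evh, eah, p, mode, drive)
        for j in range(NSTATE):
            yt[j] = y[j] + 0.5 * dt * k2[j]
        _rhs(yt, k3, evh, eah, p, mode, drive)
        for j in range(NSTATE):
            yt[j] = y[j] + dt * k3[j]
        _rhs(yt, k4, ev1, ea1, p, mode, drive)
        for j in range(NSTATE):
            y[j] += dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])

    if record:
        for j in range(NSTATE):
            traj[nsteps, j] = y[j]

    inv = 1.0 / nsteps
    metrics[0] = s_map * inv
    metrics[1] = s_co * inv
    metrics[2] = s_qe * inv
    metrics[3] = s_rap * inv
    metrics[4] = s_lap * inv
    metrics[5] = s_pap * inv
    metrics[6] = s_psv * inv
    metrics[7] = s_ppv * inv
    metrics[8] = v_lv_max - v_lv_min
    metrics[9] = _total_volume(y, p)
    metrics[10] = metrics[9] - v0
    metrics[11] = p_sa_max
    metrics[12] = p_sa_min
    metrics[13] = s_copulm * inv
    metrics[14] = rap_min


@njit(cache=True)
def integrate_to_periodic(y0, p, act_v, act_a, dt, nsteps, mode, drive,
                          max_beats, tol_map, tol_co, record_last):
    """Run beats until cycle-averaged MAP, CO and ECMO flow settle.

    Returns (state, metrics, n_beats, converged, trajectory-of-last-beat).
    """
    y = y0.copy()
    metrics = np.zeros(NMETRICS)
    prev = np.zeros(NMETRICS)
    traj = np.zeros((nsteps + 1, NSTATE)) if record_last else np.zeros((1, NSTATE))
    converged = False
    n = 0
    for b in range(max_beats):
        _run_beat(y, p, act_v, act_a, dt, nsteps, mode, drive, metrics, traj, False)
        n = b + 1
        if not np.isfinite(metrics[0]) or not np.isfinite(y).all():
            return y, metrics, n, False, traj
        if b >= 3:
            if (abs(metrics[0] - prev[0]) < tol_map
                    and abs(metrics[1] - prev[1]) < tol_co
                    and abs(metrics[2] - prev[2]) < tol_co):
                converged = True
                break
        prev[:] = metrics
    if record_last:
        # one extra beat from the periodic state, recorded
        _run_beat(y, p, act_v, act_a, dt, nsteps, mode, drive, metrics, traj, True)
        n += 1
    return y, metrics, n, converged, traj
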
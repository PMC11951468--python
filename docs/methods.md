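# Methods

## Scope and intent

`ecmotwin` is a numerical stand-in for a rigid mock circulatory loop
(MCL) supporting a simulated cardiogenic-shock patient on femoro-femoral
VA ECMO.  It reproduces cycle-averaged operating points — flows,
pressures, pump speeds — across cannula combinations and vascular
resistance states.  It does not model blood rheology, haemolysis,
compliant-vessel collapse mechanics, baroreflexes, respiratory variation
of venous return, or body-surface-area scaling; the right-atrial
pressure crossing 0 mmHg is reported as a *collapse surrogate* flag
only, exactly as a rigid rig would.

## Circulation model

State (11 ODEs): four chamber volumes, four compartment pressures
(systemic/pulmonary, arterial/venous), two inertance branch flows, and
the ECMO branch flow.

* **Chambers.** `P = E(t)(V − V0)` with a double-Hill activation
  waveform normalised to [0, 1] (ascending Hill exponent 1.9,
  descending 21.9), systolic fraction 0.3 of the cycle.  Atria are
  passive compliances with weak contraction (`Emax_a = 2 Emin_a`),
  activated 10% of the cycle early.  Ventricular presets: severely
  depressed LV (`Emax_LV` calibrated, order 0.5 mmHg/mL), preserved RV
  (`Emax_RV = 0.9` mmHg/mL).
* **Valves.** Ideal diodes with a small series resistance shared by all
  four valves; the aortic valve resistance also lumps the proximal
  aortic (characteristic) impedance, which is why its calibration bound
  extends to 0.6 mmHg·min/L.
* **Vascular beds.** Five-element Windkessel each.  The characteristic
  resistance is placed in series with the peripheral resistance in the
  inertance branch (downstream of the arterial compliance node), so the
  set SVR/PVR spans exactly the arterial-to-venous node pair and the
  clinical resistance identity `79.9959·(MAP − P_ven)/Q = SVR` holds to
  numerical tolerance — this is what the bench's own printed numbers
  obey.  A small fixed venous-return resistance (1.0 / 0.5 mmHg·min/L
  systemic/pulmonary) connects each venous reservoir to its atrium.
* **Volume.** The closed loop conserves volume exactly (Kirchhoff node
  law); the stressed volume `v_total` is imposed on every start state by
  absorbing the mismatch into the systemic venous reservoir.

Fixed vascular parameters (chosen once to make the three printed disease
baselines reachable by the four cardiac free parameters, then frozen):
`C_sa = 1.2`, `Cv_s = 25`, `C_pa = 3.5`, `Cv_p = 8` mL/mmHg; inertances
0.25 / 0.10 mmHg·s/(L/min); `Rc` fraction 0.05 of the set resistance.

## ECMO branch

Drainage cannula → 200 cm of 3/8-inch tubing → centrifugal pump → 75 cm
tubing → oxygenator → 200 cm tubing → arterial cannula, from the
right-atrial chamber to the aortic node distal to the arterial
compliance (retrograde femoral return).  Each passive element:
`ΔP = k1 Q + k2 Q|Q|`, `k1` from Hagen–Poiseuille on the element's
geometry, `k2` calibrated.  Branch inertance is computed from geometry
(`ρ·ΣL/A ≈ 14 mmHg·s/(L/min)`) and held fixed.  Pump head
`H = a2 ω² + a1 ω Q + a0 Q²` (ω in krpm), coefficients calibrated,
4500 rpm speed limit.  Flow in the cannulae is transitional
(Re ≈ 3000–5000 at clinical flows); a Reynolds diagnostic is available
on every element but no behaviour branches on it — the k1+k2 law with a
calibrated quadratic term absorbs the transitional excess directly from
the operating-point data.

Cannula lumens follow the French convention `d = Fr/3 − 2·wall` with a
0.5 mm wall.  Quadratic coefficients scale with lumen within each role,
`k2(d) = k2_ref (d_ref/d)^p`: the arterial exponent is the rigid-pipe
dynamic-head value p = 4; the drainage exponent is calibrated (bounds
2–6) because multi-stage side holes make the effective flow area scale
in an unknown way.  Hydraulic lengths are shared per role and calibrated
(arterial 0.10–0.40 m, drainage 0.30–0.70 m) since the rig's inserted +
external lengths are not documented.

## Numerical solution

Operating points are solved by time integration to the periodic state —
not an algebraic fixed point — preserving pulsatile MAP and valve
switching.  The integrator is a compiled fixed-step classic Runge–Kutta
kernel, dt = 1 ms (750 steps per beat at HR 80); the fastest time
constant in the system is ≥ 2.5 ms, giving a comfortable stability
margin, and the kernel agrees with an adaptive LSODA reference on the
same equations to < 0.1 mmHg in cycle-averaged MAP (tested).
Convergence: consecutive-beat changes below 0.1 mmHg (MAP) and
0.02 L/min (CO, branch flow), minimum 4 beats, cap 400; inside the
calibration loop the tolerances are tightened tenfold so the
finite-difference Jacobians are not dominated by the stopping rule's
discreteness.  Warm-starting from a previously converged state of the
same configuration cuts the beat count roughly threefold in sweeps and
fits; results are independent of the start state to the stated
tolerance.  Speed searches (`find_speed_for_flow`) bracket the monotone
steady flow–speed curve and bisect to 2 rpm.

## Calibration

Thirteen free parameters against 31 observed scalars: `Emax_LV`,
`Emin_LV`, stressed volume, valve resistance; arterial length and
`k2` reference; drainage length, `k2` reference and size exponent;
oxygenator `k1`; pump `a2, a1, a0`.  Weighted least squares with
sensor-noise weights (2 mmHg, 0.05 L/min, 50 rpm); one-sided hinge
residuals for observations recorded only as beyond a threshold (the
357 mmHg transducer limit, the < 300 mmHg and RAP ≤ 0 findings);
difference residuals (σ·√2) for quantities reported as differences
between two configurations.  The fit exploits the model's triangular
structure — baselines and flow-setpoint haemodynamics depend only on the
cardiac block; inlet pressures at set flow add only the arterial
cannula; speed-driven points determine pump/drainage/oxygenator — as
three staged solves followed by a joint polish over all parameters, the
whole cascade repeated from five jittered starts (seeded, bit-for-bit
reproducible) with best-of selection.  A finite-difference Jacobian
column-rank audit runs at the solution; rank deficiency is reported,
never silently accepted.

## Synthetic data

`make_ground_truth(seed)` draws hydraulic parameters uniformly within
the calibration bounds and the cardiac block from the central half of
its bounds, so every ground truth is a plausible severe-LV-failure bench
state (baseline CO ≈ 1.6–4.6 L/min at SVR 2500 across seeds 0–99) rather
than a corner of the box.  `synthesize_fixtures` simulates the bench's
reporting design (same configurations, observed-field masks and
comparison kinds as the real table) and adds independent Gaussian sensor
noise (2 mmHg, 0.05 L/min, 25 rpm; differences get σ·√2).  Cycle
averages justify the no-autocorrelation assumption.  What passing
recovery tests show: with self-consistent data at sensor noise the
pipeline recovers sharply identified parameters (arterial k2 to ~10%
median).  What they do not show: parameters on sloppy ridges —
`Emax_LV` trades off against stressed volume and valve resistance and
recovers only to ~25–30% median at the same noise, and real bench data
add systematic (non-Gaussian) structure that no replicate of this
generator contains.

## Known structural limits

* The fixed-contractility elastance heart compresses the MAP spread
  across SVR states under high support: the bench's inlet pressures at
  3 L/min (253.3 / 293.9 / 241.7 mmHg at SVR 1600/2500/1000) imply a
  ~40 mmHg MAP spread at identical cannula ΔP, while the model ceiling
  is ~20–24 mmHg for any contractility consistent with the three
  baselines.  The physical rig's Frank–Starling autoregulation (out of
  scope here by design) is the likely cause.  Consequences: the
  calibrated weighted RMS plateaus near 1.6 rather than 1.0; the
  high-SVR inlet pressure fits ~11 mmHg low in-sample and ~21 mmHg low
  out-of-sample; all other printed points are reproduced within their
  stated bands.
* The drainage-size interaction is directionally right (upsizing
  drainage pays off far more with a 21 Fr than a 15 Fr arterial cannula)
  but the 15 Fr gain calibrates to ~0.33 L/min against the bench's 0.2;
  the shared drainage k2-scaling law cannot shrink it further without
  breaking the 21 Fr contrast.
* Saturated pressures are reported at their computed value with a flag
  (the rig plotted such points beyond the transducer limit the same
  way).  Negative RAP is permitted numerically — rigid chambers.
* Problem sizes used by the shipped tests and the acceptance script:
  31-row fixture table, 5-start calibration, 135-configuration sweep
  with 1 L/min setpoints, 20-replicate parameter recovery, 500-replicate
  noise-scatter check.
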
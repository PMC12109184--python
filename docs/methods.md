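# Methods

This note documents the model, its parameters, the synthetic patient
fixtures, and the numerical choices, in enough detail that a reader can
judge what the simulations do and do not show.

## The closed loop

The circulation is a 0D (lumped-parameter) network in mmHg / mL / s.

**Chambers.** Left and right ventricles and atria are modified
time-varying elastance elements. Chamber pressure is the activation-
weighted blend of the end-systolic pressure–volume relation (ESPVR,
`Ees·(V−V0)`) and the exponential end-diastolic relation (EDPVR,
`A·(e^{B(V−V0)}−1)`), both anchored at zero pressure at the volume
intercept `V0`. The activation is a raised cosine: zero outside systole,
rising to exactly 1 at a configurable peak fraction of the systolic
duration `Ts = 0.3·√T` (ventricles; `0.16·√T` for atria), falling back to
zero at `Ts`. Atrial activation precedes ventricular activation by an AV
delay of `0.16·√(T/0.8)` s. Ventricular interdependence is a
pressure-superposition septal term `P_lv += k_sept·(V_rv − V_rv,ref)` (and
symmetrically), with a small default `k_sept = 0.02 mmHg/mL`; setting it to
zero exactly decouples the chambers.

**Network.** Sixteen compliant nodes joined by resistive links, five of
them (the aortic chain) inertant. Parallel systemic branches carry
approximately 25 % (upper limbs and head), 30 % (renal–hepatic), 25 %
(splanchnic), 15 % (lower limbs) and 5 % (coronary) of resting cardiac
output. Cerebral flow is reported as the upper-limbs-and-head branch
inflow; coronary flow as the coronary branch inflow (an RC path from the
aortic root to the right atrium). Valves are ideal diodes with series
resistance and an optional quadratic smoothing of width 0.1 mmHg at the
corner (keeps the right-hand side C1 for the stiff integrator). No
regurgitation, no venous valves, external (intrathoracic) pressure 0 mmHg
by default but configurable per segment.

Two placement choices matter for the device comparisons and were fixed
during fixture calibration:

* the venae cavae drain into the right atrium through small but non-trivial
  resistances (0.12 mmHg·s/mL each), so that a pump draining the RA
  directly can lower RA pressure — and right-heart preload — much more
  effectively than one draining the femoral vein;
* the pulmonary venous resistance (0.16 mmHg·s/mL) sits downstream of the
  pulmonary-veins node where wedge pressure is read, so PCWP carries a
  flow-dependent (post-capillary) component on top of left-atrial pressure.

Without the first, central and peripheral cannulation become almost
indistinguishable upstream of the right heart; without the second, PCWP is
pinned to LV end-diastolic pressure and cannot fall while the LV remains
dilated. Both values are within the range used for venous/pulmonary-venous
segments in 0D modelling.

**VA ECMO.** Centrifugal pump head `ΔP = k₁ω² − k₂Qω − k₃Q²`
(k₁ = 2·10⁻⁵ mmHg/rpm², k₂ = 4·10⁻⁴, k₃ = 10⁻²) in series with lumped
cannula resistance (0.45 central, 0.70 peripheral, mmHg·s/mL — the
peripheral circuit has longer percutaneous cannulae; the oxygenator is
folded into this resistance) and inertance 0.004 mmHg·s²/mL. The
coefficients were calibrated once (`scripts/calibrate.py`) so circuit flow
spans ≈ 2.5–5 L/min over 3000–4000 rpm against the shock afterload, the
clinically typical range. A backflow valve keeps circuit flow
non-negative. Central mode drains the RA and returns to the ascending
aorta; peripheral drains the femoral vein and returns to the femoral
artery. Published descriptions of comparable circuits disagree on the
return site (ascending vs descending aorta; femoral vs thoracic artery),
so both attachment nodes are plain configuration fields and the defaults
above are this package's choice, not a claim about any reference system.

**IABP.** A 40 mL balloon at the descending-thoracic-aorta node, driven by
a 260 mmHg pressure tank (inflation) and a −10 mmHg vacuum tank
(deflation) through a gas resistance of 0.5 mmHg·s/mL. Balloon gas volume
is a state clamped to [0, V_max] with a 1 mL linear taper; the blood flow
injected at the balloon node equals `+dV_gas/dt` (positive during
diastolic inflation). Inflation triggers at the aortic-valve-closure
fraction detected on the previous beat (bootstrap: 0.35 of the cycle on
the first beat); deflation begins 0.05 s before systole onset. The small
pre-systolic deflation lead is deliberate: with deflation at systole onset
the balloon is still emptying during early ejection and the expected LV
unloading (lower LVEDV with IABP) does not materialise; pre-systolic
deflation is also standard pump timing.

## Synthetic patients

No published per-segment parameter table exists for the study conditions
this package emulates, so both fixtures are stand-ins built from
`data/default_patient.yaml` (every default lives in that one file):

* **Healthy reference** (HR 70, BSA 1.8 m², blood volume 5550 mL):
  calibrated once so the simulation lands in a documented sanity band —
  CO 4.5–6 L/min, mean aortic pressure 85–100 mmHg. The shipped
  parameters give CO 4.58 L/min, mean AoP 90.7 mmHg
  (`scripts/calibrate.py` reprints these).
* **Cardiogenic shock** (HR 90 — typical shock tachycardia; same BSA):
  derived from the healthy reference by a deterministic tuner with three
  knobs — a ventricular systolic *remodeling* scale, a total-blood-volume
  scale, and a systemic microcirculatory resistance scale (coronary branch
  excluded so coronary comparisons keep a fixed resistance). The tuner
  bisects one knob per clinical bound in a fixed order (remodeling ↓ until
  the cardiac-index target, volume until the PCWP target, resistance until
  the SVRi target), repeats the pass up to three times, and verifies all
  four criteria on a converged run: SBP < 90 mmHg, SVRi < 1800
  dyn·s·cm⁻⁵·m², PCWP > 15 mmHg, CI < 2.2 L/min/m². It is fully
  deterministic: rerunning it, from the default or from perturbed starting
  knobs, returns a fixture meeting all bounds (bounds-recovery is part of
  the test suite).

The remodeling knob is more than a bare Ees scale. Lowering the scale `s`
multiplies LV Ees by `s`, shifts the volume intercept right by
`100·(1−s)` mL and stiffens the EDPVR exponent by `(1+0.6·(1−s))` (RV: half
as strong). This is the dilated-failing-ventricle phenotype: the ventricle
operates enlarged at elevated filling pressure, but its ESPVR slope stays
moderate, so end-systolic volume does not react unboundedly to the
afterload rise that retrograde ECMO return produces. A slope-only scaling
that still satisfies CI < 2.2 and PCWP > 15 makes the LV so
afterload-sensitive that no support mode can decongest the left side —
physiologically the difference between "weak but compact" and "dilated,
remodeled" ventricles.

## Numerics

* Stiff-capable adaptive integration (LSODA; rtol 10⁻⁶, atol 10⁻⁴),
  one cardiac cycle per solver call, output sampled at 500 Hz.
* Periodic steady state: LV/RV stroke volume and mean aortic,
  pulmonary-arterial and pulmonary-venous pressures must change < 10⁻³
  (relative) between successive beats; ≥ 5 beats, ≤ 80. The shocked
  baseline converges in 26 beats; halving solver tolerances moves every
  reported metric by < 0.5 % (asserted in the suite).
* Mass is conserved structurally (every flow enters one balance and leaves
  another; balloon gas is subtracted from the balloon node's blood
  volume); drift over 20 beats is below 0.5 % at the default tolerances.
* End-systole for Ea is located at the maximal-elastance point
  (max of `P/(V−V0)`), where pressure, volume and elastance are all
  locally stationary; sampling pressure at the volume minimum instead sits
  on the steep isovolumic-relaxation flank and is grid-phase sensitive.
  Landmark detection (end-diastole/end-systole/valve closure) still uses
  the volume extrema and the last fall of valve flow to zero.
* Loop areas use the shoelace formula; atrial loops, which self-intersect
  (a- and v-loops), are split at their crossings and the absolute sub-loop
  areas summed. PVA = EW + PE holds by construction and is asserted.
* SVRi follows the clinical convention `79.9·(MAP − CVP)/CI`
  (dyn·s·cm⁻⁵·m²). Cardiac output and index are *native* LV output
  (SV × HR); "total flow" adds the mean pump flow. Unit conversions
  happen only at the report boundary.

## What the fixtures do and do not show

The study pipeline runs 13 conditions (baseline ∪ {central, peripheral} ×
{3000, 3500, 4000 rpm} × {IABP off/on}) in ≈ 1 minute on one CPU and
reports absolute metrics plus signed percentage changes versus baseline.
The directional pattern — central support decongests the pulmonary
circulation and unloads the right heart while raising LV afterload;
peripheral support raises wedge and pulmonary pressures and dilates both
ventricles; IABP raises mean aortic pressure and trims LV volumes; flows
grow with pump speed — is a robust property of the model class and is what
the test suite asserts. The *magnitudes* of the percentage changes depend
on the stand-in parameterization and should not be read as predictions for
any specific patient or any specific reference simulator. Baroreflex and
autonomic control, respiratory coupling, gas exchange, pump suction events
and haemolysis are all outside scope.
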
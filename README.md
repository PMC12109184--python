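# cardioloop

Closed-loop lumped-parameter (0D) simulation of the human circulation under
mechanical circulatory support, built to compare **central vs peripheral
veno-arterial ECMO** with and without an **intra-aortic balloon pump (IABP)**
in cardiogenic shock.

It is aimed at researchers in computational physiology and mechanical
circulatory support who want a transparent, scriptable model of how support
strategy shapes haemodynamics (pressures, flows, chamber volumes) and
ventricular energetics (pressure–volume loop analysis).

## Model

The heart is four time-varying elastance chambers with septal interaction.
Each chamber blends its end-systolic and end-diastolic pressure–volume
relations with a periodic activation `a(t) ∈ [0, 1]`:

    P(V, t) = a(t) · Ees (V − V0)  +  (1 − a(t)) · A (e^{B (V − V0)} − 1)

The vasculature is a closed RLC network: ascending/descending aorta with
aortic arch and thoracic resistance, upper-limbs-and-head, coronary (RC),
renal–hepatic, splanchnic, abdominal and lower-limbs branches, venae cavae,
and the pulmonary circulation. Valves are diode–resistor elements.

VA ECMO is a centrifugal pump with head curve
`ΔP = k₁ω² − k₂Qω − k₃Q²` and cannula R/L: central mode drains the right
atrium and returns to the ascending aorta, peripheral mode drains the
femoral vein and returns to the femoral artery (both attachment nodes are
configurable). The IABP is a pneumatic source (drive 260 mmHg / vacuum
−10 mmHg through a gas resistance) inflating a balloon in the descending
thoracic aorta during diastole and deflating it before systole.

The metric suite covers min/mean/max of LAP, AoP, PAP and LVP, PCWP,
ESV/EDV of all chambers, cardiac output and index, total (native + pump)
flow, SVRi, coronary and cerebral flow, ventricular external work (EW),
potential energy (PE), pressure–volume area (PVA = EW + PE), atrial loop
areas, and ventricular–arterial coupling (Ea = Pes/SV, Ea/Ees).

## Worked example

```python
import cardioloop as cl

patient = cl.make_cs_patient()          # deterministic cardiogenic-shock tuner
report = cl.run_full_matrix(patient)    # 13 conditions: baseline ∪ {central,
                                        # peripheral} × {3000,3500,4000 rpm} × {±IABP}
print(report.percent_change.loc[
    ["central_3000rpm", "peripheral_3000rpm", "central_3000rpm_iabp"],
    ["pcwp", "pap_mean", "lvesv", "rvedv", "total_flow"]].round(1))
```

prints (percentage change versus the unassisted pathological baseline):

```
                      pcwp  pap_mean  lvesv  rvedv  total_flow
central_3000rpm      -30.6     -32.9   13.0  -28.3        48.7
peripheral_3000rpm    47.0      37.4   14.2    5.7        65.8
central_3000rpm_iabp -30.1     -31.4    9.4  -25.2        54.2
```

Central ECMO decongests the left side (wedge and pulmonary pressures fall,
right ventricle unloads) at the cost of a higher LV afterload (LVESV
rises); peripheral ECMO congests the pulmonary circulation and dilates both
ventricles; adding the IABP recovers part of the LV loading penalty while
raising mean aortic pressure. `cl.directional_consistency_check(report)`
evaluates the full list of expected signs.

A thin CLI wraps the same calls:

```bash
cardioloop simulate --patient cs --ecmo central --rpm 3000 --iabp
cardioloop study --patient cs --out study_report
```

## Limitations

The per-segment parameter values are literature-informed stand-ins
calibrated to documented sanity bands, not a published patient dataset;
see `docs/methods.md` for the model assumptions, tuning procedure and
numerical choices.
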
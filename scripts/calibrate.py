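#!/usr/bin/env python
"""Calibration report for the packaged fixtures and pump coefficients.

Prints the sanity quantities the defaults were calibrated against:

* healthy reference — cardiac output and mean aortic pressure at HR 70
  (documented band: 4.5-6 L/min, 85-100 mmHg),
* cardiogenic-shock baseline — the four clinical criteria,
* ECMO pump — equilibrium circuit flow at 3000/3500/4000 rpm against the
  shocked afterload (expected to span roughly 2.5-5 L/min).

Run after any change to ``data/default_patient.yaml`` or the pump
coefficients to confirm the fixtures still land where the documentation
says they do.
"""

from __future__ import annotations

import cardioloop as cl
from cardioloop.devices import EcmoConfig, EcmoMode


def main() -> None:
    healthy = cl.make_healthy_patient()
    h, _ = cl.compute_reports(cl.run_to_steady_state(healthy))
    print(f"healthy:  CO {h.cardiac_output:.2f} L/min   mean AoP {h.aop_mean:.1f} mmHg")

    cs = cl.make_cs_patient()
    hc, ec = cl.compute_reports(cl.run_to_steady_state(cs))
    print(
        f"CS:       SBP {hc.aop_max:.1f} (<90)   SVRi {hc.svri:.0f} (<1800)   "
        f"PCWP {hc.pcwp:.1f} (>15)   CI {hc.cardiac_index:.2f} (<2.2)"
    )
    print(f"          knobs {cs.knobs}   Ea/Ees {ec.ea_over_ees_systemic:.2f}")

    cfg = EcmoConfig(mode=EcmoMode.CENTRAL, rpm=3000)
    dp = hc.aop_mean - hc.cvp  # representative pump pressure rise
    for rpm in (3000, 3500, 4000):
        q = cl.pump_equilibrium_flow(dp, rpm, cfg) * 60 / 1000
        print(f"pump {rpm} rpm vs {dp:.0f} mmHg: {q:.2f} L/min")


if __name__ == "__main__":
    main()
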
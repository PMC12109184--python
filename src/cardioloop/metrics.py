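"""Haemodynamic and energetic metrics computed from a converged beat.

Internal units are mmHg, mL and s; conversions to reporting units happen in
one place only, at the report boundary:

* flows to L/min (``* 60 / 1000``) or mL/min (``* 60``),
* SVRi to dyn·s·cm⁻⁵·m² (``* 79.9``).

Cardiac output is the native left-ventricular output (stroke volume × heart
rate); total flow adds the mean ECMO circuit flow.  Ventricular external
work (EW) is the area of the pressure-volume loop, the potential energy
(PE) the area between the ESPVR and EDPVR left of the end-systolic point,
and PVA = EW + PE by construction.  The effective arterial elastance is
Ea = Pes / SV with Pes the ventricular pressure at end-systole; Ea/Ees uses
the chamber's end-systolic elastance parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from shapely.geometry import LineString
from shapely.ops import polygonize, unary_union

from .chambers import ChamberParams
from .simulator import BeatSeries

__all__ = [
    "HaemodynamicReport",
    "EnergeticReport",
    "cycle_stats",
    "loop_area",
    "atrial_loop_area",
    "potential_energy",
    "effective_arterial_elastance",
    "svri",
    "coronary_blood_flow_mean",
    "pcwp",
    "percentage_change",
    "compute_reports",
]

MMHG_TO_DYN = 79.9  # mmHg*min/L -> dyn*s*cm^-5


@dataclass
class HaemodynamicReport:
    """Per-beat haemodynamic variables in clinical reporting units."""

    lap_min: float
    lap_mean: float
    lap_max: float
    aop_min: float
    aop_mean: float
    aop_max: float
    pap_min: float
    pap_mean: float
    pap_max: float
    lvp_min: float
    lvp_mean: float
    lvp_max: float
    pcwp: float  # mmHg
    lvesv: float
    lvedv: float
    rvesv: float
    rvedv: float
    laesv: float
    laedv: float  # mL
    cardiac_output: float  # L/min, native LV output
    pump_flow: float  # L/min, mean ECMO circuit flow
    total_flow: float  # L/min, native + pump
    cardiac_index: float  # L/min/m^2
    svri: float  # dyn*s*cm^-5*m^2
    cvp: float  # mmHg, mean right atrial pressure
    coronary_flow: float  # mL/min, simulated branch flow
    coronary_flow_index: float  # mL/min, (AoP_dia - LVEDP)/R_cor surrogate
    cerebral_flow: float  # mL/min

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass
class EnergeticReport:
    """Per-beat energetic variables (mmHg·mL unless noted)."""

    lv_ew: float
    rv_ew: float
    lv_pe: float
    rv_pe: float
    lv_pva: float
    rv_pva: float
    la_pvla: float
    ra_pvla: float
    ea_systemic: float  # mmHg/mL
    ea_pulmonary: float  # mmHg/mL
    ea_over_ees_systemic: float
    ea_over_ees_pulmonary: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def cycle_stats(t: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """(min, time-weighted trapezoidal mean, max) of a sampled signal."""
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.size < 2 or x.size != t.size:
        raise ValueError("cycle_stats requires >= 2 samples spanning one beat")
    mean = float(np.trapezoid(x, t) / (t[-1] - t[0]))
    return float(x.min()), mean, float(x.max())


def loop_area(
    p: np.ndarray, v: np.ndarray, closure_tolerance: float = 0.05
) -> float:
    """Absolute shoelace area (mmHg·mL) of a closed pressure-volume loop.

    The first and last samples must coincide within ``closure_tolerance``
    relative to the signal ranges; the polygon is then closed exactly.
    """
    p = np.asarray(p, dtype=float)
    v = np.asarray(v, dtype=float)
    if p.size != v.size or p.size < 3:
        raise ValueError("loop_area requires matching P and V with >= 3 samples")
    p_rng = max(float(p.max() - p.min()), 1e-12)
    v_rng = max(float(v.max() - v.min()), 1e-12)
    if (
        abs(p[0] - p[-1]) > closure_tolerance * p_rng
        or abs(v[0] - v[-1]) > closure_tolerance * v_rng
    ):
        raise ValueError("pressure-volume loop is not closed within tolerance")
    x = np.append(v, v[0])
    y = np.append(p, p[0])
    area = 0.5 * np.sum(x[:-1] * y[1:] - x[1:] * y[:-1])
    return float(abs(area))


def atrial_loop_area(p: np.ndarray, v: np.ndarray) -> float:
    """Total unsigned area of a possibly self-intersecting atrial loop.

    Atrial pressure-volume trajectories cross themselves (the a- and
    v-loops form a figure of eight); the trajectory is split at
    self-intersections and the absolute sub-loop areas are summed.
    """
    p = np.asarray(p, dtype=float)
    v = np.asarray(v, dtype=float)
    pts = list(zip(v, p))
    if pts[0] != pts[-1]:
        pts.append(pts[0])
    merged = unary_union(LineString(pts))
    return float(sum(poly.area for poly in polygonize(merged)))


def potential_energy(v_es: float, params: ChamberParams) -> float:
    """Elastic potential energy stored at end-systole (mmHg·mL).

    The area between the ESPVR and the EDPVR to the left of the
    end-systolic point::

        PE = Ees*(V_es - V0)^2 / 2 - integral_{V0}^{V_es} A*(e^{B(v-V0)}-1) dv

    Clamped at zero (with no stored energy) when ``V_es < V0``.
    """
    x = v_es - params.v0
    if x <= 0:
        return 0.0
    espvr_area = 0.5 * params.ees * x * x
    a, b = params.edpvr_a, params.edpvr_b
    if b > 0:
        edpvr_area = a * (math.expm1(b * x) / b - x)
    else:
        edpvr_area = 0.0
    return max(espvr_area - edpvr_area, 0.0)


def effective_arterial_elastance(pes: float, stroke_volume: float) -> float:
    """Effective arterial elastance Ea = Pes / SV (mmHg/mL)."""
    if stroke_volume <= 0:
        raise ValueError("no ejection: stroke volume must be > 0 to define Ea")
    return pes / stroke_volume


def svri(map_mmhg: float, cvp_mmhg: float, co_l_min: float, bsa_m2: float) -> float:
    """Systemic vascular resistance index, dyn·s·cm⁻⁵·m².

    ``79.9 * (MAP - CVP) / (CO / BSA)`` — the clinical convention
    SVR × BSA expressed through the cardiac index.
    """
    if co_l_min <= 0:
        raise ValueError("cardiac output must be > 0")
    if bsa_m2 <= 0:
        raise ValueError("BSA must be > 0")
    return MMHG_TO_DYN * (map_mmhg - cvp_mmhg) / (co_l_min / bsa_m2)


def coronary_blood_flow_mean(beat: BeatSeries) -> tuple[float, float]:
    """Coronary flow, two ways, both in mL/min.

    Returns ``(simulated, index)``: the trapezoidal mean of the simulated
    coronary branch inflow, and the clinical perfusion-pressure surrogate
    (diastolic aortic pressure − LV end-diastolic pressure) divided by the
    total coronary resistance.
    """
    t = beat.t
    q = beat.signals["Q_aorta_to_coronary"]
    simulated = float(np.trapezoid(q, t) / (t[-1] - t[0])) * 60.0

    aop_dia = float(beat.signals["P_ascending_aorta"].min())
    i_ed = int(np.argmax(beat.signals["V_LV"]))
    lvedp = float(beat.signals["P_LV"][i_ed])
    topo = beat.patient.topology
    r_total = topo.link("aorta_to_coronary").resistance + topo.link(
        "coronary_to_ra"
    ).resistance
    index = (aop_dia - lvedp) / r_total * 60.0
    return simulated, index


def pcwp(beat: BeatSeries) -> float:
    """Mean pulmonary venous (wedge-position) pressure over the beat, mmHg."""
    _, mean, _ = cycle_stats(beat.t, beat.signals["P_pulmonary_veins"])
    return mean


def percentage_change(assisted: float, pathological: float) -> float:
    """Signed percentage change of an assisted value vs the baseline."""
    if pathological == 0:
        raise ValueError("baseline value is zero: percentage change undefined")
    return 100.0 * (assisted - pathological) / pathological


def _mean(t: np.ndarray, x: np.ndarray) -> float:
    return float(np.trapezoid(x, t) / (t[-1] - t[0]))


def _end_systolic_pressure(p: np.ndarray, v: np.ndarray, v0: float) -> float:
    """Ventricular pressure at the maximal-elastance point.

    End-systole is located as the maximum of the instantaneous pressure-
    volume ratio E(t) = P / (V - V0).  At that stationary point pressure,
    volume and elastance are all locally flat, which makes the sampled
    value insensitive to grid phase — unlike the pressure at the volume
    minimum, which sits on the steep isovolumic-relaxation flank.
    """
    x = np.maximum(v - v0, 1e-6)
    return float(p[int(np.argmax(p / x))])


def compute_reports(beat: BeatSeries) -> tuple[HaemodynamicReport, EnergeticReport]:
    """Full metric suite from one converged beat."""
    t = beat.t
    sig = beat.signals
    patient = beat.patient

    lap = cycle_stats(t, sig["P_LA"])
    aop = cycle_stats(t, sig["P_ascending_aorta"])
    pap = cycle_stats(t, sig["P_pulmonary_artery"])
    lvp = cycle_stats(t, sig["P_LV"])

    v_lv, v_rv, v_la = sig["V_LV"], sig["V_RV"], sig["V_LA"]
    lvesv, lvedv = float(v_lv.min()), float(v_lv.max())
    rvesv, rvedv = float(v_rv.min()), float(v_rv.max())
    laesv, laedv = float(v_la.min()), float(v_la.max())

    hr = beat.heart_rate
    co = (lvedv - lvesv) * hr / 1000.0  # L/min, native
    pump = _mean(t, sig["Q_ecmo"]) * 60.0 / 1000.0
    total = co + pump
    ci = co / patient.bsa
    cvp = _mean(t, sig["P_RA"])
    svri_val = svri(aop[1], cvp, co, patient.bsa)
    cbf_sim, cbf_index = coronary_blood_flow_mean(beat)
    cerebral = _mean(t, sig["Q_arch_to_upper_body"]) * 60.0

    haemo = HaemodynamicReport(
        lap_min=lap[0], lap_mean=lap[1], lap_max=lap[2],
        aop_min=aop[0], aop_mean=aop[1], aop_max=aop[2],
        pap_min=pap[0], pap_mean=pap[1], pap_max=pap[2],
        lvp_min=lvp[0], lvp_mean=lvp[1], lvp_max=lvp[2],
        pcwp=pcwp(beat),
        lvesv=lvesv, lvedv=lvedv, rvesv=rvesv, rvedv=rvedv,
        laesv=laesv, laedv=laedv,
        cardiac_output=co, pump_flow=pump, total_flow=total,
        cardiac_index=ci, svri=svri_val, cvp=cvp,
        coronary_flow=cbf_sim, coronary_flow_index=cbf_index,
        cerebral_flow=cerebral,
    )

    lv_ew = loop_area(sig["P_LV"], v_lv)
    rv_ew = loop_area(sig["P_RV"], v_rv)
    lv_pe = potential_energy(lvesv, patient.chambers["LV"])
    rv_pe = potential_energy(rvesv, patient.chambers["RV"])
    pes_lv = _end_systolic_pressure(sig["P_LV"], v_lv, patient.chambers["LV"].v0)
    pes_rv = _end_systolic_pressure(sig["P_RV"], v_rv, patient.chambers["RV"].v0)
    ea_sys = effective_arterial_elastance(pes_lv, lvedv - lvesv)
    ea_pul = effective_arterial_elastance(pes_rv, rvedv - rvesv)

    energetic = EnergeticReport(
        lv_ew=lv_ew, rv_ew=rv_ew, lv_pe=lv_pe, rv_pe=rv_pe,
        lv_pva=lv_ew + lv_pe, rv_pva=rv_ew + rv_pe,
        la_pvla=atrial_loop_area(sig["P_LA"], v_la),
        ra_pvla=atrial_loop_area(sig["P_RA"], sig["V_RA"]),
        ea_systemic=ea_sys, ea_pulmonary=ea_pul,
        ea_over_ees_systemic=ea_sys / patient.chambers["LV"].ees,
        ea_over_ees_pulmonary=ea_pul / patient.chambers["RV"].ees,
    )
    return haemo, energetic
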
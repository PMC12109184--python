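"""Global ODE assembly, beat-by-beat integration and steady-state driver.

The state vector concatenates, in this fixed order:

* chamber volumes ``V_LV, V_RV, V_LA, V_RA`` (mL),
* one pressure per compliant vascular node, in topology order (mmHg),
* one flow per inertant link, in topology order (mL/s),
* the ECMO cannula flow (mL/s),
* the IABP balloon gas volume (mL).

The layout map (name -> index) is exported on the assembled model so tests
and post-processing can address variables by name.

Integration proceeds one cardiac cycle at a time with a stiff-capable
adaptive solver (LSODA by default).  After each beat a small set of monitor
scalars (stroke volumes, mean arterial/pulmonary/venous pressures) is
compared with the previous beat; the run stops when every relative change
falls below the steady-state tolerance.  IABP inflation timing for each
beat uses the aortic-valve-closure fraction detected on the previous beat,
falling back to fixed cycle fractions on the first beat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy.integrate import solve_ivp

from .chambers import activation_fraction, chamber_pressure, valve_flow
from .devices import DeviceConfig, EcmoMode, iabp_gas_flow, iabp_phase
from .network import total_blood_volume

if TYPE_CHECKING:  # pragma: no cover
    from .fixtures import PatientParams

__all__ = [
    "SimulationConfig",
    "BeatSeries",
    "AssembledModel",
    "SteadyStateError",
    "assemble_derivative",
    "initial_state",
    "run_to_steady_state",
    "detect_landmarks",
]

CHAMBER_ORDER = ("LV", "RV", "LA", "RA")

#: aortic flow (mL/s) below which the valve is considered closed when
#: locating the closure landmark
_VALVE_CLOSED_FLOW = 1.0


class SteadyStateError(RuntimeError):
    """Periodic steady state not reached within the beat budget."""

    def __init__(self, message: str, residuals: dict[str, float] | None = None):
        super().__init__(message)
        self.residuals = residuals or {}


@dataclass
class SimulationConfig:
    """Numerical settings for the beat integrator."""

    rtol: float = 1e-6
    atol: float = 1e-4
    method: str = "LSODA"
    max_beats: int = 80
    min_beats: int = 5
    steady_tolerance: float = 1e-3  # relative change per beat
    sampling_rate: float = 500.0  # Hz, output grid
    seed: int | None = None  # unused by the deterministic model; reserved

    def __post_init__(self) -> None:
        if self.steady_tolerance <= 0:
            raise ValueError("steady-state tolerance must be > 0")
        if self.max_beats < 3:
            raise ValueError("max_beats must be >= 3")


@dataclass
class BeatSeries:
    """Uniformly sampled final beat(s) with named signals and landmarks."""

    t: np.ndarray  # s, starting at 0
    signals: dict[str, np.ndarray]
    landmarks: dict[str, float]
    period: float
    heart_rate: float
    n_beats_run: int
    patient: "PatientParams"
    devices: DeviceConfig

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("BeatSeries time grid must be strictly increasing")


class AssembledModel:
    """Derivative function of the full closed loop, with a layout map.

    Calling the instance evaluates the right-hand side; ``signals_at``
    recomputes every algebraic quantity (chamber pressures, valve and link
    flows, device flows) at a given state for post-processing.
    """

    def __init__(self, patient: "PatientParams", devices: DeviceConfig):
        self.patient = patient
        self.devices = devices
        topo = patient.topology
        self.node_order = list(topo.node_order)
        n_nodes = len(self.node_order)

        # pressure-vector indexing: chambers 0..3, then nodes
        self._p_index = {name: i for i, name in enumerate(CHAMBER_ORDER)}
        for i, name in enumerate(self.node_order):
            self._p_index[name] = 4 + i

        # state layout
        self.layout: dict[str, int] = {}
        for i, name in enumerate(CHAMBER_ORDER):
            self.layout[f"V_{name}"] = i
        for i, name in enumerate(self.node_order):
            self.layout[f"P_{name}"] = 4 + i
        self._inertant = []
        off = 4 + n_nodes
        for lk in topo.inertant_links:
            self.layout[f"Q_{lk.name}"] = off
            self._inertant.append(
                (
                    off,
                    self._p_index[lk.source],
                    self._p_index[lk.target],
                    lk.resistance,
                    1.0 / lk.inertance,
                )
            )
            off += 1
        self.layout["Q_ecmo"] = off
        self.layout["V_gas"] = off + 1
        self.n_states = off + 2

        self._resistive = [
            (
                lk.name,
                self._p_index[lk.source],
                self._p_index[lk.target],
                1.0 / lk.resistance,
            )
            for lk in topo.resistive_links
        ]
        self._inv_c = [1.0 / topo.nodes[n].compliance for n in self.node_order]

        ch = patient.chambers
        self._chambers = [ch["LV"], ch["RV"], ch["LA"], ch["RA"]]
        self._septum = patient.septum
        self._valves = patient.valves  # mitral, aortic, tricuspid, pulmonic
        self._aa_i = self._p_index["ascending_aorta"]
        self._pa_i = self._p_index["pulmonary_artery"]

        ecmo = devices.ecmo
        self._ecmo_on = ecmo.mode is not EcmoMode.OFF
        if self._ecmo_on:
            self._ecmo_drain_i = self._p_index[ecmo.drainage_node]
            self._ecmo_return_i = self._p_index[ecmo.return_node]
        iabp = devices.iabp
        self._iabp_on = iabp.enabled
        self._balloon_i = self._p_index[iabp.balloon_node]

        #: per-beat IABP trigger fractions, updated by the steady-state
        #: driver from detected landmarks; None means bootstrap defaults
        self.landmark_fractions: dict[str, float | None] = {
            "inflation": None,
            "deflation": None,
        }
        self.period = patient.period

    # -- right-hand side ------------------------------------------------
    def __call__(self, t: float, y) -> np.ndarray:
        patient = self.patient
        dy = np.zeros(self.n_states)
        acc = [0.0] * (4 + len(self.node_order))

        a = [activation_fraction(t, c.timing) for c in self._chambers]
        p_ch = [chamber_pressure(y[i], a[i], self._chambers[i]) for i in range(4)]
        sep = self._septum
        if sep.k_sept:
            p_lv = p_ch[0] + sep.k_sept * (y[1] - sep.v_rv_ref)
            p_rv = p_ch[1] + sep.k_sept * (y[0] - sep.v_lv_ref)
            p_ch[0], p_ch[1] = p_lv, p_rv
        if sep.k_atrial:
            p_la = p_ch[2] + sep.k_atrial * (y[3] - sep.v_ra_ref)
            p_ra = p_ch[3] + sep.k_atrial * (y[2] - sep.v_la_ref)
            p_ch[2], p_ch[3] = p_la, p_ra

        p_all = p_ch + [y[4 + i] for i in range(len(self.node_order))]

        # valves: LA->LV, LV->aorta, RA->RV, RV->PA
        q_mi = valve_flow(p_all[2], p_all[0], self._valves["mitral"])
        q_ao = valve_flow(p_all[0], p_all[self._aa_i], self._valves["aortic"])
        q_ti = valve_flow(p_all[3], p_all[1], self._valves["tricuspid"])
        q_po = valve_flow(p_all[1], p_all[self._pa_i], self._valves["pulmonic"])
        acc[0] += q_mi - q_ao
        acc[1] += q_ti - q_po
        acc[2] -= q_mi
        acc[3] -= q_ti
        acc[self._aa_i] += q_ao
        acc[self._pa_i] += q_po

        for _, si, ti, inv_r in self._resistive:
            q = (p_all[si] - p_all[ti]) * inv_r
            acc[si] -= q
            acc[ti] += q
        for off, si, ti, r, inv_l in self._inertant:
            q = y[off]
            acc[si] -= q
            acc[ti] += q
            dy[off] = (p_all[si] - p_all[ti] - r * q) * inv_l

        i_qe = self.layout["Q_ecmo"]
        if self._ecmo_on:
            ecmo = self.devices.ecmo
            q = y[i_qe]
            q_eff = max(q, 0.0) if ecmo.backflow_valve else q
            ch = ecmo.characteristic
            head = ch.k1 * ecmo.rpm * ecmo.rpm - ch.k2 * q_eff * ecmo.rpm - ch.k3 * q_eff * q_eff
            dq = (
                head
                - (p_all[self._ecmo_return_i] - p_all[self._ecmo_drain_i])
                - ecmo.cannula_resistance * q_eff
            ) / ecmo.cannula_inertance
            if ecmo.backflow_valve and q <= 0.0 and dq < 0.0:
                dq = 0.0
            dy[i_qe] = dq
            acc[self._ecmo_drain_i] -= q_eff
            acc[self._ecmo_return_i] += q_eff

        i_vg = self.layout["V_gas"]
        if self._iabp_on:
            iabp = self.devices.iabp
            phi = (t / self.period) % 1.0
            phase = iabp_phase(
                phi,
                iabp,
                self.landmark_fractions["inflation"],
                self.landmark_fractions["deflation"],
                y[i_vg],
            )
            gf = iabp_gas_flow(phase, p_all[self._balloon_i], y[i_vg], iabp)
            dy[i_vg] = gf
            acc[self._balloon_i] += gf

        dy[0:4] = acc[0:4]
        for i, inv_c in enumerate(self._inv_c):
            dy[4 + i] = acc[4 + i] * inv_c
        return dy

    # -- algebraic signal recovery --------------------------------------
    def signals_at(self, t: float, y) -> dict[str, float]:
        """All algebraic signals (pressures, flows) at one state sample."""
        out: dict[str, float] = {}
        a = [activation_fraction(t, c.timing) for c in self._chambers]
        p_ch = [chamber_pressure(y[i], a[i], self._chambers[i]) for i in range(4)]
        sep = self._septum
        if sep.k_sept:
            p_lv = p_ch[0] + sep.k_sept * (y[1] - sep.v_rv_ref)
            p_rv = p_ch[1] + sep.k_sept * (y[0] - sep.v_lv_ref)
            p_ch[0], p_ch[1] = p_lv, p_rv
        p_all = p_ch + [y[4 + i] for i in range(len(self.node_order))]
        for i, name in enumerate(CHAMBER_ORDER):
            out[f"P_{name}"] = p_ch[i]
            out[f"V_{name}"] = y[i]
            out[f"a_{name}"] = a[i]
        for i, name in enumerate(self.node_order):
            out[f"P_{name}"] = y[4 + i]
        out["Q_mitral"] = valve_flow(p_all[2], p_all[0], self._valves["mitral"])
        out["Q_aortic"] = valve_flow(p_all[0], p_all[self._aa_i], self._valves["aortic"])
        out["Q_tricuspid"] = valve_flow(p_all[3], p_all[1], self._valves["tricuspid"])
        out["Q_pulmonic"] = valve_flow(p_all[1], p_all[self._pa_i], self._valves["pulmonic"])
        for name, si, ti, inv_r in self._resistive:
            out[f"Q_{name}"] = (p_all[si] - p_all[ti]) * inv_r
        for lk, (off, *_rest) in zip(
            self.patient.topology.inertant_links, self._inertant
        ):
            out[f"Q_{lk.name}"] = y[off]
        q = y[self.layout["Q_ecmo"]]
        if self._ecmo_on and self.devices.ecmo.backflow_valve:
            q = max(q, 0.0)
        out["Q_ecmo"] = q if self._ecmo_on else 0.0
        out["V_gas"] = y[self.layout["V_gas"]]
        if self._iabp_on:
            iabp = self.devices.iabp
            phi = (t / self.period) % 1.0
            phase = iabp_phase(
                phi,
                iabp,
                self.landmark_fractions["inflation"],
                self.landmark_fractions["deflation"],
                out["V_gas"],
            )
            out["Q_iabp"] = iabp_gas_flow(
                phase, p_all[self._balloon_i], out["V_gas"], iabp
            )
        else:
            out["Q_iabp"] = 0.0
        return out


def assemble_derivative(patient: "PatientParams", devices: DeviceConfig) -> AssembledModel:
    """Build the global derivative function for one patient + device setup."""
    return AssembledModel(patient, devices)


def initial_state(patient: "PatientParams", devices: DeviceConfig) -> np.ndarray:
    """Initial condition with total blood volume matched to the patient.

    Node pressures start from the parameter file's reference values; the
    difference between the implied total volume and the patient's
    ``total_blood_volume`` is distributed over the large venous reservoirs
    (venae cavae, femoral vein, splanchnic bed) in proportion to compliance.
    """
    model = AssembledModel(patient, devices)
    y0 = np.zeros(model.n_states)
    for i, name in enumerate(CHAMBER_ORDER):
        y0[i] = patient.initial_chamber_volumes[name]
    topo = patient.topology
    for i, name in enumerate(model.node_order):
        y0[4 + i] = topo.nodes[name].init_pressure

    pressures = {n: y0[4 + i] for i, n in enumerate(model.node_order)}
    v_ref = total_blood_volume(pressures, topo, y0[0:4])
    dv = patient.total_blood_volume - v_ref
    reservoirs = [
        "inferior_vena_cava",
        "superior_vena_cava",
        "femoral_vein",
        "splanchnic",
    ]
    c_total = sum(topo.nodes[n].compliance for n in reservoirs)
    for n in reservoirs:
        i = model.node_order.index(n)
        y0[4 + i] += dv / c_total
    return y0


def _beat_monitors(t: np.ndarray, Y: np.ndarray, model: AssembledModel) -> dict[str, float]:
    lay = model.layout
    v_lv = Y[lay["V_LV"]]
    v_rv = Y[lay["V_RV"]]
    return {
        "lv_sv": float(v_lv.max() - v_lv.min()),
        "rv_sv": float(v_rv.max() - v_rv.min()),
        "mean_aop": float(np.trapezoid(Y[lay["P_ascending_aorta"]], t) / (t[-1] - t[0])),
        "mean_pap": float(np.trapezoid(Y[lay["P_pulmonary_artery"]], t) / (t[-1] - t[0])),
        "mean_pvp": float(np.trapezoid(Y[lay["P_pulmonary_veins"]], t) / (t[-1] - t[0])),
    }


def _aortic_closure_fraction(t: np.ndarray, q_ao: np.ndarray, period: float) -> float | None:
    """Cycle fraction at which aortic flow last falls to (near) zero."""
    open_idx = np.flatnonzero(q_ao > _VALVE_CLOSED_FLOW)
    if open_idx.size == 0 or open_idx[-1] == len(t) - 1:
        return None
    t_close = t[open_idx[-1] + 1]
    return float(((t_close - t[0]) / period) % 1.0)


def run_to_steady_state(
    patient: "PatientParams",
    devices: DeviceConfig | None = None,
    sim: SimulationConfig | None = None,
) -> BeatSeries:
    """Integrate beat by beat until periodic steady state, return final beat.

    Convergence requires every monitor scalar (LV/RV stroke volume, mean
    aortic, pulmonary-arterial and pulmonary-venous pressures) to change by
    less than the steady-state tolerance, relatively, between successive
    beats.  Raises :class:`SteadyStateError` with the last residuals if the
    beat budget is exhausted, and a solver diagnostic naming the worst state
    variable if a step fails.
    """
    devices = devices or DeviceConfig()
    sim = sim or SimulationConfig()
    model = AssembledModel(patient, devices)
    T = patient.period
    n_samp = max(int(round(T * sim.sampling_rate)), 20) + 1

    y = initial_state(patient, devices)
    prev: dict[str, float] | None = None
    residuals: dict[str, float] = {}
    for beat in range(sim.max_beats):
        t0, t1 = beat * T, (beat + 1) * T
        t_eval = np.linspace(t0, t1, n_samp)
        sol = solve_ivp(
            model,
            (t0, t1),
            y,
            method=sim.method,
            rtol=sim.rtol,
            atol=sim.atol,
            t_eval=t_eval,
            dense_output=False,
        )
        if not sol.success:
            inv_layout = {v: k for k, v in model.layout.items()}
            worst = inv_layout.get(int(np.argmax(np.abs(model(sol.t[-1], sol.y[:, -1])))), "?")
            raise SteadyStateError(
                f"solver failed in beat {beat + 1} ({sol.message}); "
                f"largest local derivative on {worst}"
            )
        y = sol.y[:, -1]

        mon = _beat_monitors(sol.t, sol.y, model)
        if prev is not None:
            residuals = {
                k: abs(mon[k] - prev[k]) / max(abs(mon[k]), 1.0) for k in mon
            }
            if beat + 1 >= sim.min_beats and all(
                r < sim.steady_tolerance for r in residuals.values()
            ):
                return _package_beat(sol, model, patient, devices, beat + 1)
        prev = mon

        if devices.iabp.enabled:
            q_ao = np.array(
                [
                    model.signals_at(tt, sol.y[:, k])["Q_aortic"]
                    for k, tt in enumerate(sol.t)
                ]
            )
            frac = _aortic_closure_fraction(sol.t, q_ao, T)
            model.landmark_fractions["inflation"] = frac
            lead = devices.iabp.deflation_lead
            model.landmark_fractions["deflation"] = (1.0 - lead / T) % 1.0

    raise SteadyStateError(
        f"no periodic steady state within {sim.max_beats} beats "
        f"(worst residual {max(residuals.values()):.3e})"
        if residuals
        else f"no periodic steady state within {sim.max_beats} beats",
        residuals,
    )


def _package_beat(sol, model: AssembledModel, patient, devices, n_beats: int) -> BeatSeries:
    t = sol.t - sol.t[0]
    samples = [model.signals_at(tt, sol.y[:, k]) for k, tt in enumerate(sol.t)]
    signals = {
        key: np.array([s[key] for s in samples]) for key in samples[0]
    }
    series = BeatSeries(
        t=t,
        signals=signals,
        landmarks={},
        period=patient.period,
        heart_rate=patient.heart_rate,
        n_beats_run=n_beats,
        patient=patient,
        devices=devices,
    )
    series.landmarks = detect_landmarks(series)
    return series


def detect_landmarks(beat: BeatSeries) -> dict[str, float]:
    """Cycle landmarks of one beat, per ventricle.

    End-diastole is the time of maximum ventricular volume, end-systole the
    time of minimum volume; aortic (pulmonic) valve closure is the last time
    forward valve flow falls to zero within the beat.  Raises ``ValueError``
    on non-beating (flat) volume signals.
    """
    t = beat.t
    lm: dict[str, float] = {}
    for side, q_name in (("LV", "Q_aortic"), ("RV", "Q_pulmonic")):
        v = beat.signals[f"V_{side}"]
        if float(v.max() - v.min()) < 1e-6 * max(float(v.max()), 1.0):
            raise ValueError(f"flat {side} volume signal: no beat to analyse")
        lm[f"t_ed_{side}"] = float(t[int(np.argmax(v))])
        lm[f"t_es_{side}"] = float(t[int(np.argmin(v))])
        q = beat.signals[q_name]
        open_idx = np.flatnonzero(q > _VALVE_CLOSED_FLOW)
        if open_idx.size and open_idx[-1] < len(t) - 1:
            lm[f"t_valve_close_{side}"] = float(t[open_idx[-1] + 1])
    lm["t_systole_onset"] = 0.0
    return lm
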
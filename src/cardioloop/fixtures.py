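"""Patient parameter fixtures: healthy reference and cardiogenic shock.

No published per-segment parameter table exists for the study conditions
this package emulates, so the fixtures are stand-ins: the healthy reference
is read verbatim from the packaged ``data/default_patient.yaml`` (the single
source of truth for every default), and the cardiogenic-shock (CS) patient
is derived from it by a deterministic tuner that adjusts three knobs —

* a ventricular systolic remodeling scale (Ees slope, volume-intercept
  shift and EDPVR exponent together; LV-dominant — see ``apply_knobs``),
* total blood volume,
* a systemic peripheral resistance scale —

until the converged simulation simultaneously satisfies the clinical CS
criteria: systolic blood pressure < 90 mmHg, SVRi < 1800 dyn·s·cm⁻⁵·m²,
PCWP > 15 mmHg and cardiac index < 2.2 L/min/m².  The tuner is bisection on
one knob per bound in a fixed documented order, so rerunning it always
returns the same parameters.

The CS patient's heart rate is fixed at 90 bpm (typical CS tachycardia) and
BSA at 1.8 m²; both are package choices.
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .chambers import (
    ActivationTiming,
    ChamberParams,
    ConfigurationError,
    SeptumParams,
    ValveParams,
    atrial_timing,
    ventricular_timing,
)
from .network import NetworkTopology, build_topology

__all__ = [
    "PatientParams",
    "TuningSpec",
    "default_config",
    "patient_from_config",
    "patient_to_config",
    "make_healthy_patient",
    "make_cs_patient",
    "export_patient",
    "load_patient",
]

#: systemic microcirculatory links scaled by the resistance knob (the
#: coronary branch is deliberately excluded so coronary-flow comparisons
#: keep a fixed coronary resistance)
SYSTEMIC_RESISTANCE_LINKS = (
    "arch_to_upper_body",
    "upper_body_to_svc",
    "abdominal_to_renal",
    "renal_to_ivc",
    "abdominal_to_splanchnic",
    "splanchnic_to_ivc",
    "femoral_to_lower_body",
    "lower_body_to_fv",
)


@dataclass
class PatientParams:
    """Complete closed-loop parameter set for one virtual patient."""

    chambers: dict[str, ChamberParams]
    septum: SeptumParams
    valves: dict[str, ValveParams]
    topology: NetworkTopology
    heart_rate: float  # bpm
    bsa: float  # m^2
    total_blood_volume: float  # mL
    initial_chamber_volumes: dict[str, float]
    label: str = "patient"
    knobs: dict[str, float] = field(
        default_factory=lambda: {"ees_scale": 1.0, "volume_scale": 1.0, "res_scale": 1.0}
    )

    def __post_init__(self) -> None:
        if not 40 <= self.heart_rate <= 140:
            raise ConfigurationError(
                f"heart rate must lie in [40, 140] bpm, got {self.heart_rate}"
            )
        if self.bsa <= 0 or self.total_blood_volume <= 0:
            raise ConfigurationError("BSA and total blood volume must be positive")
        for name in ("LV", "RV", "LA", "RA"):
            if name not in self.chambers:
                raise ConfigurationError(f"missing chamber {name}")

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate


@dataclass
class TuningSpec:
    """Targets and knob bounds for the deterministic CS tuner."""

    sbp_bound: float = 90.0  # mmHg, simulated SBP must be below
    svri_bound: float = 1800.0  # dyn*s*cm^-5*m^2, below
    pcwp_bound: float = 15.0  # mmHg, above
    ci_bound: float = 2.2  # L/min/m^2, below
    # interior targets the bisections aim at, leaving margin inside each bound
    ci_target: float = 1.95
    pcwp_target: float = 16.5
    svri_target: float = 1700.0
    ees_scale_bounds: tuple[float, float] = (0.1, 1.0)
    volume_scale_bounds: tuple[float, float] = (0.9, 1.35)
    res_scale_bounds: tuple[float, float] = (0.35, 1.1)
    max_iterations: int = 150
    bisection_steps: int = 6
    outer_passes: int = 3
    heart_rate: float = 90.0
    initial_knobs: dict[str, float] = field(
        default_factory=lambda: {"ees_scale": 0.34, "volume_scale": 1.00, "res_scale": 0.56}
    )

    def __post_init__(self) -> None:
        if self.max_iterations < 10:
            raise ConfigurationError("max_iterations must be >= 10")
        for lo, hi in (
            self.ees_scale_bounds,
            self.volume_scale_bounds,
            self.res_scale_bounds,
        ):
            if not lo < hi:
                raise ConfigurationError("knob bounds must satisfy lo < hi")


def default_config() -> dict:
    """Parsed contents of the packaged default parameter file."""
    ref = importlib.resources.files("cardioloop") / "data" / "default_patient.yaml"
    return yaml.safe_load(ref.read_text())


def patient_from_config(config: dict, label: str = "patient") -> PatientParams:
    """Build a :class:`PatientParams` from a configuration mapping."""
    hr = float(config["heart_rate"])
    period = 60.0 / hr
    chambers: dict[str, ChamberParams] = {}
    for name, c in config["chambers"].items():
        timing = (
            ventricular_timing(period)
            if name in ("LV", "RV")
            else atrial_timing(period)
        )
        chambers[name] = ChamberParams(
            name=name,
            ees=float(c["ees"]),
            v0=float(c["v0"]),
            edpvr_a=float(c["edpvr_a"]),
            edpvr_b=float(c["edpvr_b"]),
            timing=timing,
        )
    septum = SeptumParams(**{k: float(v) for k, v in config["septum"].items()})
    valves = {
        name: ValveParams(
            name=name,
            resistance=float(v["resistance"]),
            regularization=float(v.get("regularization", 0.0)),
        )
        for name, v in config["valves"].items()
    }
    topology = build_topology(config)
    return PatientParams(
        chambers=chambers,
        septum=septum,
        valves=valves,
        topology=topology,
        heart_rate=hr,
        bsa=float(config["bsa"]),
        total_blood_volume=float(config["total_blood_volume"]),
        initial_chamber_volumes={
            k: float(v) for k, v in config["initial_chamber_volumes"].items()
        },
        label=label,
    )


def patient_to_config(patient: PatientParams) -> dict:
    """Serialise a patient back to the configuration-file structure."""
    cfg: dict = {
        "heart_rate": patient.heart_rate,
        "bsa": patient.bsa,
        "total_blood_volume": patient.total_blood_volume,
        "chambers": {
            n: {
                "ees": c.ees,
                "v0": c.v0,
                "edpvr_a": c.edpvr_a,
                "edpvr_b": c.edpvr_b,
            }
            for n, c in patient.chambers.items()
        },
        "septum": {
            "k_sept": patient.septum.k_sept,
            "v_lv_ref": patient.septum.v_lv_ref,
            "v_rv_ref": patient.septum.v_rv_ref,
        },
        "valves": {
            n: {"resistance": v.resistance, "regularization": v.regularization}
            for n, v in patient.valves.items()
        },
        "nodes": {
            n: {
                "compliance": s.compliance,
                "unstressed_volume": s.unstressed_volume,
                "init_pressure": s.init_pressure,
            }
            for n, s in patient.topology.nodes.items()
        },
        "links": {
            lk.name: {
                "source": lk.source,
                "target": lk.target,
                "resistance": lk.resistance,
                "inertance": lk.inertance,
            }
            for lk in patient.topology.links
        },
        "initial_chamber_volumes": dict(patient.initial_chamber_volumes),
        "label": patient.label,
        "knobs": dict(patient.knobs),
    }
    return cfg


def export_patient(patient: PatientParams, path: str | Path) -> Path:
    """Write a patient to a YAML file the simulator can reload."""
    path = Path(path)
    path.write_text(yaml.safe_dump(patient_to_config(patient), sort_keys=False))
    return path


def load_patient(path: str | Path) -> PatientParams:
    """Load a patient from a YAML configuration file."""
    cfg = yaml.safe_load(Path(path).read_text())
    patient = patient_from_config(cfg, label=cfg.get("label", "patient"))
    if "knobs" in cfg:
        patient.knobs = {k: float(v) for k, v in cfg["knobs"].items()}
    return patient


def make_healthy_patient() -> PatientParams:
    """Healthy reference patient, built verbatim from the packaged defaults."""
    return patient_from_config(default_config(), label="healthy")


def apply_knobs(
    base_config: dict,
    ees_scale: float,
    volume_scale: float,
    res_scale: float,
    heart_rate: float,
    label: str = "patient",
) -> PatientParams:
    """Apply the three tuning knobs to a copy of a base configuration.

    Only the declared knobs change: ventricular systolic remodeling (the
    ``ees_scale`` knob), total blood volume, and the systemic
    microcirculatory resistances.  Everything else is untouched.

    The remodeling knob implements the dilated failing-ventricle phenotype
    rather than a bare slope change: lowering the scale ``s`` reduces the
    ESPVR slope (Ees × s), shifts the ESPVR/EDPVR volume intercept rightward
    (V0 + 100·(1−s) mL for the LV), and stiffens the EDPVR exponent
    (B × (1 + 0.3·(1−s))), so the shocked ventricle operates dilated at
    elevated filling pressure without becoming unboundedly
    afterload-sensitive.  The right ventricle remodels half as strongly
    (slope factor (1+s)/2, intercept +50·(1−s), exponent ×(1+0.2·(1−s))) —
    the typical left-dominant cardiogenic-shock picture.
    """
    cfg = copy.deepcopy(base_config)
    cfg["heart_rate"] = heart_rate
    s = ees_scale
    lv = cfg["chambers"]["LV"]
    lv["ees"] = float(lv["ees"]) * s
    lv["v0"] = float(lv["v0"]) + 100.0 * (1.0 - s)
    lv["edpvr_b"] = float(lv["edpvr_b"]) * (1.0 + 0.6 * (1.0 - s))
    rv = cfg["chambers"]["RV"]
    rv["ees"] = float(rv["ees"]) * (0.5 + 0.5 * s)
    rv["v0"] = float(rv["v0"]) + 50.0 * (1.0 - s)
    rv["edpvr_b"] = float(rv["edpvr_b"]) * (1.0 + 0.3 * (1.0 - s))
    cfg["total_blood_volume"] = float(cfg["total_blood_volume"]) * volume_scale
    for name in SYSTEMIC_RESISTANCE_LINKS:
        cfg["links"][name]["resistance"] = (
            float(cfg["links"][name]["resistance"]) * res_scale
        )
    patient = patient_from_config(cfg, label=label)
    patient.knobs = {
        "ees_scale": ees_scale,
        "volume_scale": volume_scale,
        "res_scale": res_scale,
    }
    return patient


def _cs_metrics(patient: PatientParams, sim=None) -> dict[str, float]:
    """Converged-run metrics the tuner targets (SBP, SVRi, PCWP, CI)."""
    from .metrics import compute_reports
    from .simulator import run_to_steady_state

    beat = run_to_steady_state(patient, sim=sim)
    haemo, _ = compute_reports(beat)
    return {
        "sbp": haemo.aop_max,
        "svri": haemo.svri,
        "pcwp": haemo.pcwp,
        "ci": haemo.cardiac_index,
    }


def make_cs_patient(
    spec: TuningSpec | None = None,
    sim=None,
    initial_knobs: dict[str, float] | None = None,
) -> PatientParams:
    """Deterministically tune the cardiogenic-shock baseline patient.

    Fixed knob order, each adjusted by bisection against a monotone target:

    1. ventricular ``ees_scale`` down until cardiac index reaches its
       interior target (which also pulls systolic pressure under its bound),
    2. ``volume_scale`` up until PCWP reaches its target,
    3. ``res_scale`` down until SVRi reaches its target,

    with the whole pass repeated (knobs interact weakly) and all four bounds
    verified on the final converged run.  Raises ``ConfigurationError``
    listing the violated bounds if they cannot all be met within the knob
    bounds.
    """
    spec = spec or TuningSpec()
    base = default_config()
    knobs = dict(initial_knobs or spec.initial_knobs)
    evaluations = 0
    memo: dict[tuple[float, float, float], dict[str, float]] = {}

    def run(k: dict[str, float]) -> dict[str, float]:
        nonlocal evaluations
        key = (k["ees_scale"], k["volume_scale"], k["res_scale"])
        if key in memo:
            return memo[key]
        evaluations += 1
        if evaluations > spec.max_iterations:
            raise ConfigurationError(
                f"CS tuner exceeded {spec.max_iterations} simulations"
            )
        p = apply_knobs(
            base, k["ees_scale"], k["volume_scale"], k["res_scale"],
            heart_rate=spec.heart_rate, label="cardiogenic_shock",
        )
        memo[key] = _cs_metrics(p, sim=sim)
        return memo[key]

    def bisect(knob: str, bounds: tuple[float, float], metric: str,
               target: float, increasing: bool, rel_tol: float = 0.02) -> None:
        """Move one knob until ``metric`` is within rel_tol of ``target``.

        ``increasing`` states whether the metric grows with the knob value;
        bisection is seeded at the current knob value.
        """
        lo, hi = bounds
        m = run(knobs)[metric]
        if abs(m - target) / max(abs(target), 1e-9) <= rel_tol:
            return
        x = knobs[knob]
        # establish a bracket from the current point
        if (m > target) == increasing:
            hi = x
        else:
            lo = x
        for _ in range(spec.bisection_steps):
            x = 0.5 * (lo + hi)
            knobs[knob] = x
            m = run(knobs)[metric]
            if abs(m - target) / max(abs(target), 1e-9) <= rel_tol:
                return
            if (m > target) == increasing:
                hi = x
            else:
                lo = x

    for _ in range(spec.outer_passes):
        bisect("ees_scale", spec.ees_scale_bounds, "ci", spec.ci_target, True)
        bisect("volume_scale", spec.volume_scale_bounds, "pcwp", spec.pcwp_target, True)
        bisect("res_scale", spec.res_scale_bounds, "svri", spec.svri_target, True)
        final = run(knobs)
        ok = (
            final["sbp"] < spec.sbp_bound
            and final["svri"] < spec.svri_bound
            and final["pcwp"] > spec.pcwp_bound
            and final["ci"] < spec.ci_bound
        )
        if ok:
            return apply_knobs(
                base, knobs["ees_scale"], knobs["volume_scale"], knobs["res_scale"],
                heart_rate=spec.heart_rate, label="cardiogenic_shock",
            )

    violations = []
    if not final["sbp"] < spec.sbp_bound:
        violations.append(f"SBP {final['sbp']:.1f} !< {spec.sbp_bound}")
    if not final["svri"] < spec.svri_bound:
        violations.append(f"SVRi {final['svri']:.0f} !< {spec.svri_bound}")
    if not final["pcwp"] > spec.pcwp_bound:
        violations.append(f"PCWP {final['pcwp']:.1f} !> {spec.pcwp_bound}")
    if not final["ci"] < spec.ci_bound:
        violations.append(f"CI {final['ci']:.2f} !< {spec.ci_bound}")
    raise ConfigurationError(
        "CS tuning bounds unreachable within knob limits: " + "; ".join(violations)
    )
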
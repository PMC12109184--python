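"""Full study pipeline: the 13-condition run matrix and percentage changes.

The matrix crosses the pathological (unassisted) baseline with every
combination of ECMO configuration (central or peripheral), pump speed
(3000, 3500, 4000 rpm) and IABP state (off, or on at 260 / −10 mmHg drive /
vacuum pressure) — 1 + 2×3×2 = 13 conditions.  Every metric is also
reported as a signed percentage change versus the baseline, and a
directional consistency suite checks the qualitative physiology expected of
each support mode.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .devices import DeviceConfig, EcmoConfig, EcmoMode, IabpConfig
from .fixtures import PatientParams, patient_to_config
from .metrics import EnergeticReport, HaemodynamicReport, compute_reports, percentage_change
from .simulator import BeatSeries, SimulationConfig, SteadyStateError, run_to_steady_state

__all__ = [
    "Condition",
    "RunMatrix",
    "StudyReport",
    "build_run_matrix",
    "run_condition",
    "run_full_matrix",
    "directional_consistency_check",
    "export_report",
]

RPM_SETTINGS = (3000.0, 3500.0, 4000.0)
IABP_DRIVE_MMHG = 260.0
IABP_VACUUM_MMHG = -10.0


@dataclass(frozen=True)
class Condition:
    """One cell of the study matrix."""

    name: str
    ecmo_mode: EcmoMode
    rpm: float
    iabp: bool

    def devices(self) -> DeviceConfig:
        return DeviceConfig(
            ecmo=EcmoConfig(mode=self.ecmo_mode, rpm=self.rpm),
            iabp=IabpConfig(
                enabled=self.iabp,
                drive_pressure=IABP_DRIVE_MMHG,
                vacuum_pressure=IABP_VACUUM_MMHG,
            ),
        )


@dataclass
class RunMatrix:
    """Ordered condition list; the pathological baseline is always first."""

    conditions: list[Condition]

    def __post_init__(self) -> None:
        if len(self.conditions) != 13:
            raise ValueError(f"run matrix must have 13 conditions, got {len(self.conditions)}")
        first = self.conditions[0]
        if first.ecmo_mode is not EcmoMode.OFF or first.iabp:
            raise ValueError("first condition must be the unassisted baseline")


@dataclass
class StudyReport:
    """Absolute metrics per condition plus percentage changes vs baseline."""

    absolute: pd.DataFrame  # index: condition name; columns: metrics
    percent_change: pd.DataFrame  # 12 rows, same columns
    provenance: dict = field(default_factory=dict)


def build_run_matrix() -> RunMatrix:
    conditions = [Condition("pathological", EcmoMode.OFF, 0.0, False)]
    for mode in (EcmoMode.CENTRAL, EcmoMode.PERIPHERAL):
        for rpm in RPM_SETTINGS:
            for iabp in (False, True):
                name = f"{mode.value}_{int(rpm)}rpm" + ("_iabp" if iabp else "")
                conditions.append(Condition(name, mode, rpm, iabp))
    return RunMatrix(conditions)


def run_condition(
    patient: PatientParams,
    condition: Condition,
    sim: SimulationConfig | None = None,
) -> tuple[HaemodynamicReport, EnergeticReport, BeatSeries]:
    """Simulate one condition to steady state and compute its metrics."""
    try:
        beat = run_to_steady_state(patient, condition.devices(), sim)
    except SteadyStateError as err:
        raise SteadyStateError(
            f"condition {condition.name!r}: {err}", getattr(err, "residuals", None)
        ) from err
    haemo, energetic = compute_reports(beat)
    return haemo, energetic, beat


def _metric_row(haemo: HaemodynamicReport, energetic: EnergeticReport) -> dict[str, float]:
    row = haemo.as_dict()
    row.update(energetic.as_dict())
    return row


def run_full_matrix(
    patient: PatientParams,
    matrix: RunMatrix | None = None,
    sim: SimulationConfig | None = None,
    keep_beats: bool = False,
) -> StudyReport:
    """Run all 13 conditions and tabulate absolute and percentage metrics."""
    matrix = matrix or build_run_matrix()
    rows: dict[str, dict[str, float]] = {}
    beats: dict[str, BeatSeries] = {}
    for cond in matrix.conditions:
        haemo, energetic, beat = run_condition(patient, cond, sim)
        rows[cond.name] = _metric_row(haemo, energetic)
        if keep_beats:
            beats[cond.name] = beat

    absolute = pd.DataFrame.from_dict(rows, orient="index")
    base = absolute.iloc[0]
    pct = absolute.iloc[1:].apply(
        lambda row: pd.Series(
            {
                col: percentage_change(row[col], base[col])
                for col in absolute.columns
                if base[col] != 0
            }
        ),
        axis=1,
    )

    cfg_text = json.dumps(patient_to_config(patient), sort_keys=True)
    sim_cfg = sim or SimulationConfig()
    provenance = {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "patient_label": patient.label,
        "solver": {
            "method": sim_cfg.method,
            "rtol": sim_cfg.rtol,
            "atol": sim_cfg.atol,
            "steady_tolerance": sim_cfg.steady_tolerance,
        },
        "package_version": _package_version(),
    }
    report = StudyReport(absolute=absolute, percent_change=pct, provenance=provenance)
    if keep_beats:
        report.provenance["n_beats_run"] = {k: b.n_beats_run for k, b in beats.items()}
        report.beats = beats  # type: ignore[attr-defined]
    return report


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("cardioloop")
    except Exception:  # pragma: no cover
        return "unknown"


#: directional expectations distilled from the qualitative findings the
#: model family reports: (check name, condition, metric, expected sign)
def _directional_expectations() -> list[tuple[str, str, str, int]]:
    checks: list[tuple[str, str, str, int]] = []
    checks += [
        ("central alone raises LVESV", "central_3000rpm", "lvesv", +1),
        ("central alone lowers RVEDV", "central_3000rpm", "rvedv", -1),
    ]
    for m in ("lvesv", "lvedv", "rvesv", "rvedv", "laesv", "laedv"):
        checks.append((f"peripheral alone raises {m.upper()}", "peripheral_3000rpm", m, +1))
    for m in ("lvedv", "rvedv", "laedv"):
        checks.append((f"central + IABP lowers {m.upper()}", "central_3000rpm_iabp", m, -1))
    for rpm in (3000, 3500, 4000):
        checks.append((f"peripheral {rpm} raises PCWP", f"peripheral_{rpm}rpm", "pcwp", +1))
        checks.append((f"peripheral {rpm} raises mean PAP", f"peripheral_{rpm}rpm", "pap_mean", +1))
        checks.append((f"central {rpm} lowers PCWP", f"central_{rpm}rpm", "pcwp", -1))
        checks.append((f"central {rpm} lowers mean PAP", f"central_{rpm}rpm", "pap_mean", -1))
    return checks


@dataclass
class DirectionalResult:
    name: str
    condition: str
    metric: str
    expected_sign: int
    observed_pct: float
    passed: bool


def directional_consistency_check(report: StudyReport) -> list[DirectionalResult]:
    """Evaluate the documented sign expectations against a study report.

    Besides fixed sign checks, monotonicity with pump speed is required of
    coronary flow and total flow in every configuration, and mean aortic
    pressure must be higher with IABP than without at matched conditions.
    Failures are reported, never raised.
    """
    pct = report.percent_change
    absolute = report.absolute
    results: list[DirectionalResult] = []

    for name, cond, metric, sign in _directional_expectations():
        obs = float(pct.loc[cond, metric])
        results.append(
            DirectionalResult(name, cond, metric, sign, obs, obs * sign > 0)
        )

    for mode in ("central", "peripheral"):
        for iabp_suffix in ("", "_iabp"):
            for metric in ("coronary_flow", "total_flow"):
                conds = [f"{mode}_{rpm}rpm{iabp_suffix}" for rpm in (3000, 3500, 4000)]
                vals = [float(absolute.loc[c, metric]) for c in conds]
                increasing = vals[0] < vals[1] < vals[2]
                results.append(
                    DirectionalResult(
                        f"{metric} increases with rpm ({mode}{iabp_suffix or ''})",
                        conds[-1],
                        metric,
                        +1,
                        percentage_change(vals[-1], vals[0]),
                        increasing,
                    )
                )

    for mode in ("central", "peripheral"):
        for rpm in (3000, 3500, 4000):
            off_c, on_c = f"{mode}_{rpm}rpm", f"{mode}_{rpm}rpm_iabp"
            off_v = float(absolute.loc[off_c, "aop_mean"])
            on_v = float(absolute.loc[on_c, "aop_mean"])
            results.append(
                DirectionalResult(
                    f"IABP raises mean AoP ({mode} {rpm} rpm)",
                    on_c,
                    "aop_mean",
                    +1,
                    percentage_change(on_v, off_v),
                    on_v > off_v,
                )
            )
    return results


def export_report(report: StudyReport, path: str | Path) -> dict[str, Path]:
    """Write tidy CSVs and a machine-readable summary; returns the paths."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    abs_path = path / "metrics_absolute.csv"
    pct_path = path / "metrics_percent_change.csv"
    summary_path = path / "summary.json"
    report.absolute.to_csv(abs_path, index_label="condition")
    report.percent_change.to_csv(pct_path, index_label="condition")
    summary = {
        "provenance": report.provenance,
        "conditions": list(report.absolute.index),
        "metrics": list(report.absolute.columns),
        "absolute": report.absolute.to_dict(orient="index"),
        "percent_change": report.percent_change.to_dict(orient="index"),
    }
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    return {"absolute": abs_path, "percent_change": pct_path, "summary": summary_path}
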
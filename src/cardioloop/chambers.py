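"""Time-varying elastance heart chambers, septal coupling and diode valves.

Each chamber blends an end-systolic pressure-volume relation (ESPVR) and an
end-diastolic one (EDPVR) with a periodic activation fraction ``a(t)``::

    P(V, t) = a(t) * Ees * (V - V0) + (1 - a(t)) * A * (exp(B * (V - V0)) - 1)

``Ees`` is the ESPVR slope (mmHg/mL), ``V0`` its volume intercept (mL), and
``A`` (mmHg) / ``B`` (1/mL) shape the exponential EDPVR.  Both relations are
anchored at zero pressure for ``V = V0``.

The activation fraction is a raised cosine rising from 0 at systole onset to
exactly 1 at a configurable peak fraction of the systolic duration ``Ts`` and
falling back to 0 at ``Ts``; it is zero for the rest of the cycle::

    phi = ((t/T - t0) mod 1) * T / Ts          (0 <= phi <= 1 during systole)
    a   = 0.5 * (1 - cos(pi * phi / p))        for phi <= p  (peak fraction p)
    a   = 0.5 * (1 + cos(pi * (phi - p)/(1-p)))  for phi >  p

Ventricular interdependence is a pressure-superposition septal term:
``P_lv = P_lv,free + k_sept * (V_rv - V_rv,ref)`` and symmetrically for the
right ventricle; zero coupling recovers independent chambers.

Units throughout: mmHg, mL, s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ActivationTiming",
    "ChamberParams",
    "SeptumParams",
    "ValveParams",
    "activation_fraction",
    "chamber_pressure",
    "septal_coupled_pressures",
    "valve_flow",
]


class ConfigurationError(ValueError):
    """Raised when a parameter set violates its physical constraints."""


@dataclass
class ActivationTiming:
    """Timing of one chamber's activation within the cardiac cycle.

    Parameters
    ----------
    period : float
        Cardiac period T in seconds.
    onset_fraction : float
        Systole onset t0 as a fraction of T, in ``[0, 1)``.  Atrial onsets
        typically sit near the end of the cycle so that atrial contraction
        precedes ventricular contraction by the AV delay.
    systolic_duration : float
        Duration Ts of the active phase in seconds, ``0 < Ts < T``.
    peak_fraction : float
        Position of the activation peak within Ts, in ``(0, 1)``.
    """

    period: float
    onset_fraction: float
    systolic_duration: float
    peak_fraction: float = 0.45

    def __post_init__(self) -> None:
        if not self.period > 0:
            raise ConfigurationError(f"period must be positive, got {self.period}")
        if not 0 <= self.onset_fraction < 1:
            raise ConfigurationError(
                f"onset_fraction must lie in [0, 1), got {self.onset_fraction}"
            )
        if not 0 < self.systolic_duration < self.period:
            raise ConfigurationError(
                "systolic_duration must satisfy 0 < Ts < T, got "
                f"Ts={self.systolic_duration}, T={self.period}"
            )
        if not 0 < self.peak_fraction < 1:
            raise ConfigurationError(
                f"peak_fraction must lie in (0, 1), got {self.peak_fraction}"
            )


def ventricular_timing(period: float, peak_fraction: float = 0.45) -> ActivationTiming:
    """Default ventricular timing: onset at cycle start, Ts = 0.3*sqrt(T)."""
    return ActivationTiming(
        period=period,
        onset_fraction=0.0,
        systolic_duration=0.3 * math.sqrt(period),
        peak_fraction=peak_fraction,
    )


def atrial_timing(
    period: float, av_delay: float | None = None, peak_fraction: float = 0.5
) -> ActivationTiming:
    """Atrial timing preceding ventricular systole by the AV delay.

    The default AV delay is 0.16 s at a 0.8 s cycle, scaled as sqrt(T/0.8)
    with heart rate.  The atrial onset wraps to the end of the previous
    cycle so that atrial systole completes around ventricular onset.
    """
    if av_delay is None:
        av_delay = 0.16 * math.sqrt(period / 0.8)
    if av_delay < 0:
        raise ConfigurationError(f"AV delay must be >= 0, got {av_delay}")
    ts = 0.16 * math.sqrt(period)
    onset = (1.0 - av_delay / period) % 1.0
    return ActivationTiming(
        period=period,
        onset_fraction=onset,
        systolic_duration=ts,
        peak_fraction=peak_fraction,
    )


@dataclass
class ChamberParams:
    """Elastance parameters of one chamber (see module docstring)."""

    name: str
    ees: float  # ESPVR slope, mmHg/mL
    v0: float  # unstressed volume, mL
    edpvr_a: float  # EDPVR scale A, mmHg
    edpvr_b: float  # EDPVR exponent B, 1/mL
    timing: ActivationTiming

    def __post_init__(self) -> None:
        if self.ees <= 0:
            raise ConfigurationError(f"{self.name}: Ees must be > 0, got {self.ees}")
        if self.edpvr_a < 0 or self.edpvr_b < 0 or self.v0 < 0:
            raise ConfigurationError(
                f"{self.name}: A, B, V0 must be non-negative "
                f"(A={self.edpvr_a}, B={self.edpvr_b}, V0={self.v0})"
            )


@dataclass
class SeptumParams:
    """Pressure-superposition septal coupling between the ventricles.

    ``k_sept`` (mmHg/mL) adds ``k_sept * (V_other - V_other_ref)`` to each
    ventricle's free-wall pressure.  Zero coupling decouples the chambers.
    Optional analogous atrial coupling defaults to zero.
    """

    k_sept: float = 0.0
    v_lv_ref: float = 100.0
    v_rv_ref: float = 100.0
    k_atrial: float = 0.0
    v_la_ref: float = 50.0
    v_ra_ref: float = 50.0

    def __post_init__(self) -> None:
        if self.k_sept < 0 or self.k_atrial < 0:
            raise ConfigurationError("septal coupling coefficients must be >= 0")


@dataclass
class ValveParams:
    """Ideal diode valve with series resistance.

    ``regularization`` (mmHg) optionally smooths the diode corner over a
    quadratic transition of that width, which keeps the right-hand side C1
    for stiff integrators.  Flow is never negative: no regurgitation.
    """

    name: str
    resistance: float  # mmHg*s/mL
    regularization: float = 0.0

    def __post_init__(self) -> None:
        if self.resistance <= 0:
            raise ConfigurationError(
                f"{self.name}: valve resistance must be > 0, got {self.resistance}"
            )
        if self.regularization < 0:
            raise ConfigurationError(
                f"{self.name}: regularization width must be >= 0"
            )


def activation_fraction(t: float, timing: ActivationTiming) -> float:
    """Periodic activation fraction in [0, 1] at time ``t`` (s).

    Zero outside systole, raised-cosine rise to exactly 1 at the peak
    fraction of Ts, raised-cosine fall back to 0 at Ts.  Continuous
    everywhere and periodic with the cycle period.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    T = timing.period
    phase = (t / T - timing.onset_fraction) % 1.0  # cycle fraction since onset
    s = phase * T / timing.systolic_duration
    if s >= 1.0:
        return 0.0
    p = timing.peak_fraction
    if s <= p:
        return 0.5 * (1.0 - math.cos(math.pi * s / p))
    return 0.5 * (1.0 + math.cos(math.pi * (s - p) / (1.0 - p)))


def espvr_pressure(v: float, p: ChamberParams) -> float:
    """End-systolic pressure Ees*(V - V0) at volume ``v``."""
    return p.ees * (v - p.v0)


def edpvr_pressure(v: float, p: ChamberParams) -> float:
    """End-diastolic pressure A*(exp(B*(V - V0)) - 1) at volume ``v``."""
    return p.edpvr_a * (math.expm1(p.edpvr_b * (v - p.v0)))


def chamber_pressure(v: float, a: float, p: ChamberParams) -> float:
    """Instantaneous chamber pressure: activation-weighted ESPVR/EDPVR blend."""
    return a * espvr_pressure(v, p) + (1.0 - a) * edpvr_pressure(v, p)


def septal_coupled_pressures(
    v_lv: float,
    v_rv: float,
    a_lv: float,
    a_rv: float,
    lv: ChamberParams,
    rv: ChamberParams,
    septum: SeptumParams,
) -> tuple[float, float]:
    """Ventricular pressures including the septal superposition term."""
    p_lv = chamber_pressure(v_lv, a_lv, lv)
    p_rv = chamber_pressure(v_rv, a_rv, rv)
    k = septum.k_sept
    if k:
        p_lv = p_lv + k * (v_rv - septum.v_rv_ref)
        p_rv = p_rv + k * (v_lv - septum.v_lv_ref)
    return p_lv, p_rv


def valve_flow(p_up: float, p_down: float, valve: ValveParams) -> float:
    """Diode-resistor valve flow (mL/s); zero for a reverse gradient.

    With a regularization width ``w`` the flow is quadratic in the gradient
    on ``(0, w)`` and linear with slope 1/R beyond, matching value and slope
    at the junction (so the open-valve flow is ``(dP - w/2)/R``).
    """
    dp = p_up - p_down
    w = valve.regularization
    if dp <= 0.0:
        return 0.0
    if w > 0.0:
        if dp < w:
            return dp * dp / (2.0 * w * valve.resistance)
        return (dp - 0.5 * w) / valve.resistance
    return dp / valve.resistance
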
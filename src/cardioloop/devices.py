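"""Mechanical circulatory support devices: VA ECMO and IABP.

VA ECMO
-------
A centrifugal pump drains venous blood and returns it to the arterial tree
through cannulae with resistance and inertance.  The pump head curve follows
the standard centrifugal similarity form::

    dP_head(Q, w) = k1*w^2 - k2*Q*w - k3*Q^2      [mmHg; w rpm; Q mL/s]

and the cannula flow obeys::

    L_cann * dQ/dt = dP_head(Q, w) - (P_return - P_drain) - R_cann * Q

In the *central* configuration the circuit drains the right atrium and
returns to the ascending aorta; in the *peripheral* configuration it drains
the femoral vein and returns to the femoral artery.  Both attachment nodes
are configurable.  A backflow valve (default on) keeps circuit flow
non-negative.

IABP
----
The balloon in the descending thoracic aorta is driven by a pneumatic
source: a drive-pressure tank during inflation and a vacuum tank during
deflation, each discharging through the gas delivery resistance R_gas::

    dV_gas/dt = (P_tank - P_balloon) / R_gas      (clamped to [0, V_max])

The balloon membrane transmits pressure, so ``P_balloon`` equals the blood
pressure at the balloon node, and the blood flow injected at that node is
``+dV_gas/dt``: positive (augmentation) during diastolic inflation, negative
during systolic deflation.  Inflation is triggered at aortic valve closure,
deflation at a configurable lead before systole onset (default 0.05 s, so
the balloon is already emptying as isovolumic contraction begins).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .chambers import ConfigurationError
from .network import DEVICE_NODES

__all__ = [
    "PumpCharacteristic",
    "EcmoMode",
    "EcmoConfig",
    "IabpConfig",
    "BalloonState",
    "BalloonPhase",
    "DeviceConfig",
    "pump_head",
    "pump_operating_flow",
    "pump_equilibrium_flow",
    "iabp_phase",
    "iabp_gas_flow",
    "balloon_blood_displacement",
]

#: smoothing interval (mL) for the balloon volume clamps
_CLAMP_WIDTH = 1.0


@dataclass
class PumpCharacteristic:
    """Centrifugal pump head curve coefficients.

    Defaults are calibrated once (scripts/calibrate.py) so that, against the
    cardiogenic-shock fixture afterload, circuit flow spans roughly
    2.5-5 L/min over 3000-4000 rpm — the clinically typical VA ECMO range.
    """

    k1: float = 2.0e-5  # mmHg / rpm^2
    k2: float = 4.0e-4  # mmHg / (rpm * mL/s)
    k3: float = 1.0e-2  # mmHg / (mL/s)^2

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 < 0 or self.k3 < 0:
            raise ConfigurationError("pump coefficients require k1 > 0, k2, k3 >= 0")


class EcmoMode(str, Enum):
    OFF = "off"
    CENTRAL = "central"
    PERIPHERAL = "peripheral"


@dataclass
class EcmoConfig:
    """VA ECMO circuit configuration."""

    mode: EcmoMode = EcmoMode.OFF
    rpm: float = 0.0
    drainage_node: str | None = None  # default follows mode
    return_node: str | None = None  # default follows mode
    cannula_resistance: float = 0.45  # mmHg*s/mL, both limbs lumped
    cannula_inertance: float = 0.004  # mmHg*s^2/mL
    priming_volume: float = 400.0  # mL, rigid circuit
    backflow_valve: bool = True
    characteristic: PumpCharacteristic = field(default_factory=PumpCharacteristic)

    def __post_init__(self) -> None:
        if isinstance(self.mode, str):
            self.mode = EcmoMode(self.mode)
        if self.mode is EcmoMode.CENTRAL:
            self.drainage_node = self.drainage_node or "RA"
            self.return_node = self.return_node or "ascending_aorta"
        elif self.mode is EcmoMode.PERIPHERAL:
            self.drainage_node = self.drainage_node or "femoral_vein"
            self.return_node = self.return_node or "femoral_artery"
            # longer percutaneous cannulae: higher default resistance
            if self.cannula_resistance == EcmoConfig.cannula_resistance:
                self.cannula_resistance = 0.70
        if self.mode is not EcmoMode.OFF:
            if self.rpm < 0:
                raise ConfigurationError("rpm must be >= 0")
            for node in (self.drainage_node, self.return_node):
                if node not in DEVICE_NODES:
                    raise ConfigurationError(
                        f"ECMO attachment node {node!r} is not one of {DEVICE_NODES}"
                    )
        if self.cannula_resistance <= 0 or self.cannula_inertance < 0:
            raise ConfigurationError("cannula R must be > 0 and L >= 0")


@dataclass
class IabpConfig:
    """Intra-aortic balloon pump configuration (§ values are clinical)."""

    enabled: bool = False
    drive_pressure: float = 260.0  # mmHg
    vacuum_pressure: float = -10.0  # mmHg
    gas_resistance: float = 0.5  # mmHg*s/mL
    balloon_max_volume: float = 40.0  # mL
    balloon_node: str = "descending_aorta"
    deflation_lead: float = 0.05  # s before systole onset
    # bootstrap cycle fractions used until valve-closure landmarks exist
    first_beat_inflation_fraction: float = 0.35
    first_beat_deflation_fraction: float = 0.95

    def __post_init__(self) -> None:
        if self.enabled:
            if not (self.drive_pressure > 0 > self.vacuum_pressure):
                raise ConfigurationError(
                    "require drive pressure > 0 > vacuum pressure, got "
                    f"{self.drive_pressure} / {self.vacuum_pressure}"
                )
            if not 0 < self.balloon_max_volume <= 60:
                raise ConfigurationError(
                    f"balloon max volume must be in (0, 60] mL, got {self.balloon_max_volume}"
                )
            if self.gas_resistance <= 0:
                raise ConfigurationError("gas resistance must be > 0")
            if self.balloon_node not in DEVICE_NODES:
                raise ConfigurationError(
                    f"balloon node {self.balloon_node!r} is not one of {DEVICE_NODES}"
                )


class BalloonPhase(str, Enum):
    INFLATING = "inflating"
    INFLATED = "inflated"
    DEFLATING = "deflating"
    DEFLATED = "deflated"


@dataclass
class BalloonState:
    """Gas content and drive phase of the balloon."""

    gas_volume: float = 0.0  # mL
    phase: BalloonPhase = BalloonPhase.DEFLATED


@dataclass
class DeviceConfig:
    """All support-device settings for one simulated condition."""

    ecmo: EcmoConfig = field(default_factory=EcmoConfig)
    iabp: IabpConfig = field(default_factory=IabpConfig)


def pump_head(q: float, rpm: float, char: PumpCharacteristic) -> float:
    """Pump pressure head (mmHg) at flow ``q`` (mL/s) and speed ``rpm``."""
    return char.k1 * rpm * rpm - char.k2 * q * rpm - char.k3 * q * q


def pump_operating_flow(
    p_drain: float,
    p_return: float,
    cfg: EcmoConfig,
    q: float,
) -> float:
    """Cannula flow derivative dQ/dt (mL/s^2) for the pump momentum balance.

    With the backflow valve enabled the flow state is prevented from going
    negative: at Q <= 0 any further deceleration is suppressed.
    """
    if cfg.mode is EcmoMode.OFF:
        return 0.0
    q_eff = max(q, 0.0) if cfg.backflow_valve else q
    head = pump_head(q_eff, cfg.rpm, cfg.characteristic)
    dq = (
        head - (p_return - p_drain) - cfg.cannula_resistance * q_eff
    ) / cfg.cannula_inertance
    if cfg.backflow_valve and q <= 0.0 and dq < 0.0:
        return 0.0
    return dq


def pump_equilibrium_flow(dp: float, rpm: float, cfg: EcmoConfig) -> float:
    """Steady circuit flow against a constant pressure rise ``dp`` (mmHg).

    Solves ``k1 w^2 - k2 Q w - k3 Q^2 = dp + R_cann Q`` for the physical
    root; with the backflow valve on the result is clamped at zero.
    """
    char = cfg.characteristic
    a = char.k3
    b = char.k2 * rpm + cfg.cannula_resistance
    c = dp - char.k1 * rpm * rpm
    if a == 0:
        q = -c / b
    else:
        disc = b * b - 4 * a * c
        if disc < 0:
            # head curve never meets the load line: no forward operating
            # point; the backflow valve holds the circuit at zero flow
            if cfg.backflow_valve:
                return 0.0
            raise ValueError("no real pump operating point")
        q = (-b + disc**0.5) / (2 * a)
    if cfg.backflow_valve:
        q = max(q, 0.0)
    return q


def iabp_phase(
    cycle_fraction: float,
    cfg: IabpConfig,
    inflation_fraction: float | None = None,
    deflation_fraction: float | None = None,
    gas_volume: float = 0.0,
) -> BalloonPhase:
    """Drive phase at a cycle fraction (0 = ventricular systole onset).

    ``inflation_fraction`` is the aortic-valve-closure fraction detected on
    the previous beat; when landmarks are not yet available the bootstrap
    fractions from the configuration are used.  Deflation begins
    ``deflation_lead`` seconds before the next systole onset, expressed here
    as a cycle fraction by the caller.
    """
    if not cfg.enabled:
        return BalloonPhase.DEFLATED
    f_infl = (
        inflation_fraction
        if inflation_fraction is not None
        else cfg.first_beat_inflation_fraction
    )
    f_defl = (
        deflation_fraction
        if deflation_fraction is not None
        else cfg.first_beat_deflation_fraction
    )
    phi = cycle_fraction % 1.0
    if f_infl <= f_defl:
        inflation_window = f_infl <= phi < f_defl
    else:  # deflation fraction wraps past systole onset
        inflation_window = phi >= f_infl or phi < f_defl
    if inflation_window:
        if gas_volume >= cfg.balloon_max_volume - 1e-9:
            return BalloonPhase.INFLATED
        return BalloonPhase.INFLATING
    if gas_volume <= 1e-9:
        return BalloonPhase.DEFLATED
    return BalloonPhase.DEFLATING


def _smooth_clip01(x: float) -> float:
    return 0.0 if x <= 0.0 else (1.0 if x >= 1.0 else x)


def iabp_gas_flow(
    phase: BalloonPhase,
    p_balloon: float,
    gas_volume: float,
    cfg: IabpConfig,
) -> float:
    """Gas flow into the balloon (mL/s) for the current drive phase.

    Inflation discharges the drive tank, deflation the vacuum tank, through
    the gas resistance; flows taper linearly over the last millilitre before
    the volume clamps so the right-hand side stays continuous.
    """
    if not cfg.enabled:
        return 0.0
    if phase in (BalloonPhase.INFLATING, BalloonPhase.INFLATED):
        raw = (cfg.drive_pressure - p_balloon) / cfg.gas_resistance
        if raw > 0:
            raw *= _smooth_clip01((cfg.balloon_max_volume - gas_volume) / _CLAMP_WIDTH)
        return raw
    raw = (cfg.vacuum_pressure - p_balloon) / cfg.gas_resistance
    if raw < 0:
        raw *= _smooth_clip01(gas_volume / _CLAMP_WIDTH)
    return raw


def balloon_blood_displacement(gas_flow: float) -> float:
    """Blood flow (mL/s) injected at the balloon node: +dV_gas/dt.

    Positive during diastolic inflation (augmentation), negative during
    systolic deflation; integrates to zero over a periodic cycle.
    """
    return gas_flow
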
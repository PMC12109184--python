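"""Closed-loop RLC vascular network.

The circulation is a directed graph of compliant *nodes* (each with a
compliance ``C`` and an unstressed volume) joined by resistive, optionally
inertant, *links*.  The systemic arterial tree is a chain — ascending aorta,
aortic arch, thoracic aorta, descending (thoracic) aorta with the thoracic
resistance, abdominal aorta, femoral artery — with parallel perfusion
branches (upper limbs and head, coronary, renal-hepatic, splanchnic, lower
limbs) that drain through the superior and inferior venae cavae back to the
right atrium.  The pulmonary circulation connects the right ventricle to the
left atrium through the pulmonary artery and pulmonary veins; the coronary
branch is a plain RC path from the aortic root to the right atrium.

Governing relations (mmHg, mL, s):

    C * dP/dt = Q_in - Q_out                     (compliant node)
    L * dQ/dt = P_in - P_out - R * Q             (inertant link)
    Q         = (P_in - P_out) / R               (purely resistive link)

The four heart chambers appear in the graph as the special node names
``LV``, ``RV``, ``LA``, ``RA``; their pressures come from the elastance
model, not from a compliance, and the valves joining them are modelled in
:mod:`cardioloop.chambers`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .chambers import ConfigurationError

__all__ = [
    "SegmentParams",
    "LinkParams",
    "NetworkTopology",
    "NetworkState",
    "TopologyError",
    "build_topology",
    "resistive_flow",
    "inertant_flow_derivative",
    "compliant_pressure_derivative",
    "segment_dynamics",
    "coronary_flow",
    "total_blood_volume",
    "CHAMBER_NODES",
    "DEVICE_NODES",
]

CHAMBER_NODES = ("LV", "RV", "LA", "RA")

#: nodes a support device may attach to (validated by name)
DEVICE_NODES = (
    "RA",
    "ascending_aorta",
    "descending_aorta",
    "thoracic_aorta",
    "femoral_artery",
    "femoral_vein",
)

#: compliant nodes every topology must contain
MANDATORY_NODES = (
    "ascending_aorta",
    "aortic_arch",
    "thoracic_aorta",
    "descending_aorta",
    "abdominal_aorta",
    "femoral_artery",
    "upper_body",
    "renal_hepatic",
    "splanchnic",
    "lower_body",
    "femoral_vein",
    "inferior_vena_cava",
    "superior_vena_cava",
    "coronary",
    "pulmonary_artery",
    "pulmonary_veins",
)

#: link carrying cerebral (upper-limbs-and-head) inflow
CEREBRAL_LINK = "arch_to_upper_body"
#: link carrying coronary inflow from the aortic root
CORONARY_IN_LINK = "aorta_to_coronary"


class TopologyError(ValueError):
    """Raised when the vessel graph is not a valid closed loop."""


@dataclass
class SegmentParams:
    """One compliant vascular segment."""

    name: str
    compliance: float  # mL/mmHg
    unstressed_volume: float  # mL
    init_pressure: float = 0.0  # mmHg, used to seed the state
    external_pressure: float = 0.0  # mmHg (intrathoracic), default 0

    def __post_init__(self) -> None:
        if self.compliance <= 0:
            raise ConfigurationError(
                f"{self.name}: compliance must be > 0, got {self.compliance}"
            )
        if self.unstressed_volume < 0:
            raise ConfigurationError(f"{self.name}: unstressed volume must be >= 0")

    def volume(self, pressure: float) -> float:
        """Segment blood volume at a given pressure."""
        return self.unstressed_volume + self.compliance * (
            pressure - self.external_pressure
        )


@dataclass
class LinkParams:
    """Resistive (optionally inertant) connection between two nodes."""

    name: str
    source: str
    target: str
    resistance: float  # mmHg*s/mL
    inertance: float = 0.0  # mmHg*s^2/mL

    def __post_init__(self) -> None:
        if self.resistance < 0 or self.inertance < 0:
            raise ConfigurationError(f"{self.name}: R and L must be >= 0")
        if self.resistance == 0 and self.inertance == 0:
            raise ConfigurationError(
                f"{self.name}: R=0 with L=0 is an ill-posed algebraic loop"
            )


@dataclass
class NetworkTopology:
    """Validated closed-loop vessel graph."""

    nodes: dict[str, SegmentParams]
    links: list[LinkParams]
    node_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.node_order:
            self.node_order = list(self.nodes)

    def link(self, name: str) -> LinkParams:
        for lk in self.links:
            if lk.name == name:
                return lk
        raise KeyError(name)

    @property
    def inertant_links(self) -> list[LinkParams]:
        return [lk for lk in self.links if lk.inertance > 0]

    @property
    def resistive_links(self) -> list[LinkParams]:
        return [lk for lk in self.links if lk.inertance == 0]


@dataclass
class NetworkState:
    """Pressures of compliant nodes and flows of inertant links."""

    pressures: dict[str, float]
    flows: dict[str, float] = field(default_factory=dict)

    def volumes(self, topology: NetworkTopology) -> dict[str, float]:
        return {
            name: topology.nodes[name].volume(self.pressures[name])
            for name in topology.nodes
        }


def _strongly_connected(edges: list[tuple[str, str]], nodes: set[str]) -> bool:
    """Single-SCC check by forward and reverse reachability from one node."""
    fwd: dict[str, list[str]] = {n: [] for n in nodes}
    rev: dict[str, list[str]] = {n: [] for n in nodes}
    for a, b in edges:
        fwd[a].append(b)
        rev[b].append(a)

    def reach(adj: Mapping[str, list[str]], start: str) -> set[str]:
        seen = {start}
        stack = [start]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return seen

    start = next(iter(nodes))
    return reach(fwd, start) == nodes and reach(rev, start) == nodes


def build_topology(config: Mapping) -> NetworkTopology:
    """Build and validate the vessel graph from a configuration mapping.

    ``config`` must contain ``nodes`` (name -> compliance/unstressed_volume/
    init_pressure) and ``links`` (name -> source/target/resistance/
    inertance).  Validation enforces the presence of every mandatory branch
    and that the graph — including the implicit chamber path
    LA→LV→aorta…RA→RV→PA…LA through the valves — is one closed loop
    (a single strongly connected component).
    """
    nodes = {
        name: SegmentParams(
            name=name,
            compliance=float(spec["compliance"]),
            unstressed_volume=float(spec["unstressed_volume"]),
            init_pressure=float(spec.get("init_pressure", 0.0)),
            external_pressure=float(spec.get("external_pressure", 0.0)),
        )
        for name, spec in config["nodes"].items()
    }
    links = [
        LinkParams(
            name=name,
            source=spec["source"],
            target=spec["target"],
            resistance=float(spec["resistance"]),
            inertance=float(spec.get("inertance", 0.0)),
        )
        for name, spec in config["links"].items()
    ]

    missing = [n for n in MANDATORY_NODES if n not in nodes]
    if missing:
        raise ConfigurationError(f"missing mandatory vascular nodes: {missing}")

    all_names = set(nodes) | set(CHAMBER_NODES)
    for lk in links:
        for end in (lk.source, lk.target):
            if end not in all_names:
                raise TopologyError(f"link {lk.name} references unknown node {end}")

    # implicit chamber/valve edges close the loop through the heart
    edges = [(lk.source, lk.target) for lk in links]
    edges += [
        ("LA", "LV"),
        ("LV", "ascending_aorta"),
        ("RA", "RV"),
        ("RV", "pulmonary_artery"),
    ]
    if not _strongly_connected(edges, all_names):
        raise TopologyError(
            "vessel graph is not a single closed loop (disconnected or dead-end branch)"
        )
    return NetworkTopology(nodes=nodes, links=links)


def resistive_flow(p_in: float, p_out: float, r: float) -> float:
    """Algebraic flow through a purely resistive link (mL/s)."""
    return (p_in - p_out) / r


def inertant_flow_derivative(
    p_in: float, p_out: float, q: float, r: float, l: float
) -> float:
    """dQ/dt of an inertant link: (P_in - P_out - R*Q)/L."""
    return (p_in - p_out - r * q) / l


def compliant_pressure_derivative(q_net: float, c: float) -> float:
    """dP/dt of a compliant node: net inflow over compliance."""
    return q_net / c


def segment_dynamics(
    p: float,
    q: float,
    p_in: float,
    q_out: float,
    r: float,
    l: float,
    c: float,
) -> tuple[float, float]:
    """Derivatives of one RLC segment.

    The segment stores pressure ``p`` on its compliance ``c``, is fed
    through its resistance ``r`` (and inertance ``l`` when present) from the
    upstream pressure ``p_in``, and discharges the prescribed outflow
    ``q_out`` (mL/s) downstream.

    Returns ``(dP/dt, dQ/dt)``; for ``l == 0`` the inflow is algebraic
    ``(p_in - p)/r`` and ``dQ/dt`` is reported as 0.
    """
    if l > 0:
        dq = inertant_flow_derivative(p_in, p, q, r, l)
        q_in = q
    else:
        if r == 0:
            raise ConfigurationError("R=0 with L=0 is ill-posed")
        dq = 0.0
        q_in = resistive_flow(p_in, p, r)
    return compliant_pressure_derivative(q_in - q_out, c), dq


def coronary_flow(
    p_ao: float,
    p_ra: float,
    r_in: float,
    r_out: float,
    p_node: float | None = None,
) -> float:
    """Flow through the coronary RC branch (mL/s).

    With the internal node pressure ``p_node`` given, returns the
    instantaneous inflow from the aortic root; otherwise the steady-state
    flow across both resistances.
    """
    if p_node is None:
        return (p_ao - p_ra) / (r_in + r_out)
    return (p_ao - p_node) / r_in


def total_blood_volume(
    node_pressures: Mapping[str, float],
    topology: NetworkTopology,
    chamber_volumes: Iterable[float],
    balloon_gas_volume: float = 0.0,
    circuit_volume: float = 0.0,
) -> float:
    """Total blood volume (mL): chambers + segments + circuit − balloon gas.

    Balloon gas occupies part of the descending-aorta segment volume that
    the compliance relation attributes to blood, so it is subtracted.
    """
    seg = sum(
        topology.nodes[name].volume(node_pressures[name]) for name in topology.nodes
    )
    return seg + sum(chamber_volumes) + circuit_volume - balloon_gas_volume
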
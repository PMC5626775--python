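"""Injection protocols and mito-stress-test summary metrics.

A protocol is an ordered list of injection events plus a measurement schedule.
The standard catalog reproduces the experiment designs of the study this
package emulates: the classic mito stress test (oligomycin → 2,4-DNP →
rotenone/antimycin A), uncoupled-respiration assays (oligomycin followed by
isoproterenol, all-trans retinoic acid or palmitate-BSA), the reversed-order
validation design, and variants with BSA fatty-acid scavenging or cyclosporine
A pre-treatment.

Timing convention: measurements every 7 min starting at t = 0; injections 3 min
after the last measurement of the preceding phase; 3 measurements per phase
except 6 in the final stimulation phase of the uncoupled-respiration designs
(a longer follow-up of the discriminating phase).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .io import OCRTrace, ValidationError
from .model import AGENTS

__all__ = [
    "InjectionEvent",
    "Protocol",
    "StressTestSummary",
    "ProtocolError",
    "build_standard_protocols",
    "phase_slices",
    "phase_means",
    "compute_stress_test_summary",
]

VALID_AGENTS = AGENTS + ("vehicle",)

MEASUREMENT_CADENCE_MIN = 7.0
INJECTION_LAG_MIN = 3.0


class ProtocolError(ValueError):
    """A protocol is malformed or does not support the requested analysis."""


@dataclass(frozen=True)
class InjectionEvent:
    time_min: float
    agent: str
    label: str = ""

    def __post_init__(self):
        if self.agent not in VALID_AGENTS:
            raise ProtocolError(f"unknown agent {self.agent!r}")
        if self.time_min < 0:
            raise ProtocolError(f"injection time must be >= 0, got {self.time_min}")


@dataclass
class Protocol:
    protocol_id: str
    events: list = field(default_factory=list)
    measurement_times: list = field(default_factory=list)
    pre_held_agents: frozenset = frozenset()
    description: str = ""

    def __post_init__(self):
        self.pre_held_agents = frozenset(self.pre_held_agents)
        self.validate()

    def validate(self) -> None:
        times = np.asarray(self.measurement_times, dtype=float)
        if len(times) == 0:
            raise ProtocolError(f"{self.protocol_id}: empty measurement schedule")
        if np.any(np.diff(times) <= 0):
            raise ProtocolError(
                f"{self.protocol_id}: measurement_times must be strictly increasing"
            )
        ev_times = [e.time_min for e in self.events]
        if any(b < a for a, b in zip(ev_times, ev_times[1:])):
            raise ProtocolError(f"{self.protocol_id}: events must be time-ordered")
        for e in self.events:
            if not times[0] <= e.time_min <= times[-1]:
                raise ProtocolError(
                    f"{self.protocol_id}: event {e.agent!r} at {e.time_min} min lies "
                    "outside the measurement span"
                )
        for a in self.pre_held_agents:
            if a not in AGENTS:
                raise ProtocolError(f"{self.protocol_id}: unknown pre-held agent {a!r}")

    @property
    def injection_times(self) -> list[float]:
        return [e.time_min for e in self.events if e.agent != "vehicle"]

    def to_dict(self) -> dict:
        return {
            "protocol_id": self.protocol_id,
            "pre_held_agents": sorted(self.pre_held_agents),
            "events": [
                {"time_min": e.time_min, "agent": e.agent, "label": e.label}
                for e in self.events
            ],
            "measurement_times": [float(t) for t in self.measurement_times],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        return cls(
            protocol_id=d["protocol_id"],
            events=[
                InjectionEvent(e["time_min"], e["agent"], e.get("label", ""))
                for e in d["events"]
            ],
            measurement_times=list(d["measurement_times"]),
            pre_held_agents=frozenset(d.get("pre_held_agents", [])),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Protocol":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _phased(protocol_id, phases, pre_held=(), description=""):
    """Build a protocol from (agent-or-None, n_measurements) phases."""
    times, events = [], []
    k = 0
    for agent, n in phases:
        if agent is not None:
            t_inj = times[-1] + INJECTION_LAG_MIN if times else 0.0
            events.append(InjectionEvent(t_inj, agent, label=agent))
        for _ in range(n):
            times.append(k * MEASUREMENT_CADENCE_MIN)
            k += 1
    return Protocol(
        protocol_id=protocol_id,
        events=events,
        measurement_times=times,
        pre_held_agents=frozenset(pre_held),
        description=description,
    )


def build_standard_protocols() -> dict[str, Protocol]:
    """The study's protocol catalog, keyed by protocol id.

    P1 mito stress test; P2/P2v oligomycin → Iso/vehicle; P3 oligomycin →
    all-trans RA; P4 reversed order (Iso → oligomycin, the validation design);
    P5 as P2 with BSA scavenging in the medium; P6 oligomycin → palmitate-BSA;
    P7 as P2 with cyclosporine A pre-treatment; P0 direct Iso stimulation
    without oligomycin (total-OCR fold-change readout).
    """
    cat = {}
    cat["P1"] = _phased(
        "P1",
        [(None, 3), ("oligomycin", 3), ("dnp", 3), ("rot_aa", 3)],
        description="mito stress test",
    )
    cat["P2"] = _phased(
        "P2",
        [(None, 3), ("oligomycin", 3), ("iso", 6)],
        description="uncoupled respiration upon isoproterenol",
    )
    cat["P2v"] = _phased(
        "P2v",
        [(None, 3), ("oligomycin", 3), ("vehicle", 6)],
        description="vehicle arm of P2",
    )
    cat["P3"] = _phased(
        "P3",
        [(None, 3), ("oligomycin", 3), ("atra", 6)],
        description="uncoupled respiration upon all-trans retinoic acid",
    )
    cat["P4"] = _phased(
        "P4",
        [(None, 3), ("iso", 6), ("oligomycin", 3)],
        description="reversed stimulation order (validation design)",
    )
    cat["P5"] = _phased(
        "P5",
        [(None, 3), ("oligomycin", 3), ("iso", 6)],
        pre_held=("bsa_scavenge",),
        description="P2 with extracellular FFA scavenged by BSA",
    )
    cat["P6"] = _phased(
        "P6",
        [(None, 3), ("oligomycin", 3), ("palmitate_bsa", 6)],
        description="exogenous FFA supply via palmitate-BSA",
    )
    cat["P7"] = _phased(
        "P7",
        [(None, 3), ("oligomycin", 3), ("iso", 6)],
        pre_held=("csa",),
        description="P2 with cyclosporine A pre-treatment",
    )
    cat["P0"] = _phased(
        "P0",
        [(None, 3), ("iso", 6)],
        description="direct isoproterenol stimulation, no oligomycin",
    )
    return cat


def phase_slices(trace: OCRTrace, protocol: Protocol, drop_first: bool = True):
    """Partition a trace's time points into phases separated by injections.

    Returns a list of (agent_or_None, boolean mask).  With ``drop_first`` the
    first measurement after each injection is excluded from the mask (mixing
    artifact in plate assays).
    """
    times = np.asarray(trace.time_min, dtype=float)
    inj = _injection_events(protocol)
    bounds = [-math.inf] + [e.time_min for e in inj] + [math.inf]
    agents = [None] + [e.agent for e in inj]
    out = []
    for i, agent in enumerate(agents):
        mask = (times > bounds[i]) & (times <= bounds[i + 1])
        if drop_first and i > 0 and mask.any():
            mask[np.argmax(mask)] = False
        out.append((agent, mask))
    return out


def _injection_events(protocol: Protocol):
    return [e for e in protocol.events if e.agent != "vehicle"]


def phase_means(trace: OCRTrace, protocol: Protocol, drop_first: bool = True):
    """Mean OCR per phase (same exclusion rule as :func:`phase_slices`)."""
    out = []
    for agent, mask in phase_slices(trace, protocol, drop_first):
        if not mask.any():
            raise ProtocolError(
                f"{protocol.protocol_id}: phase {agent!r} has no usable measurements"
            )
        out.append((agent, float(np.mean(trace.ocr_mean[mask]))))
    return out


@dataclass
class StressTestSummary:
    """Standard mito-stress-test decomposition (OCR units; crcr dimensionless).

    basal = pre-oligomycin minus non-mitochondrial OCR; leak = oligomycin-
    insensitive OCR (index of uncoupled respiration); atp_turnover = basal -
    leak; max_capacity = DNP-uncoupled OCR; spare_capacity = max - basal;
    crcr (cell respiratory control ratio) = max_capacity / leak.
    """

    basal: float
    atp_turnover: float
    leak: float
    max_capacity: float
    spare_capacity: float
    nonmito: float
    crcr: float | None
    crcr_defined: bool = True

    def to_dict(self) -> dict:
        d = {
            "basal": self.basal,
            "atp_turnover": self.atp_turnover,
            "leak": self.leak,
            "max_capacity": self.max_capacity,
            "spare_capacity": self.spare_capacity,
            "nonmito": self.nonmito,
            "crcr": self.crcr,
            "crcr_defined": self.crcr_defined,
        }
        return d


def compute_stress_test_summary(
    trace: OCRTrace, protocol: Protocol, drop_first: bool = True
) -> StressTestSummary:
    """Summary metrics from a mito-stress-test trace.

    Requires oligomycin, DNP and rotenone/antimycin phases; all values are
    corrected for non-mitochondrial OCR (the post-rot/AA phase mean).  When
    the leak rate is not positive, crcr is reported as undefined rather than
    raising.
    """
    means = dict(phase_means(trace, protocol, drop_first))
    for needed in (None, "oligomycin", "dnp", "rot_aa"):
        if needed not in means:
            raise ProtocolError(
                f"{protocol.protocol_id}: missing phase "
                f"{'basal' if needed is None else needed} for stress-test summary"
            )
    nonmito = means["rot_aa"]
    basal = means[None] - nonmito
    leak = means["oligomycin"] - nonmito
    max_capacity = means["dnp"] - nonmito
    crcr_defined = leak > 0
    return StressTestSummary(
        basal=basal,
        atp_turnover=basal - leak,
        leak=leak,
        max_capacity=max_capacity,
        spare_capacity=max_capacity - basal,
        nonmito=nonmito,
        crcr=max_capacity / leak if crcr_defined else None,
        crcr_defined=crcr_defined,
    )
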
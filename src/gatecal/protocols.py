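"""Piecewise-constant voltage-clamp protocol templates.

A protocol is an ordered list of segments, each holding the membrane at a
fixed voltage for a fixed duration.  Exactly one quantity — one segment's
voltage or one segment's duration — is a *sweep variable*: the protocol is
repeated once per sweep value (e.g. a family of test voltages for an I-V
curve, or a family of inter-pulse intervals for a recovery experiment).

Built-in templates cover the conventional experiment families: activation
I-V, availability (steady-state inactivation), recovery from inactivation,
deactivation, and pulse trains.  The exact holding potentials and durations
of the source experimental publications are not restated anywhere public;
the defaults here are documented representative values and every constant
is user-configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "SWEEP",
    "ProtocolError",
    "ProtocolSegment",
    "ProtocolTemplate",
    "activation_iv",
    "availability",
    "recovery",
    "deactivation",
    "pulse_train",
    "builtin_templates",
    "load_protocol",
    "save_protocol",
]

#: Marker placing the sweep variable in a segment's voltage or duration slot.
SWEEP = "sweep"


class ProtocolError(ValueError):
    """Malformed protocol definition."""


@dataclass(frozen=True)
class ProtocolSegment:
    """One fixed-voltage epoch: voltage (mV), duration (ms), record flag."""

    voltage: float | str
    duration: float | str
    record: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.voltage, str) and self.voltage != SWEEP:
            raise ProtocolError(f"voltage must be a number or {SWEEP!r}")
        if isinstance(self.duration, str) and self.duration != SWEEP:
            raise ProtocolError(f"duration must be a number or {SWEEP!r}")
        if not isinstance(self.duration, str) and not self.duration > 0:
            raise ProtocolError("segment duration must be > 0")


@dataclass
class ProtocolTemplate:
    """Parameterized voltage-step program with one sweep variable.

    Attributes
    ----------
    name : template identifier.
    segments : ordered ProtocolSegment list; exactly one SWEEP marker among
        all voltage/duration slots, at least one recorded segment.
    sweep_name : label of the sweep variable ("test_voltage", "interval", ...).
    sweep_values : values the sweep variable takes, one protocol
        realization each (mV for a voltage sweep, ms for a duration sweep).
    sample_interval : ms between recorded samples (default 0.05).
    """

    name: str
    segments: list[ProtocolSegment]
    sweep_name: str
    sweep_values: np.ndarray
    sample_interval: float = 0.05

    def __post_init__(self) -> None:
        self.sweep_values = np.asarray(self.sweep_values, dtype=float)
        markers = sum(
            (s.voltage == SWEEP) + (s.duration == SWEEP) for s in self.segments
        )
        if markers != 1:
            raise ProtocolError(f"protocol {self.name!r}: need exactly one sweep marker, found {markers}")
        if not any(s.record for s in self.segments):
            raise ProtocolError(f"protocol {self.name!r}: no recorded segment")
        if self.sweep_values.ndim != 1 or self.sweep_values.size == 0:
            raise ProtocolError(f"protocol {self.name!r}: sweep_values must be a non-empty 1-d list")
        if not self.sample_interval > 0:
            raise ProtocolError("sample_interval must be > 0")

    @property
    def n_sweeps(self) -> int:
        return int(self.sweep_values.size)

    @property
    def holding_voltage(self) -> float:
        v0 = self.segments[0].voltage
        if isinstance(v0, str):
            raise ProtocolError(f"protocol {self.name!r}: first (holding) segment cannot carry the sweep")
        return float(v0)

    def realize(self, sweep_value: float) -> list[ProtocolSegment]:
        """Concrete segment list for one sweep value."""
        out = []
        for s in self.segments:
            v = float(sweep_value) if s.voltage == SWEEP else s.voltage
            d = float(sweep_value) if s.duration == SWEEP else s.duration
            if not d > 0:
                raise ProtocolError(f"protocol {self.name!r}: non-positive realized duration {d}")
            out.append(ProtocolSegment(v, d, s.record))
        return out


# ---------------------------------------------------------------------------
# Built-in template family.  Voltages mV, durations ms.


def activation_iv(
    test_voltages: Sequence[float] = tuple(range(-60, 50, 10)),
    holding: float = -80.0,
    hold_ms: float = 50.0,
    step_ms: float = 100.0,
    sample_interval: float = 0.05,
) -> ProtocolTemplate:
    """Hold, then step to a swept test voltage; record the test step."""
    return ProtocolTemplate(
        name="activation_iv",
        segments=[
            ProtocolSegment(holding, hold_ms),
            ProtocolSegment(SWEEP, step_ms, record=True),
        ],
        sweep_name="test_voltage",
        sweep_values=test_voltages,
        sample_interval=sample_interval,
    )


def availability(
    conditioning_voltages: Sequence[float] = tuple(range(-120, -30, 10)),
    holding: float = -100.0,
    test_voltage: float = -20.0,
    hold_ms: float = 50.0,
    conditioning_ms: float = 500.0,
    test_ms: float = 30.0,
    sample_interval: float = 0.05,
) -> ProtocolTemplate:
    """Swept conditioning pre-pulse followed by a fixed test pulse (recorded)."""
    return ProtocolTemplate(
        name="availability",
        segments=[
            ProtocolSegment(holding, hold_ms),
            ProtocolSegment(SWEEP, conditioning_ms),
            ProtocolSegment(test_voltage, test_ms, record=True),
        ],
        sweep_name="conditioning_voltage",
        sweep_values=conditioning_voltages,
        sample_interval=sample_interval,
    )


def recovery(
    intervals: Sequence[float] = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0),
    holding: float = -100.0,
    hold_ms: float = 50.0,
    pulse_voltage: float = -20.0,
    pulse_ms: float = 30.0,
    sample_interval: float = 0.05,
) -> ProtocolTemplate:
    """P1 pulse, swept recovery interval at holding, P2 pulse; both pulses recorded."""
    return ProtocolTemplate(
        name="recovery",
        segments=[
            ProtocolSegment(holding, hold_ms),
            ProtocolSegment(pulse_voltage, pulse_ms, record=True),  # P1
            ProtocolSegment(holding, SWEEP),  # inter-pulse interval
            ProtocolSegment(pulse_voltage, pulse_ms, record=True),  # P2
        ],
        sweep_name="interval",
        sweep_values=intervals,
        sample_interval=sample_interval,
    )


def deactivation(
    tail_voltages: Sequence[float] = tuple(range(-120, -50, 10)),
    holding: float = -80.0,
    hold_ms: float = 50.0,
    activating_voltage: float = 20.0,
    activating_ms: float = 100.0,
    tail_ms: float = 30.0,
    sample_interval: float = 0.05,
) -> ProtocolTemplate:
    """Activating step, then a swept repolarizing tail voltage (recorded)."""
    return ProtocolTemplate(
        name="deactivation",
        segments=[
            ProtocolSegment(holding, hold_ms),
            ProtocolSegment(activating_voltage, activating_ms),
            ProtocolSegment(SWEEP, tail_ms, record=True),
        ],
        sweep_name="tail_voltage",
        sweep_values=tail_voltages,
        sample_interval=sample_interval,
    )


def pulse_train(
    n_pulses: int = 100,
    holding: float = -140.0,
    pulse_voltage: float = -30.0,
    pulse_ms: float = 100.0,
    rate_hz: float = 1.0,
    record_all: bool = False,
    sample_interval: float = 0.05,
) -> ProtocolTemplate:
    """n identical pulses at a fixed rate; records the last pulse (or all).

    The pulse period is 1000/rate_hz ms; each cycle is a pulse followed by
    the holding potential for the remainder of the period.  The sweep
    variable is the (single) holding duration entry so the template fits the
    one-sweep protocol contract; with one sweep value the template yields a
    single trace.
    """
    if n_pulses < 1:
        raise ProtocolError("n_pulses must be >= 1")
    period = 1000.0 / rate_hz
    gap = period - pulse_ms
    if gap <= 0:
        raise ProtocolError("pulse duration must be shorter than the period")
    segments = [ProtocolSegment(holding, SWEEP)]
    for i in range(n_pulses):
        record = record_all or (i == n_pulses - 1)
        segments.append(ProtocolSegment(pulse_voltage, pulse_ms, record=record))
        if i < n_pulses - 1:
            segments.append(ProtocolSegment(holding, gap))
    return ProtocolTemplate(
        name="pulse_train",
        segments=segments,
        sweep_name="initial_hold",
        sweep_values=[gap],
        sample_interval=sample_interval,
    )


def builtin_templates() -> dict[str, ProtocolTemplate]:
    """Library of parameterized step-protocol templates with default constants."""
    return {
        "activation_iv": activation_iv(),
        "availability": availability(),
        "recovery": recovery(),
        "deactivation": deactivation(),
        "pulse_train": pulse_train(),
    }


_TEMPLATE_FACTORIES = {
    "activation_iv": activation_iv,
    "availability": availability,
    "recovery": recovery,
    "deactivation": deactivation,
    "pulse_train": pulse_train,
}


# ---------------------------------------------------------------------------
# Config serialization


def protocol_to_dict(p: ProtocolTemplate) -> dict:
    return {
        "name": p.name,
        "sweep_name": p.sweep_name,
        "sweep_values": [float(v) for v in p.sweep_values],
        "sample_interval": float(p.sample_interval),
        "segments": [
            {
                "voltage": s.voltage if isinstance(s.voltage, str) else float(s.voltage),
                "duration": s.duration if isinstance(s.duration, str) else float(s.duration),
                "record": bool(s.record),
            }
            for s in p.segments
        ],
    }


def protocol_from_dict(d: Mapping) -> ProtocolTemplate:
    if "template" in d:
        # named template + keyword constants
        name = d["template"]
        if name not in _TEMPLATE_FACTORIES:
            raise ProtocolError(
                f"unknown template {name!r}; available: {sorted(_TEMPLATE_FACTORIES)}"
            )
        kwargs = {k: v for k, v in d.items() if k != "template"}
        try:
            return _TEMPLATE_FACTORIES[name](**kwargs)
        except TypeError as exc:
            raise ProtocolError(f"bad constants for template {name!r}: {exc}") from exc
    try:
        segments = [
            ProtocolSegment(s["voltage"], s["duration"], bool(s.get("record", False)))
            for s in d["segments"]
        ]
        return ProtocolTemplate(
            name=d["name"],
            segments=segments,
            sweep_name=d["sweep_name"],
            sweep_values=d["sweep_values"],
            sample_interval=float(d.get("sample_interval", 0.05)),
        )
    except KeyError as exc:
        raise ProtocolError(f"protocol config missing key {exc}") from exc


def save_protocol(p: ProtocolTemplate, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(protocol_to_dict(p), fh, sort_keys=False)


def load_protocol(path) -> ProtocolTemplate:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, Mapping):
        raise ProtocolError(f"{path}: not a protocol config mapping")
    return protocol_from_dict(d)
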
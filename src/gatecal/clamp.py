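"""Voltage-clamp simulation engine.

Because clamp protocols are piecewise-constant in voltage, each gate's
first-order kinetics admit an exact per-segment solution::

    gamma(t) = gamma_inf + (gamma_0 - gamma_inf) * exp(-t / tau)

with gamma_inf and tau evaluated at the segment voltage.  The engine
propagates this update exactly from segment to segment, sampling recorded
segments on a uniform grid; there is no integration error to control.  A
general-purpose ODE solver is used only as an independent oracle in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .channels import (
    ChannelSpec,
    InvalidParameterError,
    channel_current,
    gate_steady_state_tau,
)
from .protocols import ProtocolTemplate

__all__ = ["SimulationFailure", "RecordedWindow", "Trace", "propagate_segment", "run_protocol"]


class SimulationFailure(RuntimeError):
    """A simulation could not be completed for the given parameters.

    The distance layer maps this to an infinite distance so samplers can
    reject the parameter set rather than crash.
    """


@dataclass(frozen=True)
class RecordedWindow:
    """Slice of a trace belonging to one recorded segment."""

    segment_index: int
    sl: slice
    voltage: float
    t_start: float


@dataclass
class Trace:
    """Sampled current response for one sweep of a protocol.

    times are absolute protocol times (ms, strictly increasing across the
    recorded windows); gates maps gate name -> open fraction on the same
    grid; windows locate each recorded segment's samples.
    """

    times: np.ndarray
    current: np.ndarray
    gates: dict[str, np.ndarray]
    sweep_value: float
    windows: list[RecordedWindow] = field(default_factory=list)

    def window(self, k: int = 0) -> RecordedWindow:
        """k-th recorded window of this trace."""
        return self.windows[k]


def _segment_kinetics(channel: ChannelSpec, params: Mapping[str, float], V: float):
    """(gamma_inf, tau) per gate at fixed V, resolving tied gates."""
    out: dict[str, tuple[float, float]] = {}
    for g in channel.gates:
        if g.tied_to is None:
            gi, tau = gate_steady_state_tau(g, V, params)
            out[g.name] = (float(gi), float(tau))
    for g in channel.gates:
        if g.tied_to is not None:
            gi, tau = gate_steady_state_tau(
                g, V, params, sibling=out[g.tied_to], scale=params[f"{g.name}.scale"]
            )
            out[g.name] = (float(gi), float(tau))
    return out


def propagate_segment(
    channel: ChannelSpec,
    params: Mapping[str, float],
    state: Mapping[str, float],
    V: float,
    duration: float,
    t_eval: np.ndarray | None = None,
):
    """Advance all gates through one fixed-voltage segment.

    Returns ``(endpoint_state, trajectories)`` where trajectories is None
    when ``t_eval`` is None, else a dict of gate arrays evaluated at the
    requested times (ms, relative to segment start).
    """
    kin = _segment_kinetics(channel, params, V)
    end: dict[str, float] = {}
    traj: dict[str, np.ndarray] | None = None if t_eval is None else {}
    for g in channel.gates:
        gi, tau = kin[g.name]
        g0 = float(state[g.name])
        if not 0.0 <= g0 <= 1.0:
            raise SimulationFailure(f"gate {g.name!r} state {g0} outside [0, 1]")
        if np.isinf(tau):  # constant gate
            end[g.name] = g0
            if traj is not None:
                traj[g.name] = np.full_like(np.asarray(t_eval, float), g0)
            continue
        if not tau > 0:
            raise SimulationFailure(f"gate {g.name!r}: non-positive time constant")
        end[g.name] = gi + (g0 - gi) * np.exp(-duration / tau)
        if traj is not None:
            traj[g.name] = gi + (g0 - gi) * np.exp(-np.asarray(t_eval, float) / tau)
    return end, traj


def steady_state(channel: ChannelSpec, params: Mapping[str, float], V: float) -> dict[str, float]:
    """Equilibrium gate state at fixed voltage V."""
    kin = _segment_kinetics(channel, params, V)
    out = {}
    for g in channel.gates:
        gi, tau = kin[g.name]
        out[g.name] = float(g.constant) if g.constant is not None else float(gi)
    return out


def run_protocol(
    channel: ChannelSpec,
    theta,
    protocol: ProtocolTemplate,
) -> list[Trace]:
    """Simulate every sweep of a protocol; one Trace per sweep value.

    The initial gate state is the steady state at the first (holding)
    segment's voltage.  Recorded segments are sampled every
    ``protocol.sample_interval`` ms; unrecorded segments advance the state
    only.  Any invalid-parameter evaluation raises SimulationFailure.
    """
    params = channel.params_dict(theta)
    dt = protocol.sample_interval
    traces: list[Trace] = []
    try:
        for sweep_value in protocol.sweep_values:
            segments = protocol.realize(float(sweep_value))
            state = steady_state(channel, params, float(segments[0].voltage))
            t_abs = 0.0
            times_parts: list[np.ndarray] = []
            gate_parts: dict[str, list[np.ndarray]] = {g.name: [] for g in channel.gates}
            current_parts: list[np.ndarray] = []
            windows: list[RecordedWindow] = []
            n_samples = 0
            for si, seg in enumerate(segments):
                V = float(seg.voltage)
                d = float(seg.duration)
                if seg.record:
                    t_rel = np.arange(0.0, d + 0.5 * dt, dt)
                    t_rel = t_rel[t_rel <= d + 1e-12]
                    state, traj = propagate_segment(channel, params, state, V, d, t_rel)
                    gate_vals = {k: v for k, v in traj.items()}
                    current = channel_current(channel, gate_vals, V)
                    times_parts.append(t_abs + t_rel)
                    current_parts.append(np.atleast_1d(current))
                    for k, v in gate_vals.items():
                        gate_parts[k].append(v)
                    windows.append(
                        RecordedWindow(
                            segment_index=si,
                            sl=slice(n_samples, n_samples + t_rel.size),
                            voltage=V,
                            t_start=t_abs,
                        )
                    )
                    n_samples += t_rel.size
                else:
                    state, _ = propagate_segment(channel, params, state, V, d)
                t_abs += d
            times = np.concatenate(times_parts)
            current = np.concatenate(current_parts)
            gates = {k: np.concatenate(v) for k, v in gate_parts.items()}
            if not np.all(np.isfinite(current)):
                raise SimulationFailure("non-finite current in trace")
            traces.append(
                Trace(
                    times=times,
                    current=current,
                    gates=gates,
                    sweep_value=float(sweep_value),
                    windows=windows,
                )
            )
    except InvalidParameterError as exc:
        raise SimulationFailure(str(exc)) from exc
    return traces
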
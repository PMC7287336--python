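"""Reduction of simulated current traces to experimental-style summary curves.

Patch-clamp papers report low-dimensional features of the recorded
currents — peak I-V relations, normalized steady-state activation and
availability curves, exponential time constants of activation/inactivation
decay, and recovery fractions — rather than full traces.  Calibration
compares the model to data in exactly this summary space, so each
experiment is declared as an :class:`ExperimentDesign` naming the protocol
and the statistic to extract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .channels import ChannelSpec
from .clamp import SimulationFailure, Trace, run_protocol
from .protocols import ProtocolTemplate

__all__ = [
    "STATISTIC_TYPES",
    "SummaryCurve",
    "ExperimentDesign",
    "FitError",
    "peak_current",
    "steady_state_curve",
    "fit_time_constant",
    "recovery_fraction",
    "simulate_summary",
]

STATISTIC_TYPES = (
    "peak_iv",
    "steady_state_activation",
    "steady_state_inactivation",
    "time_constant",
    "recovery_fraction",
)


class FitError(RuntimeError):
    """Exponential fit failed to converge or input was degenerate."""


@dataclass
class SummaryCurve:
    """One summary statistic as a function of its sweep variable.

    x is the sweep value (mV or ms, strictly monotone); y the statistic.
    Normalized curves have max |y| = 1.
    """

    statistic_type: str
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.statistic_type not in STATISTIC_TYPES:
            raise ValueError(f"unknown statistic type {self.statistic_type!r}")
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-d arrays of equal length")
        dx = np.diff(self.x)
        if self.x.size > 1 and not (np.all(dx > 0) or np.all(dx < 0)):
            raise ValueError("x must be strictly monotone")


def peak_current(trace: Trace, window_index: int = 0) -> float:
    """Signed largest-magnitude current within a recorded window."""
    if not trace.windows:
        raise ValueError("trace has no recorded windows")
    w = trace.windows[window_index]
    seg = trace.current[w.sl]
    if seg.size == 0:
        raise ValueError("empty recorded window")
    return float(seg[np.argmax(np.abs(seg))])


def _normalize(y: np.ndarray) -> np.ndarray:
    m = np.max(np.abs(y))
    if m == 0:
        return y.copy()
    return y / m


def steady_state_curve(
    traces: Sequence[Trace],
    mode: str,
    channel: ChannelSpec | None = None,
    window_index: int = 0,
    use_conductance_proxy: bool = True,
) -> SummaryCurve:
    """Normalized steady-state activation or availability curve.

    activation: per test voltage, peak current divided by driving force
    (V - E; a conductance proxy) — or raw peak if ``use_conductance_proxy``
    is False — normalized by the maximum absolute value across the sweep.
    Sweep points with V == E are excluded with a warning (zero driving
    force).

    availability: peak test-pulse current per conditioning voltage,
    normalized likewise (the test voltage is fixed, so no driving-force
    division is needed).
    """
    if mode not in ("activation", "availability"):
        raise ValueError(f"unknown steady-state mode {mode!r}")
    xs, ys = [], []
    for tr in traces:
        pk = peak_current(tr, window_index)
        x = tr.sweep_value
        if mode == "activation" and use_conductance_proxy:
            if channel is None:
                raise ValueError("activation conductance proxy needs the channel (for E)")
            df = x - channel.reversal_potential
            if df == 0:
                warnings.warn(
                    f"sweep point V = E = {x} mV excluded (zero driving force)",
                    stacklevel=2,
                )
                continue
            pk = pk / df
        xs.append(x)
        ys.append(pk)
    stat = "steady_state_activation" if mode == "activation" else "steady_state_inactivation"
    return SummaryCurve(stat, np.asarray(xs), _normalize(np.asarray(ys)))


# ---------------------------------------------------------------------------
# Exponential time-constant fitting


def _loglin_single(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Deterministic single-exponential initializer via the integral method.

    For y = c + A exp(-t/tau), y(t) = y(0) - (1/tau) S(t) + (c/tau) t with
    S the running integral of y, so (tau, c) come from one linear
    regression and A from a second.  Exact for perfect data up to
    quadrature error, including truncated tails.
    """
    from scipy.integrate import cumulative_trapezoid

    S = cumulative_trapezoid(y, t, initial=0.0)
    M = np.column_stack([S, t, np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(M, y, rcond=None)
    b1 = float(coef[0])
    span = float(t[-1] - t[0])
    if b1 >= 0 or not np.isfinite(b1):
        # not decaying on this window (e.g. tau >> duration); report a
        # beyond-window scale so the caller still gets a finite estimate
        tau = 10.0 * span
        c = float(y[-1])
    else:
        tau = -1.0 / b1
        c = float(coef[1]) * tau
    e = np.exp(-t / tau)
    A = float(np.dot(e - e.mean(), y - y.mean()) / max(np.dot(e - e.mean(), e - e.mean()), 1e-300))
    return c, A, float(tau)


def fit_time_constant(
    t: np.ndarray,
    y: np.ndarray,
    n_components: int = 1,
    refine: bool = True,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Least-squares fit of ``y(t) = c + sum_i A_i exp(-t/tau_i)``.

    Returns ``(taus, amplitudes, offset, residual)`` with taus sorted
    ascending (fast first) and residual the root-mean-square misfit.
    Initialization is derivative-free and deterministic: the integral
    (regression-on-running-integral) method for one component; peeling
    (fit the slow tail first, subtract, fit the fast remainder) for two.
    Iterative refinement runs only when the initializer leaves residual
    structure, since the initializer is exact on noiseless
    single-exponential traces.

    Raises FitError for constant traces, too-few samples, or
    non-convergence; callers in the calibration path map this to an
    infinite distance.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size or t.size < 10:
        raise FitError("need at least 10 samples to fit a time constant")
    if np.ptp(y) == 0:
        raise FitError("constant trace")
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    t0 = t[0]
    ts = t - t0

    # Relaxations faster than the sampling grid leave too few points on the
    # decay to regress; report a resolution-censored estimate at the sample
    # interval instead of failing, so that out-of-scale kinetics are
    # penalized by the distance rather than discarded.
    r0 = y - y[-1]
    resolved = np.abs(r0) > 1e-12 + 1e-6 * np.max(np.abs(r0))
    if resolved.sum() < 3:
        dt = float(np.median(np.diff(ts)))
        taus = np.full(n_components, dt)
        amps = np.zeros(n_components)
        amps[0] = float(y[0] - y[-1])
        return taus, amps, float(y[-1]), float(np.abs(r0).max())

    if n_components == 1:
        c, a, tau = _loglin_single(ts, y)
        p0 = [c, a, tau]

        def model(tt, c, a, tau):
            return c + a * np.exp(-tt / tau)

        # skip the iterative refinement when the linear initializer already
        # explains the trace to high precision (noiseless single-exponential)
        if refine and tau > 0:
            init_resid = float(np.sqrt(np.mean((model(ts, *p0) - y) ** 2)))
            if init_resid <= 1e-6 * max(np.max(np.abs(y)), 1e-300):
                refine = False
    else:
        # peel: slow component from the latter half, fast from the remainder
        half = ts.size // 2
        c, a_slow, tau_slow = _loglin_single(ts[half:], y[half:])
        resid = y - (c + a_slow * np.exp(-ts / tau_slow))
        try:
            _, a_fast, tau_fast = _loglin_single(ts[:half], resid[:half])
        except FitError:
            a_fast, tau_fast = resid[0], max(tau_slow / 10.0, 1e-6)
        p0 = [c, a_fast, tau_fast, a_slow, tau_slow]

        def model(tt, c, a1, tau1, a2, tau2):
            return c + a1 * np.exp(-tt / tau1) + a2 * np.exp(-tt / tau2)

    if refine:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(model, ts, y, p0=p0, maxfev=2000)
        except (RuntimeError, ValueError) as exc:
            raise FitError(f"exponential fit did not converge: {exc}") from exc
    else:
        popt = np.asarray(p0, dtype=float)

    c = popt[0]
    amps = popt[1::2]
    taus = popt[2::2]
    if np.any(taus <= 0) or not np.all(np.isfinite(popt)):
        raise FitError("fit produced non-positive or non-finite time constant")
    order = np.argsort(taus)
    taus, amps = taus[order], amps[order]
    residual = float(np.sqrt(np.mean((model(ts, *popt) - y) ** 2)))
    return np.asarray(taus, float), np.asarray(amps, float), float(c), residual


def recovery_fraction(p1_peaks, p2_peaks, intervals) -> SummaryCurve:
    """P2/P1 peak-current ratio per inter-pulse interval."""
    p1 = np.asarray(p1_peaks, dtype=float)
    p2 = np.asarray(p2_peaks, dtype=float)
    iv = np.asarray(intervals, dtype=float)
    if not (p1.shape == p2.shape == iv.shape):
        raise ValueError("P1, P2 and intervals must align")
    if np.any(p1 == 0):
        raise ValueError("P1 peak of zero; recovery fraction undefined")
    return SummaryCurve("recovery_fraction", iv, p2 / p1)


# ---------------------------------------------------------------------------
# Experiment declaration and forward simulation to summary space


@dataclass
class ExperimentDesign:
    """Declares how one experiment reduces a protocol's traces to a curve.

    Attributes
    ----------
    name : experiment identifier (aligns simulated output with a dataset).
    statistic_type : one of STATISTIC_TYPES.
    protocol : the voltage program to run.
    window_index : which recorded window the statistic is read from.
    n_components : exponential components for time-constant experiments.
    component : "fast" or "slow" — which fitted tau the experiment reports
        (declared, never inferred).
    fit_from_peak : fit the decay from the in-window peak onward (True) or
        the relaxation from window start (False, e.g. activation rise).
    """

    name: str
    statistic_type: str
    protocol: ProtocolTemplate
    window_index: int = 0
    n_components: int = 1
    component: str = "fast"
    fit_from_peak: bool = False

    def __post_init__(self) -> None:
        if self.statistic_type not in STATISTIC_TYPES:
            raise ValueError(f"unknown statistic type {self.statistic_type!r}")
        if self.component not in ("fast", "slow"):
            raise ValueError("component must be 'fast' or 'slow'")


def _time_constant_curve(traces: Sequence[Trace], design: ExperimentDesign) -> SummaryCurve:
    xs, ys = [], []
    for tr in traces:
        w = tr.windows[design.window_index]
        t = tr.times[w.sl]
        y = tr.current[w.sl]
        if design.fit_from_peak:
            k = int(np.argmax(np.abs(y)))
            if y.size - k < 10:
                raise FitError("fewer than 10 samples after the peak")
            t, y = t[k:], y[k:]
        try:
            taus, _, _, _ = fit_time_constant(t, y, design.n_components)
        except FitError:
            raise
        tau = taus[0] if design.component == "fast" else taus[-1]
        xs.append(tr.sweep_value)
        ys.append(tau)
    return SummaryCurve("time_constant", np.asarray(xs), np.asarray(ys))


def simulate_summary(channel: ChannelSpec, theta, design: ExperimentDesign) -> SummaryCurve:
    """Run the design's protocol at theta and extract its summary curve.

    Raises SimulationFailure (invalid parameters, failed fit) which the
    distance layer maps to an infinite distance.
    """
    traces = run_protocol(channel, theta, design.protocol)
    try:
        st = design.statistic_type
        if st == "peak_iv":
            x = np.array([tr.sweep_value for tr in traces])
            y = np.array([peak_current(tr, design.window_index) for tr in traces])
            return SummaryCurve("peak_iv", x, y)
        if st == "steady_state_activation":
            return steady_state_curve(traces, "activation", channel, design.window_index)
        if st == "steady_state_inactivation":
            return steady_state_curve(traces, "availability", channel, design.window_index)
        if st == "time_constant":
            return _time_constant_curve(traces, design)
        if st == "recovery_fraction":
            p1 = [peak_current(tr, 0) for tr in traces]
            p2 = [peak_current(tr, 1) for tr in traces]
            iv = [tr.sweep_value for tr in traces]
            return recovery_fraction(p1, p2, iv)
        raise ValueError(f"unknown statistic type {st!r}")
    except FitError as exc:
        raise SimulationFailure(str(exc)) from exc
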
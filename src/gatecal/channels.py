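"""Hodgkin-Huxley channel specifications and the standardized Eyring-rate gating model.

A channel is an ordered collection of gates.  Each gate ``gamma`` is a
dimensionless open fraction in [0, 1] evolving by first-order kinetics
between a voltage-dependent opening rate ``alpha(V)`` and closing rate
``beta(V)``::

    d(gamma)/dt = (gamma_inf(V) - gamma) / tau(V)
    tau = 1 / (alpha + beta)
    gamma_inf = alpha * tau   (activating gate)
    gamma_inf = beta * tau    (inactivating gate)

The channel current is ``I = g * prod_j gamma_j**k_j * (V - E)``.

The standardized ("S") formulation uses Eyring-form transition rates
grounded in transition-state theory::

    alpha(V) = lam1 * exp(+lam2 * V)
    beta(V)  = lam3 * exp(-lam4 * V)

with lam1, lam3 rate amplitudes (ms^-1) and lam2, lam4 voltage
sensitivities (mV^-1), all non-negative.  A slow second inactivation gate
may be *tied* to an existing inactivation gate: it shares the sibling's
steady state while its time constant is scaled by a single free parameter
``a`` (tau_2 = a * tau_1), so a tied gate contributes exactly one free
parameter.

Units package-wide: mV, ms, ms^-1 rates, mV^-1 voltage sensitivities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "InvalidParameterError",
    "ChannelConfigError",
    "RateParams",
    "EyringRates",
    "ExpressionRates",
    "GateSpec",
    "ChannelSpec",
    "PriorBox",
    "eval_rates",
    "gate_steady_state_tau",
    "channel_current",
    "build_standard_channel",
    "default_standard_prior",
    "standard_ina_layout",
    "nygren_ina_layout",
    "courtemanche_ina_layout",
    "load_channel",
    "save_channel",
    "channel_to_dict",
    "channel_from_dict",
]

ACTIVATING = "activating"
INACTIVATING = "inactivating"

# exp argument beyond this is treated as an invalid-parameter evaluation
# (caller maps to infinite distance) rather than silent inf/0.
_EXP_ARG_MAX = 700.0


class InvalidParameterError(ValueError):
    """Rate evaluation produced a non-finite or out-of-domain value."""


class ChannelConfigError(ValueError):
    """Malformed channel/gate layout configuration."""


@dataclass(frozen=True)
class RateParams:
    """Eyring-rate parameter quadruple (lam1, lam2, lam3, lam4), all >= 0."""

    lam1: float
    lam2: float
    lam3: float
    lam4: float

    def __post_init__(self) -> None:
        for name in ("lam1", "lam2", "lam3", "lam4"):
            v = getattr(self, name)
            if not (v >= 0.0):
                raise InvalidParameterError(f"{name} must be >= 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.lam1, self.lam2, self.lam3, self.lam4])


class EyringRates:
    """Standardized transition rates alpha = lam1*exp(lam2*V), beta = lam3*exp(-lam4*V)."""

    param_names: tuple[str, ...] = ("lam1", "lam2", "lam3", "lam4")

    def __call__(self, V, params: Mapping[str, float]):
        l1, l2, l3, l4 = (params[k] for k in self.param_names)
        if isinstance(V, (int, float)):  # scalar fast path (hot in the clamp engine)
            a_arg, b_arg = l2 * V, -l4 * V
            if abs(a_arg) > _EXP_ARG_MAX or abs(b_arg) > _EXP_ARG_MAX:
                raise InvalidParameterError("exponential overflow in rate evaluation")
            alpha, beta = l1 * math.exp(a_arg), l3 * math.exp(b_arg)
            if not (math.isfinite(alpha) and math.isfinite(beta)):
                raise InvalidParameterError("non-finite rate value")
            return alpha, beta
        V = np.asarray(V, dtype=float)
        a_arg = l2 * V
        b_arg = -l4 * V
        if np.any(np.abs(a_arg) > _EXP_ARG_MAX) or np.any(np.abs(b_arg) > _EXP_ARG_MAX):
            raise InvalidParameterError("exponential overflow in rate evaluation")
        alpha = l1 * np.exp(a_arg)
        beta = l3 * np.exp(b_arg)
        if not (np.all(np.isfinite(alpha)) and np.all(np.isfinite(beta))):
            raise InvalidParameterError("non-finite rate value")
        return alpha, beta

    def to_dict(self) -> dict:
        return {"form": "eyring"}


class ExpressionRates:
    """User-supplied declarative rate expressions over V and named parameters.

    Expressions are parsed once (sympy) and evaluated numerically.  This is
    the entry point for gating formulations other than the standardized
    Eyring form, e.g. the inherited equations of published atrial cell
    models.
    """

    def __init__(self, alpha: str, beta: str, param_names: Sequence[str]):
        import sympy

        self.alpha_expr = alpha
        self.beta_expr = beta
        self.param_names = tuple(param_names)
        symbols = {"V": sympy.Symbol("V")}
        symbols.update({p: sympy.Symbol(p) for p in self.param_names})
        order = [symbols["V"]] + [symbols[p] for p in self.param_names]
        try:
            a = sympy.sympify(alpha, locals=symbols)
            b = sympy.sympify(beta, locals=symbols)
        except (sympy.SympifyError, TypeError) as exc:
            raise ChannelConfigError(f"cannot parse rate expression: {exc}") from exc
        free = (a.free_symbols | b.free_symbols) - set(order)
        if free:
            raise ChannelConfigError(f"rate expressions use undeclared symbols: {sorted(map(str, free))}")
        self._alpha_fn: Callable = sympy.lambdify(order, a, modules="numpy")
        self._beta_fn: Callable = sympy.lambdify(order, b, modules="numpy")

    def __call__(self, V, params: Mapping[str, float]):
        V = np.asarray(V, dtype=float)
        args = [params[p] for p in self.param_names]
        with np.errstate(over="raise", divide="raise", invalid="raise"):
            try:
                alpha = np.asarray(self._alpha_fn(V, *args), dtype=float)
                beta = np.asarray(self._beta_fn(V, *args), dtype=float)
            except FloatingPointError as exc:
                raise InvalidParameterError(f"rate expression evaluation failed: {exc}") from exc
        alpha = np.broadcast_to(alpha, V.shape) if V.shape else alpha
        beta = np.broadcast_to(beta, V.shape) if V.shape else beta
        if not (np.all(np.isfinite(alpha)) and np.all(np.isfinite(beta))):
            raise InvalidParameterError("non-finite rate value")
        return alpha, beta

    def to_dict(self) -> dict:
        return {
            "form": "expression",
            "alpha": self.alpha_expr,
            "beta": self.beta_expr,
            "params": list(self.param_names),
        }


@dataclass
class GateSpec:
    """One gate of a channel.

    Parameters
    ----------
    name : identifier used to prefix parameter names ("m.lam1", ...).
    role : "activating" or "inactivating"; selects the gamma_inf branch.
    exponent : positive integer k, the number of identical gates in parallel.
    rates : rate-function object (EyringRates or ExpressionRates); None for
        tied or constant gates.
    tied_to : name of a sibling gate this gate shares its steady state with;
        a tied gate's only free parameter is the time-constant scale ``a``.
    constant : if set, the gate is held at this fixed open fraction and
        contributes no free parameters (calcium-dependent inactivation is
        represented this way).
    """

    name: str
    role: str = ACTIVATING
    exponent: int = 1
    rates: EyringRates | ExpressionRates | None = None
    tied_to: str | None = None
    constant: float | None = None

    def __post_init__(self) -> None:
        if self.role not in (ACTIVATING, INACTIVATING):
            raise ChannelConfigError(f"gate {self.name!r}: unknown role {self.role!r}")
        if not (isinstance(self.exponent, (int, np.integer)) and self.exponent >= 1):
            raise ChannelConfigError(f"gate {self.name!r}: exponent must be a positive integer")
        if self.tied_to == self.name:
            raise ChannelConfigError(f"gate {self.name!r} cannot be tied to itself")
        if self.tied_to is not None and self.constant is not None:
            raise ChannelConfigError(f"gate {self.name!r}: tied gate cannot also be constant")
        if self.rates is None and self.tied_to is None and self.constant is None:
            self.rates = EyringRates()

    @property
    def free_param_names(self) -> tuple[str, ...]:
        if self.constant is not None:
            return ()
        if self.tied_to is not None:
            return (f"{self.name}.scale",)
        return tuple(f"{self.name}.{p}" for p in self.rates.param_names)


@dataclass
class ChannelSpec:
    """A named Hodgkin-Huxley channel: ordered gates, conductance, driving force.

    Conductance ``g`` scales the current amplitude only; summary statistics
    are normalized, so ``g`` is never a calibration parameter (it defaults
    to 1 and is held fixed during calibration).  The driving force is
    linear, ``f(V) = V - E``.
    """

    name: str
    gates: list[GateSpec]
    conductance: float = 1.0
    reversal_potential: float = 0.0

    def __post_init__(self) -> None:
        names = [g.name for g in self.gates]
        if len(set(names)) != len(names):
            raise ChannelConfigError("duplicate gate names")
        for g in self.gates:
            if g.tied_to is not None:
                if g.tied_to not in names:
                    raise ChannelConfigError(
                        f"gate {g.name!r} tied to missing gate {g.tied_to!r}"
                    )
                sib = self.gate(g.tied_to)
                if sib.tied_to is not None:
                    raise ChannelConfigError(f"gate {g.name!r}: cannot tie to a tied gate")

    def gate(self, name: str) -> GateSpec:
        for g in self.gates:
            if g.name == name:
                return g
        raise KeyError(name)

    @property
    def param_names(self) -> tuple[str, ...]:
        out: list[str] = []
        for g in self.gates:
            out.extend(g.free_param_names)
        return tuple(out)

    @property
    def free_parameter_count(self) -> int:
        return len(self.param_names)

    def params_dict(self, theta: Sequence[float] | Mapping[str, float]) -> dict[str, float]:
        """Normalize a parameter vector or mapping to {qualified name: value}."""
        names = self.param_names
        if isinstance(theta, Mapping):
            missing = set(names) - set(theta)
            if missing:
                raise InvalidParameterError(f"missing parameters: {sorted(missing)}")
            return {k: float(theta[k]) for k in names}
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(names),):
            raise InvalidParameterError(
                f"expected {len(names)} parameters {names}, got shape {theta.shape}"
            )
        return dict(zip(names, map(float, theta)))


def eval_rates(gate: GateSpec, V, params) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate (alpha, beta) in ms^-1 at membrane potential V (mV).

    ``params`` is a RateParams, a mapping of the gate's bare parameter names,
    or a mapping of qualified "<gate>.<param>" names.
    """
    if gate.rates is None:
        raise ChannelConfigError(f"gate {gate.name!r} has no rate functions")
    if isinstance(params, RateParams):
        local = {"lam1": params.lam1, "lam2": params.lam2, "lam3": params.lam3, "lam4": params.lam4}
    else:
        prefix = f"{gate.name}."
        local = {
            (k[len(prefix):] if k.startswith(prefix) else k): float(v)
            for k, v in dict(params).items()
        }
    return gate.rates(V, local)


def gate_steady_state_tau(
    gate: GateSpec,
    V,
    params,
    sibling: tuple[np.ndarray, np.ndarray] | None = None,
    scale: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (gamma_inf, tau) at V.

    For an untied gate, tau = 1/(alpha+beta) and gamma_inf is alpha*tau
    (activating) or beta*tau (inactivating).  For a tied gate, pass the
    sibling's (gamma_inf, tau) and the scale ``a``: the tied gate shares the
    sibling's steady state with tau = a * sibling tau.
    """
    if gate.constant is not None:
        V = np.asarray(V, dtype=float)
        g = np.broadcast_to(float(gate.constant), V.shape).copy()
        return g, np.full_like(g, np.inf)
    if gate.tied_to is not None:
        if sibling is None or scale is None:
            raise ChannelConfigError(f"tied gate {gate.name!r} needs sibling values and scale")
        if not scale > 0:
            raise InvalidParameterError("tied-gate scale must be > 0")
        sib_inf, sib_tau = sibling
        return np.asarray(sib_inf, float), scale * np.asarray(sib_tau, float)
    alpha, beta = eval_rates(gate, V, params)
    total = alpha + beta
    if np.any(total <= 0.0):
        raise InvalidParameterError(f"gate {gate.name!r}: alpha + beta = 0 (degenerate gate)")
    tau = 1.0 / total
    gamma_inf = alpha * tau if gate.role == ACTIVATING else beta * tau
    return gamma_inf, tau


def channel_steady_state(channel: ChannelSpec, V, theta) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """(gamma_inf, tau) for every gate of the channel at V, handling ties."""
    params = channel.params_dict(theta)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for g in channel.gates:
        if g.tied_to is None:
            out[g.name] = gate_steady_state_tau(g, V, params)
    for g in channel.gates:
        if g.tied_to is not None:
            out[g.name] = gate_steady_state_tau(
                g, V, params, sibling=out[g.tied_to], scale=params[f"{g.name}.scale"]
            )
    return out


def channel_current(channel: ChannelSpec, gate_values: Mapping[str, np.ndarray], V):
    """I = g * prod_j gamma_j**k_j * (V - E)."""
    V = np.asarray(V, dtype=float)
    open_frac = 1.0
    for g in channel.gates:
        gamma = np.asarray(gate_values[g.name], dtype=float)
        open_frac = open_frac * gamma**g.exponent
    return channel.conductance * open_frac * (V - channel.reversal_potential)


# ---------------------------------------------------------------------------
# Layout construction


def build_standard_channel(config: Mapping) -> ChannelSpec:
    """Construct a standardized (Eyring-rate) channel from a gate layout.

    ``config`` maps::

        name: str
        reversal_potential: mV (default 0)
        conductance: S/F (default 1; fixed during calibration)
        gates:
          - {name, role, exponent, tied_to?, constant?}

    Every untied, non-constant gate receives Eyring rates (4 free
    parameters); every tied gate contributes one free scale parameter.
    """
    try:
        gate_cfgs = config["gates"]
        name = config["name"]
    except (KeyError, TypeError) as exc:
        raise ChannelConfigError(f"layout must define 'name' and 'gates': {exc}") from exc
    gates = []
    for gc in gate_cfgs:
        gates.append(
            GateSpec(
                name=gc["name"],
                role=gc.get("role", ACTIVATING),
                exponent=int(gc.get("exponent", 1)),
                rates=None if (gc.get("tied_to") or gc.get("constant") is not None) else EyringRates(),
                tied_to=gc.get("tied_to"),
                constant=gc.get("constant"),
            )
        )
    return ChannelSpec(
        name=name,
        gates=gates,
        conductance=float(config.get("conductance", 1.0)),
        reversal_potential=float(config.get("reversal_potential", 0.0)),
    )


def standard_ina_layout() -> ChannelSpec:
    """Standardized fast sodium channel: m^3 activation, paired inactivation.

    The activation gate carries an exponent of 3 (three identical gates in
    parallel, consistent with the classical I_Na formulations); the slow
    inactivation gate is tied to the fast one by a single time-constant
    scale, so the channel has 4 + 4 + 1 = 9 free gating parameters.
    """
    return build_standard_channel(
        {
            "name": "INa.S",
            "reversal_potential": 60.0,
            "gates": [
                {"name": "m", "role": ACTIVATING, "exponent": 3},
                {"name": "h1", "role": INACTIVATING},
                {"name": "h2", "role": INACTIVATING, "tied_to": "h1"},
            ],
        }
    )


def nygren_ina_layout() -> ChannelSpec:
    """Synthetic structural stand-in for the Nygren-model fast sodium channel.

    The exact published rate equations are not reproduced here; this layout
    mirrors only the published gate structure (m^3 activation plus two
    independent inactivation gates) and its total of 15 free gating
    parameters (5 per gate), using representative thermodynamic/sigmoid
    rate forms.  Synthetic: parameter placeholders p1..p15, not fitted
    published values.
    """
    m = GateSpec(
        "m",
        ACTIVATING,
        exponent=3,
        rates=ExpressionRates(
            alpha="p1*(V + p2)/(1 - exp(-(V + p2)/p3))",
            beta="p4*exp(-V/p5)",
            param_names=["p1", "p2", "p3", "p4", "p5"],
        ),
    )
    h1 = GateSpec(
        "h1",
        INACTIVATING,
        rates=ExpressionRates(
            alpha="p6*exp(-(V + p7)/p8)",
            beta="p9/(1 + exp(-(V + p10)/p8))",
            param_names=["p6", "p7", "p8", "p9", "p10"],
        ),
    )
    h2 = GateSpec(
        "h2",
        INACTIVATING,
        rates=ExpressionRates(
            alpha="p11*exp(-(V + p12)/p13)",
            beta="p14/(1 + exp(-(V + p15)/p13))",
            param_names=["p11", "p12", "p13", "p14", "p15"],
        ),
    )
    return ChannelSpec("INa.N", [m, h1, h2], reversal_potential=60.0)


def courtemanche_ina_layout() -> ChannelSpec:
    """Synthetic structural stand-in for the Courtemanche-model fast sodium channel.

    Mirrors the published gate structure (m^3 activation with fast and slow
    inactivation gates h and j of Luo-Rudy heritage) and its total of 29
    free gating parameters (5 + 10 + 14), using representative rate forms
    with placeholder parameters q1..q29.  Synthetic: structure and
    parameter count only, not the published equations.
    """
    m = GateSpec(
        "m",
        ACTIVATING,
        exponent=3,
        rates=ExpressionRates(
            alpha="q1*(V + q2)/(1 - exp(-q3*(V + q2)))",
            beta="q4*exp(-V/q5)",
            param_names=["q1", "q2", "q3", "q4", "q5"],
        ),
    )
    # h and j's published forms are piecewise in V; the stand-ins fold the
    # second branch into an extra sigmoid/exponential term so the free
    # constant count matches the published total.
    h = GateSpec(
        "h",
        INACTIVATING,
        rates=ExpressionRates(
            alpha="q6*exp(-(V + q7)/q8)",
            beta="q9*exp(q10*V) + q11*exp(q12*V) + q13/(1 + exp(-(V + q14)/q15))",
            param_names=["q6", "q7", "q8", "q9", "q10", "q11", "q12", "q13", "q14", "q15"],
        ),
    )
    j = GateSpec(
        "j",
        INACTIVATING,
        rates=ExpressionRates(
            alpha="(-q16*exp(q17*V) - q18*exp(-q19*V))*(V + q20)/(1 + exp(q21*(V + q22)))",
            beta=(
                "q23*exp(q24*V)/(1 + exp(-q25*(V + q26)))"
                " + q27*exp(-q28*V)/(1 + exp(-q29*(V + q26)))"
            ),
            param_names=[
                "q16", "q17", "q18", "q19", "q20", "q21", "q22",
                "q23", "q24", "q25", "q26", "q27", "q28", "q29",
            ],
        ),
    )
    channel = ChannelSpec("INa.C", [m, h, j], reversal_potential=60.0)
    assert channel.free_parameter_count == 29
    return channel


# ---------------------------------------------------------------------------
# Priors


@dataclass
class PriorBox:
    """Independent uniform prior box over named parameters."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    def __init__(self, names: Sequence[str], lower, upper):
        self.names = tuple(names)
        self.lower = np.asarray(lower, dtype=float)
        self.upper = np.asarray(upper, dtype=float)
        if not (self.lower.shape == self.upper.shape == (len(self.names),)):
            raise ChannelConfigError("prior bounds must match parameter names")
        if not np.all(self.lower < self.upper):
            bad = [self.names[i] for i in np.nonzero(~(self.lower < self.upper))[0]]
            raise ChannelConfigError(f"prior lower >= upper for {bad}")

    @property
    def dim(self) -> int:
        return len(self.names)

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        if size is None:
            return rng.uniform(self.lower, self.upper)
        return rng.uniform(self.lower, self.upper, size=(size, self.dim))

    def contains(self, theta: np.ndarray) -> np.ndarray | bool:
        theta = np.asarray(theta, dtype=float)
        inside = (theta >= self.lower) & (theta <= self.upper)
        return inside.all(axis=-1)

    def to_dict(self) -> dict:
        return {
            name: [float(lo), float(hi)]
            for name, lo, hi in zip(self.names, self.lower, self.upper)
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Sequence[float]]) -> "PriorBox":
        names = list(d)
        lo = [d[n][0] for n in names]
        hi = [d[n][1] for n in names]
        return cls(names, lo, hi)


#: Default S-model prior ranges: rate amplitudes (ms^-1), voltage
#: sensitivities (mV^-1), tied time-constant scale.
DEFAULT_S_PRIOR_RANGES = {
    "amplitude": (1e-7, 1e3),
    "sensitivity": (1e-7, 0.4),
    "scale": (1.0, 500.0),
}


def default_standard_prior(channel: ChannelSpec, ranges: Mapping | None = None) -> PriorBox:
    """Uniform prior box for a standardized channel's free parameters."""
    r = dict(DEFAULT_S_PRIOR_RANGES)
    if ranges:
        r.update(ranges)
    lo, hi = [], []
    for name in channel.param_names:
        leaf = name.split(".", 1)[1]
        if leaf in ("lam1", "lam3"):
            b = r["amplitude"]
        elif leaf in ("lam2", "lam4"):
            b = r["sensitivity"]
        elif leaf == "scale":
            b = r["scale"]
        else:
            raise ChannelConfigError(
                f"no default prior for non-standard parameter {name!r}; supply bounds explicitly"
            )
        lo.append(b[0])
        hi.append(b[1])
    return PriorBox(channel.param_names, lo, hi)


# ---------------------------------------------------------------------------
# Config serialization (YAML dialect)


def channel_to_dict(channel: ChannelSpec) -> dict:
    gates = []
    for g in channel.gates:
        gd: dict = {"name": g.name, "role": g.role, "exponent": int(g.exponent)}
        if g.tied_to is not None:
            gd["tied_to"] = g.tied_to
        if g.constant is not None:
            gd["constant"] = float(g.constant)
        if g.rates is not None:
            gd["rates"] = g.rates.to_dict()
        gates.append(gd)
    return {
        "name": channel.name,
        "conductance": float(channel.conductance),
        "reversal_potential": float(channel.reversal_potential),
        "gates": gates,
    }


def channel_from_dict(d: Mapping) -> ChannelSpec:
    gates = []
    for gd in d.get("gates", []):
        rates_cfg = gd.get("rates")
        rates = None
        if rates_cfg is not None and gd.get("tied_to") is None and gd.get("constant") is None:
            form = rates_cfg.get("form", "eyring")
            if form == "eyring":
                rates = EyringRates()
            elif form == "expression":
                rates = ExpressionRates(rates_cfg["alpha"], rates_cfg["beta"], rates_cfg["params"])
            else:
                raise ChannelConfigError(f"unknown rate form {form!r}")
        gates.append(
            GateSpec(
                name=gd["name"],
                role=gd.get("role", ACTIVATING),
                exponent=int(gd.get("exponent", 1)),
                rates=rates,
                tied_to=gd.get("tied_to"),
                constant=gd.get("constant"),
            )
        )
    return ChannelSpec(
        name=d["name"],
        gates=gates,
        conductance=float(d.get("conductance", 1.0)),
        reversal_potential=float(d.get("reversal_potential", 0.0)),
    )


def save_channel(channel: ChannelSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(channel_to_dict(channel), fh, sort_keys=False)


def load_channel(path) -> ChannelSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, Mapping):
        raise ChannelConfigError(f"{path}: not a channel config mapping")
    return channel_from_dict(d)
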
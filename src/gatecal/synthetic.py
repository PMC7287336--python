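"""Synthetic pseudo-experimental datasets with known ground truth.

Published voltage-clamp datasets are digitized summary curves reported as
mean +/- s.d. across cells.  This module emulates them: a known
ground-truth channel is simulated under the scenario's protocols, each
summary point is perturbed with Gaussian noise across simulated "cells"
(sd = rel * |y| + abs), and the per-point sample mean, sample s.d. and
cell count are reported in the same delimited format the distance module
reads.  Because the generating parameters are known, the full
calibration-and-identifiability pipeline can be validated end to end
(parameter recovery, identifiability patterns).

Noise is applied at summary level, not to raw traces: calibration compares
model and data in summary space, so trace-level artifact modelling is not
required for the pipeline to be exercised faithfully.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .channels import ChannelSpec, PriorBox, build_standard_channel, default_standard_prior
from .clamp import SimulationFailure
from .distance import ExperimentDataset
from .protocols import activation_iv, availability, deactivation, recovery
from .summaries import ExperimentDesign, simulate_summary

__all__ = [
    "NoiseModel",
    "Scenario",
    "generate_dataset",
    "scenario_library",
    "single_gate_channel",
    "two_gate_channel",
    "SINGLE_GATE_TRUTH",
    "TWO_GATE_TRUTH",
]


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian summary-level noise: sd = rel_sd * |y| + abs_sd, over n_cells.

    Defaults (2% relative, 0.01 absolute floor, 10 cells) give a visual
    spread comparable to published patch-clamp summary figures.
    ``noiseless()`` gives exact means with zero reported s.d.
    """

    rel_sd: float = 0.02
    abs_sd: float = 0.01
    n_cells: int = 10

    def __post_init__(self) -> None:
        if self.rel_sd < 0 or self.abs_sd < 0:
            raise ValueError("sd components must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    @property
    def noiseless(self) -> bool:
        return self.rel_sd == 0.0 and self.abs_sd == 0.0

    def to_dict(self) -> dict:
        return {"rel_sd": self.rel_sd, "abs_sd": self.abs_sd, "n_cells": self.n_cells}


def _design_seed(seed: int, design_name: str) -> np.random.SeedSequence:
    # keyed by design name so scenarios sharing an experiment produce
    # identical data from the same master seed
    return np.random.SeedSequence(entropy=[int(seed), zlib.crc32(design_name.encode())])


def generate_dataset(
    channel: ChannelSpec,
    true_params,
    designs: Sequence[ExperimentDesign],
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> tuple[list[ExperimentDataset], dict]:
    """Simulate each declared experiment at the ground truth and add noise.

    Returns (datasets, ground_truth_record).  The record holds everything
    needed to regenerate the datasets exactly: channel name, parameter
    values, noise config and seed.  Simulation failure at the ground truth
    is an error — the truth must be simulable.
    """
    noise = noise or NoiseModel()
    params = channel.params_dict(true_params)
    datasets = []
    for design in designs:
        try:
            curve = simulate_summary(channel, params, design)
        except SimulationFailure as exc:
            raise ValueError(
                f"ground truth is not simulable for experiment {design.name!r}: {exc}"
            ) from exc
        gen_sd = noise.rel_sd * np.abs(curve.y) + noise.abs_sd
        if noise.noiseless:
            mean, sd = curve.y.copy(), np.zeros_like(curve.y)
        else:
            rng = np.random.default_rng(_design_seed(seed, design.name))
            cells = curve.y[None, :] + rng.normal(size=(noise.n_cells, curve.y.size)) * gen_sd[None, :]
            mean = cells.mean(axis=0)
            sd = cells.std(axis=0, ddof=1) if noise.n_cells > 1 else np.zeros_like(mean)
        datasets.append(
            ExperimentDataset(
                name=design.name,
                statistic_type=design.statistic_type,
                x=curve.x,
                mean=mean,
                sd=sd,
                n_cells=np.full(curve.x.size, noise.n_cells),
            )
        )
    record = {
        "channel": channel.name,
        "true_params": {k: float(v) for k, v in params.items()},
        "noise": noise.to_dict(),
        "seed": int(seed),
        "experiments": [d.name for d in designs],
    }
    return datasets, record


# ---------------------------------------------------------------------------
# Ground-truth channels and scenario library


#: Ground truth for the single activating-gate channel (a slow, IKr-like
#: delayed-rectifier gate): half-activation near -30 mV, slope ~7.7 mV,
#: peak time constant ~11 ms.
SINGLE_GATE_TRUTH = {
    "a.lam1": 0.5,
    "a.lam2": 0.08,
    "a.lam3": 0.0101,
    "a.lam4": 0.05,
}

#: Ground truth for the two-gate (activation m^3 + inactivation h) channel,
#: a fast-sodium-like current: activation V1/2 ~ -23 mV with tau ~0.3 ms,
#: inactivation V1/2 ~ -70 mV with tau 6-60 ms.
TWO_GATE_TRUTH = {
    "m.lam1": 20.0,
    "m.lam2": 0.12,
    "m.lam3": 0.4,
    "m.lam4": 0.05,
    "h.lam1": 0.5,
    "h.lam2": 0.06,
    "h.lam3": 5.6e-5,
    "h.lam4": 0.07,
}


def single_gate_channel() -> ChannelSpec:
    """Standardized channel with one activating gate (k = 1), E = -85 mV."""
    return build_standard_channel(
        {
            "name": "K.single",
            "reversal_potential": -85.0,
            "gates": [{"name": "a", "role": "activating", "exponent": 1}],
        }
    )


def two_gate_channel() -> ChannelSpec:
    """Standardized channel with m^3 activation and one inactivation gate."""
    return build_standard_channel(
        {
            "name": "Na.two",
            "reversal_potential": 60.0,
            "gates": [
                {"name": "m", "role": "activating", "exponent": 3},
                {"name": "h", "role": "inactivating"},
            ],
        }
    )


@dataclass
class Scenario:
    """A named experiment battery over a ground-truth channel."""

    name: str
    channel_factory: Callable[[], ChannelSpec]
    true_params: Mapping[str, float]
    designs: list[ExperimentDesign]
    noise: NoiseModel = field(default_factory=NoiseModel)

    def channel(self) -> ChannelSpec:
        return self.channel_factory()

    def prior(self) -> PriorBox:
        return default_standard_prior(self.channel())

    def generate(self, seed: int = 0) -> tuple[list[ExperimentDataset], dict]:
        ds, record = generate_dataset(
            self.channel(), dict(self.true_params), self.designs, self.noise, seed
        )
        record["scenario"] = self.name
        return ds, record

    @property
    def experiment_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.designs)


def _single_gate_designs() -> dict[str, ExperimentDesign]:
    act_ss = ExperimentDesign(
        name="act_ss",
        statistic_type="steady_state_activation",
        protocol=activation_iv(
            test_voltages=np.arange(-60.0, 41.0, 10.0),
            holding=-80.0,
            hold_ms=20.0,
            step_ms=100.0,
            sample_interval=0.5,
        ),
    )
    act_tau = ExperimentDesign(
        name="act_tau",
        statistic_type="time_constant",
        protocol=activation_iv(
            test_voltages=np.arange(-50.0, 1.0, 10.0),
            holding=-80.0,
            hold_ms=20.0,
            step_ms=60.0,
            sample_interval=0.05,
        ),
        fit_from_peak=False,
    )
    deact_tau = ExperimentDesign(
        name="deact_tau",
        statistic_type="time_constant",
        protocol=deactivation(
            tail_voltages=np.arange(-120.0, -69.0, 10.0),  # avoids V = E = -85
            holding=-80.0,
            hold_ms=20.0,
            activating_voltage=20.0,
            activating_ms=80.0,
            tail_ms=20.0,
            sample_interval=0.02,
        ),
        fit_from_peak=False,
    )
    return {"act_ss": act_ss, "act_tau": act_tau, "deact_tau": deact_tau}


def _two_gate_designs() -> dict[str, ExperimentDesign]:
    act_ss = ExperimentDesign(
        name="na_act_ss",
        statistic_type="steady_state_activation",
        protocol=activation_iv(
            test_voltages=np.arange(-55.0, 6.0, 10.0),
            holding=-100.0,
            hold_ms=20.0,
            step_ms=30.0,
            sample_interval=0.02,
        ),
    )
    avail = ExperimentDesign(
        name="na_avail",
        statistic_type="steady_state_inactivation",
        protocol=availability(
            conditioning_voltages=np.arange(-120.0, -39.0, 10.0),
            holding=-100.0,
            test_voltage=-20.0,
            hold_ms=20.0,
            conditioning_ms=500.0,
            test_ms=25.0,
            sample_interval=0.02,
        ),
    )
    inact_tau = ExperimentDesign(
        name="na_inact_tau",
        statistic_type="time_constant",
        protocol=activation_iv(
            test_voltages=np.arange(-40.0, 21.0, 10.0),
            holding=-100.0,
            hold_ms=20.0,
            step_ms=40.0,
            sample_interval=0.02,
        ),
        fit_from_peak=True,
    )
    recov = ExperimentDesign(
        name="na_recovery",
        statistic_type="recovery_fraction",
        protocol=recovery(
            intervals=np.array([2.0, 5.0, 10.0, 20.0, 40.0, 80.0]),
            holding=-100.0,
            hold_ms=20.0,
            pulse_voltage=-20.0,
            pulse_ms=25.0,
            sample_interval=0.02,
        ),
    )
    deact_tau = ExperimentDesign(
        name="na_deact_tau",
        statistic_type="time_constant",
        protocol=deactivation(
            tail_voltages=np.arange(-120.0, -59.0, 10.0),
            holding=-100.0,
            hold_ms=20.0,
            activating_voltage=-20.0,
            activating_ms=0.5,
            tail_ms=5.0,
            sample_interval=0.005,
        ),
        fit_from_peak=True,
    )
    return {
        "na_act_ss": act_ss,
        "na_avail": avail,
        "na_inact_tau": inact_tau,
        "na_recovery": recov,
        "na_deact_tau": deact_tau,
    }


def scenario_library() -> dict[str, Scenario]:
    """Named scenarios mirroring the experimental-design families.

    For each ground-truth channel three batteries are provided:

    - ``steady-state-only`` — only steady-state (no kinetic) experiments,
      the situation in which time-constant parameters are practically
      unidentifiable;
    - ``full`` — steady-state plus time-constant/recovery experiments;
    - ``unified`` — ``full`` plus deactivation time constants (a superset,
      mirroring the union of all data sources).

    Keys are "<channel>:<battery>", e.g. "single-gate:full".
    """
    sg = _single_gate_designs()
    tg = _two_gate_designs()
    lib: dict[str, Scenario] = {}

    def add(key, designs_map, names, factory, truth):
        lib[key] = Scenario(
            name=key,
            channel_factory=factory,
            true_params=truth,
            designs=[designs_map[n] for n in names],
        )

    add("single-gate:steady-state-only", sg, ["act_ss"], single_gate_channel, SINGLE_GATE_TRUTH)
    add("single-gate:full", sg, ["act_ss", "act_tau"], single_gate_channel, SINGLE_GATE_TRUTH)
    add(
        "single-gate:unified",
        sg,
        ["act_ss", "act_tau", "deact_tau"],
        single_gate_channel,
        SINGLE_GATE_TRUTH,
    )
    add(
        "two-gate:steady-state-only",
        tg,
        ["na_act_ss", "na_avail"],
        two_gate_channel,
        TWO_GATE_TRUTH,
    )
    add(
        "two-gate:full",
        tg,
        ["na_act_ss", "na_avail", "na_inact_tau", "na_recovery"],
        two_gate_channel,
        TWO_GATE_TRUTH,
    )
    add(
        "two-gate:unified",
        tg,
        ["na_act_ss", "na_avail", "na_inact_tau", "na_recovery", "na_deact_tau"],
        two_gate_channel,
        TWO_GATE_TRUTH,
    )
    return lib


def write_ground_truth(record: Mapping, path) -> None:
    """Persist the ground-truth sidecar next to a generated dataset."""
    with open(path, "w") as fh:
        json.dump(dict(record), fh, indent=1, sort_keys=True)


def read_ground_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
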
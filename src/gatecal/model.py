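"""Model/Results interface for channel calibration.

:class:`ChannelCalibration` bundles a channel specification, the
experiment designs, the datasets to fit and the prior; ``fit()`` runs the
ABC-SMC sampler and returns a :class:`CalibrationResult` carrying the
weighted posterior, per-parameter uncertainty summaries (mean, sd, RSD,
HDPI), the converged residual and the sampler trajectory, with
``summary()``, posterior-predictive bands and plotting attached.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .channels import ChannelSpec, PriorBox, default_standard_prior, load_channel
from .clamp import SimulationFailure
from .distance import (
    DistanceConfig,
    ExperimentDataset,
    per_experiment_residuals,
    read_datasets,
    weighted_distance,
)
from .posterior import (
    PosteriorSamples,
    analysis_table,
    hdpi as _hdpi,
    posterior_predictive as _ppc,
    rsd as _rsd,
)
from .smc import Population, SamplerConfig, SMCDiagnostics, run as _smc_run
from .summaries import ExperimentDesign, simulate_summary

__all__ = ["ChannelCalibration", "CalibrationResult"]


class ChannelCalibration:
    """ABC-SMC calibration of a Hodgkin-Huxley channel to summary datasets.

    Parameters
    ----------
    channel : the channel specification; its free gating parameters are
        the quantities calibrated (conductance stays fixed).
    designs : experiment designs declaring how each dataset's statistic is
        simulated.  Every dataset must have a design of the same name.
    datasets : experimental-style summary datasets (x, mean, sd, n).
    prior : uniform prior box; defaults to the standardized-model ranges.
    distance_config : weighted-distance settings (eps0 regularization).
    sampler_config : ABC-SMC settings (population size, epsilon schedule,
        stopping rule, seed).
    """

    def __init__(
        self,
        channel: ChannelSpec,
        designs: Sequence[ExperimentDesign],
        datasets: Sequence[ExperimentDataset],
        prior: PriorBox | None = None,
        distance_config: DistanceConfig | None = None,
        sampler_config: SamplerConfig | None = None,
    ):
        self.channel = channel
        self.designs = list(designs)
        self.datasets = list(datasets)
        self.prior = prior or default_standard_prior(channel)
        self.distance_config = distance_config or DistanceConfig()
        self.sampler_config = sampler_config or SamplerConfig()
        design_names = {d.name for d in self.designs}
        missing = [ds.name for ds in self.datasets if ds.name not in design_names]
        if missing:
            raise ValueError(f"datasets without a matching design: {missing}")
        if tuple(self.prior.names) != tuple(channel.param_names):
            raise ValueError(
                "prior parameters do not match the channel's free parameters: "
                f"{self.prior.names} vs {channel.param_names}"
            )
        # cached x-alignment between each dataset and its design's curve
        # (the sweep order is deterministic, so the index map is static)
        self._aligners: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None

    @classmethod
    def from_scenario(cls, scenario, seed: int = 0, **kwargs) -> "ChannelCalibration":
        """Build a calibration from a synthetic scenario (generates its data)."""
        datasets, _ = scenario.generate(seed)
        channel = scenario.channel()
        return cls(channel, scenario.designs, datasets, prior=scenario.prior(), **kwargs)

    @classmethod
    def from_files(
        cls,
        channel_path,
        dataset_path,
        designs: Sequence[ExperimentDesign],
        **kwargs,
    ) -> "ChannelCalibration":
        return cls(load_channel(channel_path), designs, read_datasets(dataset_path), **kwargs)

    # -- forward map ------------------------------------------------------

    def simulate(self, theta) -> dict:
        """Summary curves at theta for every design (keyed by experiment name)."""
        return {d.name: simulate_summary(self.channel, theta, d) for d in self.designs}

    def _build_aligners(self, sim) -> None:
        aligners = {}
        eps0 = self.distance_config.eps0
        for ds in self.datasets:
            curve = sim[ds.name]
            idx = []
            for x in ds.x:
                j = np.nonzero(np.isclose(curve.x, x, rtol=1e-9, atol=1e-9))[0]
                if j.size != 1:
                    from .distance import AlignmentError

                    raise AlignmentError(f"{ds.name}: no simulated point at x = {x}")
                idx.append(j[0])
            idx = np.asarray(idx)
            aligners[ds.name] = (idx, ds.mean.copy(), ds.sd + eps0)
        self._aligners = aligners

    def distance(self, theta) -> float:
        """Weighted regularized distance at theta; +inf for failed simulations."""
        try:
            sim = self.simulate(np.asarray(theta, dtype=float))
        except SimulationFailure:
            return float("inf")
        if self._aligners is None:
            # first successful simulation fixes the x-alignment; fall back to
            # the reference implementation so errors surface identically
            d = weighted_distance(sim, self.datasets, self.distance_config)
            self._build_aligners(sim)
            return d
        total = 0.0
        norm = self.distance_config.per_experiment_norm
        for ds in self.datasets:
            idx, y, sde = self._aligners[ds.name]
            yhat = sim[ds.name].y[idx]
            if not np.all(np.isfinite(yhat)):
                return float("inf")
            z = (yhat - y) / sde
            contrib = float(z @ z)
            total += contrib / idx.size if norm else contrib
        return float(np.sqrt(total))

    # -- fitting ----------------------------------------------------------

    def _sampler_config(self) -> SamplerConfig:
        """Sampler config with log-scale kernel dims for amplitude parameters.

        Rate amplitudes (lam1, lam3) and tied time-constant scales are
        positive scale parameters spanning orders of magnitude under the
        default prior; they are perturbed on log scale unless the config
        already names its own dims.
        """
        from dataclasses import replace

        cfg = self.sampler_config
        if not cfg.log_scale_dims:
            dims = tuple(
                i
                for i, name in enumerate(self.channel.param_names)
                if name.rsplit(".", 1)[-1] in ("lam1", "lam3", "scale") and self.prior.lower[i] > 0
            )
            if dims:
                cfg = replace(cfg, log_scale_dims=dims)
        if cfg.epsilon_min is None:
            # discrepancy principle: do not tighten past the distance the
            # generating model itself would score given the reported noise
            from .distance import noise_floor_epsilon

            floor = noise_floor_epsilon(
                self.datasets, self.distance_config, seed=cfg.seed % (2**31)
            )
            cfg = replace(cfg, epsilon_min=floor)
        return cfg

    def fit(
        self,
        checkpoint_dir=None,
        resume: bool = False,
        progress: bool = False,
    ) -> "CalibrationResult":
        """Run ABC-SMC to convergence; deterministic given the config seed."""

        def _report(pop: Population) -> None:
            print(
                f"generation {pop.generation:3d}  epsilon {pop.epsilon:10.4g}  "
                f"acceptance {pop.acceptance_rate:7.2%}"
            )

        pop, diag = _smc_run(
            self.distance,
            self.prior,
            self._sampler_config(),
            checkpoint_dir=checkpoint_dir,
            resume=resume,
            progress=_report if progress else None,
            param_names=self.channel.param_names,
        )
        return CalibrationResult(self, pop, diag)


class CalibrationResult:
    """Weighted posterior population plus uncertainty diagnostics."""

    def __init__(self, model: ChannelCalibration, population: Population, diagnostics: SMCDiagnostics):
        self.model = model
        self.population = population
        self.diagnostics = diagnostics
        self.param_names = tuple(model.channel.param_names)
        self.samples = PosteriorSamples(population.params, population.weights, self.param_names)

    # -- point estimates and uncertainty ----------------------------------

    @property
    def params(self) -> pd.Series:
        """Posterior medians (weight-resampled), the headline point estimate."""
        med = []
        for j in range(len(self.param_names)):
            v = self.population.params[:, j]
            order = np.argsort(v)
            cw = np.cumsum(self.population.weights[order])
            med.append(float(v[order][np.searchsorted(cw, 0.5)]))
        return pd.Series(med, index=list(self.param_names), name="posterior_median")

    def rsd(self, unweighted: bool = False) -> pd.Series:
        out = {}
        for j, name in enumerate(self.param_names):
            out[name] = _rsd(self.population.params[:, j], self.population.weights, unweighted=unweighted)
        return pd.Series(out, name="rsd")

    def hdpi(self, mass: float = 0.89, seed: int = 0) -> pd.DataFrame:
        rows = {}
        for j, name in enumerate(self.param_names):
            rows[name] = _hdpi(self.population.params[:, j], self.population.weights, mass=mass, seed=seed)
        return pd.DataFrame(rows, index=["low", "high"]).T

    @property
    def converged_residual(self) -> float:
        """Goodness of fit: median accepted distance at convergence."""
        return self.diagnostics.converged_residual

    def per_experiment_fit(self) -> pd.DataFrame:
        """Weighted squared residual per experiment at the posterior median."""
        sim = self.model.simulate(self.params.to_numpy())
        return per_experiment_residuals(sim, self.model.datasets, self.model.distance_config)

    def posterior_predictive(self, design: ExperimentDesign | str, n_draws: int = 100, seed: int = 0):
        if isinstance(design, str):
            matches = [d for d in self.model.designs if d.name == design]
            if not matches:
                raise KeyError(design)
            design = matches[0]
        return _ppc(self.model.channel, self.samples, design, n_draws=n_draws, seed=seed)

    # -- reporting ---------------------------------------------------------

    def table(self, mass: float = 0.89, seed: int = 0) -> pd.DataFrame:
        return analysis_table(self.samples, mass=mass, seed=seed)

    def summary(self, mass: float = 0.89) -> str:
        """Human-readable calibration report."""
        buf = io.StringIO()
        d = self.diagnostics
        buf.write(f"ABC-SMC calibration of channel {self.model.channel.name!r}\n")
        buf.write("=" * 64 + "\n")
        buf.write(f"particles: {self.population.n}    generations: {self.population.generation + 1}\n")
        buf.write(f"final epsilon: {self.population.epsilon:.6g}    ")
        buf.write(f"final acceptance: {self.population.acceptance_rate:.2%}\n")
        buf.write(f"converged residual (median distance): {self.converged_residual:.6g}\n")
        buf.write(f"stop: {d.stopped_reason}\n\n")
        tab = self.table(mass=mass)
        tab = tab.rename(columns={"hdpi_low": f"hdpi{int(mass * 100)}_low", "hdpi_high": f"hdpi{int(mass * 100)}_high"})
        buf.write(tab.to_string(index=False, float_format=lambda v: f"{v:.5g}"))
        buf.write("\n")
        return buf.getvalue()

    # -- plotting ----------------------------------------------------------

    def plot_marginals(self, params: Sequence[str] | None = None):
        """KDE of each marginal posterior (returns the matplotlib figure)."""
        import matplotlib.pyplot as plt

        from .posterior import kde

        names = list(params or self.param_names)
        fig, axes = plt.subplots(1, len(names), figsize=(3 * len(names), 2.5), squeeze=False)
        for ax, name in zip(axes[0], names):
            v = self.samples.column(name)
            grid, dens = kde(v, self.samples.weights)
            ax.plot(grid, dens)
            ax.set_xlabel(name)
        fig.tight_layout()
        return fig

    def plot_posterior_predictive(self, design, n_draws: int = 100, seed: int = 0):
        """Median curve and HDPI band against the fitted dataset."""
        import matplotlib.pyplot as plt

        band = self.posterior_predictive(design, n_draws=n_draws, seed=seed)
        name = design if isinstance(design, str) else design.name
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.fill_between(band["x"], band["low"], band["high"], alpha=0.3, label="89% HDPI")
        ax.plot(band["x"], band["median"], label="median")
        for ds in self.model.datasets:
            if ds.name == name:
                ax.errorbar(ds.x, ds.mean, yerr=ds.sd, fmt="k+", capsize=2, label="data")
        ax.set_title(name)
        ax.legend()
        fig.tight_layout()
        return fig

    # -- persistence -------------------------------------------------------

    def save(self, directory) -> None:
        from .smc import save_population

        save_population(self.population, Path(directory), self.diagnostics, names=self.param_names)
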
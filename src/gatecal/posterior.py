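"""Posterior uncertainty and unidentifiability analysis.

Quantifies how well calibration constrained each parameter: relative
standard deviation (RSD = sigma/|mu|, scale-invariant; large values flag
poorly constrained, potentially unidentifiable parameters), highest-density
posterior intervals (HDPI, default 89% mass), weighted kernel density
estimates, posterior-predictive bands, and rank tests for comparing RSD
sets between calibrations (Wilcoxon signed-rank when paired, Mann-Whitney
U when not).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .channels import ChannelSpec
from .clamp import SimulationFailure
from .summaries import ExperimentDesign, simulate_summary

__all__ = [
    "PosteriorSamples",
    "UndefinedRSDError",
    "weighted_mean_std",
    "rsd",
    "hdpi",
    "kde",
    "ComparisonResult",
    "compare_rsd_sets",
    "posterior_predictive",
    "eyring_gate_combinations",
    "analysis_table",
]


class UndefinedRSDError(ZeroDivisionError):
    """RSD is undefined because the weighted mean is zero."""


@dataclass
class PosteriorSamples:
    """Weighted posterior parameter matrix with named columns."""

    params: np.ndarray  # (n, dim)
    weights: np.ndarray  # (n,)
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        self.names = tuple(self.names)
        if self.params.shape != (self.weights.size, len(self.names)):
            raise ValueError("params / weights / names shapes disagree")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("non-finite posterior samples")
        s = self.weights.sum()
        if not np.isclose(s, 1.0, atol=1e-9):
            raise ValueError(f"weights sum to {s}, not 1")

    def column(self, name: str) -> np.ndarray:
        return self.params[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.params, columns=list(self.names))
        df["weight"] = self.weights
        return df


def weighted_mean_std(values, weights=None) -> tuple[float, float]:
    """Weighted mean and *population* standard deviation.

    Particles are a weighted measure, not i.i.d. draws, so no n-1
    correction is applied; at uniform weights this equals the plain
    population moments exactly.
    """
    values = np.asarray(values, dtype=float)
    if weights is None:
        weights = np.full(values.size, 1.0 / values.size)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    mu = float(np.sum(weights * values))
    var = float(np.sum(weights * (values - mu) ** 2))
    return mu, float(np.sqrt(var))


def rsd(values, weights=None, unweighted: bool = False) -> float:
    """Relative standard deviation sigma/|mu| of one parameter's posterior.

    Raises UndefinedRSDError when the weighted mean is zero (reported, not
    fabricated).  ``unweighted=True`` ignores the particle weights.
    """
    if unweighted:
        weights = None
    mu, sigma = weighted_mean_std(values, weights)
    if mu == 0.0:
        raise UndefinedRSDError("weighted mean is zero; RSD undefined")
    return sigma / abs(mu)


def _resample(values, weights, n_draws: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    if weights is None:
        weights = np.full(values.shape[0], 1.0 / values.shape[0])
    weights = np.asarray(weights, dtype=float) / np.sum(weights)
    idx = rng.choice(values.shape[0], size=n_draws, p=weights)
    return values[idx]


def hdpi(
    values,
    weights=None,
    mass: float = 0.89,
    n_resample: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Narrowest interval containing >= ``mass`` of the weighted sample.

    Weights are handled by resampling ``n_resample`` draws (seeded), then
    an exhaustive search over all sorted windows of ceil(mass*n) samples —
    identical by construction to the brute-force definition.
    """
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 2:
        v = float(values[0])
        return (v, v)
    draws = np.sort(_resample(values, weights, n_resample, seed))
    k = int(np.ceil(mass * draws.size))
    widths = draws[k - 1 :] - draws[: draws.size - k + 1]
    i = int(np.argmin(widths))
    return float(draws[i]), float(draws[i + k - 1])


def kde(
    values,
    weights=None,
    grid: np.ndarray | None = None,
    n_grid: int = 512,
    bw_method: str = "silverman",
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted Gaussian KDE evaluated on a grid; integrates to ~1.

    Bandwidth follows Silverman's rule.  A zero-variance sample falls back
    to a delta-like narrow kernel with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 samples for a KDE")
    if weights is not None:
        weights = np.asarray(weights, dtype=float) / np.sum(weights)
    lo, hi = values.min(), values.max()
    if lo == hi:
        warnings.warn("zero-variance sample; KDE degenerates to a narrow kernel")
        span = max(abs(lo), 1.0) * 1e-6
        grid = np.linspace(lo - 5 * span, hi + 5 * span, n_grid) if grid is None else grid
        dens = stats.norm.pdf(grid, loc=lo, scale=span)
        return grid, dens
    k = stats.gaussian_kde(values, bw_method=bw_method, weights=weights)
    if grid is None:
        pad = 3.0 * k.covariance_factor() * values.std()
        grid = np.linspace(lo - pad, hi + pad, n_grid)
    return grid, k(grid)


# ---------------------------------------------------------------------------
# RSD-set comparisons


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a paired/unpaired rank test on two RSD sets.

    ``too_few`` is set (and statistic/pvalue are None) when, after
    discarding zero paired differences, too few pairs remain for the
    normal approximation to be meaningful.
    """

    test: str
    statistic: float | None
    pvalue: float | None
    too_few: bool = False
    n_effective: int = 0


def compare_rsd_sets(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool,
    min_pairs: int = 6,
) -> ComparisonResult:
    """Wilcoxon signed-rank (paired) or Mann-Whitney U (unpaired) on RSDs.

    Paired comparisons discard zero differences first; if fewer than
    ``min_pairs`` remain the result carries the "too few" flag instead of
    a p-value (e.g. when re-calibration left one gate's parameters — and
    hence their RSDs — unchanged).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty RSD set")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal lengths")
        diff = a - b
        nz = diff[diff != 0]
        if nz.size < min_pairs:
            return ComparisonResult("wilcoxon", None, None, too_few=True, n_effective=nz.size)
        res = stats.wilcoxon(a, b, zero_method="wilcox", method="approx")
        return ComparisonResult("wilcoxon", float(res.statistic), float(res.pvalue), n_effective=nz.size)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return ComparisonResult(
        "mannwhitneyu", float(res.statistic), float(res.pvalue), n_effective=min(a.size, b.size)
    )


# ---------------------------------------------------------------------------
# Posterior predictive


def posterior_predictive(
    channel: ChannelSpec,
    samples: PosteriorSamples,
    design: ExperimentDesign,
    n_draws: int = 100,
    mass: float = 0.89,
    seed: int = 0,
) -> pd.DataFrame:
    """Median and HDPI band of the simulated statistic across posterior draws.

    Draws ``n_draws`` parameter vectors by weight (with replacement,
    seeded), simulates the design for each, and reports per-x median and
    89% HDPI.  Failed draws are excluded and counted in the ``n_failed``
    attribute of the returned frame.
    """
    draws = _resample(samples.params, samples.weights, n_draws, seed)
    curves = []
    n_failed = 0
    for theta in draws:
        try:
            curves.append(simulate_summary(channel, theta, design))
        except SimulationFailure:
            n_failed += 1
    if not curves:
        raise SimulationFailure("all posterior-predictive draws failed")
    x = curves[0].x
    Y = np.array([c.y for c in curves])
    med = np.median(Y, axis=0)
    lo = np.empty_like(med)
    hi = np.empty_like(med)
    for j in range(x.size):
        lo[j], hi[j] = hdpi(Y[:, j], mass=mass, n_resample=min(10_000, 50 * Y.shape[0]), seed=seed)
    out = pd.DataFrame({"x": x, "median": med, "low": lo, "high": hi})
    out.attrs["n_failed"] = n_failed
    out.attrs["n_draws"] = n_draws
    return out


# ---------------------------------------------------------------------------
# Identifiability combinations for Eyring gates


def eyring_gate_combinations(samples: PosteriorSamples, gate: str) -> dict[str, np.ndarray]:
    """Diagnostic parameter combinations of one standardized gate.

    The steady state of an Eyring gate depends only on lam1/lam3 and
    lam2+lam4, so those are the combinations steady-state data can
    identify; the orthogonal combinations lam1*lam3 and lam2-lam4 move the
    time constant without changing the steady state and require kinetic
    (tau) data.  Returns per-sample values of log(lam1*lam3), lam2-lam4,
    log(lam1/lam3) and lam2+lam4.
    """
    l1 = samples.column(f"{gate}.lam1")
    l2 = samples.column(f"{gate}.lam2")
    l3 = samples.column(f"{gate}.lam3")
    l4 = samples.column(f"{gate}.lam4")
    with np.errstate(divide="ignore"):
        return {
            "log_product": np.log(l1 * l3),
            "sensitivity_difference": l2 - l4,
            "log_ratio": np.log(l1 / l3),
            "sensitivity_sum": l2 + l4,
        }


def analysis_table(samples: PosteriorSamples, mass: float = 0.89, seed: int = 0) -> pd.DataFrame:
    """Per-parameter summary: weighted mean, sd, RSD, HDPI bounds."""
    rows = []
    for j, name in enumerate(samples.names):
        v = samples.params[:, j]
        mu, sigma = weighted_mean_std(v, samples.weights)
        try:
            r = rsd(v, samples.weights)
        except UndefinedRSDError:
            r = float("nan")
        lo, hi = hdpi(v, samples.weights, mass=mass, seed=seed)
        rows.append((name, mu, sigma, r, lo, hi))
    return pd.DataFrame(rows, columns=["parameter", "mean", "sd", "rsd", "hdpi_low", "hdpi_high"])
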
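"""Weighted, regularized least-squares distance between model and data.

Experimental summary points carry a mean, a standard deviation across
cells, and a cell count.  The calibration distance standardizes each
residual by (sigma + eps0) — the regularization eps0 (default 0.05) avoids
division by zero for points reported without spread — and weights each
experiment by the inverse of its point count so that experiments with many
points do not dominate those with few::

    d = sqrt( sum_e (1/n_e) sum_i [ (yhat_ei - y_ei) / (sigma_ei + eps0) ]^2 )

A failed simulation yields +inf (always rejected by the sampler); a
missing simulated point is an alignment error, which is a programming
mistake rather than a parameter problem and raises.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .summaries import STATISTIC_TYPES, SummaryCurve

__all__ = [
    "DatasetError",
    "AlignmentError",
    "ExperimentDataset",
    "DistanceConfig",
    "align",
    "weighted_distance",
    "read_datasets",
    "write_datasets",
    "DATASET_COLUMNS",
]

DATASET_COLUMNS = ("experiment", "statistic_type", "x", "mean", "sd", "n")


class DatasetError(ValueError):
    """Malformed experiment dataset."""


class AlignmentError(RuntimeError):
    """Simulated curves do not cover the dataset's points or types."""


@dataclass
class ExperimentDataset:
    """One published-style experiment: points (x, mean, sd, n_cells)."""

    name: str
    statistic_type: str
    x: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_cells: np.ndarray
    protocol: str | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.n_cells = np.asarray(self.n_cells, dtype=int)
        if self.statistic_type not in STATISTIC_TYPES:
            raise DatasetError(f"{self.name}: unknown statistic type {self.statistic_type!r}")
        if not (self.x.shape == self.mean.shape == self.sd.shape == self.n_cells.shape):
            raise DatasetError(f"{self.name}: column lengths differ")
        if np.any(self.sd < 0):
            raise DatasetError(f"{self.name}: sd must be >= 0")
        if np.unique(self.x).size != self.x.size:
            raise DatasetError(f"{self.name}: x values must be unique")

    @property
    def n_points(self) -> int:
        return int(self.x.size)


@dataclass
class DistanceConfig:
    """eps0: additive sigma regularization; per_experiment_norm: 1/n_e factor."""

    eps0: float = 0.05
    per_experiment_norm: bool = True

    def __post_init__(self) -> None:
        if not self.eps0 > 0:
            raise ValueError("eps0 must be > 0")


def align(
    simulated: Mapping[str, SummaryCurve],
    datasets: Sequence[ExperimentDataset],
) -> pd.DataFrame:
    """Pair every dataset point with its simulated counterpart.

    Returns a table with one row per dataset point (experiment, x, y, sd,
    yhat); per-experiment sub-residuals for goodness-of-fit reporting come
    from grouping this table.  Raises AlignmentError on missing curves,
    type mismatches, or missing x points.
    """
    rows = []
    for ds in datasets:
        if ds.name not in simulated:
            raise AlignmentError(f"no simulated curve for experiment {ds.name!r}")
        curve = simulated[ds.name]
        if curve.statistic_type != ds.statistic_type:
            raise AlignmentError(
                f"{ds.name}: statistic type mismatch "
                f"(data {ds.statistic_type!r}, simulated {curve.statistic_type!r})"
            )
        # match on x within tolerance; protocols realize sweeps at the data x
        for x, y, sd in zip(ds.x, ds.mean, ds.sd):
            j = np.nonzero(np.isclose(curve.x, x, rtol=1e-9, atol=1e-9))[0]
            if j.size != 1:
                raise AlignmentError(f"{ds.name}: no simulated point at x = {x}")
            rows.append((ds.name, float(x), float(y), float(sd), float(curve.y[j[0]])))
    return pd.DataFrame(rows, columns=["experiment", "x", "y", "sd", "yhat"])


def weighted_distance(
    simulated: Mapping[str, SummaryCurve] | None,
    datasets: Sequence[ExperimentDataset],
    cfg: DistanceConfig | None = None,
) -> float:
    """The calibration distance; +inf if the simulation failed (None) or
    produced non-finite values."""
    cfg = cfg or DistanceConfig()
    if simulated is None:
        return float("inf")
    table = align(simulated, datasets)
    if table.empty:
        return 0.0
    if not np.all(np.isfinite(table["yhat"].to_numpy())):
        return float("inf")
    z = (table["yhat"] - table["y"]) / (table["sd"] + cfg.eps0)
    sq = z.to_numpy() ** 2
    total = 0.0
    for _, grp in pd.Series(sq).groupby(table["experiment"].to_numpy()):
        contrib = grp.sum()
        if cfg.per_experiment_norm:
            contrib /= grp.size
        total += contrib
    return float(np.sqrt(total))


def per_experiment_residuals(
    simulated: Mapping[str, SummaryCurve],
    datasets: Sequence[ExperimentDataset],
    cfg: DistanceConfig | None = None,
) -> pd.DataFrame:
    """Per-experiment weighted squared residuals (summing to the squared total)."""
    cfg = cfg or DistanceConfig()
    table = align(simulated, datasets)
    out = []
    for name, grp in table.groupby("experiment"):
        z = (grp["yhat"] - grp["y"]) / (grp["sd"] + cfg.eps0)
        contrib = float((z**2).sum())
        if cfg.per_experiment_norm:
            contrib /= len(grp)
        out.append((name, len(grp), contrib))
    return pd.DataFrame(out, columns=["experiment", "n_points", "weighted_sq_residual"])


def noise_floor_epsilon(
    datasets: Sequence[ExperimentDataset],
    cfg: DistanceConfig | None = None,
    quantile: float = 0.999,
    n_mc: int = 4000,
    seed: int = 0,
) -> float:
    """Distance the data-generating model itself would be expected to score.

    With a deterministic simulator, an ABC threshold tightened
    indefinitely collapses the posterior onto the least-squares optimum,
    fitting the noise in the data.  The discrepancy-principle remedy is to
    stop once the threshold reaches the distance a model reproducing the
    true means would plausibly attain given the reported per-point
    uncertainty.  That null distribution is simulated here from the
    datasets alone: for each point, ``n`` cell values are drawn with the
    reported s.d., and the resulting sample mean (standardized by the
    resulting sample s.d. plus eps0) contributes to the distance exactly
    as a model residual would.  Returns the requested quantile; 0 for
    noiseless data.
    """
    cfg = cfg or DistanceConfig()
    rng = np.random.default_rng(seed)
    totals = np.zeros(n_mc)
    for ds in datasets:
        if ds.n_points == 0:
            continue
        contrib = np.zeros(n_mc)
        for sd, n in zip(ds.sd, ds.n_cells):
            if sd == 0 or n < 2:
                continue
            cells = rng.normal(0.0, sd, size=(n_mc, int(n)))
            m = cells.mean(axis=1)
            s = cells.std(axis=1, ddof=1)
            contrib += (m / (s + cfg.eps0)) ** 2
        if cfg.per_experiment_norm:
            contrib /= ds.n_points
        totals += contrib
    return float(np.quantile(np.sqrt(totals), quantile))


# ---------------------------------------------------------------------------
# Delimited-text dataset format


def write_datasets(datasets: Sequence[ExperimentDataset], path) -> None:
    """Write experiments as comma-delimited text with the documented header."""
    frames = []
    for ds in datasets:
        frames.append(
            pd.DataFrame(
                {
                    "experiment": ds.name,
                    "statistic_type": ds.statistic_type,
                    "x": ds.x,
                    "mean": ds.mean,
                    "sd": ds.sd,
                    "n": ds.n_cells,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def read_datasets(path) -> list[ExperimentDataset]:
    """Read the comma-delimited dataset format, validating the schema."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, OSError) as exc:
        raise DatasetError(f"{path}: cannot parse dataset file: {exc}") from exc
    missing = set(DATASET_COLUMNS) - set(df.columns)
    if missing:
        raise DatasetError(
            f"{path}: missing required columns {sorted(missing)}; "
            f"expected header {', '.join(DATASET_COLUMNS)}"
        )
    for col in ("x", "mean", "sd"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise DatasetError(f"{path}: column {col!r} must be numeric")
    out = []
    for (name, stat), grp in df.groupby(["experiment", "statistic_type"], sort=False):
        out.append(
            ExperimentDataset(
                name=str(name),
                statistic_type=str(stat),
                x=grp["x"].to_numpy(),
                mean=grp["mean"].to_numpy(),
                sd=grp["sd"].to_numpy(),
                n_cells=grp["n"].to_numpy(),
            )
        )
    return out
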
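"""Sequential Monte Carlo ABC sampler (Toni-style).

Likelihood-free calibration: parameters are drawn from the prior, the
model simulated, and draws accepted when their summary-statistic distance
to data falls below a threshold epsilon.  Generations repeat with epsilon
set to a quantile of the previous generation's accepted distances;
particles are resampled by importance weight, perturbed with an adaptive
multivariate-normal kernel, and re-weighted as

    w_i  propto  pi(theta_i) / sum_j w_j K(theta_i | theta_j).

Sampling stops when a generation's particle acceptance rate drops below a
floor (default 1%) or a generation cap is reached.  The run is
deterministic given the seed: each generation draws from its own child RNG
derived from (seed, generation), which also makes checkpoint resumption
reproduce the uninterrupted run exactly.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .channels import PriorBox

__all__ = [
    "Particle",
    "Population",
    "SamplerConfig",
    "SMCDiagnostics",
    "sample_initial",
    "step",
    "run",
    "save_population",
    "load_population",
]


@dataclass(frozen=True)
class Particle:
    """One weighted parameter sample with its distance."""

    params: np.ndarray
    weight: float
    distance: float


@dataclass
class Population:
    """A weighted particle population at one SMC generation."""

    generation: int
    params: np.ndarray  # (N, dim)
    weights: np.ndarray  # (N,), sums to 1
    distances: np.ndarray  # (N,)
    epsilon: float
    acceptance_rate: float

    def __post_init__(self) -> None:
        # fixed C layout so reductions are bit-reproducible regardless of
        # whether the population was computed in memory or loaded from disk
        self.params = np.ascontiguousarray(np.atleast_2d(np.asarray(self.params, dtype=float)))
        self.weights = np.ascontiguousarray(np.asarray(self.weights, dtype=float))
        self.distances = np.ascontiguousarray(np.asarray(self.distances, dtype=float))
        if not math.isclose(self.weights.sum(), 1.0, abs_tol=1e-9):
            raise ValueError(f"weights sum to {self.weights.sum()}, not 1")
        if np.any(self.distances > self.epsilon):
            raise ValueError("particle distance exceeds epsilon")

    @property
    def n(self) -> int:
        return self.params.shape[0]

    @property
    def dim(self) -> int:
        return self.params.shape[1]

    def particles(self) -> list[Particle]:
        return [
            Particle(self.params[i].copy(), float(self.weights[i]), float(self.distances[i]))
            for i in range(self.n)
        ]

    def weighted_mean_distance(self) -> float:
        return float(np.sum(self.weights * self.distances))


@dataclass
class SamplerConfig:
    """ABC-SMC settings.

    n_particles : accepted particles per generation.
    quantile : epsilon schedule; next epsilon is this quantile of the
        previous generation's accepted distances (default median).
    kernel_scale : perturbation covariance = kernel_scale x weighted
        empirical covariance of the previous population.
    log_scale_dims : parameter indices perturbed on log scale (a geometric
        random walk).  Positive scale parameters such as rate amplitudes
        span orders of magnitude under a wide uniform prior; a linear
        kernel sized to the population covariance cannot reach small
        values from large ones, whereas a log-scale kernel explores all
        magnitudes.  The kernel density used in the importance weights
        includes the corresponding Jacobian.
    acceptance_floor : stop once a generation's acceptance rate drops below
        this (default 1%).
    max_generations : hard cap on generations after the initial one.
    epsilon0 : initial acceptance threshold (inf accepts everything finite).
    epsilon_min : terminal tolerance; the schedule never goes below it and
        the run stops once it is reached.  For a deterministic simulator
        this should be the noise-floor distance of the data (see
        distance.noise_floor_epsilon): tightening beyond it fits noise and
        collapses the posterior onto the least-squares optimum.  None asks
        the model layer to compute that floor automatically; an explicit
        0.0 disables the floor (tighten until the sampler stalls, the
        behaviour of acceptance-rate-based stopping).
    epsilon_stall_tol : also stop when epsilon's relative decrease over the
        last epsilon_stall_window generations falls below this (the sampler
        has reached the attainable distance floor).
    seed : master seed; every random draw derives from it.
    """

    n_particles: int = 1000
    quantile: float = 0.5
    kernel_scale: float = 2.0
    acceptance_floor: float = 0.01
    max_generations: int = 20
    epsilon0: float = float("inf")
    epsilon_min: float | None = None
    epsilon_stall_tol: float = 1e-3
    epsilon_stall_window: int = 3
    log_scale_dims: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must be in (0, 1)")
        if not 0 < self.acceptance_floor < 1:
            raise ValueError("acceptance_floor must be in (0, 1)")


@dataclass
class SMCDiagnostics:
    """Per-generation trajectory of the sampler."""

    epsilons: list[float] = field(default_factory=list)
    acceptance_rates: list[float] = field(default_factory=list)
    n_simulations: list[int] = field(default_factory=list)
    n_failures: list[int] = field(default_factory=list)
    stopped_reason: str = ""

    @property
    def converged_residual(self) -> float:
        """Final epsilon-scale distance summary (median accepted distance
        of the last completed generation)."""
        return self._final_median

    _final_median: float = float("nan")


def _gen_rng(seed: int, generation: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(entropy=seed, spawn_key=(generation,)))
    )


def sample_initial(
    prior: PriorBox,
    n: int,
    distance_fn: Callable[[np.ndarray], float],
    epsilon0: float = float("inf"),
    rng: np.random.Generator | None = None,
    acceptance_floor: float = 0.01,
) -> tuple[Population, int, int]:
    """Rejection-sample the first population from the prior.

    Returns (population, n_proposed, n_failures).  Particles carry uniform
    weights 1/n and distances below epsilon0 (non-finite distances count
    as simulation failures and are never accepted).  Aborts with a
    diagnostic if the acceptance rate falls below the floor already here.
    """
    if not epsilon0 > 0:
        raise ValueError("epsilon0 must be > 0 (or inf)")
    rng = rng or np.random.default_rng()
    max_proposals = max(int(np.ceil(n / acceptance_floor)), n)
    accepted_params, accepted_d = [], []
    proposed = failures = 0
    while len(accepted_params) < n:
        if proposed >= max_proposals:
            raise RuntimeError(
                f"initial sampling acceptance rate below {acceptance_floor:.2%} "
                f"({len(accepted_params)}/{proposed} accepted); "
                "check the prior, protocols, or epsilon0"
            )
        theta = prior.sample(rng)
        proposed += 1
        d = distance_fn(theta)
        if not np.isfinite(d):
            failures += 1
            continue
        if d < epsilon0:
            accepted_params.append(theta)
            accepted_d.append(d)
    pop = Population(
        generation=0,
        params=np.array(accepted_params),
        weights=np.full(n, 1.0 / n),
        distances=np.array(accepted_d),
        epsilon=float(epsilon0),
        acceptance_rate=n / proposed,
    )
    return pop, proposed, failures


def _weighted_cov(params: np.ndarray, weights: np.ndarray) -> np.ndarray:
    mu = np.average(params, axis=0, weights=weights)
    xc = params - mu
    return (weights[:, None] * xc).T @ xc


def _kernel_cov(pop: Population, kernel_scale: float) -> np.ndarray:
    cov = kernel_scale * _weighted_cov(pop.params, pop.weights)
    # guard degenerate axes so the kernel density stays evaluable
    floor = 1e-12 * max(1.0, float(np.max(np.abs(pop.params))) ** 2)
    d = np.diag(cov).copy()
    d[d < floor] = floor
    cov[np.diag_indices_from(cov)] = d
    return cov


def _mvn_logpdf(dx: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """log N(dx; 0, cov) for rows of dx, with diagonal fallback if singular."""
    dim = cov.shape[0]
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        warnings.warn("singular perturbation kernel covariance; falling back to diagonal")
        cov = np.diag(np.diag(cov))
        chol = np.linalg.cholesky(cov)
    z = np.linalg.solve(chol, dx.T)
    maha = np.sum(z**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (maha + logdet + dim * np.log(2.0 * np.pi))


def step(
    population: Population,
    prior: PriorBox,
    distance_fn: Callable[[np.ndarray], float],
    cfg: SamplerConfig,
    rng: np.random.Generator | None = None,
    epsilon: float | None = None,
) -> tuple[Population | None, int, int]:
    """One SMC generation.

    The new epsilon defaults to the cfg.quantile quantile of the previous
    accepted distances (never above the previous epsilon).  Returns
    (population | None, n_proposed, n_failures); None means the proposal
    budget (n_particles / acceptance_floor) was exhausted before the
    population filled, i.e. the sampler has stalled.
    """
    rng = rng or np.random.default_rng()
    if epsilon is None:
        epsilon = float(np.quantile(population.distances, cfg.quantile))
        epsilon = min(epsilon, population.epsilon)

    mask = np.zeros(population.dim, dtype=bool)
    if cfg.log_scale_dims:
        mask[list(cfg.log_scale_dims)] = True
        if np.any(prior.lower[mask] <= 0):
            raise ValueError("log-scale kernel requires positive prior lower bounds")

    def to_working(p: np.ndarray) -> np.ndarray:
        w = np.array(p, dtype=float, copy=True)
        w[..., mask] = np.log(w[..., mask])
        return w

    def from_working(w: np.ndarray) -> np.ndarray:
        p = np.array(w, dtype=float, copy=True)
        p[..., mask] = np.exp(p[..., mask])
        return p

    wparams = to_working(population.params)
    cov = cfg.kernel_scale * _weighted_cov(wparams, population.weights)
    floor = 1e-12 * max(1.0, float(np.max(np.abs(wparams))) ** 2)
    d = np.diag(cov).copy()
    d[d < floor] = floor
    cov[np.diag_indices_from(cov)] = d
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        warnings.warn("singular perturbation kernel covariance; falling back to diagonal")
        cov = np.diag(np.diag(cov))
        chol = np.linalg.cholesky(cov)

    n = cfg.n_particles
    max_proposals = max(int(np.ceil(n / cfg.acceptance_floor)), n)
    new_params = np.empty((n, population.dim))
    new_d = np.empty(n)
    filled = proposed = failures = 0
    while filled < n:
        if proposed >= max_proposals:
            return None, proposed, failures
        idx = rng.choice(population.n, p=population.weights)
        theta = from_working(wparams[idx] + chol @ rng.standard_normal(population.dim))
        proposed += 1
        if not prior.contains(theta):
            continue
        d = distance_fn(theta)
        if not np.isfinite(d):
            failures += 1
            continue
        if d <= epsilon:
            new_params[filled] = theta
            new_d[filled] = d
            filled += 1
    # importance weights: uniform prior density is constant inside the box,
    # so w_i reduces to 1 / sum_j w_j K(theta_i | theta_j); the kernel
    # density in theta space carries a Jacobian for the log-scale dims,
    # which factors out of the sum over j.
    new_w = to_working(new_params)
    dx = new_w[:, None, :] - wparams[None, :, :]
    dxf = dx.reshape(-1, population.dim)
    logk = _mvn_logpdf(dxf, cov).reshape(n, population.n)
    m = logk.max(axis=1, keepdims=True)
    denom = (population.weights[None, :] * np.exp(logk - m)).sum(axis=1)
    log_jac = new_w[:, mask].sum(axis=1) if mask.any() else 0.0
    logw = -(m[:, 0] + np.log(denom) - log_jac)
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    return (
        Population(
            generation=population.generation + 1,
            params=new_params,
            weights=w,
            distances=new_d,
            epsilon=float(epsilon),
            acceptance_rate=filled / proposed,
        ),
        proposed,
        failures,
    )


def run(
    distance_fn: Callable[[np.ndarray], float],
    prior: PriorBox,
    cfg: SamplerConfig,
    checkpoint_dir: str | Path | None = None,
    resume: bool = False,
    progress: Callable[[Population], None] | None = None,
    param_names: Sequence[str] | None = None,
) -> tuple[Population, SMCDiagnostics]:
    """Full ABC-SMC run: initial rejection generation plus SMC refinements.

    Every generation is drawn from a child RNG keyed by (cfg.seed,
    generation), so two runs with the same seed are identical and a resumed
    run continues exactly where the checkpointed one stopped.  If
    ``checkpoint_dir`` is given every generation is persisted there as
    delimited text + JSON metadata.
    """
    diag = SMCDiagnostics()
    pop: Population | None = None
    if resume and checkpoint_dir is not None:
        pop, diag = _load_checkpoints(Path(checkpoint_dir))
    if pop is None:
        rng = _gen_rng(cfg.seed, 0)
        pop, proposed, failures = sample_initial(
            prior, cfg.n_particles, distance_fn, cfg.epsilon0, rng, cfg.acceptance_floor
        )
        diag.epsilons.append(pop.epsilon)
        diag.acceptance_rates.append(pop.acceptance_rate)
        diag.n_simulations.append(proposed)
        diag.n_failures.append(failures)
        if checkpoint_dir is not None:
            save_population(pop, Path(checkpoint_dir), diag, names=param_names)
        if progress:
            progress(pop)
    eps_min = cfg.epsilon_min if cfg.epsilon_min is not None else 0.0
    while pop.generation < cfg.max_generations:
        if pop.epsilon <= eps_min * (1.0 + 1e-12):
            diag.stopped_reason = f"reached terminal epsilon {eps_min:.6g}"
            break
        rng = _gen_rng(cfg.seed, pop.generation + 1)
        eps_next = min(float(np.quantile(pop.distances, cfg.quantile)), pop.epsilon)
        eps_next = max(eps_next, eps_min)
        new_pop, proposed, failures = step(pop, prior, distance_fn, cfg, rng, epsilon=eps_next)
        if new_pop is None:
            diag.stopped_reason = (
                f"stalled: could not fill generation {pop.generation + 1} within the proposal budget"
            )
            break
        pop = new_pop
        diag.epsilons.append(pop.epsilon)
        diag.acceptance_rates.append(pop.acceptance_rate)
        diag.n_simulations.append(proposed)
        diag.n_failures.append(failures)
        if checkpoint_dir is not None:
            save_population(pop, Path(checkpoint_dir), diag, names=param_names)
        if progress:
            progress(pop)
        if pop.acceptance_rate < cfg.acceptance_floor:
            diag.stopped_reason = (
                f"acceptance rate {pop.acceptance_rate:.3%} below floor {cfg.acceptance_floor:.1%}"
            )
            break
        w = cfg.epsilon_stall_window
        first_finite = next((e for e in diag.epsilons if np.isfinite(e)), np.inf)
        if (
            len(diag.epsilons) > w
            and np.isfinite(diag.epsilons[-w - 1])
            # plateaus early in a run are slow traversal, not convergence;
            # only treat stagnation as the distance floor once epsilon has
            # come well down from its first finite value
            and diag.epsilons[-1] < 0.5 * first_finite
        ):
            rel_drop = (diag.epsilons[-w - 1] - diag.epsilons[-1]) / diag.epsilons[-w - 1]
            if rel_drop < cfg.epsilon_stall_tol:
                diag.stopped_reason = (
                    f"epsilon stagnant ({rel_drop:.2e} relative decrease over {w} generations)"
                )
                break
    else:
        diag.stopped_reason = f"reached max_generations = {cfg.max_generations}"
    diag._final_median = float(np.median(pop.distances))
    return pop, diag


# ---------------------------------------------------------------------------
# Checkpoint persistence (delimited text + JSON metadata)


def save_population(
    pop: Population,
    directory: Path,
    diag: SMCDiagnostics | None = None,
    names: Sequence[str] | None = None,
) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cols = list(names) if names is not None else [f"p{i}" for i in range(pop.dim)]
    df = pd.DataFrame(pop.params, columns=cols)
    df["weight"] = pop.weights
    df["distance"] = pop.distances
    path = directory / f"generation_{pop.generation:03d}.csv"
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "generation": pop.generation,
        "epsilon": pop.epsilon,
        "acceptance_rate": pop.acceptance_rate,
    }
    if diag is not None:
        meta["epsilons"] = diag.epsilons
        meta["acceptance_rates"] = diag.acceptance_rates
        meta["n_simulations"] = diag.n_simulations
        meta["n_failures"] = diag.n_failures
    with open(directory / f"generation_{pop.generation:03d}.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def load_population(path: Path) -> Population:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    pcols = [c for c in df.columns if c not in ("weight", "distance")]
    return Population(
        generation=int(meta["generation"]),
        params=df[pcols].to_numpy(),
        weights=df["weight"].to_numpy(),
        distances=df["distance"].to_numpy(),
        epsilon=float(meta["epsilon"]),
        acceptance_rate=float(meta["acceptance_rate"]),
    )


def _load_checkpoints(directory: Path) -> tuple[Population | None, SMCDiagnostics]:
    diag = SMCDiagnostics()
    files = sorted(directory.glob("generation_*.csv"))
    if not files:
        return None, diag
    pop = load_population(files[-1])
    with open(files[-1].with_suffix(".json")) as fh:
        meta = json.load(fh)
    diag.epsilons = list(meta.get("epsilons", []))
    diag.acceptance_rates = list(meta.get("acceptance_rates", []))
    diag.n_simulations = list(meta.get("n_simulations", []))
    diag.n_failures = list(meta.get("n_failures", []))
    return pop, diag
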
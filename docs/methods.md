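# Methods

## The model

Each ion channel is a Hodgkin–Huxley gating model.  A gate γ ∈ [0, 1] is
the open fraction of one voltage-sensitive structure, relaxing first-order
toward a voltage-dependent equilibrium:

    dγ/dt = (γ∞(V) − γ) / τ(V),
    τ = 1/(α + β),
    γ∞ = α·τ   (activating gate)   or   β·τ   (inactivating gate),

and the channel current is I = g · Π_j γ_j^{k_j} · (V − E) with fixed
maximum conductance g, integer exponents k_j (identical gates in
parallel), and a linear driving force V − E.  GHK-type flux is not
implemented: all calibration statistics are normalized, so current
magnitude (and hence g) carries no information and is never calibrated.

The standardized ("S") gating formulation uses Eyring transition rates
derived from free-energy barrier arguments,

    α(V) = λ₁ exp(+λ₂ V),    β(V) = λ₃ exp(−λ₄ V),

with amplitudes λ₁, λ₃ (ms⁻¹) and voltage sensitivities λ₂, λ₄ (mV⁻¹),
all non-negative.  A second, slower inactivation gate may be *tied* to an
existing one: it shares the sibling's steady state and scales its time
constant by one free parameter a (τ₂ = a·τ₁).  The standardized fast
sodium channel (m³ activation, fast inactivation, tied slow inactivation)
therefore has 4 + 4 + 1 = 9 free gating parameters.  Rate functions of
other published formulations enter as declarative expression strings over
V and named parameters, parsed once (sympy) and evaluated numerically;
the shipped Nygren- and Courtemanche-style fast-sodium layouts are
*structural stand-ins* — synthetic rate forms carrying exactly the
published free-parameter counts (15 and 29) — because reproducing those
models' literal equations is outside this package's scope.  Calcium-
dependent inactivation is representable only as a constant multiplier
(default 1.0), isolating the voltage-dependent kinetics.

Units package-wide: mV, ms, ms⁻¹, mV⁻¹, conductance in S/F.

## Clamp engine

Voltage-clamp protocols are piecewise-constant in voltage, so each gate
has the exact per-segment solution γ(t) = γ∞ + (γ₀ − γ∞)e^{−t/τ}.  The
engine chains these closed forms across segments — there is no
integration error to control — and samples recorded segments on a uniform
grid (default 0.05 ms, configurable per protocol).  Initial state is the
steady state at the first (holding) segment's voltage.  A general-purpose
adaptive Runge–Kutta integration of the gating ODE exists only as an
independent oracle in the test suite; the two agree to |Δγ| < 10⁻⁸ over
multi-segment protocols.

Built-in protocol templates (activation I–V, availability, recovery from
inactivation, deactivation, pulse train) use documented representative
holding potentials and durations.  The voltages/durations of any specific
published experiment are not hard-coded anywhere; every constant is a
template argument.

## Summary statistics

Experiments are declared (`ExperimentDesign`), never inferred: each names
a protocol, a statistic type, the recorded window, and — for exponential
fits — the component (fast/slow) and fitting window convention (from the
in-window peak for decays, from window start for activation relaxations).

- Peak current: signed largest-magnitude sample in the recorded window.
- Steady-state activation: peak current divided by driving force (a
  conductance proxy; raw-peak normalization is available), normalized by
  the maximum absolute value across the sweep.  Sweep points at V = E are
  excluded with a warning.  Availability: normalized peak test-pulse
  current per conditioning voltage.
- Time constants: least squares of y(t) = c + Σ A_i e^{−t/τ_i} (1 or 2
  components).  Initialization is deterministic and derivative-free: the
  integral (regression-on-running-integral) method for one component,
  tail-peeling for two; iterative refinement runs only when the
  initializer leaves residual structure, since the initializer is already
  exact on noiseless single-exponential traces.  Relaxations faster than
  the sampling grid are reported at the resolution bound (τ̂ = sample
  interval) rather than as failures, so kinetics far outside the data's
  scale are penalized smoothly by the distance instead of being discarded
  — this keeps prior exploration well-behaved under very wide priors.
- Recovery fraction: P2/P1 peak ratio per inter-pulse interval.

Normalization uses the maximum absolute value across the sweep, which
makes every normalized curve peak at 1 and makes all summaries invariant
to conductance scaling.

## Distance

Datasets are tables of (x, mean, s.d., n_cells) per experiment.  The
calibration distance is

    d = sqrt( Σ_e (1/n_e) Σ_i [ (ŷ_ei − y_ei) / (σ_ei + ε₀) ]² ),

with ε₀ = 0.05 regularizing points reported without spread, and the 1/n_e
factor preventing experiments with many points from dominating those with
few.  Failed or non-finite simulations map to +∞ (always rejected), never
to exceptions, so the sampler is robust to pathological parameter draws.

## ABC-SMC sampler

Toni-style sequential Monte Carlo ABC.  Generation 0 is rejection
sampling from the uniform prior box at ε₀ (∞ by default).  Each later
generation sets ε to the q-quantile (default q = 0.5 here; the study
recipes use q = 0.3 for a steeper schedule) of the previous accepted
distances, resamples particles by weight, perturbs them, and re-weights
with the standard importance formula w_i ∝ π(θ_i)/Σ_j w_j K(θ_i|θ_j).

Perturbation kernel: multivariate normal with covariance 2× the weighted
empirical covariance of the previous population.  Positive *scale*
parameters — rate amplitudes and tied-τ scales, which span ten orders of
magnitude under the default prior (amplitudes ∈ [10⁻⁷, 10³] ms⁻¹,
sensitivities ∈ [10⁻⁷, 0.4] mV⁻¹, tied scale ∈ [1, 500]) — are perturbed
on log scale (a geometric random walk), with the Jacobian included in the
kernel density.  A linear kernel sized to the population covariance
cannot reach λ ~ 0.01 from a population spread over [0, 1000]; the
log-scale kernel explores all magnitudes and was the difference between
convergence and stalling on these priors.

Stopping.  Three rules, all active:

1. acceptance-rate floor (default 1%, the conventional operational rule:
   once sampling becomes this inefficient the sampler is assumed close to
   the attainable optimum);
2. a generation cap;
3. a *terminal tolerance* ε_min.  With a deterministic simulator, a
   quantile schedule tightened indefinitely collapses the posterior onto
   the least-squares optimum — it fits the realized noise.  The
   discrepancy-principle remedy implemented here stops once ε reaches the
   distance the data-generating model itself would plausibly attain given
   the reported per-point uncertainty.  That null distribution is
   simulated from the dataset alone (draw n cells per point at the
   reported s.d., standardize the resulting sample mean by the resulting
   sample s.d. + ε₀) and ε_min is set to its 99.9th percentile, so the
   generating parameters are essentially never excluded from the final
   population.  The model layer computes this automatically; passing an
   explicit ε_min = 0 disables it and tightens until the sampler stalls,
   which reproduces the behaviour of pure acceptance-rate stopping.
   An ε-stagnation rule (relative decrease < 10⁻³ over 3 generations,
   applied only after ε has at least halved from its first finite value)
   ends runs that have hit the attainable distance floor.

Determinism: every generation draws from a child RNG keyed by (seed,
generation), so identical seeds give bit-identical runs and resuming from
a checkpoint reproduces the uninterrupted run exactly (populations are
stored C-contiguous and serialized at full precision for this reason).

Channels with more than 14 free parameters are intended to be calibrated
gate-by-gate (fixing the remaining gates at reference values), mirroring
how high-dimensional published formulations must be handled; the model
layer supports this by constructing a channel whose other gates carry
fixed rate parameters.

## Posterior analysis

- RSD = σ/|μ| with *weighted population* moments (particles are a
  weighted measure, not i.i.d. draws; an unweighted variant is a flag).
  μ = 0 raises rather than fabricating a value.
- HDPI (default 89% mass): exhaustive narrowest-window search over a
  10,000-draw weight-resampled sample (seeded), matching the brute-force
  definition by construction.
- KDE: weighted Gaussian, Silverman bandwidth.
- RSD-set comparisons: Wilcoxon signed-rank for paired sets (zero
  differences discarded; fewer than 6 remaining pairs yields a "too few"
  flag instead of a normal-approximation p-value) and Mann–Whitney U for
  unpaired sets.
- Posterior predictive: median and HDPI band of the simulated statistic
  over (default) 100 weight-resampled parameter draws; failed draws are
  excluded and counted.

Identifiability diagnostics use the structure of the Eyring gate: its
steady state depends only on λ₁/λ₃ and λ₂+λ₄, so steady-state data can
identify only those combinations, while λ₁λ₃ and λ₂−λ₄ move the time
constant at fixed steady state and require kinetic data.  The RSDs of
these four combinations, compared between calibrations, reproduce the
practical-unidentifiability pattern.  Note RSD inflates when μ ≈ 0 (e.g.
λ₂−λ₄ posteriors centred near zero), a known property of the measure.

## Synthetic data generator

The generator emulates digitized patch-clamp summary figures: simulate a
known ground-truth channel through the same protocol → statistic pipeline
used in calibration, then perturb each summary point with Gaussian noise
across simulated cells (s.d. = rel·|y| + abs; defaults 2% relative, 0.01
absolute floor, 10 cells — a visual spread comparable to published
summary plots while keeping recovery feasible) and report sample mean,
sample s.d. and n.  Noise is applied at summary level, not to raw traces;
capacitive transients, series-resistance artifacts and cell-to-cell
kinetic heterogeneity are deliberately out of scope.  Passing tests
therefore demonstrate correctness of the calibration machinery under the
stated noise model, not robustness to trace-level experimental artifacts.

Two ground-truth channels ship with three experiment batteries each
("steady-state-only", "full", "unified" ⊇ "full"):

- single activating gate (IKr-like: V½ ≈ −30 mV, slope ≈ 7.7 mV, peak
  τ ≈ 11 ms; λ = 0.5, 0.08, 0.0101, 0.05).  Its "full" battery is
  steady-state activation plus activation time constants at 6 voltages;
  "unified" adds deactivation time constants (tail voltages avoid V = E).
- m³h fast-sodium-like channel (activation V½ ≈ −23 mV, τ_m ≈ 0.3 ms;
  inactivation V½ ≈ −70 mV, τ_h ≈ 7–60 ms), whose "full" battery is the
  conventional quartet: activation I–V, availability, inactivation τ,
  recovery.

Experiments are seeded per design name, so scenarios sharing an
experiment produce identical data from the same master seed, and a
ground-truth sidecar (parameters, noise config, seed) makes every dataset
exactly regenerable.

## Study recipes and problem sizes

`recipes.recovery_study` calibrates the single-gate channel to its "full"
battery (N = 200 particles, q = 0.3, ≤ 45 generations, noise-floor
terminal ε) and reports per-parameter median error and 89% HDPI coverage
of the truth; at these sizes a run takes a few minutes on one CPU and
recovers all four parameters with medians within ~15% and truth inside
every marginal interval.  `recipes.identifiability_study` calibrates the
same channel to "steady-state-only" and "unified" batteries with
acceptance-style stopping (ε_min = 0: the RSD pattern is a relative
diagnostic and is sharpest at the tightest attainable tolerance) and
compares the combination RSDs.  The sampler-correctness checks use
N = 1000 on analytically tractable toys.

## Known limitations

- The ABC posterior is tolerance-dependent by construction; the
  noise-floor ε makes its spread commensurate with the reported data
  uncertainty but it is not an exact Bayesian posterior.
- RSD is undefined at μ = 0 and inflates near it.
- The exponential-fit pipeline assumes decays are exponential mixtures;
  strongly non-exponential traces (e.g. slow activation contaminating an
  inactivation decay) bias τ̂, as they would in an experimental analysis.
- Multimodal HDPIs (unions of intervals) are not computed.
- Single-process determinism only; no parallel execution guarantees.
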
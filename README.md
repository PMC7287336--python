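# gatecal

Calibration and identifiability analysis of Hodgkin–Huxley ion-channel
gating models with sequential Monte Carlo approximate Bayesian
computation (ABC-SMC).

## The problem

Cardiac action-potential models contain ion-channel gating equations with
many parameters calibrated against voltage patch-clamp data.  Those data
are low-dimensional summaries (normalized steady-state curves, time
constants, recovery fractions) reported as mean ± s.d. across cells, and
they often cannot pin down every parameter: different parameter
combinations produce indistinguishable summaries.  Point-estimate fitting
hides this; a Bayesian posterior exposes it.  `gatecal` is for modellers
who want to calibrate gating kinetics *with* uncertainty: it simulates
channels under virtual voltage-clamp protocols, reduces the traces to
experimental-style summary statistics, calibrates parameters
likelihood-free with ABC-SMC, and quantifies which parameters (or
parameter combinations) the data actually constrain.

## The model and method

A channel is a product of gates, each with first-order kinetics

    dγ/dt = (γ∞(V) − γ)/τ(V),   τ = 1/(α+β),
    γ∞ = ατ (activating) or βτ (inactivating),
    I = g · Π_j γ_j^{k_j} · (V − E).

The standardized ("S") formulation uses Eyring-form rates
α = λ₁e^{λ₂V}, β = λ₃e^{−λ₄V}; a slow inactivation gate can be tied to a
fast one through a single time-constant scale (τ₂ = aτ₁), so the
standardized fast-sodium channel has 9 free gating parameters.  Rate
equations of other published formulations enter as expression strings.

Calibration compares simulated to measured summaries with the weighted
regularized distance

    d = sqrt( Σ_e (1/n_e) Σ_i [(ŷ_ei − y_ei)/(σ_ei + ε₀)]² ),  ε₀ = 0.05,

inside a Toni-style ABC-SMC sampler (uniform priors, adaptive
multivariate-normal kernel — log-scale for amplitude parameters — and a
quantile ε schedule with a data-driven terminal tolerance).  Posteriors
are summarized by weighted RSD (σ/|μ|), 89% highest-density intervals,
KDEs and posterior-predictive bands; RSD sets from two calibrations are
compared with Wilcoxon signed-rank or Mann–Whitney U tests.

A synthetic-data module generates the same dataset format from known
ground-truth channels (summary-level Gaussian noise across simulated
cells), so the entire pipeline is testable end to end.  See
`docs/methods.md` for the full methods note.

## Worked example

Calibrate a single-gate channel to synthetic steady-state + time-constant
data and inspect the posterior:

```python
from gatecal import ChannelCalibration, SamplerConfig
from gatecal.synthetic import scenario_library

scenario = scenario_library()["single-gate:full"]   # known truth: lam = 0.5, 0.08, 0.0101, 0.05
model = ChannelCalibration.from_scenario(
    scenario, seed=2,
    sampler_config=SamplerConfig(n_particles=200, quantile=0.3, max_generations=45, seed=2),
)
result = model.fit()
print(result.summary())
```

Output (abridged):

```
ABC-SMC calibration of channel 'K.single'
================================================================
particles: 200    generations: 24
final epsilon: 0.584255    final acceptance: 14.76%
converged residual (median distance): 0.47605
stop: reached terminal epsilon 0.584255

parameter      mean        sd      rsd  hdpi89_low  hdpi89_high
   a.lam1   0.50511  0.011326 0.022423     0.48626      0.51928
   a.lam2  0.079645 0.0020394 0.025606    0.076149     0.082444
   a.lam3 0.0097417 0.0010847  0.11135    0.008309     0.011702
   a.lam4  0.050772 0.0022553  0.04442    0.047111     0.054052
```

Every generating value lies inside its 89% HDPI, and the posterior
medians sit within a few percent of the truth — the parameters of this
gate are identifiable from steady-state plus time-constant data.  The
`rsd` column is the relative standard deviation σ/|μ| of each marginal;
values ≪ 1 indicate well-constrained parameters.  Calibrating the same
channel to steady-state data alone leaves the combinations log(λ₁λ₃) and
λ₂−λ₄ essentially at their prior spread (RSD orders of magnitude above
the identified combinations log(λ₁/λ₃) and λ₂+λ₄) — the practical
unidentifiability this package is built to expose:

```python
from gatecal.recipes import identifiability_study
report = identifiability_study(seed=1)
report.min_ratio       # unidentified/identified RSD, steady-state-only run
report.min_reduction   # RSD shrinkage after adding time-constant data
```

There is also a CLI over the same pipeline:

```bash
gatecal generate  --scenario single-gate:full --seed 1 --output data/
gatecal calibrate --config run.yaml --output out/
gatecal analyze   --posterior out/generation_024.csv --output analysis/
gatecal compare   --a out_a/posterior_table.csv --b out_b/posterior_table.csv --paired
```

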
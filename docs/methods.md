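# Methods

This note documents the models, numerical choices and validation design of
`foragefit`, in the spirit of a model-description appendix.

## Absorbed random walks as gambles

A foraging option is a walk on the non-negative integers starting at
`x0 ≥ 1`. On each of `n` days the walker moves `+(g−1)` with probability
`p` (gain `g` minus the sure cost of one point) or `−1` with probability
`1−p`. Zero absorbs: a walk that touches zero stops and its endpoint is
zero. Because down-steps have size one, zero cannot be skipped, so the
absorbed mass equals the probability of ever touching zero within the
horizon (`p_starve`).

`enumerate_walk` expands the full binary tree of step sequences, pruning at
absorption and aggregating probability mass by endpoint. At the design's
scales (`n ≤ 3`, at most 8 paths) this is exact up to float rounding; the
normalisation tolerance of 1e-12 reflects that only rounding error remains.
The test suite cross-checks the enumeration against an independent
full-sequence oracle (all `2^n` sequences with frozen-at-zero walkers), a
10⁶-draw Monte-Carlo walker, and the closed forms available for small
cases (`x0=1, n=1`: `p_starve = 1−p`; `x0=2, n=3`: `p_starve = (1−p)²`).

Summary statistics are the mean, variance and **standardized** skewness
(third central moment over `var^{3/2}`) of the endpoint distribution.
Skewness of a degenerate (zero-variance) distribution is defined as 0;
this convention only matters for hand-built distributions, since generated
options always carry `0 < p_starve < 1`.

**Gamble-set generator.** The default set mirrors the task design: 120
pairs for each combination `(x0, n) ∈ {(1,1), (1,2), (2,2), (2,3)}` (480
pairs), both options of a pair sharing `(x0, n)` because a trial has a
single energy bar and day count. Gains are uniform on `{2..6}`; success
probabilities are uniform on `[0.008, 0.9]` rounded to three decimals;
pairs are resampled until the two options differ and both have
`p_starve ∈ (0, 1)`. The generator reproduces the structural parameter
ranges of the task, not the curated selection of any particular stimulus
list; derived statistics (e.g. EV) therefore span a somewhat wider range
than a hand-tuned list would.

## Choice models

All models share the logistic rule
`P(choose 1) = 1/(1 + exp(−(V1−V2)/β))` with decision noise `β > 0`.

- **Moments family (1–4):** `V = EV (+ ρ·Var) (+ λ·Skw)` with
  unconstrained linear weights.
- **Rank-dependent utility (5–6):** `V = Σ_j π_j · x_j^μ` with power
  utility (`u(0)=0`, `μ>0`) and Prelec probability weighting
  `w(p) = exp(−β_w(−log p)^α)`; `β_w = 1` is the one-parameter variant.
  The two-parameter variant's second parameter is named `β_w` internally to
  avoid collision with the softmax `β`.
- **Homeostatic family (7–9):** the moments combinations plus a linear
  starvation term `ξ·p_starve` with unconstrained `ξ` (the hypothesis of
  interest is `ξ < 0`).
- **Adaptations (10–12):** frame-specific `ξ_foraging/ξ_casino` weights
  selected by a frame indicator; a `p_starve`-only value; day-specific
  weights `ξ_d1..ξ_d3` selected by horizon indicators.

**Ranking convention for decision weights.** Outcomes are ranked
best-first: `π_1 = w(p_best)` and `π_j = w(Σ_{k≤j} p_k) − w(Σ_{k<j} p_k)`
on the descending-ranked cumulative probabilities. This is the standard
rank-dependent weighting for gains; since every option here is a pure-gain
lottery the choice of direction is a convention, fixed and tested (weights
sum to `w(1) = 1`; with `μ = α = β_w = 1` the value reduces exactly to EV
under any ordering). Both task frames use the identical endpoint
distribution, so rank-dependent values are frame-invariant by construction.

## Maximum-likelihood fitting

Per participant and model, the negative log-likelihood of the observed
non-missed choices is minimised by Nelder–Mead. Positivity-constrained
parameters (`β`, `μ`, `α`, `β_w`) are optimised on the log scale; linear
weights are unconstrained. Choice probabilities are clipped to
`[1e-10, 1−1e-10]` before the log so near-deterministic fits stay finite;
the clip value is fixed so results are bit-reproducible.

Seeding policy: all natural-scale parameters start at `+0.5`; if the
optimiser reports non-convergence (iteration/evaluation cap or non-finite
objective), a second attempt starts the unconstrained parameters at `−0.5`
(positivity-constrained parameters cannot be negative and keep `+0.5`) and
the better converged result is kept. Simplex tolerances are 1e-6 on both
parameters and objective with at most `2000·k` evaluations. With these
settings the fitted negative log-likelihood varies by far less than 0.1
nats across perturbed starting points on simulated study-size data.

Information criteria use the half-scale convention
`BIC = −lnL + ½·k·ln n`, `AIC = −lnL + k`, with `n` the participant's
non-missed trial count. On this scale `−BIC` is directly a Laplace-style
approximation to the log model evidence, which is what the group-level
machinery consumes.

## Group-level model selection

- **Fixed effects:** per-participant IC differences against a reference
  model, summed over the group (log-group Bayes factors; smaller = more
  evidence under this sign convention).
- **Random effects:** population model frequencies get a Dirichlet prior
  (`α0 = 1` per model by default). The variational posterior iterates
  participant-wise model assignments
  `u_nk ∝ exp(log evidence_nk + ψ(α_k) − ψ(Σα))` against the count update
  `α = α0 + Σ_n u_n` until the α change is below 1e-6. Exceedance
  probabilities are estimated by drawing from the Dirichlet posterior
  (10⁶ draws by default, seeded, in fixed-size chunks) and counting
  arg-max frequencies; for two models the Beta-CDF closed form is used as
  a cross-check in the tests. Note the variational fixed point is
  degenerate when evidences are exactly identical across all participants
  *and* prior counts differ between models; this never arises with real
  evidences.
- **Family inference:** each family receives total prior mass 1, split
  equally among members, so families of unequal size compete evenly; the
  family exceedance is the posterior probability that the family's summed
  frequency is the largest, from the same sampled draws. The default
  partition is moments {1–4}, rank-dependent {5–6}, homeostatic {7–9}.
- **Sign tests:** exact two-sided binomial tests of the count of positive
  per-participant estimates under P = ½, with zeros dropped.

## Synthetic cohorts and reaction times

`simulate_cohort` mirrors the study shape: 22 agents × 480 pairs × 2
frames, both casino blocks before both foraging blocks, each frame split
into two blocks, and a missed-trial rate of 2/960
(missing-completely-at-random). Choices are Bernoulli draws from the
generating model's softmax probabilities; ground-truth parameters and
seeds are recorded next to every dataset. Reference generating values for
demonstrations are `β = 0.5` with `ξ = −3` (foraging-like) and `ξ = −1.5`
(casino-like) — synthetic choices that qualitatively mirror predominantly
negative, frame-ordered starvation weights, not estimates of any dataset.

Log RTs are generated as
`log RT = γ0 + γ1|ΔEV| + γ2|Δp_starve| + γ3|ΔEV||Δp_starve| + b_i·x + ε`
with per-participant Gaussian random effects and residual noise. Defaults
(`γ = (7.2, −0.05, −0.3, 0.15)` on the log-ms scale, random-effect SDs
`(0.25, 0.02, 0.10, 0.05)`, residual SD 0.35) give a ~1350 ms baseline
with faster responses for easier discriminations.

What the generator does *not* emulate: learning or fatigue across blocks,
sequential dependencies, non-softmax lapses, and RT mechanisms beyond a
log-linear difficulty effect. Passing recovery tests therefore shows the
*pipeline* is consistent (simulation → fitting → selection closes the
loop), not that real data satisfy these assumptions.

## Reaction-time analysis

The mixed model `log(RT) ~ |ΔEV| + |Δp_starve| + interaction` with
by-participant random intercept and slopes is fitted by **maximum
likelihood** (not REML), because fixed-effect structures are compared by
likelihood-ratio tests: each fixed effect's p-value comes from dropping it
while keeping the random structure, on 1 df. Predictors enter uncentred as
absolute differences. If the full random-effects covariance is singular or
the fit fails, the model falls back to a random intercept with a logged
warning. RTs are always log-transformed inside the fitting routine, which
rejects non-positive values, so exp-scale fitting cannot occur silently.
No RT trimming is applied by default.

## Validation design and problem sizes

- Engine: exact closed forms on a probability grid; 10⁶-draw Monte-Carlo
  agreement within 3 standard errors on every support point.
- Reductions: Prelec-I at `α=1` is the identity; RDU at `μ=α=β_w=1`
  returns EV; frame- and day-specific models with equal weights reproduce
  the base homeostatic model — all to 1e-10.
- Parameter recovery: 20 agents per model (ids 1, 5, 7, 10) at fixed
  generating values typical of empirical fits, 960 trials each; medians
  compared to truth within 15%, starvation-weight signs per agent where
  the generating magnitude is ≥ 2. For weakly-informed weights (the
  casino-frame weight at magnitude 1.5, informed by 480 trials, per-agent
  SD ≈ 0.5) the median-of-20 has sampling error comparable to the 15%
  band, so this check is near its statistical resolution limit.
- Model-selection closure: 20 cohorts of 22 agents generated by the base
  homeostatic model; family-level and within-family selection must pick
  the generating family and model in ≥ 90% of cohorts. Null cohorts
  generated by the EV-only model must leave the fitted starvation weight's
  sign test non-significant.
- RT calibration: with null effects the LRT p-values are uniform
  (Kolmogorov–Smirnov check over 60 replicates); injected effects at
  study-like magnitudes are covered by ±2 SE in ≥ 90% of 200 replicates
  and detected by the LRT in ≥ 80%. Calibration cohorts use 6 participants
  × 160 trials with intercept-only random effects matching the generator,
  which keeps the check well-specified at small size.

The acceptance script (`scripts/acceptance.py`) runs the full study-shape
pipeline (22 × 960, models 1–10) from a single seed. Under its moderate
synthetic frame gap (−3 vs −1.5 with between-agent spread) the
frame-specific model's extra parameter is not always justified by
half-BIC — the frame difference is instead reliably detected by the exact
sign test on the frame-specific weights — whereas family-level and
within-family selection identify the homeostatic family and the
EV+p_starve model with exceedance ≈ 1.

## Known limitations

- No hierarchical (empirical-Bayes) fitting across participants; each
  participant is fitted independently, as in the original procedure.
- The walk engine targets short horizons (`n ≤ 10` is enforced nowhere but
  enumeration is exponential in `n`); soft boundaries and multi-resource
  homeostasis are out of scope.
- Rank-dependent models assume pure-gain lotteries; loss outcomes (and
  hence loss aversion) are outside the model space.
- The MAT loader requires a user-supplied field map; deposited files with
  undocumented internal layout cannot be guessed.
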
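# Methods

## Model and estimands

Data are i.i.d. copies of `O = (X, Z, A, Y)` with covariates `X ∈ R^d`
(`d ≥ 0`), a binary instrument `Z`, binary exposure `A`, and an outcome `Y`
that is binary or bounded. Maintained assumptions: consistency, positivity of
the instrument propensity `λ_1(X) = P(Z=1 | X) ∈ [ε, 1−ε]`, unconfoundedness
of `Z` given `X`, and exclusion (no direct `Z → Y` effect). No monotonicity or
homogeneity is assumed, so the ATE is only partially identified.

With cell probabilities `π_{ya.z}(X) = P(Y=y, A=a | X, Z=z)`, eight lower
components `θ_{ℓ,j}` and eight upper components `θ_{u,j}` — signed sums of at
most five cells plus a constant, kept in `bound_core` as a literal text table
parsed once into coefficient arrays — give the sharp conditional bounds
`γ_ℓ = max_j θ_{ℓ,j}` and `γ_u = min_j θ_{u,j}`, and the marginal bounds
`L = E[γ_ℓ(X)]`, `U = E[γ_u(X)]`. The `oracle` module re-derives the same
quantities as optima of a linear program over the 16 response types
`(A(0), A(1), Y(0), Y(1))` (binary-counting order, scipy HiGHS, equality
constraints relaxed by 1e−10); it shares no code with the component tables and
serves as the repository's independent correctness check and exact-truth
engine for discrete designs.

A useful empirical fact from that cross-check: an estimated cell table can be
incompatible with the IV model *without* the bound crossing `γ_ℓ > γ_u`
(other instrumental inequalities can fail first). A crossing always implies LP
infeasibility, but not conversely; crossings are therefore reported as a
diagnostic fraction, never silently repaired.

## Direct estimator (margin condition)

`ψ_{ya.z}(O) = 1(Z=z)/λ_z(X) · {1(Y=y, A=a) − π_{ya.z}(X)}` are inverse-
propensity-weighted cell residuals. Component corrections `L_j`, `U_j` apply
the same signed-sum tables to `ψ` with constants dropped. The estimator plugs
in the estimated arg-extrema `d̂_ℓ, d̂_u` (ties broken to the smallest index)
and averages `φ_ℓ = L_{d̂_ℓ} + θ̂_{ℓ,d̂_ℓ}` and `φ_u = U_{d̂_u} + θ̂_{u,d̂_u}`.
Under a margin condition — the gap between the best and second-best component
has little mass near zero — this is root-n consistent and efficient when the
nuisance error product is `o(n^{−1/2})`. Variances are weighted centred second
moments of `φ`; the ATE interval is the plain Wald construction
`(L̂ − z√(V̂/n), Û + z√(Ŵ/n))` clipped to `[−1, 1]` — it covers the whole
identified set, hence is conservative for the ATE. A refined identified-set
critical value is deliberately not used (the plain construction is the one
whose printed variance form we implement; the second variance expression in
the source display repeats the first and is read as the upper-bound variance).

`margin_report` quantifies the margin's plausibility on the estimated
components: gap quantiles, near-tie fractions at 0.01/0.05/0.1, and
arg-extremum histograms. A 5%-quantile gap above 0.01 is reported as
"margin plausible with exponent 1".

## Smoothed estimator

`g_t(v) = t^{−1} log Σ_j e^{t v_j}` satisfies
`max(v) < g_t(v) ≤ max(v) + log(8)/t` (k = 8); `h_t = g_{−t}` mirrors it for
the minimum. The functionals `E[g_t(θ_ℓ(X))]`, `E[h_t(θ_u(X))]` are smooth,
so no margin condition is needed; their influence functions replace the hard
indicator with softmax/softmin weights. The reported ATE interval widens each
side by `log(8)/t`. Numerics: all log-sum-exp and softmax computations
subtract the row extremum first — at the default `t = 100 n^{1/4}` (≈ 741 at
n = 3,010, ≈ 841 at n = 5,000) unshifted exponentials would overflow. At
large `t` non-extremal terms underflow to zero and the smoothed value equals
the hard extremum exactly in double precision; the strict side of the
sandwich is only representable when margin gaps are ≲ 30/t. Temperature
selection is an open problem; only a sensitivity grid is exposed, never an
automatic choice.

## Nuisance estimation

`λ_1` is a binary regression of `Z` on `X`; the cells are ONE 4-class model of
the joint `(Y, A)` label per instrument arm (two models per fold), which keeps
each predicted slice on the simplex and matches the conditional definition of
`π`. (The factorised alternative — separate binary models — was not chosen;
the joint fit guarantees coherent cells.) Predictions are made out-of-fold
with K-fold cross-fitting (default K = 5), folds stratified on the joint
`(Z, A, Y)` cell to protect rare cells; `λ̂_1` is truncated to `[ε, 1−ε]`
(default ε = 0.01) and a Euclidean simplex projection is a safety net for
uncalibrated learners. A known constant propensity (randomised instrument)
bypasses the instrument model and the truncation. With no covariates the
nuisances reduce to weighted empirical frequencies on the full sample (no
cross-fitting), so the estimator reduces exactly to the unadjusted empirical
bounds.

Learner registry: `logistic` (standardised), `spline` (cubic spline basis +
logistic), `tree` (CART with `min_samples_leaf = 40` and cost-complexity
pruning `ccp_alpha = 1e−3` — unpruned trees leave ~0.08 systematic cell error
from leaf-frequency noise), `forest` (100 trees), `freq` (weighted frequency
table per distinct covariate row, for discrete designs and repetition-heavy
pipelines), and `ensemble` (the four model classes stacked with nonnegative
least-squares weights on internal out-of-fold probabilities). Sampling
weights are passed to every learner that accepts them (a warning is issued
otherwise) and all empirical means are weight-normalised.

## Continuous outcomes

A bounded outcome is affinely rescaled to `[0, 1]`; for each threshold `s`,
`1(Y ≤ s)` is a valid binary outcome bounding the difference of potential-
outcome distribution functions, and integrating over `s` bounds the ATE with
the *negate-and-swap* convention (the transformed problem's upper bound gives
the ATE lower bound). Two estimators:

* `estimate_grid` runs the binary estimator on a uniform `s`-grid and
  integrates per-observation influence functions by the trapezoid rule, so
  the variance respects dependence across thresholds. The endpoint `s = 1`
  (outcome identically one) is evaluated directly — it is itself a valid,
  degenerate binary instance handled by the single-class learner fallback —
  rather than special-cased.
* `estimate_continuous` draws `W_i ~ Uniform(0, 1)` independent of the data
  and runs the binary pipeline once on `1(Y ≤ W)`; this targets the component
  tables applied to the `s`-averaged cells, a looser but much cheaper bound.
  The draw is repeated `m` times (default 20) and averaged; the variance of
  the average combines the mean within-repetition influence-function variance
  with the raw between-repetition variance of the estimates (not divided by
  `m` — a deliberately conservative aggregation, since the exact combination
  is not settled). Cell nuisances are refit per repetition (the target
  changes with `W`); the instrument fit and fold map are `W`-free and reused.

Bounds are reported on both the `[0, 1]` and the original outcome scale
(affine equivariance).

## Synthetic designs and what a green test establishes

`generate_motivating` transcribes the motivating randomised design literally,
including the half-open defier interval `(−0.5, 0.5]` and the `≥ / ≤`
boundaries at `±0.99` (probability-zero boundary events). Its exact truth —
ATE 0.09225, adjusted bounds (0.0835, 0.0935), unadjusted (−0.074, 0.236) —
comes from enumeration over the four compliance-class strata (masses 0.005,
0.005, 0.15, 0.84) and is LP-cross-checked. Note the always/never-taker
strata (total mass 0.01) have six-way ties among the lower components, a
probability-0.01 margin-condition violation; ties are surfaced by the margin
diagnostics and the estimators proceed (tied components are equal, so the
extremum values are unaffected).

`DGPSpec` builds discrete-stratum designs: stratum masses, per-stratum
instrument propensity, compliance-class mixtures, and class-specific outcome
means (Bernoulli, or Beta with a concentration parameter for continuous
outcomes). Truth comes from exact response-type enumeration (binary) or
high-resolution trapezoid integration of the exact threshold cells
(continuous, default 1,001 points). The continuous design frozen in the test
suite was chosen once so that the grid-integrated truth interval is *strictly*
inside the uniform-augmentation interval (gap ≈ 0.02 per side) and the true
ATE (≈ 0.235) is well interior — otherwise the containment and coverage
checks would be vacuous. `perturbed_oracle_nuisances` injects a systematic
cell error of size `scale · n^{−rate}` to emulate slow nuisance convergence.

These generators are piecewise-constant in the covariates with compliance
driven entirely by observables or simple latent classes; real data have
continuous heterogeneous nuisance surfaces, informative missingness, and
instrument confounding. Green tests therefore establish correctness of the
estimating machinery and its stated asymptotics on designs with computable
truth — not performance guarantees on any particular applied dataset.

## Numerical conventions

* Simplex validation tolerance 1e−9; projections exact to float precision.
* Arg-extremum ties broken to the smallest index (tied values are equal, so
  bound values are unaffected).
* `γ_ℓ > γ_u` flagged when the crossing exceeds 1e−9 (exact-tie strata differ
  only by float noise); crossed estimates are reported unmodified with a
  warning, and a crossing of the aggregated bounds `L̂ > Û` likewise.
* LP equality constraints relaxed to ±1e−10; infeasibility (status 2) is
  distinguished from solver failure and raised as IV incompatibility.
* All randomness (fold assignment, learners, W draws, generators) flows from
  explicit integer seeds; repeated runs with the same configuration are
  bit-identical apart from timings.

## Known limitations

* Binary instrument and exposure only; multi-valued or continuous `Z`/`A`
  have no closed-form sharp bounds of this shape.
* Continuous-outcome bounds are valid but not sharp; sharpness there is open.
* The margin exponent is diagnosed, not estimated; no higher-order influence
  corrections.
* The identified-set interval is conservative for the ATE by construction;
  no refined critical values.
* The stacked ensemble uses squared-error stacking on probabilities, a
  lightweight stand-in for full cross-validated loss-specific stacking.
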
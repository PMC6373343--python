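# Methods

## Model and offline estimation

The package fits the linear multilevel model

```
y_ij = x_ij' β + z_ij' b_j + ε_ij,    b_j ~ MVN(0, Φ),    ε_ij ~ N(0, σ²)
```

by maximum likelihood via EM, treating the random effects b_j as missing
data.  Intercepts are explicit constant-1 columns of x (and z); nothing
is added implicitly, so the stream format is unambiguous.

The E-step computes, per individual, C_j = Z_j'Z_j + σ²Φ⁻¹ and
b̂_j = C_j⁻¹(Z_j'y_j − Z_j'X_jβ), and accumulates the complete-data
sufficient statistics

- t₁ = Σ_j X_j'Z_j b̂_j  (feeds β),
- T₂ = Σ_j b̂_j b̂_j' + σ² Σ_j C_j⁻¹  (feeds Φ),
- t₃ = Σ_j u_j'u_j + σ² Σ_j tr(C_j⁻¹ Z_j'Z_j), u_j the residual (feeds σ²).

The M-step is closed form: β = (ΣX_j'X_j)⁻¹(ΣX_j'y_j − t₁), Φ = T₂/J,
σ² = t₃/n.  Convergence is declared on the parameters — largest absolute
change over β, the lower triangle of Φ and σ² below `tol` (default 1e-4,
cap 800 iterations) — not on the likelihood.  Internally the E-step runs
on per-individual cross-products (Z'Z, X'Z, Z'y, Σy²), which is
algebraically identical to the raw-row sums and makes an iteration O(J)
instead of O(n); the identity is enforced by tests.

The conditional expectation of the residual sum of squares contributes
σ²·tr(C_j⁻¹ Z_j'Z_j) per individual.  We use this form in *both* the
batch and the streaming t₃ (a per-individual σ²·tr(C_j⁻¹) variant circulates
but breaks the exact equality between the two routes and is not the
conditional-expectation identity E[ε'ε | y]).

Two log-likelihood surfaces exist and are deliberately not comparable:
`complete_data_loglik` omits the additive (n/2)ln 2π and (Jr/2)ln 2π
constants, while `marginal_loglik` (the observed-data likelihood with
V_j = Z_jΦZ_j' + σ²I, used for monotonicity checks) includes them.

## Streaming estimation (SEMA)

Per arriving point the algorithm (i) ingests: rank-one updates of the
arriving individual's stored cross-products and of the global X'X, x'y,
with (X'X)⁻¹ maintained by the Sherman–Morrison identity; (ii) runs the
E-step for that individual only, swapping its contributions into the
running CDSS totals (total ← total − old + new); (iii) runs the M-step.
Because other individuals' contributions are not recomputed, the totals
are an approximation to the batch CDSS at the current parameters; the
approximation improves as individuals keep returning.  The optional
periodic *sweep* ("SEMA Update", default cadence every 1,000 points)
re-runs the per-individual E-step for all stored individuals — one batch
EM iteration executed purely on aggregates — and counteracts staleness
when individuals drop out.

Predictions are prequential: ŷ = x'β + z'b̂_j is emitted before the point
updates anything, with b̂_j = 0 for never-seen individuals.

Warm start: batch EM on a training prefix (default 2,000 points, tol
1e-4, cap 800), after which every individual's contribution is computed
at the fitted parameters and X'X is inverted once directly.  Without an
explicit training size, points are buffered until X'X reaches full rank
and at least max(5p, 100) rows arrived.  New individuals increment J at
first sight and enter T₂ after their first E-step.

### Numerical choices

- Before inversion, Φ's eigenvalues are floored at 1e-8·tr(Φ)/r
  (early-stream Φ can be near-singular; the floor is invisible for a
  well-conditioned Φ).  A singular C_j triggers one harder
  regularization retry, then the individual is skipped with a warning.
- The maintained (X'X)⁻¹ is re-inverted directly every 1e5 rank-one
  updates (configurable), and immediately whenever the Sherman–Morrison
  denominator falls below 1e-12, to cap drift.
- T₂ and Φ are symmetrized after each update; σ² is floored at 1e-10 in
  the streaming M-step.
- Non-finite records are rejected with a warning and the stream
  continues; a t₃ total below −1e-6 raises (it signals corrupted
  bookkeeping, not noise).
- Checkpoints are versioned JSON; floats round-trip exactly via
  shortest-repr serialization.

## Comparators

*Batched incremental EM* keeps per-individual cross-products for all
data seen, refits every 1,000 points (20 warm-started iterations) and
runs to convergence at stream end.  *Sliding-window EM* keeps the m most
recent points (default 10,000) in a strict per-point FIFO and refits
every 1,000 points; between refits, returning individuals get b̂
recomputed from their current window rows at the last-refit parameters,
individuals absent from the window fall back to x'β.  Eviction is per
data point, not per individual.

## Synthetic streams

The generator emulates a longitudinal monitoring study: J = 1000
individuals; 15 fixed effects (true values 100.0, 0.1, 0.5, …, 5.3):
intercept, five level-1 continuous covariates, a four-category level-1
factor, three level-2 continuous covariates, a two- and a three-category
level-2 factor; residual variance 5.  Condition A has a single random
intercept (variance 50); conditions B–D add random slopes on the first
four level-1 covariates (variances 0.2, 0.6, 1.8, 5.0) with exchangeable
correlation 0, .15, .5.  Streams draw an individual uniformly at each of
50,000 steps, so n_j ≈ 50 in expectation.

Where the study design leaves details open we chose once: level-1
continuous covariates are i.i.d. standard normal per observation;
level-2 continuous covariates standard MVN with identity correlation;
categorical factors equiprobable with reference-level dummy coding;
level-1 categories resampled per observation; the correlation in C/D
applied uniformly to every random-effect pair (the minimal exchangeable
reading).  The generator is stationary, Gaussian, balanced in
expectation, and has no missingness, attrition, drift (beyond an
explicit two-regime test stream) or measurement artifacts — passing
tests therefore demonstrate correctness of the estimators under the
model's own assumptions, not robustness to real-data violations.

## Study reproduction sizes

The reference study uses 1000 replications per condition; this package's
test suite replays the identical per-replication protocol at S = 40
condition-A replications (plus condition-D runs), and
`scripts/acceptance.py` at S = 20 — sizes chosen so a full run completes
in minutes on one CPU.  Monte-Carlo bands scale accordingly: the
across-run standard error of the intercept is ≈0.48/√S.  The Monte-Carlo
SE convention follows the study: centered on the true value,
√(Σ(θ̂_s−θ)²/(S−1))/√S.  Empirical confidence intervals use
linearly-interpolated quantiles.

## Known limitations

- β's intercept and the level-2 (between-individual) coefficients share
  the likelihood's flattest direction with the random-intercept mean
  when Φ is large relative to σ²/n_j.  EM moves along that direction
  with rate ≈ 1 − σ²/(σ² + n_j·φ) per iteration (thousands of iterations
  for the study's φ = 50, σ² = 5, n_j ≈ 50), and single-stream SEMA and
  batch EM land at points that differ by O(0.1) in those coefficients on
  a given replication even though both are unbiased across replications
  and agree closely in their Monte-Carlo means, in all variance
  components, and in prediction error.  Level-1 slopes agree to ~1e-3.
- ML variance components are slightly biased downward (no REML
  correction is implemented).
- Assumes stationarity; under drift use the sliding-window comparator.
- Gaussian responses and nested (non-crossed) random effects only; the
  covariate set is fixed at stream open — effects that only become
  identifiable later (e.g. calendar effects) cannot be added mid-stream.
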
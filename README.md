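# semastream

Streaming estimation of **linear multilevel models** (linear mixed models)
on data streams.

When individuals are monitored continuously — patients weighing themselves
on connected scales, students answering items, customers returning to a
site — observations arrive one at a time and are nested within
individuals.  The standard model is

```
y_ij = x_ij' β + z_ij' b_j + ε_ij,      b_j ~ MVN(0, Φ),   ε_ij ~ N(0, σ²)
```

with fixed effects β (length p), individual-specific random effects b_j
(length r, covariance Φ), and residual variance σ².  Maximum-likelihood
estimation normally runs iterative EM over the full data set, which is
infeasible to redo at every arriving point.

`semastream` implements **SEMA** (streaming EM approximation): each
incoming data point triggers rank-one updates of stored cross-products, a
single E-step *for the arriving individual only* (its posterior b̂_j and
its contributions to the complete-data sufficient statistics t₁, T₂, t₃
are recomputed and swapped into running totals), and a closed-form M-step
with (X'X)⁻¹ maintained by the Sherman–Morrison formula.  Cost per point
is O(1) in the stream length n; memory grows with the number of
individuals J only.  Alongside SEMA the package provides:

- **batch EM** (`EMRegressor`, `fit_em`) — the offline reference
  estimator, also used for warm starts;
- **SEMA Update** — SEMA plus periodic "sweeps" that refresh every
  individual's contributions without revisiting raw data;
- **sliding-window EM** (`SlidingWindowEMRegressor`) — batch refits over
  the m most recent points, for drifting streams;
- a **stream simulator** for the four study conditions (A: random
  intercept, variance 50; B–D: five correlated variance components) and a
  **prequential evaluation** harness (predict each point before it
  updates any state; MAE/RMSE and moving-window error series).

## Worked example

```python
import semastream as ss

cond = ss.condition_preset("A")          # random-intercept study condition
pop = ss.make_population(cond, seed=11)
stream = ss.stream_arrays(pop, cond, 10_000, seed=12)

log, trajectory = ss.prequential_run(
    "sema", stream, train_n=2000, start=cond.true_params()
)
final = trajectory[-1]
print(f"intercept estimate : {final['beta'][0]:.3f}   (truth 100.0)")
print(f"random-intercept var: {final['phi'][0, 0]:.3f}  (truth 50.0)")
print(f"residual variance  : {final['sigma2']:.3f}   (truth 5.0)")
print(f"prequential MAE    : {ss.mae(log):.3f}")
```

prints

```
intercept estimate : 99.065   (truth 100.0)
random-intercept var: 49.881  (truth 50.0)
residual variance  : 5.110   (truth 5.0)
prequential MAE    : 2.085
```

The first 2,000 points warm-start a batch EM fit; the remaining 8,000 are
processed one at a time, each predicted before it updates the model.  The
MAE reflects the irreducible noise (σ² = 5 gives E|ε| ≈ 1.8) plus
estimation error of the per-individual intercepts.

The same estimators are available with a scikit-learn surface
(`SEMARegressor(...).partial_fit(X, y, Z=Z, groups=ids)`), and a CLI:

```
semastream simulate --condition A --seed 1 --out stream.jsonl
semastream fit stream.jsonl --method sema --out fit.json
semastream benchmark --conditions A --methods sema,em_batched --reps 2 \
    --seed 1 --out results.csv
```

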
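# lifeclust

Survival clustering of registry-style patient cohorts: a neural
lifetime-clustering model that partitions patients into K groups with
maximally distinct one-year outcome distributions, compared against
k-prototypes, Cox-screened semi-supervised clustering (SSC-Bair), and
the SPI-II clinical risk score.

The package is aimed at biostatisticians and clinical-ML researchers
studying risk stratification from right-censored time-to-event data —
for example, one-year composite vascular outcomes (recurrent stroke,
myocardial infarction, death) after an index ischemic stroke.

## The model

Each patient's covariates `x_i` pass through a feed-forward network
whose softmax output `q_i ∈ Δ^{K−1}` assigns soft cluster memberships.
Cluster k's survival curve is the Kaplan–Meier product-limit estimate
weighted by the memberships,

    Ŝ_k(t) = Π_{t_j ≤ t} (1 − d_j/n_j),
    d_j = Σ_i q_ik 1[T_i = t_j, δ_i = 1],   n_j = Σ_i q_ik 1[T_i ≥ t_j],

and the network weights W are trained to maximize the *minimum*
pairwise divergence between cluster curves,

    W* = argmax_W  min_{i≠j} Δ(Ŝ_i, Ŝ_j),

with a hinge penalty that keeps every cluster above a minimum mass
fraction. Δ is either an upper bound on the two-sample Kuiper p-value
(`−log p`, with `λ = (√n_e + 0.155 + 0.24/√n_e)·V` and
`p = 2(4λ²−1)e^{−2λ²}` clamped to `[10⁻³⁰, 1]`) or the squared maximum
mean discrepancy with a Gaussian kernel over follow-up times. Training
runs on the package's own reverse-mode autodiff engine; the best
checkpoint across a hyperparameter grid is selected by validation
K-sample log-rank. Clusterings are scored by Harrell's C-index, the
K-sample log-rank chi-square, and the IPCW Brier score at one year.

Because the registry data the problem comes from are not public, the
package ships a synthetic-cohort generator
(`lifeclust.default_stroke_spec`) that plants three latent risk groups
(prevalences 0.10/0.45/0.45, one-year event probabilities
0.45/0.13/0.06, overall rate ≈ 13%) beneath ~30 mixed-type covariates
whose marginals match a large ischemic-stroke registry. See
`docs/methods.md` for the model, the generator, and their limitations.

## Worked example

Simulate a cohort, split it 60:20:20 stratified on the outcome, fit the
Kuiper-bound lifetime-clustering model, and score the held-out test
split:

```python
import numpy as np
from lifeclust import (default_stroke_spec, simulate_cohort,
                       stratified_split, impute, fit_transform,
                       apply_transform, dlc_fit, HyperparameterGrid,
                       km_estimate, logrank_statistic)

cohort = simulate_cohort(default_stroke_spec(n=3000, seed=0))
print(f"cohort: n={len(cohort)}, one-year event rate "
      f"{cohort.event_rate():.3f}")

split = stratified_split(cohort, seed=0)
train = impute(split.train)
medians = {s.name: float(train.df[s.name].median())
           for s in cohort.schema if s.kind == "continuous"}
val = impute(split.validation, medians=medians)
test = impute(split.test, medians=medians)
fm = fit_transform(train)
fmv, fmt = apply_transform(fm.state, val), apply_transform(fm.state, test)

grid = HyperparameterGrid(n_layers=(0,), hidden_width=(16,),
                          learning_rate=(1e-2,), activation=("tanh",),
                          epochs=300, n_restarts=8)
model = dlc_fit(fm.values, train.times, train.events,
                fmv.values, val.times, val.events, grid=grid, seed=0)

labels = model.predict(fmt.values).hard_labels
for k in range(3):
    mask = labels == k
    rate = 1 - float(km_estimate(test.times[mask],
                                 test.events[mask]).survival_at(365))
    print(f"cluster {k}: n={mask.sum():3d}  one-year event rate {rate:.3f}")
print(f"test log-rank chi2 = "
      f"{logrank_statistic(test.times, test.events, labels):.1f}")
```

Output:

```
cohort: n=3000, one-year event rate 0.129
cluster 0: n= 24  one-year event rate 0.500
cluster 1: n=141  one-year event rate 0.184
cluster 2: n=434  one-year event rate 0.090
test log-rank chi2 = 49.4
```

Cluster labels are risk-ordered (0 = highest risk), so the model has
isolated a small very-high-risk stratum (50% one-year event rate on
held-out patients), a medium group (18%), and a large low-risk group
(9%); the log-rank chi-square of 49.4 quantifies the separation of the
three test-split survival curves. For a full repeated comparison
against SPI-II, k-prototypes, and SSC-Bair — means and SDs over
repetitions, ANOVA across methods, outcome tables, KM exports — use
`lifeclust.run_comparison` or the CLI:

```
lifeclust simulate --n 3000 --seed 0 --out cohort.csv
lifeclust compare --config experiment.yaml --out-dir results/
```

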
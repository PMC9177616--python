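# Methods

## Problem setting

`lifeclust` compares ways of partitioning an ischemic-stroke-like cohort
into K risk groups with maximally distinct one-year outcome
distributions. A cohort is one row per patient: follow-up time in days,
a binary composite-event indicator (recurrent stroke, myocardial
infarction, or death within one year), and ~30 mixed-type covariates.
Follow-up is administratively censored at 365 days. Four methods are
compared: the SPI-II clinical score (a fixed 0–15 point instrument cut
into low/medium/high tiers), k-prototypes (variance-weighted clustering
of the covariates), SSC-Bair (univariate Cox screening at p < 0.1
followed by k-means), and a neural lifetime-clustering model trained to
separate the clusters' survival curves directly.

## The lifetime-clustering model

A feed-forward network maps the preprocessed covariates of patient *i*
to softmax memberships `q_i ∈ Δ^{K-1}`. For cluster *k* the soft
Kaplan–Meier curve uses `q_{·k}` as case weights:

    d_j = Σ_i q_ik 1[T_i = t_j, δ_i = 1]
    n_j = Σ_i q_ik 1[T_i ≥ t_j]
    Ŝ_k(t) = Π_{t_j ≤ t} (1 − d_j / n_j)

Training maximizes the minimum pairwise divergence Δ(Ŝ_i, Ŝ_j) over
cluster pairs, with a quadratic hinge penalty on cluster mass fractions
below `m_min`:

    loss = − min_{i<j} Δ(Ŝ_i, Ŝ_j) + ρ Σ_k max(0, m_min − w_k/n)²

where `w_k = Σ_i q_ik`. No terminating-signal model is estimated: event
indicators are observed, so the assignment network is the only learned
component.

Two divergences are implemented.

**Kuiper p-value upper bound.** The Kuiper two-sample statistic
`V = sup_t (Ŝ_i − Ŝ_j) + sup_t (Ŝ_j − Ŝ_i)` is evaluated exactly over
the union of step points. With effective sizes equal to the soft cluster
masses, `n_e = w_i w_j / (w_i + w_j)` and
`λ = (√n_e + 0.155 + 0.24/√n_e)·V`, the tail bound is the leading term
of the Kuiper series, `p = 2(4λ² − 1)e^{−2λ²}`, clamped to
`[1e−30, 1]`. The public `kuiper_pvalue_ub` returns 1 for λ ≤ 1/2,
where the term is negative and carries no evidence. Inside the loss the
term's non-monotone rise up to its peak at λ = √3/2 would push
barely-separated clusters back together, so the trainable divergence
uses the decreasing branch only, shifted so identical curves give
exactly zero, and is max-combined with a capped quadratic ramp
`min(0.2λ², 1)` that supplies gradient below the peak:

    Δ_kuiper(λ) = max( min(0.2λ², 1),  log p_peak − log p(max(λ, √3/2)) )

This is monotone in V, symmetric, non-negative, zero for identical
curves, and equal to `−log p + const` wherever the bound is informative.

**MMD.** The biased (V-statistic) squared maximum mean discrepancy with
a Gaussian kernel over all observed follow-up times, weights normalized
to sum one; bandwidth from the median pairwise-distance heuristic,
computed once per fit. Censored rows are included (their observation
times carry distributional information under administrative censoring;
an events-only variant was considered and rejected as discarding 87% of
rows).

**Optimization.** All gradients come from a small reverse-mode autodiff
engine written on numpy (`lifeclust.autodiff`); reductions (min over
pairs, sup over step points, hinges, clamps) use the argmax
subgradient, so the piecewise-smooth objective differentiates correctly
almost everywhere. Training is full-batch Adam (mini-batches ≥ 512
behind a flag). For every hyperparameter grid point — and
`n_restarts` seeded re-initializations of each — the validation
selection metric (K-sample log-rank of the hard validation labels by
default) is evaluated every 10 epochs, and the single best checkpoint
across all configurations is kept. Checkpoints whose smallest soft
cluster mass falls below `m_min·n/2` are discarded as collapsed.

Defaults: `K = 3`, `m_min = 0.05`, `ρ = 2·10⁴` (the hinge must compete
with divergences measured in tens of log-units; with weak ρ the
optimum shaves clusters below any sensible size), Xavier
initialization, learning rates {1e−3, 1e−2}, widths {16, 32}, depths
{0, 1, 2}, 300 epochs. Depth 0 (a linear softmax) is deliberately in
the default grid: it has the least capacity to memorize
Kaplan–Meier noise and is, on cohorts of this size and event rate, the
most reliably selected architecture.

**Risk ordering.** After fitting, raw cluster indices are ranked by
their one-year KM cumulative event probability on the training split
(ties broken by cluster size), so label 0 is always the highest-risk
group and labels are comparable across fits and methods.

## Known behaviour and limitations of the objective

The max–min-divergence objective, evaluated on a finite training
sample, systematically prefers two kinds of solution over the
generative partition of a planted-group cohort:

1. *Mass shaving.* Because the Kuiper bound's λ grows with √(effective
   size)·V, carving an extreme-risk core out of the highest-risk group
   down to the mass floor raises the weakest pairwise divergence even
   in population. A numerical search over all group-to-cluster mixing
   matrices on the default cohort shows the population optimum shaves
   the 10% high-risk group to the 5% floor.
2. *KM-noise memorization.* The sup-statistic V is selection-inflated:
   with a few hundred events and ~60 feature dimensions the network
   can always find covariate rules correlated with the realized event
   times, and such partitions beat structure-aligned ones on the
   empirical objective by a wide margin. The result is a large
   train-to-test separation gap — the same signature the original
   registry experiment shows (training log-rank several times the test
   log-rank). Capacity control, input-noise regularization, softmax
   temperature annealing, and soft-min variants reduce but do not
   remove this; checkpoint selection on validation separation is the
   effective mitigation and is built into the fit.

Consequently the fitted clusters should be read as *risk strata that
generalize*, not as estimates of any latent mixture component; adjusted
Rand agreement with planted groups is bounded well below 1 even at the
information-theoretic optimum of the default cohort.

## Comparators

* **SPI-II** — 3·CHF + 3·diabetes + 3·prior stroke + 2·(age > 70,
  strict) + 2·(index stroke) + 1·severe hypertension (SBP > 180 mmHg
  here) + 1·coronary disease; tiers low 0–3, medium 4–7, high ≥ 8 (the
  only tier reading consistent with the medium band).
* **k-prototypes** — Lloyd iterations on squared Euclidean distance for
  the min-max-scaled continuous block plus γ-weighted mismatch counts
  for binaries/categoricals; γ defaults to half the mean standard
  deviation of the continuous columns; empty clusters re-seed at the
  worst-fitting row.
* **SSC-Bair** — single-covariate Cox fits (Newton–Raphson on the
  partial likelihood, Breslow tie handling, |β| capped at 20 under
  monotone likelihood) screen features at Wald p < 0.1; k-means
  (k-means++, 10 restarts) clusters the selected columns; fall back to
  all columns with a warning if nothing passes.

## Evaluation

Metrics are computed per split (train/validation/test from a 60:20:20
outcome-stratified split with largest-remainder rounding inside each
event stratum):

* **Harrell's C** over pairs comparable iff `T_i < T_j` and δ_i = 1;
  tied risks count ½. The per-patient risk score for any clustering is
  its cluster's training-split one-year KM event probability.
* **K-sample log-rank chi-square** (the "log-rank score"; the statistic
  itself, not a p-value), via lifelines.
* **IPCW Brier score** at the horizon, weights from the censoring
  KM estimate Ĝ with `1/Ĝ(T⁻)` for events by the horizon and `1/Ĝ(τ)`
  for survivors. Because administrative censoring puts all remaining
  mass exactly at day 365, the pipeline evaluates at τ = 364.5 — just
  inside the boundary — so administratively censored patients count as
  survivors rather than being discarded.

The comparison pipeline repeats split→fit→evaluate with seed base+r
(re-split *and* re-initialize per repetition; a fixed-split mode exists
behind a flag), reports mean/SD per (method, split, metric), one-way
ANOVA across methods, per-method outcome tables (counts and
percentages per cluster with chi-square p-values, plus a KM
cumulative-incidence column) and per-cluster KM curve exports.

## Synthetic cohorts

The generator plants a latent risk group per patient (prevalences
0.10/0.45/0.45), draws exponential event times whose one-year event
probabilities are 0.45/0.13/0.06 (overall ≈ 13%, closed form), applies
optional independent exponential censoring (default rate 0) and
administrative censoring at 365 days, and records follow-up in whole
days (producing realistic ties).

Covariate marginals reproduce a large single-center ischemic-stroke
registry: age 68.6 ± 12.4, 57.9% male, NIHSS median ≈ 3–4, 58%
hypertension, 27% diabetes, 24.7% atrial fibrillation, TOAST and
large-artery-disease category frequencies, laboratory means/SDs.
Group-conditional effects follow the registry's documented geometry:
NIHSS is the dominant prognostic covariate (strongly group-shifted on
the log scale) but becomes variance-minor after min-max scaling over
0–42; age, laboratories, histories, and medications carry realistic
moderate gradients; and a sex-linked block (smoking almost entirely
male, hemoglobin +1.6 g/dL in men, creatinine/BMI/WBC shifted) supplies
a dominant covariate-structure direction unrelated to risk. This is the
regime in which variance-weighted clustering finds little risk
separation while learned-weight methods can — the phenomenon the
package exists to study. `effect_scale` multiplies every association
around its fixed marginal; at 2.0 a Bayes-rule classifier on the
generating model recovers the groups with accuracy ≈ 0.99 (the
recoverability sanity bound), at the default 1.0 accuracy is ≈ 0.87.

What the generator does **not** emulate: within-group covariate
correlation beyond the sex block, non-proportional or time-varying
hazards, informative censoring, TOAST-specific outcome structure, and
measurement error. Passing tests on these cohorts therefore demonstrate
correctness of the estimators and the qualitative method ordering under
a known truth, not clinical performance on registry data.

## Numerical choices

* Kuiper suprema: evaluated at every step point of both curves and at
  their left limits; step functions attain their extrema there, so this
  is exact (verified against a dense-grid oracle).
* Kuiper p-bound clamp ε = 1e−30; divergence cap ≈ 69 log-units.
* Weighted KM: at-risk sums via suffix sums over time-sorted weights;
  zero-weight guards at 1e−12; hazards clipped below 1 − 1e−9 inside
  the loss graph.
* Cox Newton steps clipped to ±5 on the standardized scale, convergence
  at |step| < 1e−10, 60 iterations max.
* k-means/k-prototypes ties: lowest index wins (numpy argmin).
* Degenerate inputs: curves with no events are flagged degenerate with
  Ŝ ≡ 1; event-free clusters contribute zero divergence rather than
  raising; metrics that are undefined on a repetition are recorded as
  null with a reason, not fabricated.
* All randomness flows from integer seeds through
  `numpy.random.default_rng`; fits, splits, simulations, and the
  comparison pipeline are bit-reproducible given (data, seed).

Problem sizes used by the test suite — cohorts of 600–3,000 patients,
5 seeded repetitions, grids restricted to the linear architecture with
8 restarts for the headline comparisons — are scaled-down study
conditions chosen so the full suite completes in minutes while keeping
every qualitative conclusion testable.
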
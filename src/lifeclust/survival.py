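"""Kaplan-Meier estimation (hard and soft-weighted), curve divergences,
and the evaluation metrics used to score risk groupings.

The soft-weighted product-limit estimator is the central primitive: the
neural clustering model builds one survival curve per cluster from its
softmax membership weights, and separation between those curves is what
training maximizes.  Two divergences are provided — an upper bound on
the Kuiper two-sample p-value and the (biased) Gaussian-kernel maximum
mean discrepancy — plus the three scoring metrics (Harrell's C, the
K-sample log-rank chi-square, and the IPCW Brier score at a horizon).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "SurvivalCurve",
    "DivergenceSpec",
    "km_estimate",
    "kuiper_statistic",
    "kuiper_pvalue_ub",
    "mmd_divergence",
    "logrank_statistic",
    "concordance_index",
    "brier_score",
    "chisq_test",
    "anova_f",
    "KUIPER_P_FLOOR",
]

#: lower clamp of the Kuiper p-value bound; -log of it caps the divergence
KUIPER_P_FLOOR = 1e-30


@dataclass(frozen=True)
class SurvivalCurve:
    """A right-continuous step estimate of S(t) = P(T > t).

    ``event_times`` holds the distinct times carrying positive (weighted)
    event mass; between steps the curve is constant and S(t) = 1 before
    the first event time.  ``total_weight`` is the effective sample size
    (sum of the row weights the curve was built from).
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    total_weight: float
    degenerate: bool = field(default=False)

    def __post_init__(self):
        s = np.asarray(self.survival)
        if s.size and (np.any(np.diff(s) > 1e-12) or s[0] > 1 + 1e-12):
            raise ValueError("survival curve must be non-increasing and <= 1")

    def survival_at(self, t) -> np.ndarray:
        """S(t) (right-continuous step lookup); vectorized over t."""
        idx = np.searchsorted(self.event_times, np.asarray(t, float),
                              side="right")
        padded = np.concatenate([[1.0], self.survival])
        return padded[idx]

    def survival_before(self, t) -> np.ndarray:
        """Left limit S(t-)."""
        idx = np.searchsorted(self.event_times, np.asarray(t, float),
                              side="left")
        padded = np.concatenate([[1.0], self.survival])
        return padded[idx]

    def to_tsv(self, path) -> None:
        """Export (time, survival, at_risk, deaths) for KM plotting."""
        arr = np.column_stack([self.event_times, self.survival,
                               self.at_risk, self.deaths])
        header = "time\tsurvival\tat_risk\tdeaths"
        np.savetxt(path, arr, delimiter="\t", header=header, comments="")


@dataclass(frozen=True)
class DivergenceSpec:
    """Which curve divergence the clustering objective uses."""

    kind: str = "kuiper_ub"  # {"kuiper_ub", "mmd"}
    mmd_bandwidth: float | str = "median-heuristic"
    kuiper_clamp: float = KUIPER_P_FLOOR

    def __post_init__(self):
        if self.kind not in ("kuiper_ub", "mmd"):
            raise ValueError(f"unknown divergence kind {self.kind!r}")


def km_estimate(times, events, weights=None) -> SurvivalCurve:
    """Weighted product-limit (Kaplan-Meier) estimator.

    With unit weights this is the classical KM estimate; with soft cluster
    membership probabilities as weights it gives the per-cluster curve of
    the clustering objective.  Censored rows contribute to the at-risk
    counts up to their censoring time only.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if weights is None:
        weights = np.ones_like(times)
    weights = np.asarray(weights, dtype=float)
    if times.shape != events.shape or times.shape != weights.shape:
        raise ValueError("times, events, weights must have equal length")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")

    event_mask = events.astype(bool)
    uniq = np.unique(times[event_mask & (weights > 0)])
    if uniq.size == 0:
        return SurvivalCurve(np.empty(0), np.empty(0), np.empty(0),
                             np.empty(0), float(weights.sum()),
                             degenerate=True)
    # d_j: weighted events at t_j; n_j: weighted at-risk just before t_j
    ev_sel = event_mask & (weights > 0)
    ev_idx = np.searchsorted(uniq, times[ev_sel])
    d = np.bincount(ev_idx, weights=weights[ev_sel], minlength=uniq.size)
    order = np.argsort(times, kind="stable")
    sorted_t, sorted_w = times[order], weights[order]
    suffix = np.concatenate([np.cumsum(sorted_w[::-1])[::-1], [0.0]])
    n = suffix[np.searchsorted(sorted_t, uniq, side="left")]
    surv = np.cumprod(1.0 - d / n)
    return SurvivalCurve(uniq, surv, n, d, float(weights.sum()))


def _steps_on(curve: SurvivalCurve, grid: np.ndarray):
    """Values of the step function at grid points and just before them."""
    return curve.survival_at(grid), curve.survival_before(grid)


def kuiper_statistic(s1: SurvivalCurve, s2: SurvivalCurve) -> float:
    """Kuiper two-sample statistic V = D+ + D- between two survival curves.

    Both one-sided suprema are attained at step points of either curve
    (approached from the right or the left), so evaluating on the union
    of step points is exact.
    """
    grid = np.union1d(s1.event_times, s2.event_times)
    if grid.size == 0:
        return 0.0
    a_r, a_l = _steps_on(s1, grid)
    b_r, b_l = _steps_on(s2, grid)
    diff = np.concatenate([a_r - b_r, a_l - b_l, [0.0]])  # 0: before t_min
    return float(np.max(diff) + np.max(-diff))


def kuiper_pvalue_ub(v: float, n1_eff: float, n2_eff: float) -> float:
    """Differentiable upper bound on the two-sample Kuiper p-value.

    Uses the leading term of the Kuiper asymptotic tail series with the
    finite-sample lambda correction, clamped to (KUIPER_P_FLOOR, 1].
    The term only carries evidence once lambda exceeds its zero crossing
    at 1/2; below that (in particular V = 0) there is no separation and
    the bound saturates at 1.
    """
    if not 0.0 <= v <= 2.0 + 1e-12:
        raise ValueError("Kuiper statistic must lie in [0, 2]")
    if n1_eff <= 0 or n2_eff <= 0:
        raise ValueError("effective sizes must be positive")
    n_e = n1_eff * n2_eff / (n1_eff + n2_eff)
    lam = (np.sqrt(n_e) + 0.155 + 0.24 / np.sqrt(n_e)) * v
    if lam <= 0.5:
        return 1.0
    p = 2.0 * (4.0 * lam**2 - 1.0) * np.exp(-2.0 * lam**2)
    return float(np.clip(p, KUIPER_P_FLOOR, 1.0))


def kuiper_series_pvalue(v: float, n_e: float, terms: int = 100) -> float:
    """Full Kuiper asymptotic series (reference/cross-check, not a bound)."""
    lam = (np.sqrt(n_e) + 0.155 + 0.24 / np.sqrt(n_e)) * v
    j = np.arange(1, terms + 1)
    s = (4.0 * j**2 * lam**2 - 1.0) * np.exp(-2.0 * j**2 * lam**2)
    return float(np.clip(2.0 * s.sum(), 0.0, 1.0))


def mmd_divergence(times, q_i, q_j, bandwidth="median-heuristic") -> float:
    """Biased weighted MMD^2 between two soft clusters' follow-up times.

    Gaussian kernel k(a,b) = exp(-(a-b)^2 / (2 sigma^2)) over all observed
    times (event and censored); weights are normalized to sum one.  The
    V-statistic form keeps the estimate non-negative and differentiable.
    """
    times = np.asarray(times, dtype=float)
    q_i = np.asarray(q_i, dtype=float)
    q_j = np.asarray(q_j, dtype=float)
    for name, q in (("i", q_i), ("j", q_j)):
        if np.any(q < 0):
            raise ValueError(f"cluster {name}: negative weights")
        if q.sum() <= 0:
            raise ValueError(f"cluster {name}: zero-sum weight vector")
    sigma = _resolve_bandwidth(times, bandwidth)
    diff = times[:, None] - times[None, :]
    kern = np.exp(-(diff**2) / (2.0 * sigma**2))
    a = q_i / q_i.sum()
    b = q_j / q_j.sum()
    return float(a @ kern @ a + b @ kern @ b - 2.0 * a @ kern @ b)


def _resolve_bandwidth(times: np.ndarray, bandwidth) -> float:
    if bandwidth == "median-heuristic":
        diffs = np.abs(times[:, None] - times[None, :])
        med = float(np.median(diffs[np.triu_indices(len(times), k=1)]))
        return med if med > 0 else 1.0
    bw = float(bandwidth)
    if bw <= 0:
        raise ValueError("bandwidth must be positive")
    return bw


def logrank_statistic(times, events, group_labels) -> float:
    """K-sample log-rank chi-square statistic (the 'log-rank score').

    The reported value is the chi-square statistic itself, not its
    p-value.  Delegates to lifelines' multivariate log-rank test.
    """
    from lifelines.statistics import multivariate_logrank_test

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group_labels = np.asarray(group_labels)
    groups = np.unique(group_labels)
    if groups.size < 2:
        raise ValueError("log-rank requires at least two non-empty groups")
    if events.sum() == 0:
        raise ValueError("log-rank requires at least one event")
    res = multivariate_logrank_test(times, group_labels, events)
    return float(res.test_statistic)


def concordance_index(times, events, risk_scores) -> float:
    """Harrell's C for right-censored data; higher risk score = riskier.

    A pair (i, j) is comparable iff T_i < T_j and the event occurred for
    i; concordant if risk_i > risk_j, tied risks count one half.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    risk = np.asarray(risk_scores, dtype=float)
    # comparable[i, j]: i had the event strictly before j's follow-up end
    comparable = (times[:, None] < times[None, :]) & events[:, None]
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs (degenerate input)")
    higher = risk[:, None] > risk[None, :]
    tied = risk[:, None] == risk[None, :]
    concordant = (comparable & higher).sum()
    ties = (comparable & tied).sum()
    return float((concordant + 0.5 * ties) / n_comp)


def brier_score(times, events, predicted_survival_at_tau, tau,
                ipcw: bool = True) -> float:
    """Brier score at horizon tau, censoring-weighted (IPCW) by default.

    Weights come from the Kaplan-Meier estimate G of the censoring
    distribution (event/censoring roles swapped): rows with the event by
    tau weigh 1/G(T-), rows still under observation past tau weigh
    1/G(tau), rows censored before tau weigh 0.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    pred = np.asarray(predicted_survival_at_tau, dtype=float)
    if np.any((pred < 0) | (pred > 1)):
        raise ValueError("predicted survival must lie in [0, 1]")
    alive = times > tau
    resid = (alive.astype(float) - pred) ** 2
    if not ipcw:
        return float(resid.mean())
    g = km_estimate(times, ~events)  # censoring-distribution KM
    g_tau = float(g.survival_at(tau))
    if g_tau <= 0:
        raise ValueError("censoring survival G(tau) = 0: no information "
                         "at the requested horizon")
    w = np.zeros_like(times)
    event_by_tau = events & (times <= tau)
    w[event_by_tau] = 1.0 / g.survival_before(times[event_by_tau])
    w[alive] = 1.0 / g_tau
    return float((w * resid).mean())


def chisq_test(table) -> tuple[float, float]:
    """Pearson chi-square on a K x C contingency table (no continuity
    correction)."""
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def anova_f(samples) -> tuple[float, float]:
    """Classical one-way ANOVA F and p across >= 2 groups of values."""
    if len(samples) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrs = [np.asarray(s, dtype=float) for s in samples]
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs at least two values")
    flat = np.concatenate(arrs)
    if np.ptp(flat) == 0:  # all values identical: define F = 0
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = sps.f_oneway(*arrs)
    if not np.isfinite(f):
        return 0.0, 1.0
    return float(f), float(p)
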
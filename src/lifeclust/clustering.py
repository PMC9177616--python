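"""Comparator risk-grouping methods: the SPI-II clinical score,
k-prototypes for mixed-type data, and Cox-screened semi-supervised
clustering (SSC-Bair).

SPI-II (Stroke Prognostic Instrument II) is a 0-15 point sum over seven
clinical factors; scores are binned into low (0-3), medium (4-7), and
high (>= 8) risk tiers.  k-prototypes runs Lloyd iterations on a cost
mixing squared Euclidean distance (continuous) with gamma-weighted
category mismatches.  SSC-Bair screens features by univariate Cox
significance (p < 0.1) and clusters the survivors with k-means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.cluster import KMeans

__all__ = [
    "SPI2Inputs",
    "spi2_score",
    "spi2_risk_group",
    "spi2_from_cohort",
    "kprototypes_fit",
    "univariate_cox",
    "ssc_bair_fit",
]

BETA_CAP = 20.0  # |beta| cap under monotone partial likelihood


@dataclass(frozen=True)
class SPI2Inputs:
    """The seven SPI-II factors for one patient."""

    chf: int = 0
    dm: int = 0
    prior_stroke: int = 0
    index_is_stroke: int = 0
    severe_htn: int = 0
    cad: int = 0
    age: float = 0.0

    def __post_init__(self):
        for name in ("chf", "dm", "prior_stroke", "index_is_stroke",
                     "severe_htn", "cad"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")
        if self.age <= 0:
            raise ValueError("age must be positive")


def spi2_score(x: SPI2Inputs) -> int:
    """SPI-II sum score: CHF, diabetes, prior stroke 3 points each;
    age > 70 (strict) and index stroke 2 each; severe hypertension and
    coronary artery disease 1 each."""
    return (3 * x.chf + 3 * x.dm + 3 * x.prior_stroke
            + 2 * int(x.age > 70) + 2 * x.index_is_stroke
            + 1 * x.severe_htn + 1 * x.cad)


def spi2_risk_group(score: int) -> str:
    """Risk tier for an SPI-II score: low 0-3, medium 4-7, high >= 8."""
    if not 0 <= score <= 15:
        raise ValueError(f"SPI-II score {score} outside [0, 15]")
    if score <= 3:
        return "low"
    if score <= 7:
        return "medium"
    return "high"


_TIER_TO_LABEL = {"high": 0, "medium": 1, "low": 2}


def spi2_from_cohort(df, severe_htn_sbp: float = 180.0) -> np.ndarray:
    """Risk-ordered labels (0 high, 1 medium, 2 low) for a cohort table.

    All patients here have ischemic stroke as the index event; severe
    hypertension is taken as systolic pressure above ``severe_htn_sbp``.
    """
    labels = np.empty(len(df), dtype=int)
    for i, row in enumerate(df.itertuples(index=False)):
        x = SPI2Inputs(chf=int(row.chf), dm=int(row.dm),
                       prior_stroke=int(row.history_stroke),
                       index_is_stroke=1,
                       severe_htn=int(float(row.sbp) > severe_htn_sbp),
                       cad=int(row.history_cad), age=float(row.age))
        labels[i] = _TIER_TO_LABEL[spi2_risk_group(spi2_score(x))]
    return labels


# ---------------------------------------------------------------------------
# k-prototypes
# ---------------------------------------------------------------------------

def kprototypes_fit(x_continuous, x_categorical, k: int,
                    gamma: float | None = None, seed: int = 0,
                    max_iter: int = 100):
    """Lloyd-style k-prototypes for mixed continuous/categorical data.

    cost(row, prototype) = ||continuous diff||^2 + gamma * (number of
    categorical mismatches); prototypes update to the per-cluster mean /
    mode.  ``gamma`` defaults to half the mean standard deviation of the
    continuous columns (Huang's heuristic).  Empty clusters re-seed at
    the row farthest from its current prototype.
    """
    xc = np.asarray(x_continuous, dtype=float)
    xk = np.asarray(x_categorical)
    n = xc.shape[0] if xc.size else xk.shape[0]
    if k < 2 or n < k:
        raise ValueError("need k >= 2 and at least k rows")
    if xk.ndim == 1:
        xk = xk[:, None]
    if xc.ndim == 1:
        xc = xc[:, None]
    if gamma is None:
        gamma = 0.5 * float(xc.std(axis=0).mean()) if xc.size else 1.0

    rng = np.random.default_rng(seed)
    centers_c = xc[rng.choice(n, size=k, replace=False)].copy()
    centers_k = xk[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    for _ in range(max_iter):
        cost = np.zeros((n, k))
        if xc.size:
            cost += ((xc[:, None, :] - centers_c[None, :, :])**2).sum(axis=2)
        if xk.size:
            cost += gamma * (xk[:, None, :]
                             != centers_k[None, :, :]).sum(axis=2)
        new_labels = cost.argmin(axis=1)
        for c in range(k):
            if not np.any(new_labels == c):  # re-seed empty cluster
                worst = np.argmax(cost[np.arange(n), new_labels])
                new_labels[worst] = c
                centers_c[c] = xc[worst]
                centers_k[c] = xk[worst]
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            mask = labels == c
            if xc.size:
                centers_c[c] = xc[mask].mean(axis=0)
            for col in range(xk.shape[1]):
                vals, counts = np.unique(xk[mask, col], return_counts=True)
                centers_k[c, col] = vals[counts.argmax()]
    return labels, (centers_c, centers_k)


# ---------------------------------------------------------------------------
# univariate Cox (Breslow ties) and SSC-Bair
# ---------------------------------------------------------------------------

def _cox_derivatives(beta: float, times, events, x):
    """Partial log-likelihood score and information, Breslow ties.

    Rows sorted by time descending give cumulative risk-set sums; tied
    event times share the full risk set.
    """
    order = np.argsort(-times, kind="stable")
    t, e, xv = times[order], events[order], x[order]
    eta = np.exp(beta * xv)
    s0 = np.cumsum(eta)
    s1 = np.cumsum(xv * eta)
    s2 = np.cumsum(xv**2 * eta)
    # risk set for an event at time t_i = all rows with time >= t_i:
    # because of ties, take the cumulative sum at the LAST index sharing t_i
    last_same = np.searchsorted(-t, -t, side="right") - 1
    ev = e.astype(bool)
    i0, i1, i2 = s0[last_same[ev]], s1[last_same[ev]], s2[last_same[ev]]
    score = float((xv[ev] - i1 / i0).sum())
    info = float((i2 / i0 - (i1 / i0)**2).sum())
    loglik = float((beta * xv[ev] - np.log(i0)).sum())
    return loglik, score, info


def univariate_cox(times, events, x) -> tuple[float, float]:
    """Single-covariate Cox fit by Newton-Raphson; returns (beta, Wald p).

    Monotone likelihood (perfect separation) caps |beta| at 20 with a
    warning; a constant covariate is an error.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")
    # standardize for numerical stability; rescale beta afterwards
    scale = x.std()
    xs = (x - x.mean()) / scale
    beta = 0.0
    for _ in range(60):
        _, score, info = _cox_derivatives(beta, times, events, xs)
        if info <= 1e-12:
            break
        step = score / info
        beta += np.clip(step, -5.0, 5.0)
        if abs(beta) > BETA_CAP * scale + 50:
            break
        if abs(step) < 1e-10:
            break
    beta_x = beta / scale
    if abs(beta_x) > BETA_CAP:
        warnings.warn("monotone partial likelihood; beta capped at "
                      f"+-{BETA_CAP}")
        beta_x = float(np.sign(beta_x) * BETA_CAP)
        beta = beta_x * scale
    _, _, info = _cox_derivatives(beta, times, events, xs)
    if info <= 1e-12:
        return beta_x, 1.0
    se_x = 1.0 / np.sqrt(info) / scale
    z = beta_x / se_x
    p = 2.0 * sps.norm.sf(abs(z))
    return float(beta_x), float(p)


def ssc_bair_fit(x, times, events, k: int = 3, alpha: float = 0.10,
                 seed: int = 0):
    """Cox-screened semi-supervised clustering.

    Keeps feature columns with univariate Cox Wald p < alpha, then runs
    k-means (k-means++ init, 10 restarts) on them.  If nothing passes
    the screen, all columns are kept with a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < k:
        raise ValueError("fewer rows than clusters")
    selected = []
    for j in range(x.shape[1]):
        col = x[:, j]
        if np.ptp(col) == 0:
            continue
        _, p = univariate_cox(times, events, col)
        if p < alpha:
            selected.append(j)
    if not selected:
        warnings.warn("no feature passed the Cox screen; using all columns")
        selected = [j for j in range(x.shape[1]) if np.ptp(x[:, j]) > 0]
    km = KMeans(n_clusters=k, init="k-means++", n_init=10,
                random_state=seed)
    labels = km.fit_predict(x[:, selected])
    return selected, km.cluster_centers_, labels
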
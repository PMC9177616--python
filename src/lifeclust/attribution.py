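"""Model-agnostic Shapley-value attribution for cluster memberships.

For each explained row, feature permutations are sampled; walking each
permutation, features switch one at a time from a background row's
values to the explained row's values, and the marginal change in every
cluster's membership probability is credited to the switched feature.
Averaging over permutations and background rows gives an unbiased
Monte-Carlo estimate of the Shapley values of the membership game, with
the efficiency property holding up to sampling noise: per row and
cluster the attributions sum to prediction minus background baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AttributionResult", "shapley_attribution", "importance_summary"]


@dataclass(frozen=True)
class AttributionResult:
    values: np.ndarray        # n x d x K
    baseline: np.ndarray      # K: mean membership over the background
    feature_names: tuple

    def aggregate_onehot(self) -> "AttributionResult":
        """Sum indicator-column attributions back to source covariates
        (columns named 'cov=level' collapse onto 'cov')."""
        sources, seen = [], {}
        for name in self.feature_names:
            src = name.split("=")[0]
            if src not in seen:
                seen[src] = len(sources)
                sources.append(src)
        agg = np.zeros((self.values.shape[0], len(sources),
                        self.values.shape[2]))
        for j, name in enumerate(self.feature_names):
            agg[:, seen[name.split("=")[0]], :] += self.values[:, j, :]
        return AttributionResult(agg, self.baseline, tuple(sources))


def shapley_attribution(model, rows, background, n_permutations: int = 200,
                        seed: int = 0) -> AttributionResult:
    """Sampling-Shapley attributions of cluster membership probabilities.

    ``model`` needs a ``predict_soft(X) -> n x K`` method; ``rows`` and
    ``background`` are feature matrices (or objects with ``.values`` and
    ``.feature_names``).
    """
    x = getattr(rows, "values", rows)
    bg = getattr(background, "values", background)
    names = tuple(getattr(rows, "feature_names",
                          [f"x{j}" for j in range(np.asarray(x).shape[1])]))
    x = np.asarray(x, dtype=float)
    bg = np.asarray(bg, dtype=float)
    if bg.shape[0] == 0:
        raise ValueError("background must be non-empty")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if x.shape[1] != bg.shape[1]:
        raise ValueError("rows and background feature dimensions differ")

    n, d = x.shape
    baseline_q = model.predict_soft(bg)
    k = baseline_q.shape[1]
    baseline = baseline_q.mean(axis=0)
    rng = np.random.default_rng(seed)
    b = bg.shape[0]
    values = np.zeros((n, d, k))
    for i in range(n):
        acc = np.zeros((d, k))
        for _ in range(n_permutations):
            perm = rng.permutation(d)
            current = bg.copy()                 # batch over background rows
            prev = model.predict_soft(current).mean(axis=0)
            for j in perm:
                current[:, j] = x[i, j]
                cur = model.predict_soft(current).mean(axis=0)
                acc[j] += cur - prev
                prev = cur
        values[i] = acc / n_permutations
    return AttributionResult(values, baseline, names)


def importance_summary(attr: AttributionResult) -> pd.DataFrame:
    """Mean |attribution| per (feature, cluster), sorted descending
    within each cluster."""
    mean_abs = np.abs(attr.values).mean(axis=0)  # d x K
    records = []
    for c in range(mean_abs.shape[1]):
        order = np.argsort(-mean_abs[:, c], kind="stable")
        for rank, j in enumerate(order):
            records.append({"cluster": c, "rank": rank,
                            "feature": attr.feature_names[j],
                            "mean_abs_attribution": mean_abs[j, c]})
    return pd.DataFrame.from_records(records)
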
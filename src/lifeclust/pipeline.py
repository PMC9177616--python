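"""Orchestration of the full clustering comparison experiment.

``run_comparison`` repeats, for r = 0..n_repetitions-1: stratified
60:20:20 re-split with seed base+r, preprocessing fitted on the training
split, a fit of every requested method, and the three metrics (Harrell
C, K-sample log-rank chi-square, IPCW Brier at the horizon) on all three
splits.  Per-method risk scores for C-index/Brier are the training-split
one-year KM cumulative event probability of the patient's assigned
cluster, so an unordered clustering becomes a risk ordering through its
own survival curves.  Means/SDs over repetitions and one-way ANOVA
across methods per (split, metric) make up the metric report; the final
repetition also emits per-method outcome tables and KM curve exports.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable, read_cohort, load_schema, stratified_split
from .clustering import kprototypes_fit, spi2_from_cohort, ssc_bair_fit
from .dlc import HyperparameterGrid, dlc_fit, order_clusters_by_risk
from .preprocess import apply_transform, fit_transform, impute
from .survival import (DivergenceSpec, anova_f, brier_score, chisq_test,
                       concordance_index, km_estimate, logrank_statistic)
from .synthetic import default_stroke_spec, simulate_cohort, spec_from_dict

__all__ = ["run_comparison", "outcome_table", "KNOWN_METHODS"]

log = logging.getLogger("lifeclust.pipeline")

KNOWN_METHODS = ("spi2", "kprototype", "ssc-bair", "dlc-mmd", "dlc-kuiper")
METRICS = ("c_index", "logrank", "brier")
SPLITS = ("train", "validation", "test")


def _cluster_event_probs(labels, times, events, k, horizon) -> np.ndarray:
    """Training-split one-year KM cumulative event probability per
    cluster; empty clusters fall back to the overall rate."""
    overall = 1.0 - float(km_estimate(times, events).survival_at(horizon))
    probs = np.full(k, overall)
    for c in range(k):
        mask = np.asarray(labels) == c
        if mask.any() and events[mask].sum() > 0:
            curve = km_estimate(times[mask], events[mask])
            probs[c] = 1.0 - float(curve.survival_at(horizon))
        elif mask.any():
            probs[c] = 0.0
    return probs


def _split_categorical_continuous(cohort: CohortTable, fm):
    """Column blocks for k-prototypes: scaled continuous vs raw
    categorical/binary."""
    cont_names = [s.name for s in cohort.schema if s.kind == "continuous"]
    cont_idx = [fm.feature_names.index(n) for n in cont_names]
    xc = fm.values[:, cont_idx]
    cat_cols = [s.name for s in cohort.schema if s.kind != "continuous"]
    xk = cohort.df[cat_cols].to_numpy(object) if cat_cols else \
        np.empty((len(cohort.df), 0), object)
    return xc, xk


def _kproto_assign(centers, gamma, xc, xk) -> np.ndarray:
    centers_c, centers_k = centers
    cost = ((xc[:, None, :] - centers_c[None, :, :])**2).sum(axis=2)
    if xk.shape[1]:
        cost = cost + gamma * (xk[:, None, :]
                               != centers_k[None, :, :]).sum(axis=2)
    return cost.argmin(axis=1)


class _FittedMethod:
    """Uniform interface: labels(split_name) -> risk-ordered labels."""

    def __init__(self, label_map: dict):
        self._labels = label_map

    def labels(self, split: str) -> np.ndarray:
        return self._labels[split]


def _fit_method(method: str, parts: dict, fms: dict, k: int, seed: int,
                horizon: float, grid: HyperparameterGrid,
                mmd_bandwidth) -> _FittedMethod:
    train = parts["train"]
    if method == "spi2":
        return _FittedMethod({s: spi2_from_cohort(parts[s].df)
                              for s in SPLITS})
    if method == "kprototype":
        xc, xk = _split_categorical_continuous(train, fms["train"])
        gamma = 0.5 * float(xc.std(axis=0).mean()) if xc.size else 1.0
        labels_train, centers = kprototypes_fit(xc, xk, k=k, gamma=gamma,
                                                seed=seed)
        perm = order_clusters_by_risk(labels_train, train.times,
                                      train.events, n_clusters=k,
                                      horizon=horizon)
        out = {}
        for s in SPLITS:
            xc_s, xk_s = _split_categorical_continuous(parts[s], fms[s])
            out[s] = perm[_kproto_assign(centers, gamma, xc_s, xk_s)]
        return _FittedMethod(out)
    if method == "ssc-bair":
        selected, centroids, labels_train = ssc_bair_fit(
            fms["train"].values, train.times, train.events, k=k, seed=seed)
        perm = order_clusters_by_risk(labels_train, train.times,
                                      train.events, n_clusters=k,
                                      horizon=horizon)
        out = {}
        for s in SPLITS:
            x = fms[s].values[:, selected]
            d2 = ((x[:, None, :] - centroids[None, :, :])**2).sum(axis=2)
            out[s] = perm[d2.argmin(axis=1)]
        return _FittedMethod(out)
    if method in ("dlc-kuiper", "dlc-mmd"):
        kind = "kuiper_ub" if method == "dlc-kuiper" else "mmd"
        div = DivergenceSpec(kind=kind, mmd_bandwidth=mmd_bandwidth)
        model = dlc_fit(fms["train"].values, train.times, train.events,
                        fms["validation"].values, parts["validation"].times,
                        parts["validation"].events, grid=grid,
                        divergence=div, n_clusters=k, seed=seed)
        return _FittedMethod({s: model.predict(fms[s].values).hard_labels
                              for s in SPLITS})
    raise ValueError(f"unknown method {method!r}")


def outcome_table(labels, times, events, horizon: float = 365.0,
                  event_types=None) -> pd.DataFrame:
    """Per-cluster one-year outcome counts with chi-square p-values.

    Percentages use cluster size as the denominator (rows censored
    before the horizon stay in n); a KM cumulative-incidence column
    acknowledges that censoring.
    """
    labels = np.asarray(labels)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    clusters = np.unique(labels)
    if any(not np.any(labels == c) for c in clusters) or clusters.size == 0:
        raise ValueError("empty cluster")
    rows = []
    outcome_defs = {"primary": events.astype(bool) & (times <= horizon)}
    if event_types is not None:
        et = np.asarray(event_types, dtype=object)
        for comp in ("stroke", "mi", "mortality"):
            outcome_defs[comp] = (et == comp) & (times <= horizon)
    for name, flag in outcome_defs.items():
        counts = []
        for c in clusters:
            mask = labels == c
            n_c = int(mask.sum())
            cnt = int(flag[mask].sum())
            rec = {"outcome": name, "cluster": int(c), "n": n_c,
                   "count": cnt, "percent": 100.0 * cnt / n_c}
            if name == "primary":
                mask_ev = events[mask].sum()
                if mask_ev > 0:
                    curve = km_estimate(times[mask], events[mask])
                    rec["km_cumulative_incidence"] = \
                        100.0 * (1.0 - float(curve.survival_at(horizon)))
                else:
                    rec["km_cumulative_incidence"] = 0.0
            counts.append(rec)
        table = np.array([[r["count"], r["n"] - r["count"]]
                          for r in counts])
        try:
            _, p = chisq_test(table)
        except ValueError:
            p = np.nan
        for r in counts:
            r["chisq_p"] = p
            rows.append(r)
    return pd.DataFrame.from_records(rows)


def _resolve_cohort(config: dict) -> CohortTable:
    if "cohort" in config:
        schema = load_schema(config["schema"])
        return read_cohort(config["cohort"], schema)
    spec_cfg = config.get("synthetic_spec", "default")
    if spec_cfg == "default":
        spec = default_stroke_spec(n=int(config.get("n", 7650)),
                                   seed=int(config.get("base_seed", 0)))
    else:
        spec = spec_from_dict(dict(spec_cfg))
    return simulate_cohort(spec)


def run_comparison(config: dict, out_dir=None) -> dict:
    """Run the full repeated comparison; returns the metric report.

    Config keys: ``cohort``+``schema`` or ``synthetic_spec`` (\"default\"
    or an inline spec) with ``n``; ``methods``; ``k``; ``n_repetitions``;
    ``base_seed``; ``horizon_days``; optional ``grid`` overrides and
    ``mmd_bandwidth``.  Each repetition re-splits and re-initializes
    with seed base+r (``fixed_split: true`` re-uses the first split).
    """
    methods = list(config.get("methods", KNOWN_METHODS))
    for m in methods:
        if m not in KNOWN_METHODS:
            raise ValueError(f"unknown method {m!r}")
    k = int(config.get("k", 3))
    n_rep = int(config.get("n_repetitions", 30))
    base_seed = int(config.get("base_seed", 0))
    horizon = float(config.get("horizon_days", 365.0))
    fixed_split = bool(config.get("fixed_split", False))
    grid = HyperparameterGrid(**config["grid"]) if "grid" in config \
        else HyperparameterGrid()
    mmd_bandwidth = config.get("mmd_bandwidth", "median-heuristic")
    cohort = _resolve_cohort(config)
    brier_tau = horizon - 0.5  # just inside the administrative boundary

    values = {m: {s: {met: [] for met in METRICS} for s in SPLITS}
              for m in methods}
    failures = {m: 0 for m in methods}
    final_artifacts = {}
    for r in range(n_rep):
        seed = base_seed + (0 if fixed_split else r)
        split = stratified_split(cohort, seed=seed)
        parts = split.parts()
        train_imp = impute(parts["train"])
        train_medians = {s.name: float(train_imp.df[s.name].median())
                         for s in cohort.schema if s.kind == "continuous"}
        parts = {"train": train_imp,
                 "validation": impute(parts["validation"],
                                      medians=train_medians),
                 "test": impute(parts["test"], medians=train_medians)}
        fm_train = fit_transform(parts["train"])
        fms = {"train": fm_train,
               "validation": apply_transform(fm_train.state,
                                             parts["validation"]),
               "test": apply_transform(fm_train.state, parts["test"])}
        for m in methods:
            t0 = time.perf_counter()
            try:
                fitted = _fit_method(m, parts, fms, k, base_seed + r,
                                     horizon, grid, mmd_bandwidth)
            except Exception as exc:  # noqa: BLE001 — counted and re-raised
                failures[m] += 1
                log.warning("repetition %d method %s failed: %s", r, m, exc)
                if failures[m] > 0.2 * n_rep:
                    raise RuntimeError(
                        f"method {m!r} failed on more than 20% of "
                        "repetitions") from exc
                for s in SPLITS:
                    for met in METRICS:
                        values[m][s][met].append(np.nan)
                continue
            probs = _cluster_event_probs(fitted.labels("train"),
                                         parts["train"].times,
                                         parts["train"].events, k, horizon)
            for s in SPLITS:
                labels = fitted.labels(s)
                times, events = parts[s].times, parts[s].events
                risk = probs[labels]
                try:
                    ci = concordance_index(times, events, risk)
                except ValueError:
                    ci = np.nan
                try:
                    lr = logrank_statistic(times, events, labels)
                except ValueError:
                    lr = np.nan
                try:
                    bs = brier_score(times, events,
                                     np.clip(1.0 - risk, 0.0, 1.0),
                                     brier_tau)
                except ValueError:
                    bs = np.nan
                values[m][s]["c_index"].append(ci)
                values[m][s]["logrank"].append(lr)
                values[m][s]["brier"].append(bs)
                log.info("rep=%d method=%s split=%s c=%.4f lr=%.2f "
                         "bs=%.4f dt=%.1fs", r, m, s, ci, lr, bs,
                         time.perf_counter() - t0)
            if r == n_rep - 1:
                final_artifacts[m] = (fitted, parts)

    report = {"n_repetitions": n_rep, "methods": methods, "k": k,
              "base_seed": base_seed, "horizon_days": horizon,
              "metrics": {}, "anova": {}}
    for m in methods:
        report["metrics"][m] = {}
        for s in SPLITS:
            report["metrics"][m][s] = {}
            for met in METRICS:
                arr = np.asarray(values[m][s][met], dtype=float)
                ok = arr[~np.isnan(arr)]
                cell = {"mean": float(ok.mean()) if ok.size else None,
                        "sd": float(ok.std(ddof=1)) if ok.size > 1 else
                        (0.0 if ok.size == 1 else None),
                        "values": [None if np.isnan(v) else float(v)
                                   for v in arr]}
                if not ok.size:
                    cell["reason"] = "metric undefined on every repetition"
                report["metrics"][m][s][met] = cell
    if len(methods) >= 2 and n_rep >= 2:
        for s in SPLITS:
            report["anova"][s] = {}
            for met in METRICS:
                groups = []
                for m in methods:
                    arr = np.asarray(values[m][s][met], dtype=float)
                    arr = arr[~np.isnan(arr)]
                    if arr.size >= 2:
                        groups.append(arr)
                if len(groups) >= 2:
                    f, p = anova_f(groups)
                    report["anova"][s][met] = {"F": f, "p": p}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "metrics.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        for m, (fitted, parts) in final_artifacts.items():
            test = parts["test"]
            et = (test.df["event_type"].to_numpy(object)
                  if "event_type" in test.df.columns else None)
            tbl = outcome_table(fitted.labels("test"), test.times,
                                test.events, horizon, event_types=et)
            tbl.to_csv(out / f"outcomes_{m}.tsv", sep="\t", index=False)
            for c in np.unique(fitted.labels("test")):
                mask = fitted.labels("test") == c
                if test.events[mask].sum() == 0:
                    continue
                curve = km_estimate(test.times[mask], test.events[mask])
                curve.to_tsv(out / f"km_{m}_{int(c)}.tsv")
    return report
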
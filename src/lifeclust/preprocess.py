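"""Imputation, scaling, and encoding into the numeric feature matrix.

All transform statistics (continuous medians/min/max, categorical level
maps) are fitted on the training split only and then applied unchanged
to validation/test, so no information leaks across the split.  Missing
continuous values take the training median; missing categorical/binary
values take the declared reference level (the level not indicating the
risk factor).  Continuous columns are min-max scaled to [0,1] on the
training range; categoricals expand to one indicator column per level.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable, CovariateSchema

__all__ = ["FeatureMatrix", "TransformState", "impute",
           "fit_transform", "apply_transform"]

MISSING_WARN_FRACTION = 0.03


@dataclass(frozen=True)
class TransformState:
    """Per-column statistics fitted on training data."""

    medians: dict          # continuous name -> training median
    minmax: dict           # continuous name -> (min, max)
    levels: dict           # categorical name -> ordered level list
    feature_names: tuple   # expanded column order

    def to_json(self, path) -> None:
        payload = {"medians": self.medians,
                   "minmax": {k: list(v) for k, v in self.minmax.items()},
                   "levels": {k: list(v) for k, v in self.levels.items()},
                   "feature_names": list(self.feature_names)}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TransformState":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(d["medians"],
                   {k: tuple(v) for k, v in d["minmax"].items()},
                   {k: list(v) for k, v in d["levels"].items()},
                   tuple(d["feature_names"]))


@dataclass(frozen=True)
class FeatureMatrix:
    values: np.ndarray
    feature_names: tuple
    state: TransformState

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def impute(cohort: CohortTable, schema: list[CovariateSchema] | None = None,
           medians: dict | None = None,
           categorical_mode: bool = False) -> CohortTable:
    """Fill missing cells: continuous -> median, categorical/binary ->
    reference level (or per-column mode with ``categorical_mode=True``).

    ``medians`` lets validation/test reuse the training medians; when
    omitted they are computed from the non-missing rows of ``cohort``.
    """
    schema = cohort.schema if schema is None else schema
    df = cohort.df.copy()
    for spec in schema:
        col = df[spec.name]
        n_missing = int(col.isna().sum())
        if n_missing == 0:
            continue
        frac = n_missing / len(df)
        if frac > MISSING_WARN_FRACTION:
            warnings.warn(f"column {spec.name!r}: missing fraction "
                          f"{frac:.3f} exceeds {MISSING_WARN_FRACTION}")
        if n_missing == len(df):
            raise ValueError(f"column {spec.name!r} is entirely missing")
        if spec.kind == "continuous":
            fill = (medians or {}).get(spec.name)
            if fill is None:
                fill = float(col.dropna().median())
            df[spec.name] = col.fillna(fill)
        else:
            if categorical_mode:
                fill = col.dropna().mode().iloc[0]
            else:
                fill = 0 if spec.kind == "binary" else spec.reference_level
            df[spec.name] = col.fillna(fill)
    return CohortTable(df, schema)


def _expand(df: pd.DataFrame, schema, state: TransformState) -> np.ndarray:
    cols = []
    for spec in schema:
        col = df[spec.name]
        if spec.kind == "continuous":
            lo, hi = state.minmax[spec.name]
            x = col.to_numpy(dtype=float)
            if hi > lo:
                cols.append((x - lo) / (hi - lo))
            else:
                cols.append(np.zeros_like(x))
        elif spec.kind == "binary":
            cols.append(col.to_numpy(dtype=float))
        else:
            levels = state.levels[spec.name]
            vals = col.to_numpy(object)
            seen = np.isin(vals, levels)
            if not seen.all():
                warnings.warn(f"column {spec.name!r}: unseen level(s) "
                              f"{set(vals[~seen])}; encoding as all-zero")
            for lv in levels:
                cols.append((vals == lv).astype(float))
    return np.column_stack(cols)


def fit_transform(train: CohortTable) -> FeatureMatrix:
    """Fit scaling/encoding state on the (already imputed) training split
    and return its feature matrix."""
    df = train.df
    medians, minmax, levels, names = {}, {}, {}, []
    for spec in train.schema:
        if spec.kind == "continuous":
            x = df[spec.name].to_numpy(dtype=float)
            if np.isnan(x).any():
                raise ValueError(f"column {spec.name!r} still has missing "
                                 "values; run impute first")
            medians[spec.name] = float(np.median(x))
            lo, hi = float(x.min()), float(x.max())
            if hi <= lo:
                warnings.warn(f"column {spec.name!r} is constant; mapped "
                              "to 0.0")
            minmax[spec.name] = (lo, hi)
            names.append(spec.name)
        elif spec.kind == "binary":
            names.append(spec.name)
        else:
            levels[spec.name] = list(spec.levels)
            names.extend(f"{spec.name}={lv}" for lv in spec.levels)
    state = TransformState(medians, minmax, levels, tuple(names))
    return FeatureMatrix(_expand(df, train.schema, state), tuple(names),
                         state)


def apply_transform(state: TransformState, cohort: CohortTable
                    ) -> FeatureMatrix:
    """Transform a cohort with previously fitted state (training min/max
    and level maps); continuous values may fall outside [0,1]."""
    values = _expand(cohort.df, cohort.schema, state)
    return FeatureMatrix(values, state.feature_names, state)
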
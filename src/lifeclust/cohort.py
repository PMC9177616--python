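"""Cohort tables: reading, validation, and outcome-stratified splitting.

A cohort is one row per patient — identifier, follow-up time in days,
binary event indicator, and a set of typed covariates (continuous,
binary, or categorical with a declared level set).  Splitting is
60:20:20 by default, stratified on the event indicator with
largest-remainder allocation inside each stratum so the event rate is
preserved to within one patient per part.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CovariateSchema",
    "CohortTable",
    "SplitResult",
    "read_cohort",
    "write_cohort",
    "load_schema",
    "save_schema",
    "stratified_split",
]

MANDATORY = ("patient_id", "time", "event")


@dataclass(frozen=True)
class CovariateSchema:
    """Declared type of one covariate column.

    ``reference_level`` is the value imputation falls back to for
    categorical/binary columns: the level that does not, by itself,
    indicate elevated risk (absence of the risk factor).
    """

    name: str
    kind: str  # {"continuous", "binary", "categorical"}
    levels: tuple = ()
    reference_level: object = None

    def __post_init__(self):
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.levels:
                raise ValueError(f"{self.name}: categorical needs levels")
            if self.reference_level not in self.levels:
                raise ValueError(
                    f"{self.name}: reference_level {self.reference_level!r} "
                    f"not among levels")
        if self.kind == "binary" and self.reference_level not in (None, 0):
            raise ValueError(f"{self.name}: binary reference level must be 0")


def _coerce_column(series: pd.Series, spec: CovariateSchema) -> pd.Series:
    if spec.kind == "continuous":
        return pd.to_numeric(series, errors="coerce")
    if spec.kind == "binary":
        vals = pd.to_numeric(series, errors="coerce")
        bad = vals.dropna()[~vals.dropna().isin([0, 1])]
        if len(bad):
            raise ValueError(f"{spec.name}: non-binary values {set(bad)}")
        return vals
    # categorical: anything outside the level set becomes missing
    s = series.astype(object).where(series.notna(), other=pd.NA)
    mask = s.isin(spec.levels) | s.isna()
    if not mask.all():
        s = s.where(mask, other=pd.NA)
    return s


@dataclass
class CohortTable:
    """Validated patient-level table plus its covariate schema."""

    df: pd.DataFrame
    schema: list[CovariateSchema] = field(default_factory=list)

    def __post_init__(self):
        df = self.df
        for col in MANDATORY:
            if col not in df.columns:
                raise ValueError(f"missing mandatory column {col!r}")
        if df["patient_id"].duplicated().any():
            dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
            raise ValueError(f"duplicate patient_id {dup!r}")
        times = pd.to_numeric(df["time"], errors="raise")
        if (times < 0).any():
            row = df.loc[times < 0, "patient_id"].iloc[0]
            raise ValueError(f"negative follow-up time for patient {row!r}")
        events = pd.to_numeric(df["event"], errors="raise")
        if not events.isin([0, 1]).all():
            row = df.loc[~events.isin([0, 1]), "patient_id"].iloc[0]
            raise ValueError(f"event not in {{0,1}} for patient {row!r}")
        for spec in self.schema:
            if spec.name not in df.columns:
                raise ValueError(f"schema column {spec.name!r} not in table")

    def __len__(self):
        return len(self.df)

    @property
    def times(self) -> np.ndarray:
        return self.df["time"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.df["event"].to_numpy(dtype=int)

    @property
    def latent_groups(self) -> np.ndarray | None:
        if "latent_group" in self.df.columns:
            return self.df["latent_group"].to_numpy(dtype=int)
        return None

    def event_rate(self) -> float:
        return float(self.events.mean())

    def subset(self, mask_or_index) -> "CohortTable":
        return CohortTable(self.df.loc[mask_or_index].reset_index(drop=True),
                           self.schema)


@dataclass(frozen=True)
class SplitResult:
    train: CohortTable
    validation: CohortTable
    test: CohortTable
    fractions: tuple[float, float, float]
    seed: int

    def parts(self):
        return {"train": self.train, "validation": self.validation,
                "test": self.test}


def load_schema(path) -> list[CovariateSchema]:
    """Read a covariate schema from a YAML or JSON file."""
    text = open(path, encoding="utf-8").read()
    data = yaml.safe_load(text)
    return [CovariateSchema(d["name"], d["kind"],
                            tuple(d.get("levels", ())),
                            d.get("reference_level"))
            for d in data]


def save_schema(schema: list[CovariateSchema], path) -> None:
    data = [{"name": s.name, "kind": s.kind, "levels": list(s.levels),
             "reference_level": s.reference_level} for s in schema]
    with open(path, "w", encoding="utf-8") as fh:
        if str(path).endswith(".json"):
            json.dump(data, fh, indent=1)
        else:
            yaml.safe_dump(data, fh)


def read_cohort(path, schema: list[CovariateSchema]) -> CohortTable:
    """Read a cohort CSV, coercing covariates to their declared kinds.

    Unparseable cells become explicit missing markers (NA), left for the
    preprocessing step to impute.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    for col in MANDATORY:
        if col not in df.columns:
            raise ValueError(f"cohort file lacks mandatory column {col!r}")
    for spec in schema:
        if spec.name not in df.columns:
            raise ValueError(f"cohort file lacks schema column {spec.name!r}")
        df[spec.name] = _coerce_column(df[spec.name], spec)
    return CohortTable(df, schema)


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.df.to_csv(path, index=False)


def _largest_remainder(n: int, fractions) -> list[int]:
    """Allocate n items to parts by largest remainder; ties favour the
    earlier part (train, then validation, then test)."""
    exact = np.asarray(fractions, dtype=float) * n
    base = np.floor(exact).astype(int)
    leftover = int(round(n - base.sum()))
    remainders = exact - base
    # stable sort descending by remainder; ties keep part order
    order = np.argsort(-remainders, kind="stable")
    for i in order[:leftover]:
        base[i] += 1
    return base.tolist()


def stratified_split(cohort: CohortTable, fractions=(0.6, 0.2, 0.2),
                     seed: int = 0) -> SplitResult:
    """Outcome-stratified train/validation/test split.

    Within each event stratum rows are shuffled by `seed` and allocated
    by largest-remainder rounding, so each part's event rate matches the
    cohort's to within one patient.  Deterministic given (row order, seed).
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be three proportions summing to 1")
    events = cohort.events
    rng = np.random.default_rng(seed)
    part_idx: list[list[int]] = [[], [], []]
    for value in (1, 0):  # fixed stratum order: events first
        idx = np.flatnonzero(events == value)
        if idx.size == 0:
            raise ValueError("cohort must contain both events and censored "
                             "rows")
        if idx.size < 3:
            warnings.warn(f"stratum event={value} has fewer than 3 rows; "
                          "allocating all of it to train")
            part_idx[0].extend(idx.tolist())
            continue
        shuffled = rng.permutation(idx)
        counts = _largest_remainder(idx.size, fractions)
        start = 0
        for p, c in enumerate(counts):
            part_idx[p].extend(shuffled[start:start + c].tolist())
            start += c
    parts = [cohort.subset(sorted(ix)) for ix in part_idx]
    return SplitResult(parts[0], parts[1], parts[2], fractions, seed)
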
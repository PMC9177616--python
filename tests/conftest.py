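import numpy as np
import pytest

from lifeclust import (default_stroke_spec, simulate_cohort,
                       stratified_split, impute, fit_transform,
                       apply_transform)


@pytest.fixture(scope="session")
def small_cohort():
    """600-row default-spec cohort (fast, shared across tests)."""
    return simulate_cohort(default_stroke_spec(n=600, seed=3))


@pytest.fixture(scope="session")
def cohort_1000():
    return simulate_cohort(default_stroke_spec(n=1000, seed=5))


@pytest.fixture(scope="session")
def prepared_split(small_cohort):
    """Imputed + transformed train/val/test of the small cohort."""
    split = stratified_split(small_cohort, seed=0)
    train = impute(split.train)
    medians = {s.name: float(train.df[s.name].median())
               for s in small_cohort.schema if s.kind == "continuous"}
    val = impute(split.validation, medians=medians)
    test = impute(split.test, medians=medians)
    fm = fit_transform(train)
    return {
        "train": (train, fm),
        "validation": (val, apply_transform(fm.state, val)),
        "test": (test, apply_transform(fm.state, test)),
    }


def random_survival(rng, n, censor_frac=0.3, scale=200.0):
    """Small random right-censored dataset in whole days."""
    times = np.ceil(rng.exponential(scale, n)).clip(1, 365)
    events = (rng.random(n) >= censor_frac).astype(int)
    if events.sum() == 0:
        events[0] = 1
    return times, events
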
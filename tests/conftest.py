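import numpy as np
import pandas as pd
import pytest

from cpfrisk import Cohort


def make_cohort(times, events, exposure="early", stratum="no_depression",
                horizon=30.0, **covariates) -> Cohort:
    """Build a cohort from plain arrays, broadcasting scalars."""
    n = len(times)

    def _col(v):
        return [v] * n if np.isscalar(v) or isinstance(v, str) else list(v)

    df = pd.DataFrame({
        "subject_id": [f"s{i:05d}" for i in range(n)],
        "time": np.asarray(times, dtype=float),
        "event": np.asarray(events, dtype=int),
        "exposure": _col(exposure),
        "stratum": _col(stratum),
    })
    for name, vals in covariates.items():
        df[name] = _col(vals)
    return Cohort(df, horizon=horizon)


def random_cohort(rng, n, p_censor=0.3, p_death=0.2, tmax=30.0, day_ties=False):
    """Random small cohort for property tests."""
    times = rng.uniform(0.5, tmax, n)
    if day_ties:
        times = np.floor(times)
    u = rng.random(n)
    events = np.where(u < p_censor, 0, np.where(u < p_censor + p_death, 2, 1))
    exposure = rng.choice(["early", "late"], n)
    stratum = rng.choice(["depression", "no_depression"], n)
    return make_cohort(times, events, exposure=exposure, stratum=stratum)


@pytest.fixture
def rng():
    return np.random.default_rng(20240404)
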
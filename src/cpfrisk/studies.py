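"""Reproducible validation studies exercising the pipeline end to end.

Each function runs one self-contained study — a worked example on the
published registry margins, an exact-oracle comparison, or a Monte Carlo
over the synthetic generator — and returns plain numbers. They back the
acceptance checks and can be rerun from the command line via
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import Cohort, truncate_at_horizon
from .descriptives import build_table2
from .nonparametric import estimate_cif, estimate_cpf
from .pipeline import PipelineConfig, run_pipeline
from .pseudo import PseudoValueGEE, compute_pseudo_values
from .simulate import (
    CellHazards,
    SimulationConfig,
    confounded_scenario,
    ground_truth,
    nhfd_like_scenario,
    null_scenario,
    or_recovery_scenario,
    simulate_cohort,
)
from .twosample import pepe_mori_test

__all__ = [
    "REGISTRY_PRINTED_COUNTS",
    "registry_worked_example",
    "closed_form_recovery_study",
    "no_censoring_oracle_study",
    "linear_reduction_study",
    "type1_error_study",
    "or_recovery_study",
    "confounding_study",
    "determinism_study",
]

#: published 30-day cell counts of the national hip-fracture registry
#: cohort (n, deaths, live discharges per stratum and mobilisation arm);
#: these margins also calibrate the synthetic scenario
REGISTRY_PRINTED_COUNTS = {
    ("depression", "early"): {"n": 7_412, "deaths": 183, "discharges": 4_022},
    ("depression", "late"): {"n": 2_247, "deaths": 162, "discharges": 997},
    ("no_depression", "early"): {"n": 84_085, "deaths": 2_548,
                                 "discharges": 46_611},
    ("no_depression", "late"): {"n": 22_530, "deaths": 2_073,
                                "discharges": 9_424},
}


def cohort_from_counts(counts=None) -> Cohort:
    """Reconstruct a cohort with exactly the given per-cell event counts.

    Times are schematic (events on day 10, deaths on day 5, everyone
    else administratively censored at day 30): count-based descriptive
    statistics do not depend on them.
    """
    counts = REGISTRY_PRINTED_COUNTS if counts is None else counts
    frames = []
    offset = 0
    for (stratum, exposure), c in counts.items():
        n = c["n"]
        events = np.zeros(n, dtype=int)
        events[: c["discharges"]] = 1
        events[c["discharges"]: c["discharges"] + c["deaths"]] = 2
        times = np.where(events == 1, 10.0, np.where(events == 2, 5.0, 30.0))
        frames.append(pd.DataFrame({
            "subject_id": [f"r{offset + i:07d}" for i in range(n)],
            "time": times, "event": events,
            "exposure": exposure, "stratum": stratum,
        }))
        offset += n
    return Cohort(pd.concat(frames, ignore_index=True))


def registry_worked_example() -> dict[str, float]:
    """Stratum-level percentages recomputed from the published counts.

    Returns the early/late mobilisation shares and the 30-day death and
    live-discharge shares per stratum, as printed percentages.
    """
    table = build_table2(cohort_from_counts()).table
    out: dict[str, float] = {}
    for stratum in ("depression", "no_depression"):
        sub = table[table["stratum"] == stratum].set_index("group")
        out[f"early_mobilised_pct_{stratum}"] = float(sub.loc["early", "n_pct"])
        out[f"late_mobilised_pct_{stratum}"] = float(sub.loc["late", "n_pct"])
        out[f"death_pct_{stratum}"] = float(sub.loc["overall", "deaths_pct"])
        out[f"discharge_pct_{stratum}"] = float(
            sub.loc["overall", "discharges_pct"])
    return out


def closed_form_recovery_study(n: int = 5000, seed: int = 1) -> dict[str, float]:
    """CPF(30) on one exponential cohort versus its closed form."""
    cell = ("no_depression", "early")
    cfg = SimulationConfig(n_per_cell={cell: n},
                           hazards={cell: CellHazards(0.10, 0.01, 0.02)},
                           seed=seed)
    curve = estimate_cpf(estimate_cif(simulate_cohort(cfg)), ci_method=None)
    return {
        "cpf30": float(curve.cpf_at(30.0)),
        "truth": float(ground_truth(cfg).cpf(30, cell)),
    }


def no_censoring_oracle_study(n_cohorts: int = 500, seed: int = 2) -> float:
    """Max |CPF - counting oracle| over random small uncensored cohorts."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cohorts):
        n = int(rng.integers(3, 51))
        times = rng.uniform(0.5, 30, n)
        events = np.where(rng.random(n) < 0.25, 2, 1)
        coh = Cohort(pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "time": times, "event": events,
            "exposure": "early", "stratum": "no_depression"}))
        curve = estimate_cpf(estimate_cif(coh), ci_method=None)
        for t in np.unique(times):
            disch = ((events == 1) & (times <= t)).sum()
            deaths = ((events == 2) & (times <= t)).sum()
            oracle = disch / (n - deaths)
            worst = max(worst, abs(float(curve.cpf_at(t)) - oracle))
    return worst


def linear_reduction_study(seed: int = 3, n: int = 400) -> float:
    """Single-cause, uncensored pipeline versus ordinary logistic fit.

    With one cause, no censoring, and a single grid time, the
    pseudo-values are the event indicators and the GEE must reproduce
    plain logistic regression; returns the max coefficient difference.
    """
    import patsy
    import statsmodels.api as sm

    rng = np.random.default_rng(seed)
    times = rng.exponential(12, n)
    age = np.clip(rng.normal(83, 8, n), 60, 105)
    exposure = np.where(rng.random(n) < 0.6, "early", "late")
    coh = Cohort(pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)], "time": times,
        "event": 1, "exposure": exposure, "stratum": "no_depression",
        "age": age}))
    pv = compute_pseudo_values(coh, grid=(10.0,))
    res = PseudoValueGEE(pv, coh, formula="early + age").fit()
    df = coh.data.assign(ind=(times <= 10.0).astype(float),
                         early=(coh.data["exposure"] == "early").astype(float))
    y, X = patsy.dmatrices("ind ~ early + age", data=df,
                           return_type="dataframe")
    glm = sm.GLM(np.asarray(y).ravel(), X, family=sm.families.Binomial()).fit()
    return float(np.max(np.abs(res.params.to_numpy() - glm.params.to_numpy())))


def type1_error_study(n_replicates: int = 2000, n_per_group: int = 200,
                      n_permutations: int = 500, seed: int = 4,
                      alpha: float = 0.05) -> float:
    """Rejection rate of the permutation test under equal hazards."""
    rejections = 0
    for rep in range(n_replicates):
        cfg = null_scenario(n_per_group, seed=(seed * 100_003 + rep) % 2**31)
        coh = simulate_cohort(cfg)
        a = coh.select((coh.data["exposure"] == "early").to_numpy())
        b = coh.select((coh.data["exposure"] == "late").to_numpy())
        res = pepe_mori_test(a, b, method="permutation",
                             n_permutations=n_permutations,
                             seed=(seed * 55_001 + rep) % 2**31)
        rejections += res.p_value < alpha
    return rejections / n_replicates


def _day30_or(res) -> tuple[float, float, float]:
    name = [nm for nm in res.exog_names
            if "early" in nm and "grid_time" in nm and "30.0" in nm][0]
    ci = res.conf_int().loc[name]
    return (float(np.exp(res.params[name])),
            float(np.exp(ci["lower"])), float(np.exp(ci["upper"])))


def or_recovery_study(n_replicates: int = 200, n: int = 2000,
                      seed: int = 5, target_or: float = 2.0) -> dict[str, float]:
    """Recovery of a configured day-30 CPF odds ratio.

    Fits the per-grid-time (time-varying effect) model and reads the
    day-30 odds ratio; returns its replicate mean and the fraction of
    Wald CIs covering the configured truth.
    """
    ors, covered = [], 0
    for rep in range(n_replicates):
        cfg = or_recovery_scenario(n, seed=(seed * 77_003 + rep) % 2**31,
                                   target_or=target_or)
        coh = simulate_cohort(cfg)
        res = PseudoValueGEE.from_cohort(coh, formula="C(grid_time):early").fit()
        est, lo, hi = _day30_or(res)
        ors.append(est)
        covered += lo <= target_or <= hi
    return {"mean_or": float(np.mean(ors)),
            "coverage": covered / n_replicates,
            "target": target_or}


def confounding_study(n_replicates: int = 200, n: int = 2000,
                      seed: int = 6, target_or: float = 2.0) -> dict[str, float]:
    """Adjusted versus unadjusted day-30 OR under care-home confounding.

    The truth is the configured day-30 odds ratio at the reference
    covariate profile; returns the fraction of replicates where the
    residence-adjusted estimate is closer to it (log scale) than the
    crude one, plus both replicate means.
    """
    closer = 0
    unadj, adj = [], []
    log_t = np.log(target_or)
    for rep in range(n_replicates):
        cfg = confounded_scenario(n, seed=(seed * 91_009 + rep) % 2**31,
                                  target_or=target_or)
        coh = simulate_cohort(cfg)
        ru = PseudoValueGEE.from_cohort(coh, formula="C(grid_time):early").fit()
        ra = PseudoValueGEE.from_cohort(
            coh, formula="C(grid_time):early + C(prefracture_residence)").fit()
        ou, *_ = _day30_or(ru)
        oa, *_ = _day30_or(ra)
        unadj.append(ou)
        adj.append(oa)
        closer += abs(np.log(oa) - log_t) < abs(np.log(ou) - log_t)
    return {"fraction_adjusted_closer": closer / n_replicates,
            "mean_unadjusted_or": float(np.mean(unadj)),
            "mean_adjusted_or": float(np.mean(adj)),
            "target": target_or}


def determinism_study(seed: int = 7, n: int = 600) -> float:
    """Max numeric difference between two identically-seeded pipeline runs."""
    def run():
        return run_pipeline(PipelineConfig(
            scenario=nhfd_like_scenario(n, seed=seed), adjustment=None,
            n_permutations=200, seed=seed))

    b1, b2 = run(), run()
    diffs = [np.max(np.abs(b1.curves_frame["cpf"].to_numpy()
                           - b2.curves_frame["cpf"].to_numpy()))]
    diffs.append(np.max(np.abs(
        b1.regression.per_stratum["or"].to_numpy()
        - b2.regression.per_stratum["or"].to_numpy())))
    for s in b1.tests:
        if hasattr(b1.tests[s], "p_value"):
            diffs.append(abs(b1.tests[s].p_value - b2.tests[s].p_value))
            diffs.append(abs(b1.tests[s].statistic - b2.tests[s].statistic))
    return float(np.max(diffs))
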
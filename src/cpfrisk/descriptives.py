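"""Descriptive tables in the registry-report style.

Table-1-style characteristics (count and percent within column for
categoricals, median and IQR for continuous variables, chi-square /
Mann-Whitney early-vs-late comparisons within stratum) and a
Table-2-style discharge summary (30-day deaths, live discharges, and the
live-discharge rate per 1,000 patient-days with a person-time Poisson
confidence interval).

Percentages are printed to one decimal place; underlying full-precision
values are kept in the machine-readable frames.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    COVARIATE_COLUMNS,
    Cohort,
    Event,
    EXPOSURE_LEVELS,
    STRATUM_LEVELS,
    truncate_at_horizon,
)

__all__ = [
    "DescriptiveTable",
    "build_table1",
    "build_table2",
    "percent",
    "person_days",
]

_CONTINUOUS = ("age", "n_comorbidities")


def percent(count: float, total: float, decimals: int = 1) -> float:
    """Percentage of ``count`` in ``total`` rounded to ``decimals`` places."""
    if total == 0:
        return float("nan")
    return round(100.0 * count / total, decimals)


def _fmt_count_pct(count: int, total: int) -> str:
    return f"{count:,} ({percent(count, total):.1f})"


@dataclasses.dataclass
class DescriptiveTable:
    """Rendered rows plus machine-readable values and comparison tests."""

    table: pd.DataFrame
    comparisons: pd.DataFrame | None = None


def build_table1(cohort: Cohort, suppress_below: int | None = None) -> DescriptiveTable:
    """Characteristics by (stratum, exposure) cell, registry-table style.

    Percentages are within column on non-missing denominators. The
    comparison column tests early versus late within each stratum:
    chi-square for categoricals, Mann-Whitney U for continuous
    variables. ``suppress_below`` masks cells with fewer than that many
    subjects (small-cell suppression), off by default.
    """
    cells = [(s, e) for s in STRATUM_LEVELS for e in EXPOSURE_LEVELS]
    sub = {c: cohort.data[(cohort.data["stratum"] == c[0])
                          & (cohort.data["exposure"] == c[1])] for c in cells}
    colnames = {c: f"{c[0]}/{c[1]}" for c in cells}
    rows: list[dict] = []
    comps: list[dict] = []

    present = [v for v in COVARIATE_COLUMNS if v in cohort.data.columns]
    header = {"variable": "n", "level": ""}
    for c in cells:
        header[colnames[c]] = f"{len(sub[c]):,}"
    rows.append(header)

    for var in present:
        if var in _CONTINUOUS:
            row = {"variable": var, "level": "median (IQR)"}
            for c in cells:
                vals = pd.to_numeric(sub[c][var], errors="coerce").dropna()
                if len(vals):
                    q1, med, q3 = np.percentile(vals, [25, 50, 75])
                    row[colnames[c]] = f"{med:.1f} ({q1:.1f}-{q3:.1f})"
                else:
                    row[colnames[c]] = ""
            rows.append(row)
            for s in STRATUM_LEVELS:
                a = pd.to_numeric(sub[(s, "early")][var], errors="coerce").dropna()
                b = pd.to_numeric(sub[(s, "late")][var], errors="coerce").dropna()
                if len(a) and len(b):
                    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                    comps.append({"variable": var, "stratum": s,
                                  "test": "mann-whitney", "statistic": float(u),
                                  "p_value": float(p)})
        else:
            col = cohort.data[var]
            levels = sorted(col.dropna().astype(str).unique())
            for lev in levels:
                row = {"variable": var, "level": lev}
                for c in cells:
                    v = sub[c][var].dropna().astype(str)
                    cnt = int((v == lev).sum())
                    if suppress_below is not None and 0 < cnt < suppress_below:
                        row[colnames[c]] = "<suppressed>"
                    else:
                        row[colnames[c]] = _fmt_count_pct(cnt, len(v)) if len(v) else ""
                rows.append(row)
            for s in STRATUM_LEVELS:
                a = sub[(s, "early")][var].dropna().astype(str)
                b = sub[(s, "late")][var].dropna().astype(str)
                if len(a) and len(b):
                    tab = pd.crosstab(
                        np.concatenate([a, b]),
                        np.concatenate([np.zeros(len(a)), np.ones(len(b))]))
                    if tab.shape[0] > 1 and tab.shape[1] > 1:
                        c2, p, _, _ = stats.chi2_contingency(tab)
                        comps.append({"variable": var, "stratum": s,
                                      "test": "chi-square",
                                      "statistic": float(c2),
                                      "p_value": float(p)})
    return DescriptiveTable(table=pd.DataFrame(rows),
                            comparisons=pd.DataFrame(comps))


def person_days(times: np.ndarray) -> float:
    """Total in-hospital follow-up.

    Days accrue on [0, t) — a subject discharged on day 10 contributes
    10 patient-days. The convention is documented rather than imposed
    by the registry.
    """
    return float(np.sum(times))


def _poisson_rate_ci(d: int, pdays: float, alpha: float = 0.05):
    """Exact Poisson CI for a rate per 1,000 patient-days."""
    if pdays <= 0:
        return float("nan"), float("nan")
    lo = stats.chi2.ppf(alpha / 2, 2 * d) / 2 if d > 0 else 0.0
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * (d + 1)) / 2
    return 1000.0 * lo / pdays, 1000.0 * hi / pdays


def build_table2(cohort: Cohort, horizon: float | None = None) -> DescriptiveTable:
    """30-day discharge summary by stratum and mobilisation timing.

    Per row: n (% of the stratum), deaths and live discharges by the
    horizon (counts, % of the stratum total), and the live-discharge
    rate per 1,000 patient-days with an exact Poisson CI. Zero
    patient-days flags the rate as undefined.
    """
    h = cohort.horizon if horizon is None else horizon
    trunc = truncate_at_horizon(cohort, h)
    rows = []
    for stratum in STRATUM_LEVELS:
        sdf = trunc.data[trunc.data["stratum"] == stratum]
        if len(sdf) == 0:
            continue
        n_str = len(sdf)
        blocks = [("overall", sdf)] + [
            (exp, sdf[sdf["exposure"] == exp]) for exp in EXPOSURE_LEVELS
        ]
        for label, df in blocks:
            n = len(df)
            deaths = int((df["event"] == int(Event.DEATH)).sum())
            disch = int((df["event"] == int(Event.DISCHARGE)).sum())
            pdays = person_days(df["time"].to_numpy(float))
            if pdays > 0:
                rate = 1000.0 * disch / pdays
                lo, hi = _poisson_rate_ci(disch, pdays)
                rate_str = f"{rate:.1f} ({lo:.1f}-{hi:.1f})"
            else:
                rate, lo, hi = float("nan"), float("nan"), float("nan")
                rate_str = "undefined (0 patient-days)"
            rows.append({
                "stratum": stratum, "group": label,
                "n": n, "n_pct": percent(n, n_str),
                "deaths": deaths, "deaths_pct": percent(deaths, n_str),
                "discharges": disch, "discharges_pct": percent(disch, n_str),
                "person_days": pdays,
                "rate_per_1000d": rate, "rate_ci_lower": lo, "rate_ci_upper": hi,
                "rendered": (f"{n:,} ({percent(n, n_str):.1f})\t"
                             f"{deaths:,} ({percent(deaths, n_str):.1f})\t"
                             f"{disch:,} ({percent(disch, n_str):.1f})\t"
                             + rate_str),
            })
    return DescriptiveTable(table=pd.DataFrame(rows))
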
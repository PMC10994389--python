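"""Jackknife pseudo-observations of the CPF and GEE regression on them.

The conditional probability of live discharge is an incompletely
observed per-subject outcome (censoring, competing death). Replacing it
with jackknife pseudo-observations

    PV_i(t) = n * CP_hat(t) - (n - 1) * CP_hat^(-i)(t)

on a fixed time grid (default days 3, 4, 6, 8, 12, 16, 20, 24, 30)
turns it into a quantity standard regression machinery can model: a
generalized estimating equation with logit link, independence working
correlation, and a cluster-robust sandwich covariance clustered on the
subject across grid times. The exposure coefficient then exponentiates
to the early-versus-late odds ratio of the conditional probability of
discharge, shared across grid times (one intercept per grid time), with
an optional time-varying-effect parametrisation for per-day odds ratios.

Pseudo-values routinely fall outside [0, 1]; that is expected and the
quasi-score estimation does not mind. The leave-one-out estimates are
full recomputations (subjects sharing a (time, event) pattern are
deduplicated, which is exact).

The model/results pair follows the usual fit-and-summarise shape:

    >>> model = PseudoValueGEE.from_cohort(cohort, formula="early + age")
    >>> res = model.fit()
    >>> res.odds_ratios()
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import patsy
import scipy.linalg
import statsmodels.api as sm
from scipy.stats import chi2, norm

from .cohort import Cohort, complete_cases
from .nonparametric import _cpf_from_cifs, estimate_cif

__all__ = [
    "DEFAULT_GRID",
    "ADJUSTMENT_RHS",
    "PseudoValueTable",
    "PseudoValueGEE",
    "PseudoValueGEEResults",
    "compute_pseudo_values",
    "run_subgroup_and_interaction_analysis",
    "SubgroupReport",
]

#: default evaluation grid in days after surgery
DEFAULT_GRID = (3.0, 4.0, 6.0, 8.0, 12.0, 16.0, 20.0, 24.0, 30.0)

#: the full adjustment set as a model formula right-hand side
ADJUSTMENT_RHS = (
    "age + C(sex) + C(ethnicity) + C(deprivation) + n_comorbidities"
    " + C(asa_grade) + C(prefracture_residence) + C(fracture_type)"
    " + C(prefracture_mobility) + C(hospital_volume)"
    " + surgery_within_36h + weekend_admission + C(admission_year)"
)


@dataclasses.dataclass
class PseudoValueTable:
    """Subject-by-grid-time matrix of pseudo-observations.

    Column means are close to the full-sample CPF at each grid time
    (jackknife near-unbiasedness); individual values may lie outside
    [0, 1]. ``beyond_last_time`` flags grid times past the last observed
    time, where the CPF is carried forward from its last value.
    """

    grid: np.ndarray
    values: np.ndarray
    subject_ids: np.ndarray
    n: int
    cpf_at_grid: np.ndarray
    beyond_last_time: bool = False


def compute_pseudo_values(
    cohort: Cohort,
    grid=DEFAULT_GRID,
    denominator: str = "1-cif_death",
    method: str = "grouped",
) -> PseudoValueTable:
    """Jackknife pseudo-observations of the CPF at the grid times.

    ``method="grouped"`` (default) deduplicates identical (time, event)
    patterns before the leave-one-out recomputation — exact and fast;
    ``method="naive"`` loops over every subject without deduplication
    and serves as the reference implementation.
    """
    grid = np.asarray(grid, dtype=float)
    n = len(cohort)
    if n < 2:
        raise ValueError("pseudo-values require at least 2 records")
    cif = estimate_cif(cohort)
    cp_full = _cpf_from_cifs(cif.cif_at(1, grid), cif.cif_at(2, grid), denominator)

    if method == "grouped":
        loo1, loo2 = cif.loo_cif_at(grid)
    elif method == "naive":
        t = cif._raw_times
        e = cif._raw_events
        loo1 = np.empty((n, len(grid)))
        loo2 = np.empty((n, len(grid)))
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            mask[i] = False
            sub = estimate_cif(cohort.select(mask))
            loo1[i] = sub.cif_at(1, grid)
            loo2[i] = sub.cif_at(2, grid)
            mask[i] = True
    else:
        raise ValueError(f"unknown method {method!r}")

    cp_loo = _cpf_from_cifs(loo1, loo2, denominator)
    values = n * cp_full[None, :] - (n - 1) * cp_loo
    return PseudoValueTable(
        grid=grid,
        values=values,
        subject_ids=cohort.data["subject_id"].to_numpy(),
        n=n,
        cpf_at_grid=cp_full,
        beyond_last_time=bool(grid.max() > cif.times.max()) if len(cif.times) else True,
    )


def _stacked_frame(pv: PseudoValueTable, cohort: Cohort) -> pd.DataFrame:
    """Long-format frame: one row per subject per grid time."""
    n, g = pv.values.shape
    df = cohort.data.copy()
    # numeric indicator coding keeps coefficient names readable
    df["early"] = (df["exposure"] == "early").astype(float)
    df["late"] = 1.0 - df["early"]
    df["depression"] = (df["stratum"] == "depression").astype(float)
    for col in df.columns:
        if str(df[col].dtype) == "Int64":
            df[col] = df[col].astype(float)
        elif str(df[col].dtype) == "boolean":
            df[col] = df[col].astype(object).map(
                {True: 1.0, False: 0.0, pd.NA: np.nan}).astype(float)
    stacked = df.loc[df.index.repeat(g)].reset_index(drop=True)
    stacked["grid_time"] = np.tile(pv.grid, n)
    stacked["pv"] = pv.values.reshape(-1)
    return stacked


def _formula_columns(formula: str, cohort: Cohort) -> list[str]:
    """Cohort columns referenced by a formula right-hand side."""
    candidates = list(cohort.data.columns) + ["early", "late", "depression"]
    import re

    tokens = set(re.findall(r"[A-Za-z_][A-Za-z0-9_]*", formula))
    mapped = {"early": "exposure", "late": "exposure", "depression": "stratum"}
    cols = []
    for tok in tokens:
        col = mapped.get(tok, tok)
        if tok in candidates and col in cohort.data.columns and col not in cols:
            cols.append(col)
    return cols


class PseudoValueGEE:
    """Marginal logit model for CPF pseudo-observations.

    Parameters
    ----------
    pv : PseudoValueTable
    cohort : Cohort
        Must be the same cohort (same order) the table was computed on.
    formula : str
        Right-hand side on top of the grid-time intercepts, e.g.
        ``"early"``, ``"early*depression + age + C(sex)"``. The columns
        ``early``, ``late`` and ``depression`` are 0/1 indicators
        derived from exposure and stratum.

    Use :meth:`from_cohort` to apply the complete-case filter and
    compute the pseudo-values in one step.
    """

    def __init__(self, pv: PseudoValueTable, cohort: Cohort,
                 formula: str = "early"):
        self.pv = pv
        self.cohort = cohort
        self.formula = formula
        self.complete_case_log: dict[str, int] = {}
        self._stacked = _stacked_frame(pv, cohort)

    @classmethod
    def from_cohort(
        cls,
        cohort: Cohort,
        formula: str = "early",
        grid=DEFAULT_GRID,
        denominator: str = "1-cif_death",
    ) -> "PseudoValueGEE":
        """Complete-case filter on the model columns, then pseudo-values.

        The jackknife is taken on the analysis (complete-case) sample;
        the dropped-row counts are recorded in ``complete_case_log``.
        """
        cols = _formula_columns(formula, cohort)
        filtered, log = complete_cases(cohort, cols) if cols else (cohort, {})
        model = cls(compute_pseudo_values(filtered, grid=grid,
                                          denominator=denominator),
                    filtered, formula=formula)
        model.complete_case_log = log
        return model

    def _design(self):
        grid_term = "C(grid_time) + " if len(self.pv.grid) > 1 else ""
        rhs = self.formula.strip() or "1"
        full = f"pv ~ {grid_term}{rhs}"
        y, X = patsy.dmatrices(full, data=self._stacked,
                               return_type="dataframe")
        # pivoted QR to detect and drop collinear columns
        _, r, piv = scipy.linalg.qr(X.to_numpy(), mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
        rank = int((diag > tol).sum())
        keep = np.sort(piv[:rank])
        dropped = [X.columns[j] for j in sorted(set(piv[rank:]))]
        return y, X.iloc[:, keep], dropped

    def fit(self, maxiter: int = 100, ctol: float = 1e-8) -> "PseudoValueGEEResults":
        y, X, dropped = self._design()
        groups = self._stacked["subject_id"].to_numpy()
        model = sm.GEE(np.asarray(y).ravel(), X, groups=groups,
                       family=sm.families.Binomial(),
                       cov_struct=sm.cov_struct.Independence())
        # starting values from least squares on the empirical logit:
        # the default start can diverge with wide dummy designs
        yv = np.clip(np.asarray(y).ravel(), 0.02, 0.98)
        eta = np.log(yv / (1.0 - yv))
        start, *_ = np.linalg.lstsq(X.to_numpy(), eta, rcond=None)
        converged = True
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = model.fit(maxiter=maxiter, ctol=ctol, start_params=start)
        for w in caught:
            if "onverg" in str(w.message):
                converged = False
        return PseudoValueGEEResults(
            model=self, _res=res, exog_names=list(X.columns),
            dropped_terms=dropped, converged=converged,
        )


@dataclasses.dataclass
class PseudoValueGEEResults:
    """Fitted pseudo-value GEE: coefficients, robust covariance, tests."""

    model: PseudoValueGEE
    _res: object
    exog_names: list[str]
    dropped_terms: list[str]
    converged: bool

    @property
    def params(self) -> pd.Series:
        return pd.Series(np.asarray(self._res.params), index=self.exog_names)

    @property
    def bse(self) -> pd.Series:
        # near-saturated dummy columns (single-subject levels) can leave
        # floating noise of either sign at ~1e-30 on the sandwich diagonal
        d = np.diag(np.asarray(self._res.cov_params())).copy()
        tol = 1e-12 * max(float(d.max()), 1.0)
        d[(d < 0) & (d > -tol)] = 0.0
        with np.errstate(invalid="ignore"):
            return pd.Series(np.sqrt(d), index=self.exog_names)

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(np.asarray(self._res.pvalues), index=self.exog_names)

    @property
    def cov_robust(self) -> pd.DataFrame:
        c = np.asarray(self._res.cov_params())
        return pd.DataFrame(c, index=self.exog_names, columns=self.exog_names)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.model._stacked["subject_id"]))

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        """exp(beta) with Wald CIs for every non-intercept term."""
        ci = self.conf_int(alpha)
        keep = [c for c in self.exog_names
                if c != "Intercept" and not c.startswith("C(grid_time)")]
        return pd.DataFrame({
            "or": np.exp(self.params[keep]),
            "ci_lower": np.exp(ci.loc[keep, "lower"]),
            "ci_upper": np.exp(ci.loc[keep, "upper"]),
            "p_value": self.pvalues[keep],
        })

    def wald_test_terms(self, names: list[str]) -> tuple[float, int, float]:
        """Joint Wald chi-squared that the named coefficients are zero."""
        idx = [self.exog_names.index(nm) for nm in names]
        beta = np.asarray(self._res.params)[idx]
        cov = np.asarray(self._res.cov_params())[np.ix_(idx, idx)]
        stat = float(beta @ np.linalg.solve(cov, beta))
        df = len(idx)
        return stat, df, float(chi2.sf(stat, df))

    def wald_interaction(self) -> tuple[float, int, float]:
        """Wald chi-squared for the exposure-by-stratum interaction block."""
        names = [c for c in self.exog_names
                 if ":" in c and "early" in c and "depression" in c]
        if not names:
            raise ValueError("no exposure-by-stratum interaction term in model")
        return self.wald_test_terms(names)

    def summary(self):
        return self._res.summary()


@dataclasses.dataclass
class SubgroupReport:
    """Per-stratum ORs, the pooled interaction test, and OR trajectories."""

    per_stratum: pd.DataFrame
    interaction: dict | None
    trajectories: pd.DataFrame | None
    notices: list[str]


def _exposure_or_row(res: PseudoValueGEEResults, label: str,
                     stratum: str) -> dict:
    orr = res.odds_ratios()
    row = orr.loc["early"]
    return {
        "stratum": stratum, "model": label,
        "or": float(row["or"]), "ci_lower": float(row["ci_lower"]),
        "ci_upper": float(row["ci_upper"]), "p_value": float(row["p_value"]),
        "converged": res.converged, "n": res.model.pv.n,
    }


def run_subgroup_and_interaction_analysis(
    cohort: Cohort,
    grid=DEFAULT_GRID,
    adjustment: str | None = "full",
    min_complete: int = 30,
) -> SubgroupReport:
    """Unadjusted and adjusted early-vs-late ORs per stratum, pooled
    interaction model with Wald test, and per-grid-time OR trajectories.

    ``adjustment`` is a formula RHS, ``"full"`` for the full adjustment
    set, or None for unadjusted-only. A stratum with fewer than
    ``min_complete`` complete cases is skipped with a notice; with a
    single populated stratum the interaction section is unavailable.
    """
    adj_rhs = ADJUSTMENT_RHS if adjustment == "full" else adjustment
    notices: list[str] = []
    rows: list[dict] = []
    traj_rows: list[dict] = []
    strata_done: list[str] = []

    for stratum in ("depression", "no_depression"):
        sub = cohort.select((cohort.data["stratum"] == stratum).to_numpy())
        if len(sub) == 0:
            notices.append(f"stratum {stratum}: no records")
            continue
        if sub.data["exposure"].nunique() < 2:
            notices.append(f"stratum {stratum}: missing exposure arm")
            continue
        unadj = PseudoValueGEE.from_cohort(sub, formula="early", grid=grid)
        if unadj.pv.n < min_complete:
            notices.append(
                f"stratum {stratum}: only {unadj.pv.n} complete cases (<{min_complete}), skipped")
            continue
        rows.append(_exposure_or_row(unadj.fit(), "unadjusted", stratum))
        if adj_rhs:
            adj = PseudoValueGEE.from_cohort(
                sub, formula=f"early + {adj_rhs}", grid=grid)
            if adj.pv.n < min_complete:
                notices.append(
                    f"stratum {stratum}: only {adj.pv.n} complete cases for the"
                    " adjusted model, skipped")
            else:
                rows.append(_exposure_or_row(adj.fit(), "adjusted", stratum))
        # per-grid-time (time-varying-effect) OR trajectory, unadjusted
        tv = PseudoValueGEE.from_cohort(
            sub, formula="C(grid_time):early", grid=grid)
        tv_res = tv.fit()
        ci = tv_res.conf_int()
        for nm in tv_res.exog_names:
            if "early" in nm and "grid_time" in nm:
                t = float(nm.split("[")[1].split("]")[0].lstrip("T."))
                traj_rows.append({
                    "stratum": stratum, "time": t,
                    "or": float(np.exp(tv_res.params[nm])),
                    "ci_lower": float(np.exp(ci.loc[nm, "lower"])),
                    "ci_upper": float(np.exp(ci.loc[nm, "upper"])),
                })
        strata_done.append(stratum)

    interaction = None
    if len(strata_done) == 2:
        rhs = "early*depression" + (f" + {adj_rhs}" if adj_rhs else "")
        pooled = PseudoValueGEE.from_cohort(cohort, formula=rhs, grid=grid)
        res = pooled.fit()
        stat, df, p = res.wald_interaction()
        interaction = {"wald_chi2": stat, "df": df, "p_value": p,
                       "converged": res.converged, "n": res.model.pv.n}
    else:
        notices.append("interaction model unavailable: fewer than two strata analysed")

    return SubgroupReport(
        per_stratum=pd.DataFrame(rows),
        interaction=interaction,
        trajectories=pd.DataFrame(traj_rows).sort_values(["stratum", "time"])
        if traj_rows else None,
        notices=notices,
    )
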
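"""Nonparametric competing-risks estimators.

Aalen-Johansen cumulative incidence for the two causes (live discharge,
in-hospital death), all-cause Kaplan-Meier survival, and the conditional
probability function (CPF)

    CP(t) = CIF_discharge(t) / (1 - CIF_death(t)),

the probability of having been discharged alive by day t conditional on
not having died in hospital by then. Pointwise confidence intervals come
from the delta method on the ratio, with the variance and covariance of
the two cumulative incidences estimated by the leave-one-out jackknife
(the same engine that powers the pseudo-observations), transformed on
the complementary log-log scale by default.

Ties are handled in shared risk sets; censorings at an event time leave
the risk set after the events at that time (standard convention).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.stats import norm

from .cohort import Cohort, EXPOSURE_LEVELS, STRATUM_LEVELS

__all__ = [
    "CIFEstimate",
    "CPFCurve",
    "GroupedCPF",
    "estimate_cif",
    "estimate_cpf",
    "cpf_by_group",
    "step_eval",
]


def step_eval(times: np.ndarray, values: np.ndarray, at, fill: float = 0.0):
    """Evaluate a right-continuous step function at query times.

    ``values[j]`` holds on ``[times[j], times[j+1])``; before ``times[0]``
    the function equals ``fill``.
    """
    at = np.asarray(at, dtype=float)
    idx = np.searchsorted(times, at, side="right") - 1
    out = np.where(idx >= 0, values[np.clip(idx, 0, len(values) - 1)], fill)
    return out if out.ndim else float(out)


def _aj_arrays(times: np.ndarray, events: np.ndarray):
    """Aalen-Johansen curves from raw (time, event) arrays.

    Returns unique times, risk-set sizes, cause-specific event counts,
    censoring counts, all-cause KM survival, and both CIFs, all as
    right-continuous step values at the unique times.
    """
    ut, inv = np.unique(times, return_inverse=True)
    m = len(ut)
    d1 = np.bincount(inv, weights=(events == 1).astype(float), minlength=m)
    d2 = np.bincount(inv, weights=(events == 2).astype(float), minlength=m)
    c = np.bincount(inv, weights=(events == 0).astype(float), minlength=m)
    removed = d1 + d2 + c
    n_risk = len(times) - np.concatenate(([0.0], np.cumsum(removed)[:-1]))
    d = d1 + d2
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n_risk > 0, d / np.where(n_risk > 0, n_risk, 1.0), 0.0)
        surv = np.cumprod(1.0 - frac)
        s_before = np.concatenate(([1.0], surv[:-1]))
        inc1 = np.where(n_risk > 0, s_before * d1 / np.where(n_risk > 0, n_risk, 1.0), 0.0)
        inc2 = np.where(n_risk > 0, s_before * d2 / np.where(n_risk > 0, n_risk, 1.0), 0.0)
    return ut, n_risk, d1, d2, c, surv, np.cumsum(inc1), np.cumsum(inc2)


@dataclasses.dataclass
class CIFEstimate:
    """Aalen-Johansen estimate for both causes on the event-time grid.

    ``survival + cif_discharge + cif_death = 1`` at every time (within
    numerical tolerance); each CIF is nondecreasing. Variance terms per
    cause are available through :meth:`jackknife_cov`, computed by
    leave-one-out on demand.
    """

    times: np.ndarray
    n_at_risk: np.ndarray
    d_discharge: np.ndarray
    d_death: np.ndarray
    n_censored: np.ndarray
    survival: np.ndarray
    cif_discharge: np.ndarray
    cif_death: np.ndarray
    n: int
    all_censored: bool = False
    _raw_times: np.ndarray = dataclasses.field(default=None, repr=False)
    _raw_events: np.ndarray = dataclasses.field(default=None, repr=False)

    def cif_at(self, cause: int, at):
        vals = self.cif_discharge if cause == 1 else self.cif_death
        return step_eval(self.times, vals, at, fill=0.0)

    def survival_at(self, at):
        return step_eval(self.times, self.survival, at, fill=1.0)

    def loo_cif_at(self, at: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Leave-one-out CIFs for every subject at the query times.

        Returns two (n, len(at)) arrays: subject i's row holds the
        cumulative incidence recomputed on the cohort without subject i.
        Subjects sharing the same (time, event) pair yield identical
        leave-one-out estimates, so only distinct patterns are
        recomputed (exact, not an approximation).
        """
        return _loo_cif_grid(self._raw_times, self._raw_events, np.asarray(at, float))

    def jackknife_cov(self, at: np.ndarray):
        """Jackknife variances of the two CIFs, and their covariance, at ``at``."""
        loo1, loo2 = self.loo_cif_at(at)
        n = self.n
        f = (n - 1) / n
        m1, m2 = loo1.mean(axis=0), loo2.mean(axis=0)
        var1 = f * ((loo1 - m1) ** 2).sum(axis=0)
        var2 = f * ((loo2 - m2) ** 2).sum(axis=0)
        cov12 = f * ((loo1 - m1) * (loo2 - m2)).sum(axis=0)
        return var1, var2, cov12


def estimate_cif(cohort: Cohort) -> CIFEstimate:
    """Aalen-Johansen cumulative incidence of discharge and death.

    An all-censored cohort yields the degenerate estimate (both CIFs
    identically zero) with ``all_censored`` set and a warning.
    """
    t = cohort.data["time"].to_numpy(dtype=float)
    e = cohort.data["event"].to_numpy(dtype=int)
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite follow-up times")
    all_censored = not np.any(e != 0)
    if all_censored:
        warnings.warn("all records censored; CIF estimate is degenerate (0)",
                      stacklevel=2)
    ut, n_risk, d1, d2, c, surv, cif1, cif2 = _aj_arrays(t, e)
    return CIFEstimate(
        times=ut, n_at_risk=n_risk, d_discharge=d1, d_death=d2,
        n_censored=c, survival=surv, cif_discharge=cif1, cif_death=cif2,
        n=len(t), all_censored=all_censored, _raw_times=t, _raw_events=e,
    )


def _loo_cif_grid(times: np.ndarray, events: np.ndarray, grid: np.ndarray):
    """Leave-one-out CIFs at grid times for all subjects.

    Subjects sharing a (time, event) pattern have identical leave-one-out
    estimates, so each distinct pattern is recomputed once, on the shared
    unique-time grid: dropping a subject observed at time u lowers the
    risk set at every time <= u by one and (for an event) the event count
    at u by one. This is exact full recomputation, not an approximation.
    """
    n = len(times)
    if n < 2:
        raise ValueError("leave-one-out requires at least 2 records")
    ut, inv = np.unique(times, return_inverse=True)
    m = len(ut)
    d1 = np.bincount(inv, weights=(events == 1).astype(float), minlength=m)
    d2 = np.bincount(inv, weights=(events == 2).astype(float), minlength=m)
    c = np.bincount(inv, weights=(events == 0).astype(float), minlength=m)
    removed = d1 + d2 + c
    n_risk = n - np.concatenate(([0.0], np.cumsum(removed)[:-1]))
    gidx = np.searchsorted(ut, grid, side="right") - 1
    gclip = np.clip(gidx, 0, m - 1)

    codes = inv * 3 + events
    upat, pinv = np.unique(codes, return_inverse=True)
    loo1 = np.empty((len(upat), len(grid)))
    loo2 = np.empty((len(upat), len(grid)))
    idx = np.arange(m)
    ones = np.ones(1)
    for k, code in enumerate(upat):
        j0, ev = divmod(int(code), 3)
        d1k = d1.copy()
        d2k = d2.copy()
        if ev == 1:
            d1k[j0] -= 1.0
        elif ev == 2:
            d2k[j0] -= 1.0
        riskk = n_risk - (idx <= j0)
        safe = np.maximum(riskk, 1.0)
        live = riskk > 0
        dk = d1k + d2k
        surv = np.cumprod(1.0 - dk / safe * live)
        s_before = np.concatenate((ones, surv[:-1]))
        cif1 = np.cumsum(s_before * d1k / safe * live)
        cif2 = np.cumsum(s_before * d2k / safe * live)
        loo1[k] = np.where(gidx >= 0, cif1[gclip], 0.0)
        loo2[k] = np.where(gidx >= 0, cif2[gclip], 0.0)
    return loo1[pinv], loo2[pinv]


@dataclasses.dataclass
class CPFCurve:
    """Conditional probability of live discharge over time.

    ``cpf`` is nondecreasing; the pointwise 95% bounds bracket it within
    [0, 1]. ``degenerate_from`` is set where the denominator 1 - CIF_death
    reached zero (everyone dead), from which point the CPF is defined as 1.
    """

    times: np.ndarray
    cpf: np.ndarray
    ci_lower: np.ndarray | None
    ci_upper: np.ndarray | None
    n_effective: np.ndarray
    n: int
    ci_method: str | None = None
    denominator: str = "1-cif_death"
    degenerate_from: float | None = None

    def cpf_at(self, at):
        return step_eval(self.times, self.cpf, at, fill=0.0)


def _cpf_from_cifs(cif1, cif2, denominator: str):
    if denominator == "1-cif_death":
        denom = 1.0 - cif2
    elif denominator == "cif_sum":
        denom = cif1 + cif2
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        cp = np.where(denom > 0, cif1 / np.where(denom > 0, denom, 1.0), 0.0)
    # denominator exhausted (everyone dead): conditional probability -> 1
    cp = np.where((denom <= 0) & (cif2 > 0), 1.0, cp)
    return np.clip(cp, 0.0, 1.0)


def estimate_cpf(
    cif: CIFEstimate,
    ci_method: str | None = "cloglog",
    alpha: float = 0.05,
    denominator: str = "1-cif_death",
) -> CPFCurve:
    """Conditional probability of discharge from a fitted CIF estimate.

    ``denominator`` selects the conditioning set: ``"1-cif_death"``
    (default — alive or already discharged) or ``"cif_sum"`` (exited
    either way, CIF1/(CIF1+CIF2)). Pointwise CIs by the delta method on
    the ratio with jackknife (co)variances of the CIFs; ``ci_method``
    is ``"cloglog"`` (default, back-transformed), ``"linear"``, or None
    to skip the interval computation.
    """
    cp = _cpf_from_cifs(cif.cif_discharge, cif.cif_death, denominator)
    denom = (1.0 - cif.cif_death if denominator == "1-cif_death"
             else cif.cif_discharge + cif.cif_death)
    degenerate = None
    bad = denom <= 0
    if denominator == "1-cif_death" and bad.any():
        degenerate = float(cif.times[np.argmax(bad)])

    lo = hi = None
    if ci_method is not None and len(cif.times):
        var1, var2, cov12 = cif.jackknife_cov(cif.times)
        c1, c2 = cif.cif_discharge, cif.cif_death
        if denominator == "1-cif_death":
            g1 = 1.0 / np.maximum(1.0 - c2, 1e-12)
            g2 = c1 / np.maximum((1.0 - c2) ** 2, 1e-12)
            var_cp = g1**2 * var1 + g2**2 * var2 + 2 * g1 * g2 * cov12
        else:
            s = np.maximum(c1 + c2, 1e-12)
            g1 = c2 / s**2
            g2 = -c1 / s**2
            var_cp = g1**2 * var1 + g2**2 * var2 + 2 * g1 * g2 * cov12
        se = np.sqrt(np.maximum(var_cp, 0.0))
        z = norm.ppf(1 - alpha / 2)
        if ci_method == "linear":
            lo = np.clip(cp - z * se, 0.0, 1.0)
            hi = np.clip(cp + z * se, 0.0, 1.0)
        elif ci_method == "cloglog":
            # theta = log(-log(p)); se_theta = se / |p log p|
            inner = np.clip(cp, 1e-12, 1 - 1e-12)
            se_theta = se / np.abs(inner * np.log(inner))
            theta = np.log(-np.log(inner))
            with np.errstate(over="ignore"):
                lo = np.exp(-np.exp(theta + z * se_theta))
                hi = np.exp(-np.exp(theta - z * se_theta))
            # degenerate points (p in {0,1} or se 0): interval collapses
            flat = se <= 0
            lo = np.where(flat, cp, np.clip(lo, 0.0, 1.0))
            hi = np.where(flat, cp, np.clip(hi, 0.0, 1.0))
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")

    return CPFCurve(
        times=cif.times, cpf=cp, ci_lower=lo, ci_upper=hi,
        n_effective=cif.n_at_risk, n=cif.n, ci_method=ci_method,
        denominator=denominator, degenerate_from=degenerate,
    )


@dataclasses.dataclass
class GroupedCPF:
    """Per-group CPF curves plus per-group error entries for empty cells."""

    curves: dict[tuple, CPFCurve]
    errors: dict[tuple, str]

    def __getitem__(self, key):
        return self.curves[key]


def cpf_by_group(
    cohort: Cohort,
    group_keys: tuple[str, ...] = ("stratum", "exposure"),
    ci_method: str | None = "cloglog",
    denominator: str = "1-cif_death",
) -> GroupedCPF:
    """Independent CPF estimation per group cell.

    When grouping by stratum and exposure, all four design cells are
    reported: empty cells appear in ``errors`` instead of failing the
    whole call.
    """
    curves: dict[tuple, CPFCurve] = {}
    errors: dict[tuple, str] = {}
    if set(group_keys) == {"stratum", "exposure"}:
        expected = [(s, e) for s in STRATUM_LEVELS for e in EXPOSURE_LEVELS]
    else:
        obs = cohort.data[list(group_keys)].drop_duplicates()
        expected = [tuple(r) for r in obs.itertuples(index=False)]
    for key in expected:
        mask = np.ones(len(cohort.data), dtype=bool)
        for col, val in zip(group_keys, key):
            mask &= (cohort.data[col] == val).to_numpy()
        if not mask.any():
            errors[key] = "empty cell"
            continue
        sub = cohort.select(mask)
        try:
            curves[key] = estimate_cpf(estimate_cif(sub), ci_method=ci_method,
                                       denominator=denominator)
        except ValueError as exc:  # e.g. single-record cell with CI request
            if len(sub) == 1:
                curves[key] = estimate_cpf(estimate_cif(sub), ci_method=None,
                                           denominator=denominator)
            else:
                errors[key] = str(exc)
    return GroupedCPF(curves=curves, errors=errors)
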
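"""Synthetic registry cohorts with known ground truth.

The generator emulates the structure of a national hip-fracture registry
cohort: two competing terminal causes (live discharge, in-hospital
death), pooled transfer/loss censoring, a 30-day administrative horizon,
a 2x2 design of depression stratum by mobilisation-timing exposure, and
the adjustment-set covariates.

The generative model is constant (exponential) cause-specific hazards
per (stratum, exposure) cell, optionally modulated multiplicatively by
covariates (proportional hazards per cause). Constant hazards give
closed-form cumulative incidence and conditional-probability functions,

    CIF_k(t) = (lam_k / lam) * (1 - exp(-lam * t)),   lam = lam_1 + lam_2,
    CPF(t)   = CIF_1(t) / (1 - CIF_2(t)),

which serve as exact oracles for every downstream estimator.

All randomness flows from a single integer seed; a fixed seed gives a
bit-reproducible cohort.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import Cohort, Event, EXPOSURE_LEVELS, STRATUM_LEVELS

__all__ = [
    "CellHazards",
    "CovariateEffect",
    "RegistryCovariateModel",
    "SimulationConfig",
    "GroundTruth",
    "UnsupportedConfigError",
    "simulate_cohort",
    "ground_truth",
    "nhfd_like_scenario",
    "null_scenario",
    "or_recovery_scenario",
    "confounded_scenario",
]

Cell = tuple[str, str]  # (stratum, exposure)


class UnsupportedConfigError(ValueError):
    """Configuration outside the constant-hazard generative family."""


@dataclasses.dataclass(frozen=True)
class CellHazards:
    """Per-day cause-specific hazards for one (stratum, exposure) cell."""

    discharge: float
    death: float
    censoring: float = 0.0

    def __post_init__(self) -> None:
        for name in ("discharge", "death", "censoring"):
            v = getattr(self, name)
            if not (np.isscalar(v) and math.isfinite(v) and v >= 0):
                raise UnsupportedConfigError(
                    f"{name} hazard must be a finite non-negative scalar, got {v!r}"
                )


@dataclasses.dataclass(frozen=True)
class CovariateEffect:
    """Multiplicative covariate effect on the cause-specific hazards.

    For a categorical/boolean covariate, ``level`` names the level that
    carries the effect; for a numeric covariate ``level`` is None and the
    log hazard ratio applies per unit above ``center``.
    """

    column: str
    log_hr_discharge: float = 0.0
    log_hr_death: float = 0.0
    level: object | None = None
    center: float = 0.0


class RegistryCovariateModel:
    """Marginal covariate distributions in the style of the registry.

    Only prefracture residence may depend on the (stratum, exposure)
    cell — late mobilisers are admitted from care homes more often, the
    main exposure-covariate dependence seen in the registry tables. All
    other covariates are drawn from fixed marginals. ``missing_rate``
    masks each covariate value independently to exercise complete-case
    handling; default 0 (complete data).
    """

    def __init__(
        self,
        care_home_prob: Mapping[Cell, float] | float = 0.20,
        missing_rate: float = 0.0,
    ) -> None:
        self.care_home_prob = care_home_prob
        self.missing_rate = float(missing_rate)

    def _care_home_p(self, cell: Cell) -> float:
        if isinstance(self.care_home_prob, Mapping):
            return float(self.care_home_prob[cell])
        return float(self.care_home_prob)

    def draw(self, rng: np.random.Generator, n: int, cell: Cell) -> pd.DataFrame:
        df = pd.DataFrame({
            "age": np.clip(np.round(rng.normal(83.0, 8.0, n)), 60, 105),
            "sex": rng.choice(["female", "male"], n, p=[0.73, 0.27]),
            "ethnicity": rng.choice(
                ["white", "black", "asian", "other"], n,
                p=[0.985, 0.005, 0.006, 0.004]),
            "deprivation": rng.integers(1, 11, n),
            "n_comorbidities": np.minimum(rng.poisson(1.8, n), 12),
            "asa_grade": rng.choice(["0-1", "2", "3-4"], n, p=[0.28, 0.58, 0.14]),
            "prefracture_residence": rng.choice(
                ["care_home", "own_home"], n,
                p=[self._care_home_p(cell), 1 - self._care_home_p(cell)]),
            "fracture_type": rng.choice(
                ["intracapsular", "intertrochanteric", "subtrochanteric"],
                n, p=[0.59, 0.35, 0.06]),
            "prefracture_mobility": rng.choice(
                ["none", "indoor_only", "indoor_outdoor"], n,
                p=[0.02, 0.25, 0.73]),
            "hospital_volume": rng.choice(
                ["low", "medium", "high"], n, p=[0.35, 0.34, 0.31]),
            "surgery_within_36h": rng.random(n) < 0.76,
            "weekend_admission": rng.random(n) < 0.31,
            "admission_year": rng.choice(["2014", "2015", "2016"], n,
                                         p=[0.27, 0.37, 0.36]),
        })
        df["deprivation"] = df["deprivation"].astype("Int64")
        df["n_comorbidities"] = df["n_comorbidities"].astype("Int64")
        df["surgery_within_36h"] = df["surgery_within_36h"].astype("boolean")
        df["weekend_admission"] = df["weekend_admission"].astype("boolean")
        if self.missing_rate > 0:
            for col in df.columns:
                mask = rng.random(n) < self.missing_rate
                df.loc[mask, col] = pd.NA
        return df


@dataclasses.dataclass
class SimulationConfig:
    """Full specification of one synthetic cohort.

    Attributes
    ----------
    n_per_cell : mapping (stratum, exposure) -> count
    hazards : mapping (stratum, exposure) -> CellHazards
        Baseline per-day cause-specific hazards (reference covariate
        profile when covariate effects are present).
    horizon : float
        Administrative follow-up in days (default 30).
    covariate_model : RegistryCovariateModel or None
        None generates the time-to-event core only (no covariates).
    covariate_effects : list of CovariateEffect
        Proportional multiplicative effects on the cause hazards.
    round_days : bool
        Floor event times to whole days (registry resolution, ties);
        default False keeps continuous times (no ties).
    seed : int
    """

    n_per_cell: dict[Cell, int]
    hazards: dict[Cell, CellHazards]
    horizon: float = 30.0
    covariate_model: RegistryCovariateModel | None = None
    covariate_effects: list[CovariateEffect] = dataclasses.field(
        default_factory=list)
    round_days: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for cell, n in self.n_per_cell.items():
            if n < 0:
                raise ValueError(f"negative cell count for {cell}")
            if cell not in self.hazards:
                raise ValueError(f"no hazards configured for cell {cell}")


@dataclasses.dataclass
class GroundTruth:
    """Closed-form functions under the configured constant hazards.

    All functions refer to the reference covariate profile (covariate
    effects at zero).
    """

    hazards: dict[Cell, CellHazards]
    horizon: float

    def _rates(self, cell: Cell) -> tuple[float, float]:
        h = self.hazards[cell]
        return h.discharge, h.death

    def cif_discharge(self, t, cell: Cell):
        l1, l2 = self._rates(cell)
        return _cif_closed_form(t, l1, l2, cause=1)

    def cif_death(self, t, cell: Cell):
        l1, l2 = self._rates(cell)
        return _cif_closed_form(t, l1, l2, cause=2)

    def survival(self, t, cell: Cell):
        l1, l2 = self._rates(cell)
        return np.exp(-(l1 + l2) * np.asarray(t, dtype=float))

    def cpf(self, t, cell: Cell):
        return self.cif_discharge(t, cell) / (1.0 - self.cif_death(t, cell))

    def true_or(self, t, stratum: str):
        """Odds ratio of CPF(t), early versus late, within a stratum."""
        pe = self.cpf(t, (stratum, "early"))
        pl = self.cpf(t, (stratum, "late"))
        return (pe / (1 - pe)) / (pl / (1 - pl))


def _cif_closed_form(t, l1: float, l2: float, cause: int):
    t = np.asarray(t, dtype=float)
    lam = l1 + l2
    lk = l1 if cause == 1 else l2
    if lam == 0:
        return np.zeros_like(t)
    return (lk / lam) * (1.0 - np.exp(-lam * t))


def ground_truth(config: SimulationConfig) -> GroundTruth:
    """Closed-form CIF/CPF oracle for a constant-hazard configuration."""
    return GroundTruth(hazards=dict(config.hazards), horizon=config.horizon)


def _subject_hazards(
    base: CellHazards,
    covariates: pd.DataFrame | None,
    effects: list[CovariateEffect],
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    log1 = np.full(n, math.log(base.discharge) if base.discharge > 0 else -np.inf)
    log2 = np.full(n, math.log(base.death) if base.death > 0 else -np.inf)
    for eff in effects:
        if covariates is None or eff.column not in covariates.columns:
            raise ValueError(f"covariate effect on absent column {eff.column!r}")
        col = covariates[eff.column]
        if eff.level is None:
            x = pd.to_numeric(col).astype(float).to_numpy() - eff.center
        else:
            x = (col == eff.level).to_numpy(dtype=float)
        log1 = log1 + eff.log_hr_discharge * x
        log2 = log2 + eff.log_hr_death * x
    return np.exp(log1), np.exp(log2)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw one cohort from the configured competing-risks process.

    For every subject, a latent all-cause event time is exponential with
    rate lam_1 + lam_2 and its cause is discharge with probability
    lam_1 / (lam_1 + lam_2); an independent censoring time is exponential
    with the cell censoring rate. The observed time is the minimum of
    event, censoring, and horizon, with the matching event label
    (administrative censoring at the horizon).
    """
    rng = np.random.default_rng(config.seed)
    frames: list[pd.DataFrame] = []
    counter = 0
    for stratum in STRATUM_LEVELS:
        for exposure in EXPOSURE_LEVELS:
            cell = (stratum, exposure)
            n = config.n_per_cell.get(cell, 0)
            if n == 0:
                continue
            base = config.hazards[cell]
            cov = (config.covariate_model.draw(rng, n, cell)
                   if config.covariate_model is not None else None)
            lam1, lam2 = _subject_hazards(base, cov, config.covariate_effects, n)
            lam = lam1 + lam2
            with np.errstate(divide="ignore", invalid="ignore"):
                t_event = np.where(lam > 0,
                                   rng.exponential(1.0, n) / np.where(lam > 0, lam, 1.0),
                                   np.inf)
            p_disch = np.where(lam > 0, lam1 / np.where(lam > 0, lam, 1.0), 0.0)
            is_disch = rng.random(n) < p_disch
            t_cens = (rng.exponential(1.0 / base.censoring, n)
                      if base.censoring > 0 else np.full(n, np.inf))
            if config.round_days:
                t_event = np.floor(t_event)
                t_cens = np.floor(t_cens)
            time = np.minimum(np.minimum(t_event, t_cens), config.horizon)
            event = np.where(
                (t_event <= t_cens) & (t_event <= config.horizon),
                np.where(is_disch, int(Event.DISCHARGE), int(Event.DEATH)),
                int(Event.CENSORED),
            )
            df = pd.DataFrame({
                "subject_id": [f"s{counter + i:07d}" for i in range(n)],
                "time": time,
                "event": event.astype(int),
                "exposure": exposure,
                "stratum": stratum,
            })
            counter += n
            if cov is not None:
                df = pd.concat([df, cov.reset_index(drop=True)], axis=1)
            frames.append(df)
    data = (pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=["subject_id", "time", "event",
                                       "exposure", "stratum"]))
    meta = {
        "seed": config.seed,
        "horizon": config.horizon,
        "n_per_cell": {f"{s}/{e}": n for (s, e), n in config.n_per_cell.items()},
        "round_days": config.round_days,
    }
    return Cohort(data, horizon=config.horizon, metadata=meta)


# ---------------------------------------------------------------------------
# scenario builders


def _cell_hazards_from_margins(
    p_discharge: float, p_death: float, p_inhospital: float, horizon: float
) -> CellHazards:
    """Solve constant hazards reproducing 30-day cell margins in expectation.

    ``p_inhospital`` is the probability of still being in hospital at the
    horizon (administratively censored); the remainder is transfer/loss
    censoring. With total rate L = -log(p_inhospital)/horizon the exit
    probabilities by the horizon split proportionally to the cause rates.
    """
    p_exit = 1.0 - p_inhospital
    total = -math.log(p_inhospital) / horizon
    p_cens = p_exit - p_discharge - p_death
    if p_cens < 0:
        raise ValueError("margins exceed total exit probability")
    return CellHazards(
        discharge=p_discharge / p_exit * total,
        death=p_death / p_exit * total,
        censoring=p_cens / p_exit * total,
    )


def _allocate_counts(fractions: dict[Cell, float], n_total: int) -> dict[Cell, int]:
    # largest-remainder rounding so counts sum exactly to n_total
    raw = {c: fractions[c] * n_total for c in fractions}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    short = n_total - sum(counts.values())
    for c in sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


#: 30-day cell margins mirroring the registry's printed discharge table:
#: (share discharged, share dead, share still in hospital at day 30)
_REGISTRY_CELL_MARGINS: dict[Cell, tuple[float, float, float]] = {
    ("depression", "early"): (0.5426, 0.0247, 0.10),
    ("depression", "late"): (0.4437, 0.0721, 0.18),
    ("no_depression", "early"): (0.5543, 0.0303, 0.10),
    ("no_depression", "late"): (0.4183, 0.0920, 0.18),
}

#: cell composition: depression prevalence 8.31%; early-mobilisation share
#: 76.7% with depression, 78.9% without
_REGISTRY_CELL_FRACTIONS: dict[Cell, float] = {
    ("depression", "early"): 0.0831 * 0.767,
    ("depression", "late"): 0.0831 * 0.233,
    ("no_depression", "early"): (1 - 0.0831) * 0.789,
    ("no_depression", "late"): (1 - 0.0831) * 0.211,
}

#: care-home admission shares by cell (late mobilisers more often from care homes)
_REGISTRY_CARE_HOME: dict[Cell, float] = {
    ("depression", "early"): 0.256,
    ("depression", "late"): 0.385,
    ("no_depression", "early"): 0.160,
    ("no_depression", "late"): 0.263,
}


def nhfd_like_scenario(n_total: int = 10_000, seed: int = 0,
                       missing_rate: float = 0.0) -> SimulationConfig:
    """Registry-calibrated scenario at a configurable total size.

    Cell sizes follow the registry's stratum/exposure composition
    (8.31% depression; 76.7% / 78.9% early mobilisation with/without
    depression) and the hazards are solved so that, in expectation, the
    per-cell 30-day shares of live discharge, death, and remaining
    in-hospital match the printed registry margins (overall roughly 52%
    discharged and 4% dead by day 30, with about a third lost to
    transfer/rehabilitation censoring). Covariates are drawn from
    registry-style marginals; they do not modulate the hazards here, so
    the closed-form ground truth applies per cell exactly.
    """
    hazards = {cell: _cell_hazards_from_margins(*margins, 30.0)
               for cell, margins in _REGISTRY_CELL_MARGINS.items()}
    return SimulationConfig(
        n_per_cell=_allocate_counts(_REGISTRY_CELL_FRACTIONS, n_total),
        hazards=hazards,
        horizon=30.0,
        covariate_model=RegistryCovariateModel(
            care_home_prob=_REGISTRY_CARE_HOME, missing_rate=missing_rate),
        seed=seed,
    )


def null_scenario(n_per_group: int = 200, seed: int = 0,
                  censoring: float = 0.02) -> SimulationConfig:
    """Equal hazards in both exposure arms of one stratum (type-I error)."""
    h = CellHazards(discharge=0.05, death=0.005, censoring=censoring)
    return SimulationConfig(
        n_per_cell={("no_depression", "early"): n_per_group,
                    ("no_depression", "late"): n_per_group},
        hazards={("no_depression", "early"): h, ("no_depression", "late"): h},
        seed=seed,
    )


def _solve_discharge_hazard_for_or(
    target_or: float, late: CellHazards, death: float, horizon: float
) -> float:
    """Early-arm discharge hazard giving the target CPF odds ratio at the horizon."""
    def cpf(l1: float) -> float:
        c1 = _cif_closed_form(horizon, l1, death, cause=1)
        c2 = _cif_closed_form(horizon, l1, death, cause=2)
        return float(c1 / (1 - c2))

    p_late = cpf(late.discharge)
    odds_target = target_or * p_late / (1 - p_late)
    p_target = odds_target / (1 + odds_target)
    return brentq(lambda l1: cpf(l1) - p_target, 1e-6, 5.0, xtol=1e-12)


def or_recovery_scenario(n_total: int = 2000, seed: int = 0,
                         target_or: float = 2.0) -> SimulationConfig:
    """Two-arm scenario whose true day-30 CPF odds ratio equals ``target_or``.

    The late arm mimics a registry late-mobilisation cell; the early-arm
    discharge hazard is solved so the closed-form day-30 conditional
    probabilities have exactly the requested odds ratio.
    """
    late = CellHazards(discharge=0.032, death=0.005, censoring=0.015)
    l1_early = _solve_discharge_hazard_for_or(target_or, late, late.death, 30.0)
    early = CellHazards(discharge=l1_early, death=late.death,
                        censoring=late.censoring)
    n_early = int(round(n_total * 0.75))
    return SimulationConfig(
        n_per_cell={("no_depression", "early"): n_early,
                    ("no_depression", "late"): n_total - n_early},
        hazards={("no_depression", "early"): early,
                 ("no_depression", "late"): late},
        seed=seed,
    )


class _ConfoundedCovariateModel(RegistryCovariateModel):
    """Care-home admission predicts late mobilisation (confounding).

    Assignment is cell-conditional: the late arm is drawn with a much
    higher care-home share than the early arm, and a separate hazard
    effect makes care-home residence slow discharge.
    """


def confounded_scenario(n_total: int = 2000, seed: int = 0,
                        target_or: float = 2.0,
                        care_home_log_hr: float = -0.7) -> SimulationConfig:
    """Scenario with care-home residence confounding the exposure effect.

    Late mobilisers are far more often admitted from care homes (45% vs
    12%), and care-home residence lowers the discharge hazard
    (log HR ``care_home_log_hr``). The configured truth is the day-30
    CPF odds ratio at the reference profile (own home), ``target_or``;
    the crude early-vs-late contrast is biased away from it.
    """
    late = CellHazards(discharge=0.035, death=0.006, censoring=0.015)
    l1_early = _solve_discharge_hazard_for_or(target_or, late, late.death, 30.0)
    early = CellHazards(discharge=l1_early, death=late.death,
                        censoring=late.censoring)
    n_early = int(round(n_total * 0.70))
    model = _ConfoundedCovariateModel(
        care_home_prob={("no_depression", "early"): 0.12,
                        ("no_depression", "late"): 0.45})
    return SimulationConfig(
        n_per_cell={("no_depression", "early"): n_early,
                    ("no_depression", "late"): n_total - n_early},
        hazards={("no_depression", "early"): early,
                 ("no_depression", "late"): late},
        covariate_model=model,
        covariate_effects=[CovariateEffect(
            column="prefracture_residence", level="care_home",
            log_hr_discharge=care_home_log_hr)],
        seed=seed,
    )
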
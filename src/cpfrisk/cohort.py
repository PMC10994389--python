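"""Subject-level registry records: data model, CSV I/O, validation.

A cohort is one row per hip-fracture admission: days from surgery to the
terminal event, the event cause (live discharge, in-hospital death, or
censoring through transfer / loss to follow-up), the mobilisation-timing
exposure, the depression stratum, and the adjustment-set covariates.

Day of surgery is day 0; follow-up is administratively censored at a
30-day horizon by default, with a closed boundary (an event at exactly
day 30 counts as within follow-up).

Event coding in files follows the usual competing-risks convention:
0 = censored, 1 = discharge (event of interest), 2 = death (competing).
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Event",
    "Cohort",
    "SubjectRecord",
    "COLUMNS",
    "COVARIATE_COLUMNS",
    "MISSING_TOKEN",
    "SchemaError",
    "ValidationError",
    "read_cohort",
    "write_cohort",
    "truncate_at_horizon",
    "complete_cases",
]


class Event(enum.IntEnum):
    """Terminal-event codes (mutually exclusive causes plus censoring)."""

    CENSORED = 0
    DISCHARGE = 1
    DEATH = 2


#: accepted spellings for each event code in input files
EVENT_ALIASES: dict[str, int] = {
    "0": 0, "censored": 0, "censor": 0, "c": 0,
    "1": 1, "discharge": 1, "discharged": 1, "live_discharge": 1,
    "2": 2, "death": 2, "died": 2, "dead": 2,
}

MISSING_TOKEN = "NA"

MANDATORY_COLUMNS = ["subject_id", "time", "event", "exposure", "stratum"]

COVARIATE_COLUMNS = [
    "age", "sex", "ethnicity", "deprivation", "n_comorbidities",
    "asa_grade", "prefracture_residence", "fracture_type",
    "prefracture_mobility", "hospital_volume", "surgery_within_36h",
    "weekend_admission", "admission_year",
]

#: fixed on-disk column order
COLUMNS = MANDATORY_COLUMNS + COVARIATE_COLUMNS

EXPOSURE_LEVELS = ("early", "late")
STRATUM_LEVELS = ("depression", "no_depression")

#: categorical covariate domains; numeric ones are validated by range
CATEGORICAL_DOMAINS: dict[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "ethnicity": ("white", "black", "asian", "other"),
    "asa_grade": ("0-1", "2", "3-4"),
    "prefracture_residence": ("own_home", "care_home"),
    "fracture_type": ("intracapsular", "intertrochanteric", "subtrochanteric"),
    "prefracture_mobility": ("none", "indoor_only", "indoor_outdoor"),
    "hospital_volume": ("low", "medium", "high"),
    "admission_year": ("2014", "2015", "2016"),
}
BOOLEAN_COVARIATES = ("surgery_within_36h", "weekend_admission")


class SchemaError(ValueError):
    """A mandatory column is missing from an input file."""


class ValidationError(ValueError):
    """The cohort as a whole violates an invariant (e.g. duplicate ids)."""


@dataclasses.dataclass(frozen=True)
class SubjectRecord:
    """One admission; ``covariates`` holds the adjustment-set values."""

    subject_id: str
    time: float
    event: Event
    exposure: str
    stratum: str
    covariates: Mapping[str, object] = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class Cohort:
    """A validated collection of subject records backed by a DataFrame.

    Attributes
    ----------
    data : pandas.DataFrame
        One row per subject, columns per :data:`COLUMNS` (covariates may be
        absent). ``event`` is an integer per :class:`Event`.
    horizon : float
        Administrative follow-up limit in days (default 30).
    metadata : dict
        Provenance: source path, simulation seed and parameters, etc.
    rejections : pandas.DataFrame
        Rows rejected at read time, columns ``row, field, reason``.
    """

    data: pd.DataFrame
    horizon: float = 30.0
    metadata: dict = dataclasses.field(default_factory=dict)
    rejections: pd.DataFrame = dataclasses.field(
        default_factory=lambda: pd.DataFrame(columns=["row", "field", "reason"])
    )

    def __post_init__(self) -> None:
        dup = self.data["subject_id"][self.data["subject_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"duplicate subject_id values: {sorted(set(dup))[:10]}"
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    def records(self) -> Iterable[SubjectRecord]:
        cov_cols = [c for c in COVARIATE_COLUMNS if c in self.data.columns]
        for row in self.data.itertuples(index=False):
            yield SubjectRecord(
                subject_id=str(row.subject_id),
                time=float(row.time),
                event=Event(int(row.event)),
                exposure=str(row.exposure),
                stratum=str(row.stratum),
                covariates={c: getattr(row, c) for c in cov_cols},
            )

    def select(self, mask: pd.Series | np.ndarray) -> "Cohort":
        """Sub-cohort by boolean mask; metadata carried over."""
        return Cohort(
            self.data.loc[mask].reset_index(drop=True),
            horizon=self.horizon,
            metadata=dict(self.metadata),
        )

    def cells(self) -> dict[tuple[str, str], "Cohort"]:
        """Split into (stratum, exposure) cells; empty cells omitted."""
        out: dict[tuple[str, str], Cohort] = {}
        for s in STRATUM_LEVELS:
            for e in EXPOSURE_LEVELS:
                mask = (self.data["stratum"] == s) & (self.data["exposure"] == e)
                if mask.any():
                    out[(s, e)] = self.select(mask.to_numpy())
        return out

    def check_cells(self) -> list[tuple[str, str]]:
        """Return the (stratum, exposure) cells that are empty.

        Stratified analyses need at least one record per cell; an empty
        cell is reported, never silently ignored.
        """
        present = set(self.cells())
        return [
            (s, e)
            for s in STRATUM_LEVELS
            for e in EXPOSURE_LEVELS
            if (s, e) not in present
        ]


def _parse_event(raw: str) -> int | None:
    return EVENT_ALIASES.get(str(raw).strip().lower())


def read_cohort(
    path: str | Path,
    *,
    delimiter: str = ",",
    column_map: Mapping[str, str] | None = None,
    horizon: float = 30.0,
) -> Cohort:
    """Read a delimited cohort file, collecting per-row rejections.

    Rows failing validation (negative or unparseable time, unknown event
    or exposure code, out-of-domain covariate) are dropped into
    ``cohort.rejections`` with their 1-based data row number and reason;
    validation is collect-all, not fail-fast. Missing covariate values
    (the ``NA`` sentinel or an empty field) are preserved as missing.

    Parameters
    ----------
    column_map : mapping, optional
        Maps file column names to schema names, e.g. ``{"id": "subject_id"}``.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")

    rejections: list[tuple[int, str, str]] = []
    n = len(raw)
    bad = np.zeros(n, dtype=bool)

    def reject(mask: np.ndarray, field: str, reason: str) -> None:
        for i in np.nonzero(mask & ~bad)[0]:
            rejections.append((int(i) + 1, field, reason))
        bad[mask] = True

    time = pd.to_numeric(raw["time"], errors="coerce")
    reject(time.isna().to_numpy(), "time", "unparseable time")
    reject((time < 0).to_numpy(), "time", "negative time")

    event = raw["event"].map(_parse_event)
    reject(event.isna().to_numpy(), "event", "unknown event code")

    exposure = raw["exposure"].str.strip().str.lower()
    reject(~exposure.isin(EXPOSURE_LEVELS).to_numpy(), "exposure",
           "unknown exposure level")
    stratum = raw["stratum"].str.strip().str.lower()
    reject(~stratum.isin(STRATUM_LEVELS).to_numpy(), "stratum",
           "unknown stratum level")

    df = pd.DataFrame({
        "subject_id": raw["subject_id"].str.strip(),
        "time": time,
        "event": event,
        "exposure": exposure,
        "stratum": stratum,
    })

    for col in COVARIATE_COLUMNS:
        if col not in raw.columns:
            continue
        vals = raw[col].str.strip()
        is_missing = (vals == "") | (vals.str.upper() == MISSING_TOKEN)
        if col in ("age",):
            parsed = pd.to_numeric(vals.where(~is_missing), errors="coerce")
            reject((parsed.isna() & ~is_missing).to_numpy(), col,
                   f"unparseable {col}")
            reject((parsed < 0).to_numpy(), col, f"negative {col}")
            df[col] = parsed
        elif col in ("deprivation", "n_comorbidities"):
            parsed = pd.to_numeric(vals.where(~is_missing), errors="coerce")
            reject((parsed.isna() & ~is_missing).to_numpy(), col,
                   f"unparseable {col}")
            if col == "deprivation":
                reject((~parsed.isin(range(1, 11)) & parsed.notna()).to_numpy(),
                       col, "deprivation decile outside 1-10")
            else:
                reject((parsed < 0).to_numpy(), col, f"negative {col}")
            df[col] = parsed.astype("Int64")
        elif col in BOOLEAN_COVARIATES:
            low = vals.str.lower()
            mapped = low.map({"true": True, "1": True, "false": False, "0": False})
            reject((mapped.isna() & ~is_missing).to_numpy(), col,
                   f"unparseable boolean {col}")
            df[col] = mapped.astype("boolean")
        else:
            low = vals.str.lower()
            domain = CATEGORICAL_DOMAINS[col]
            reject((~low.isin(domain) & ~is_missing).to_numpy(), col,
                   f"{col} outside domain {domain}")
            df[col] = low.where(~is_missing, pd.NA)

    keep = df.loc[~bad].reset_index(drop=True)
    keep["time"] = keep["time"].astype(float)
    keep["event"] = keep["event"].astype(int)

    dup_mask = keep["subject_id"].duplicated(keep=False)
    if dup_mask.any():
        raise ValidationError(
            "duplicate subject_id values: "
            f"{sorted(set(keep.loc[dup_mask, 'subject_id']))[:10]}"
        )

    rej = pd.DataFrame(rejections, columns=["row", "field", "reason"])
    return Cohort(keep, horizon=horizon,
                  metadata={"source": str(path)}, rejections=rej)


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort as CSV in the documented column order.

    Missing covariates are written as the ``NA`` sentinel; booleans as
    ``true``/``false``. Lossless round-trip with :func:`read_cohort`.
    """
    path = Path(path)
    df = cohort.data.copy()
    for col in COLUMNS:
        if col not in df.columns:
            continue
        if col in BOOLEAN_COVARIATES:
            df[col] = df[col].map({True: "true", False: "false"})
    cols = [c for c in COLUMNS if c in df.columns]
    out = df[cols]
    out.to_csv(path, index=False, na_rep=MISSING_TOKEN)
    return path


def truncate_at_horizon(cohort: Cohort, horizon: float | None = None) -> Cohort:
    """Administratively censor follow-up beyond the horizon.

    Records with ``time > horizon`` get ``time = horizon`` and
    ``event = CENSORED``; records with ``time <= horizon`` (closed
    boundary) are unchanged. Idempotent; never changes the record count.
    """
    h = cohort.horizon if horizon is None else float(horizon)
    if h <= 0:
        raise ValueError(f"horizon must be positive, got {h}")
    df = cohort.data.copy()
    beyond = df["time"].to_numpy() > h
    df.loc[beyond, "time"] = h
    df.loc[beyond, "event"] = int(Event.CENSORED)
    return Cohort(df, horizon=h, metadata=dict(cohort.metadata),
                  rejections=cohort.rejections)


def complete_cases(
    cohort: Cohort, columns: Iterable[str]
) -> tuple[Cohort, dict[str, int]]:
    """Drop records missing any of ``columns``; log what was dropped.

    Returns the filtered cohort and a per-column count of missing values
    among dropped rows (a row missing several columns is counted in each).
    """
    cols = [c for c in columns if c in cohort.data.columns]
    absent = [c for c in columns if c not in cohort.data.columns]
    if absent:
        raise KeyError(f"columns not present in cohort: {absent}")
    miss = cohort.data[cols].isna()
    dropped = {c: int(miss[c].sum()) for c in cols}
    dropped["n_dropped"] = int(miss.any(axis=1).sum())
    return cohort.select(~miss.any(axis=1).to_numpy()), dropped
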
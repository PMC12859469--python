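"""Dispensing-record domain types, delimited-text I/O and cohort filtering.

A registry is a table with one row per pharmacy dispensing event:

``patient_id,sex,birth_year,atc_code,dispense_date,days_supplied,ddd_ratio``

``ddd_ratio`` is the prescribed daily dose expressed in defined-daily-dose
(DDD) units, i.e. prescribed dose / WHO DDD.  The canonical in-memory
container is a :class:`pandas.DataFrame` with this schema;
:class:`DispensingRecord` gives single-row semantics where convenient.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .atc import ANTIDEPRESSANTS, ANXIOLYTICS, AtcClassMap, default_class_map, is_valid_atc

__all__ = [
    "REGISTRY_COLUMNS",
    "DispensingRecord",
    "CohortSpec",
    "RowRejection",
    "SchemaError",
    "read_registry",
    "write_registry",
    "records_to_frame",
    "frame_to_records",
    "filter_cohort",
]

REGISTRY_COLUMNS = (
    "patient_id",
    "sex",
    "birth_year",
    "atc_code",
    "dispense_date",
    "days_supplied",
    "ddd_ratio",
)

_SEXES = ("male", "female")


class SchemaError(ValueError):
    """The input file's header does not match the registry schema."""


@dataclass(frozen=True)
class DispensingRecord:
    """One pharmacy dispensing event."""

    patient_id: str
    sex: str
    birth_year: int
    atc_code: str
    dispense_date: dt.date
    days_supplied: int
    ddd_ratio: float

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if self.days_supplied < 1:
            raise ValueError("days_supplied must be >= 1")
        if not self.ddd_ratio > 0:
            raise ValueError("ddd_ratio must be > 0")
        if not is_valid_atc(self.atc_code):
            raise ValueError(f"invalid ATC code {self.atc_code!r}")


@dataclass(frozen=True)
class RowRejection:
    """Why one data row was rejected by :func:`read_registry`."""

    line_number: int  # 1-based line in the file (header is line 1)
    reason: str


@dataclass(frozen=True)
class CohortSpec:
    """Static-cohort definition.

    A patient enters the cohort when they have at least one dispensing of
    an index class inside the study window and their age at that first
    qualifying dispensing lies in ``[min_age, max_age]``.  Age is
    dispense-year minus birth year (the registry carries no birth day).
    """

    min_age: int = 18
    max_age: int = 65
    index_classes: tuple[str, ...] = (ANTIDEPRESSANTS, ANXIOLYTICS)
    window_start: dt.date = dt.date(2018, 1, 1)
    window_end: dt.date = dt.date(2022, 12, 31)

    def __post_init__(self) -> None:
        if self.min_age >= self.max_age:
            raise ValueError("min_age must be < max_age")
        if not self.index_classes:
            raise ValueError("index_classes must be non-empty")
        if self.window_start >= self.window_end:
            raise ValueError("window_start must be < window_end")


def records_to_frame(records: list[DispensingRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records], columns=list(REGISTRY_COLUMNS))
    df["dispense_date"] = pd.to_datetime(df["dispense_date"])
    return df


def frame_to_records(df: pd.DataFrame) -> list[DispensingRecord]:
    return [
        DispensingRecord(
            patient_id=str(r.patient_id),
            sex=r.sex,
            birth_year=int(r.birth_year),
            atc_code=r.atc_code,
            dispense_date=pd.Timestamp(r.dispense_date).date(),
            days_supplied=int(r.days_supplied),
            ddd_ratio=float(r.ddd_ratio),
        )
        for r in df.itertuples(index=False)
    ]


def read_registry(
    path: str | Path,
) -> tuple[pd.DataFrame, list[RowRejection]]:
    """Read a registry CSV, validating every row.

    Returns the valid records and a per-row rejection report; nothing is
    dropped silently.  A wrong header raises :class:`SchemaError`.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if tuple(raw.columns) != REGISTRY_COLUMNS:
        raise SchemaError(
            f"expected header {','.join(REGISTRY_COLUMNS)}, got {','.join(raw.columns)}"
        )

    reasons = pd.Series("", index=raw.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        fresh = mask & (reasons == "")
        reasons[fresh] = reason

    flag(raw["patient_id"].str.len() == 0, "empty patient_id")
    flag(~raw["sex"].isin(_SEXES), "sex must be 'male' or 'female'")

    birth_year = pd.to_numeric(raw["birth_year"], errors="coerce")
    flag(birth_year.isna() | (birth_year != birth_year.round()), "malformed birth_year")

    flag(~raw["atc_code"].map(is_valid_atc), "invalid ATC code")

    date = pd.to_datetime(raw["dispense_date"], format="%Y-%m-%d", errors="coerce")
    flag(date.isna(), "malformed dispense_date (expected YYYY-MM-DD)")

    days = pd.to_numeric(raw["days_supplied"], errors="coerce")
    flag(days.isna() | (days != days.round()), "malformed days_supplied")
    flag(days < 1, "days_supplied must be >= 1")

    ddd = pd.to_numeric(raw["ddd_ratio"], errors="coerce")
    flag(ddd.isna(), "malformed ddd_ratio")
    flag(ddd <= 0, "ddd_ratio must be > 0")

    bad = reasons != ""
    # header is line 1, first data row line 2
    rejections = [
        RowRejection(line_number=int(i) + 2, reason=reason)
        for i, reason in reasons[bad].items()
    ]

    ok = ~bad
    df = pd.DataFrame(
        {
            "patient_id": raw.loc[ok, "patient_id"],
            "sex": raw.loc[ok, "sex"],
            "birth_year": birth_year[ok].astype(int),
            "atc_code": raw.loc[ok, "atc_code"],
            "dispense_date": date[ok],
            "days_supplied": days[ok].astype(int),
            "ddd_ratio": ddd[ok].astype(float),
        }
    ).reset_index(drop=True)
    return df, rejections


def write_registry(df: pd.DataFrame, path: str | Path) -> None:
    """Write a registry DataFrame in the documented CSV schema."""
    out = df.loc[:, list(REGISTRY_COLUMNS)].copy()
    out["dispense_date"] = pd.to_datetime(out["dispense_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def filter_cohort(
    df: pd.DataFrame,
    spec: CohortSpec | None = None,
    class_map: AtcClassMap | None = None,
) -> pd.DataFrame:
    """Keep all records of patients eligible under ``spec``.

    Eligibility: >=1 dispensing of an index class inside the window, with
    age at the first such dispensing in ``[min_age, max_age]``.  All
    records (every class) of eligible patients are retained.
    """
    spec = spec or CohortSpec()
    cmap = class_map if class_map is not None else default_class_map()

    dates = pd.to_datetime(df["dispense_date"])
    labels = cmap.map_series(df["atc_code"])
    in_window = (dates >= pd.Timestamp(spec.window_start)) & (
        dates <= pd.Timestamp(spec.window_end)
    )
    qualifying = df[in_window & labels.isin(spec.index_classes)]
    if qualifying.empty:
        warnings.warn("cohort filter produced an empty cohort", stacklevel=2)
        return df.iloc[0:0].copy()

    q = qualifying.assign(_date=pd.to_datetime(qualifying["dispense_date"]))
    first = q.sort_values("_date").groupby("patient_id", sort=False).first()
    age_at_first = first["_date"].dt.year - first["birth_year"]
    eligible = first.index[
        (age_at_first >= spec.min_age) & (age_at_first <= spec.max_age)
    ]
    out = df[df["patient_id"].isin(set(eligible))].reset_index(drop=True)
    if out.empty:
        warnings.warn("cohort filter produced an empty cohort", stacklevel=2)
    return out
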
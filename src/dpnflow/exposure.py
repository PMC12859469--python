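"""Daily medication exposure derived from dispensing records.

Each dispensing covers the half-open day interval
``[dispense_date, dispense_date + days_supplied)``; day indices are
0-based offsets from the study window start.  Overlapping refills of the
same ATC code are resolved by a configurable policy:

``union``
    day-level union of the intervals (no stockpiling); on overlap days
    the most recent dispensing's ddd_ratio applies.
``shift``
    leftover days of the earlier supply are pushed after the overlap
    (stockpiling), so total covered days are preserved.

The central product is :class:`ActivityCube`, a dense
patients x days x classes array of active distinct-medication counts
(plus an optional parallel sum of per-medication kernel weights), from
which networks, co-prescription statistics and polypharmacy flags are
all computed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .atc import AtcClassMap, default_class_map

__all__ = [
    "Window",
    "ExposureInterval",
    "expand_record",
    "build_exposure",
    "daily_active_sets",
    "ActivityCube",
    "build_activity_cube",
]


@dataclass(frozen=True)
class Window:
    """Half-open study window, day 0 = ``start``."""

    start: dt.date
    end: dt.date  # inclusive last calendar day

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("window start must be <= end")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def day_index(self, date: dt.date) -> int:
        return (date - self.start).days

    def date_of(self, day: int) -> dt.date:
        return self.start + dt.timedelta(days=int(day))

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="D")


@dataclass(frozen=True)
class ExposureInterval:
    """A patient x medication half-open day interval of active supply."""

    patient_id: str
    atc_code: str
    class_label: str
    ddd_ratio: float
    start_day: int
    end_day: int  # exclusive

    def __post_init__(self) -> None:
        if self.end_day <= self.start_day:
            raise ValueError("end_day must be > start_day")


def expand_record(
    dispense_date: dt.date, days_supplied: int, window: Window
) -> tuple[int, int] | None:
    """Clipped ``[start_day, end_day)`` of one dispensing, or None if
    entirely outside the window."""
    s = window.day_index(dispense_date)
    e = s + int(days_supplied)
    s, e = max(s, 0), min(e, window.n_days)
    if e <= s:
        return None
    return s, e


def _union_group(
    starts: np.ndarray, ends: np.ndarray, ddds: np.ndarray
) -> list[tuple[int, int, float]]:
    """Union of same-ATC intervals; most recent dispensing wins per day.

    Inputs are in dispensing-date order; recency = later start, ties
    broken by input order.
    """
    pts = np.unique(np.concatenate([starts, ends]))
    out: list[tuple[int, int, float]] = []
    for a, b in zip(pts[:-1], pts[1:]):
        cover = np.flatnonzero((starts <= a) & (a < ends))
        if cover.size == 0:
            continue
        best = cover[np.lexsort((cover, starts[cover]))[-1]]
        if out and out[-1][1] == a and out[-1][2] == ddds[best]:
            out[-1] = (out[-1][0], int(b), float(ddds[best]))
        else:
            out.append((int(a), int(b), float(ddds[best])))
    return out


def _shift_group(
    starts: np.ndarray, ends: np.ndarray, ddds: np.ndarray
) -> list[tuple[int, int, float]]:
    """Stockpiling: each refill starts after the previous supply runs out."""
    out: list[tuple[int, int, float]] = []
    cur_end = -np.inf
    for s, e, d in zip(starts, ends, ddds):
        s_eff = int(max(s, cur_end))
        e_eff = s_eff + int(e - s)
        out.append((s_eff, e_eff, float(d)))
        cur_end = e_eff
    return out


def build_exposure(
    records: pd.DataFrame,
    window: Window,
    class_map: AtcClassMap | None = None,
    refill_policy: str = "union",
) -> pd.DataFrame:
    """Expand dispensing records into non-overlapping exposure segments.

    Returns a frame with columns ``patient_id, atc_code, class_label,
    ddd_ratio, start_day, end_day``; per (patient, ATC code) the segments
    never overlap, so segment coverage counts equal distinct active
    medications.
    """
    if refill_policy not in ("union", "shift"):
        raise ValueError("refill_policy must be 'union' or 'shift'")
    cmap = class_map if class_map is not None else default_class_map()

    df = records.copy()
    dates = pd.to_datetime(df["dispense_date"])
    df["_start"] = (dates - pd.Timestamp(window.start)).dt.days
    df["_end"] = df["_start"] + df["days_supplied"].astype(int)
    df["class_label"] = cmap.map_series(df["atc_code"])
    df = df.sort_values(["patient_id", "atc_code", "_start"], kind="stable")

    # fast path: ATC codes dispensed once for a patient need no merging
    grp = df.groupby(["patient_id", "atc_code"], sort=False)
    sizes = grp["_start"].transform("size")
    single = df[sizes == 1]
    multi = df[sizes > 1]

    rows = {
        "patient_id": [single["patient_id"].to_numpy()],
        "atc_code": [single["atc_code"].to_numpy()],
        "class_label": [single["class_label"].to_numpy()],
        "ddd_ratio": [single["ddd_ratio"].to_numpy(float)],
        "start_day": [single["_start"].to_numpy(int)],
        "end_day": [single["_end"].to_numpy(int)],
    }
    merge = _union_group if refill_policy == "union" else _shift_group
    if not multi.empty:
        for (pid, atc), g in multi.groupby(["patient_id", "atc_code"], sort=False):
            segs = merge(
                g["_start"].to_numpy(int), g["_end"].to_numpy(int),
                g["ddd_ratio"].to_numpy(float),
            )
            label = g["class_label"].iloc[0]
            for s, e, d in segs:
                rows["patient_id"].append(np.array([pid], dtype=object))
                rows["atc_code"].append(np.array([atc], dtype=object))
                rows["class_label"].append(np.array([label], dtype=object))
                rows["ddd_ratio"].append(np.array([d]))
                rows["start_day"].append(np.array([s]))
                rows["end_day"].append(np.array([e]))

    out = pd.DataFrame({k: np.concatenate(v) for k, v in rows.items()})
    out["start_day"] = out["start_day"].astype(int).clip(lower=0)
    out["end_day"] = out["end_day"].astype(int).clip(upper=window.n_days)
    out = out[out["end_day"] > out["start_day"]].reset_index(drop=True)
    return out


def daily_active_sets(
    segments: pd.DataFrame, day: int
) -> dict[str, set[tuple[str, str, float]]]:
    """Active medications per patient on one day.

    A medication is active on day ``d`` iff one of its segments satisfies
    ``start_day <= d < end_day``.  Returns
    ``{patient_id: {(atc_code, class_label, ddd_ratio), ...}}`` for
    patients with a non-empty set.
    """
    hit = segments[(segments["start_day"] <= day) & (day < segments["end_day"])]
    out: dict[str, set[tuple[str, str, float]]] = {}
    for r in hit.itertuples(index=False):
        out.setdefault(r.patient_id, set()).add(
            (r.atc_code, r.class_label, float(r.ddd_ratio))
        )
    return out


@dataclass
class ActivityCube:
    """Dense patients x days x classes exposure summary.

    ``counts[p, d, c]`` is the number of distinct ATC codes of class c
    active for patient p on day d.  ``weight_sum`` (same shape, present
    when a weight function was supplied) holds the sum of per-medication
    kernel weights, so ``weight_sum / counts`` is the within
    patient-day-class mean weight.
    """

    counts: np.ndarray
    patient_ids: np.ndarray
    class_labels: tuple[str, ...]
    window: Window
    weight_sum: np.ndarray | None = None

    @property
    def n_patients(self) -> int:
        return self.counts.shape[0]

    @property
    def n_days(self) -> int:
        return self.counts.shape[1]

    @property
    def active(self) -> np.ndarray:
        """Boolean (P, D, C): class has >=1 active medication."""
        return self.counts > 0

    def weight_mean(self) -> np.ndarray:
        """Mean per-medication weight per (patient, day, class); 0 where inactive."""
        if self.weight_sum is None:
            raise ValueError("cube was built without a weight function")
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(self.counts > 0, self.weight_sum / self.counts, 0.0)
        return out.astype(np.float32)

    def subset(self, patient_mask: np.ndarray) -> "ActivityCube":
        return ActivityCube(
            counts=self.counts[patient_mask],
            patient_ids=self.patient_ids[patient_mask],
            class_labels=self.class_labels,
            window=self.window,
            weight_sum=None if self.weight_sum is None else self.weight_sum[patient_mask],
        )


def build_activity_cube(
    segments: pd.DataFrame,
    window: Window,
    class_map: AtcClassMap | None = None,
    patient_ids: np.ndarray | None = None,
    weight_fn: Callable[[np.ndarray], np.ndarray] | None = None,
) -> ActivityCube:
    """Accumulate exposure segments into an :class:`ActivityCube`.

    ``patient_ids`` fixes the patient axis (useful to include patients
    with no exposure); defaults to the patients present in ``segments``.
    ``weight_fn`` maps segment ddd_ratio values to per-medication weights
    accumulated into ``weight_sum``.
    """
    cmap = class_map if class_map is not None else default_class_map()
    if patient_ids is None:
        patient_ids = np.unique(segments["patient_id"].to_numpy())
    else:
        patient_ids = np.asarray(patient_ids)
    p_lookup = {pid: i for i, pid in enumerate(patient_ids)}

    P, D, C = len(patient_ids), window.n_days, cmap.n_classes
    p = segments["patient_id"].map(p_lookup).to_numpy(int)
    c = segments["class_label"].map(
        {lab: i for i, lab in enumerate(cmap.class_labels)}
    ).to_numpy(int)
    s = segments["start_day"].to_numpy(int)
    e = segments["end_day"].to_numpy(int)
    if (s < 0).any() or (e > D).any():
        raise ValueError("segments extend outside the window")

    counts = np.zeros((P, D + 1, C), dtype=np.int16)
    np.add.at(counts, (p, s, c), 1)
    np.add.at(counts, (p, e, c), -1)
    np.cumsum(counts, axis=1, out=counts)
    counts = counts[:, :D, :]

    wsum = None
    if weight_fn is not None:
        w = np.asarray(weight_fn(segments["ddd_ratio"].to_numpy(float)), dtype=np.float32)
        wsum = np.zeros((P, D + 1, C), dtype=np.float32)
        np.add.at(wsum, (p, s, c), w)
        np.add.at(wsum, (p, e, c), -w)
        np.cumsum(wsum, axis=1, out=wsum)
        wsum = wsum[:, :D, :]

    return ActivityCube(
        counts=counts,
        patient_ids=patient_ids,
        class_labels=cmap.class_labels,
        window=window,
        weight_sum=wsum,
    )
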
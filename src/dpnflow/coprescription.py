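"""Prescription-day statistics, polypharmacy flags and subgroup networks.

A *prescription-day* counts one medication active on one day: seven
medications active on a single day contribute 7 prescription-days.
Statistics are reported per calendar year for a focal class
(antidepressants or anxiolytics):

same-class
    prescription-days on patient-days with >= 2 distinct focal-class
    medications active (each such medication counts).
multi-class
    non-focal prescription-days on patient-days where a focal-class
    medication is co-active with >= 1 medication of another class.
total
    all prescription-days (overall medication burden).

"Medications" are distinct ATC level-5 codes, not classes — same-class
co-prescription requires within-class multiplicity.  Per-person means
divide by the year's focal cohort size (patients with >= 1 focal
dispensing that year); the total row uses the whole cohort.

General polypharmacy is >= 5 medications on each of >= 30 consecutive
days (runs may span year boundaries).  Subgroups (<65 / >=65 by year,
polypharmacy yes/no, and their combination) get independently built
networks with identical parameters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .atc import AtcClassMap, default_class_map
from .centrality import daily_centrality, iso_week_label
from .exposure import ActivityCube
from .networks import WeightParams, apply_weighting

__all__ = [
    "prescription_days",
    "same_class_days",
    "multi_class_days",
    "polypharmacy_flags",
    "subgroup_labels",
    "yearly_summary",
    "subgroup_run",
    "AGE_CUTOFF",
]

AGE_CUTOFF = 65  # years; subgroup split <65 vs >=65, evaluated per calendar year


def _day_slice(cube: ActivityCube, start_day: int | None, end_day: int | None) -> slice:
    return slice(start_day or 0, cube.n_days if end_day is None else end_day)


def _patient_rows(cube: ActivityCube, patient_id: str | None) -> np.ndarray:
    if patient_id is None:
        return np.arange(cube.n_patients)
    rows = np.flatnonzero(cube.patient_ids == patient_id)
    if rows.size == 0:
        raise KeyError(f"unknown patient {patient_id!r}")
    return rows


def prescription_days(
    cube: ActivityCube,
    patient_id: str | None = None,
    start_day: int | None = None,
    end_day: int | None = None,
) -> int:
    """Total prescription-days (distinct active medications summed over days)."""
    rows = _patient_rows(cube, patient_id)
    sl = _day_slice(cube, start_day, end_day)
    return int(cube.counts[rows, sl, :].sum())


def _per_patient_stats(
    cube: ActivityCube, focal_idx: int, sl: slice
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(same_class, multi_class, total) prescription-days per patient."""
    nf = cube.counts[:, sl, focal_idx].astype(np.int64)
    total = cube.counts[:, sl, :].sum(axis=2, dtype=np.int64)
    others = total - nf
    same = np.where(nf >= 2, nf, 0).sum(axis=1)
    multi = np.where((nf >= 1) & (others >= 1), others, 0).sum(axis=1)
    return same, multi, total.sum(axis=1)


def same_class_days(
    cube: ActivityCube,
    focal_class: str,
    patient_id: str | None = None,
    start_day: int | None = None,
    end_day: int | None = None,
) -> int:
    """Focal-class prescription-days on days with >=2 focal medications."""
    fidx = cube.class_labels.index(focal_class)
    rows = _patient_rows(cube, patient_id)
    sl = _day_slice(cube, start_day, end_day)
    nf = cube.counts[rows, sl, fidx].astype(np.int64)
    return int(np.where(nf >= 2, nf, 0).sum())


def multi_class_days(
    cube: ActivityCube,
    focal_class: str,
    patient_id: str | None = None,
    start_day: int | None = None,
    end_day: int | None = None,
) -> int:
    """Non-focal prescription-days on days a focal medication is co-active."""
    fidx = cube.class_labels.index(focal_class)
    rows = _patient_rows(cube, patient_id)
    sl = _day_slice(cube, start_day, end_day)
    nf = cube.counts[rows, sl, fidx].astype(np.int64)
    others = cube.counts[rows, sl, :].sum(axis=-1, dtype=np.int64) - nf
    return int(np.where((nf >= 1) & (others >= 1), others, 0).sum())


def polypharmacy_flags(
    cube: ActivityCube, min_medications: int = 5, min_consecutive_days: int = 30
) -> np.ndarray:
    """Per-patient flag: >= ``min_medications`` active on each day of a run
    of >= ``min_consecutive_days`` consecutive days."""
    burden = cube.counts.sum(axis=2, dtype=np.int64) >= min_medications  # (P, D)
    flags = np.zeros(cube.n_patients, dtype=bool)
    for i, row in enumerate(burden):
        padded = np.concatenate(([False], row, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        if edges.size and (edges[1::2] - edges[0::2]).max() >= min_consecutive_days:
            flags[i] = True
    return flags


def subgroup_labels(
    patients: pd.DataFrame, cube: ActivityCube
) -> pd.DataFrame:
    """Per patient x year subgroup table: age group and polypharmacy flag.

    ``patients`` must carry ``patient_id`` and ``birth_year`` (one row
    per patient).  Age group is evaluated per calendar year (a cohort
    entering at <= 65 can later contain a >=65 subgroup); the
    polypharmacy flag is a whole-window property.
    """
    pat = patients.drop_duplicates("patient_id").set_index("patient_id")
    flags = dict(zip(cube.patient_ids, polypharmacy_flags(cube)))
    years = range(cube.window.start.year, cube.window.end.year + 1)
    rows = []
    for pid in cube.patient_ids:
        by = int(pat.loc[pid, "birth_year"])
        for year in years:
            age = year - by
            rows.append(
                {
                    "patient_id": pid,
                    "year": year,
                    "age_group": "<65" if age < AGE_CUTOFF else ">=65",
                    "polypharmacy": bool(flags[pid]),
                }
            )
    return pd.DataFrame(rows)


def _year_slice(cube: ActivityCube, year: int) -> slice:
    import datetime as dt

    w = cube.window
    s = max(w.day_index(dt.date(year, 1, 1)), 0)
    e = min(w.day_index(dt.date(year, 12, 31)) + 1, w.n_days)
    return slice(s, e)


def yearly_summary(
    records: pd.DataFrame,
    cube: ActivityCube,
    focal_classes: tuple[str, ...] = ("Antidepressants", "Anxiolytics"),
    class_map: AtcClassMap | None = None,
) -> pd.DataFrame:
    """Yearly same-class / multi-class / total prescription-day summary.

    One row per (year, focal class).  Totals are population sums over
    the focal cohort (total column: whole cohort); means and SDs are per
    person over the relevant cohort.
    """
    cmap = class_map if class_map is not None else default_class_map()
    labels = cmap.map_series(records["atc_code"])
    rec_year = pd.to_datetime(records["dispense_date"]).dt.year
    p_pos = {pid: i for i, pid in enumerate(cube.patient_ids)}

    rows = []
    for year in range(cube.window.start.year, cube.window.end.year + 1):
        sl = _year_slice(cube, year)
        for focal in focal_classes:
            fidx = cube.class_labels.index(focal)
            same, multi, total = _per_patient_stats(cube, fidx, sl)
            cohort_ids = records.loc[
                (labels == focal) & (rec_year == year), "patient_id"
            ].unique()
            cmask = np.zeros(cube.n_patients, dtype=bool)
            cmask[[p_pos[pid] for pid in cohort_ids if pid in p_pos]] = True

            def _stats(v: np.ndarray, mask: np.ndarray) -> tuple[int, float, float]:
                sel = v[mask]
                if sel.size == 0:
                    return 0, np.nan, np.nan
                sd = float(sel.std(ddof=1)) if sel.size > 1 else 0.0
                return int(sel.sum()), float(sel.mean()), sd

            s_tot, s_mean, s_sd = _stats(same, cmask)
            m_tot, m_mean, m_sd = _stats(multi, cmask)
            all_mask = np.ones(cube.n_patients, dtype=bool)
            t_tot, t_mean, t_sd = _stats(total, all_mask)
            rows.append(
                {
                    "year": year,
                    "focal_class": focal,
                    "same_class_total": s_tot,
                    "same_class_mean": s_mean,
                    "same_class_sd": s_sd,
                    "multi_class_total": m_tot,
                    "multi_class_mean": m_mean,
                    "multi_class_sd": m_sd,
                    "total_n": t_tot,
                    "total_mean": t_mean,
                    "total_sd": t_sd,
                }
            )
    return pd.DataFrame(rows)


def _membership(
    labels: pd.DataFrame, pairing: str
) -> dict[str, pd.DataFrame]:
    """Map group name -> per-year membership (patient_id, year) rows."""
    if pairing == "age":
        return {
            "<65": labels[labels["age_group"] == "<65"],
            ">=65": labels[labels["age_group"] == ">=65"],
        }
    if pairing == "polypharmacy":
        return {
            "non_polypharmacy": labels[~labels["polypharmacy"]],
            "polypharmacy": labels[labels["polypharmacy"]],
        }
    if pairing == "combined":
        return {
            "<65_non_polypharmacy": labels[
                (labels["age_group"] == "<65") & ~labels["polypharmacy"]
            ],
            ">=65_polypharmacy": labels[
                (labels["age_group"] == ">=65") & labels["polypharmacy"]
            ],
        }
    raise ValueError("pairing must be 'age', 'polypharmacy' or 'combined'")


def subgroup_run(
    cube: ActivityCube,
    labels: pd.DataFrame,
    pairing: str,
    params: WeightParams | None = None,
    class_weights: np.ndarray | None = None,
) -> dict[str, dict]:
    """Build per-subgroup daily networks and weekly centrality.

    Subgroup membership is evaluated per calendar year (age can change),
    the networks use identical weighting parameters, and each group gets
    ``{"counts": (D,n,n), "weighted": (D,n,n), "weekly_centrality": df}``.
    An empty subgroup is reported with a warning-style empty entry.
    """
    import warnings

    params = params or WeightParams()
    need_per_record = params.mode == "per_record" and params.combine == "multiply_counts"
    wmean = cube.weight_mean() if need_per_record else None
    n = len(cube.class_labels)
    p_pos = {pid: i for i, pid in enumerate(cube.patient_ids)}
    day_year = np.array([cube.window.date_of(d).year for d in range(cube.n_days)])

    out: dict[str, dict] = {}
    for group, member in _membership(labels, pairing).items():
        if member.empty:
            warnings.warn(f"subgroup {group!r} is empty", stacklevel=2)
            out[group] = {"counts": None, "weighted": None, "weekly_centrality": None}
            continue
        mask_by_year = {
            year: np.isin(
                np.arange(cube.n_patients),
                [p_pos[pid] for pid in g["patient_id"] if pid in p_pos],
            )
            for year, g in member.groupby("year")
        }
        counts = np.zeros((cube.n_days, n, n), dtype=np.int64)
        weighted = np.zeros((cube.n_days, n, n), dtype=float)
        active = cube.active
        for d in range(cube.n_days):
            mask = mask_by_year.get(int(day_year[d]))
            if mask is None or not mask.any():
                continue
            X = active[mask, d, :]
            Xf = X.astype(np.float64)
            counts[d] = (Xf.T @ Xf).astype(np.int64)
            weighted[d] = apply_weighting(
                counts[d], params,
                class_weights=class_weights,
                active=X,
                weight_mean=None if wmean is None else wmean[mask, d, :].astype(np.float64),
            )
        cen = daily_centrality(weighted, cube.window, cube.class_labels)
        conv = cen[cen["converged"]].copy()
        conv["week"] = iso_week_label(conv["date"]).to_numpy()
        weekly = (
            conv.groupby(["week", "class"], sort=True)["centrality"]
            .mean()
            .rename("mean_centrality")
            .reset_index()
        )
        out[group] = {"counts": counts, "weighted": weighted, "weekly_centrality": weekly}
    return out
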
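"""Daily drug-prescription networks and DDD-based edge weighting.

An individual's daily network is a binary symmetric 24x24 adjacency with
an edge between every pair of therapeutic classes concurrently active
that day.  Population networks are element-wise sums of the individual
matrices; the off-diagonal entry (i, j) counts patients with classes i
and j co-active, and the diagonal holds per-class active-patient counts
(excluded again from all network analysis).

Edge weights adjust co-prescription counts for dosing intensity: each
medication gets a Gaussian-kernel weight

    w(ddd) = 1/(sigma sqrt(2 pi)) * exp(-(ddd - 1)^2 / (2 sigma^2))

centred at the baseline DDD ratio of 1 (default sigma = 1/3), and an
edge combines the two endpoint weights by their average.  By default the
pair-average weight multiplies the co-prescription count
(``combine="multiply_counts"``); ``combine="literal_eq4"`` instead uses
the bare pair-average wherever a co-prescription exists, discarding
frequency — both conventions appear in the field and both are kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atc import AtcClassMap, default_class_map
from .exposure import ActivityCube, Window

__all__ = [
    "WeightParams",
    "gaussian_weight",
    "edge_weight",
    "DailyIndividualNetwork",
    "build_individual_daily",
    "aggregate_population",
    "class_mean_weights",
    "apply_weighting",
    "daily_networks_from_cube",
    "write_daily_edges",
    "read_daily_edges",
]


@dataclass(frozen=True)
class WeightParams:
    """Parameters of the DDD edge-weighting kernel."""

    sigma: float = 1.0 / 3.0
    baseline: float = 1.0
    #: "per_record": each dispensing's ddd_ratio is weighted, averaged within
    #: patient-day-class; "class_mean": one weight per class (mean of its
    #: per-record weights).
    mode: str = "per_record"
    combine: str = "multiply_counts"
    #: scale the kernel so w(baseline) = 1 instead of the density peak
    peak_normalized: bool = False

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.mode not in ("per_record", "class_mean"):
            raise ValueError("mode must be 'per_record' or 'class_mean'")
        if self.combine not in ("multiply_counts", "literal_eq4"):
            raise ValueError("combine must be 'multiply_counts' or 'literal_eq4'")


def gaussian_weight(ddd, params: WeightParams | None = None):
    """Gaussian-kernel weight of a DDD ratio (scalar or array)."""
    p = params or WeightParams()
    ddd = np.asarray(ddd, dtype=float)
    if np.any(ddd < 0) or not np.all(np.isfinite(ddd)):
        raise ValueError("ddd must be finite and >= 0")
    w = np.exp(-((ddd - p.baseline) ** 2) / (2.0 * p.sigma**2))
    if not p.peak_normalized:
        w = w / (p.sigma * np.sqrt(2.0 * np.pi))
    return w if w.ndim else float(w)


def edge_weight(w_i: float, w_j: float) -> float:
    """Edge weight = average of the two endpoint weights."""
    return 0.5 * (w_i + w_j)


@dataclass(frozen=True)
class DailyIndividualNetwork:
    """Binary symmetric daily adjacency of one patient.

    ``active_classes`` keeps the day's active class indices; the
    adjacency alone cannot represent a single-class day (it is all
    zero), yet such days still count on population diagonals.
    """

    patient_id: str
    day: int
    adjacency: np.ndarray
    active_classes: tuple[int, ...] = ()


def build_individual_daily(
    active: set | dict | list,
    class_map: AtcClassMap | None = None,
    patient_id: str = "",
    day: int = 0,
) -> DailyIndividualNetwork:
    """Individual daily network from an active-medication set.

    ``active`` is an iterable of ``(atc_code, class_label, ddd_ratio)``
    tuples (as produced by :func:`dpnflow.exposure.daily_active_sets`)
    or simply of class labels.  With k distinct active classes the
    network has k(k-1)/2 edges and a zero diagonal.
    """
    cmap = class_map if class_map is not None else default_class_map()
    labels = {t[1] if isinstance(t, tuple) else t for t in active}
    idx = np.array(sorted(cmap.class_index(lab) for lab in labels), dtype=int)
    n = cmap.n_classes
    A = np.zeros((n, n), dtype=np.int8)
    if idx.size >= 2:
        A[np.ix_(idx, idx)] = 1
        A[idx, idx] = 0
    return DailyIndividualNetwork(
        patient_id=patient_id, day=day, adjacency=A, active_classes=tuple(idx)
    )


def aggregate_population(
    networks: list[DailyIndividualNetwork], day: int | None = None
) -> np.ndarray:
    """Element-wise sum of individual daily networks (count matrix).

    The off-diagonal entry (i, j) is the number of patients with classes
    i and j co-active; the diagonal is filled with per-class
    active-patient counts (an individual's own diagonal is zero).
    """
    if not networks:
        raise ValueError("no networks to aggregate")
    days = {net.day for net in networks}
    if day is not None:
        days.add(day)
    if len(days) > 1:
        raise ValueError(f"networks from mixed days: {sorted(days)}")
    counts = np.zeros_like(networks[0].adjacency, dtype=np.int64)
    for net in networks:
        counts += net.adjacency
        for i in net.active_classes:
            counts[i, i] += 1
    return counts


def class_mean_weights(
    segments: pd.DataFrame, class_map: AtcClassMap, params: WeightParams
) -> np.ndarray:
    """Per-class weight: mean of per-record kernel weights (exposure-weighted)."""
    w = gaussian_weight(segments["ddd_ratio"].to_numpy(float), params)
    days = (segments["end_day"] - segments["start_day"]).to_numpy(float)
    out = np.zeros(class_map.n_classes)
    for i, lab in enumerate(class_map.class_labels):
        m = segments["class_label"].to_numpy() == lab
        out[i] = np.average(w[m], weights=days[m]) if m.any() else np.nan
    return out


def apply_weighting(
    counts: np.ndarray,
    params: WeightParams,
    class_weights: np.ndarray | None = None,
    active: np.ndarray | None = None,
    weight_mean: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted adjacency for one day.

    Class-mean mode needs ``class_weights`` (length-n vector); per-record
    mode needs the day's ``active`` (patients x classes bool) and
    ``weight_mean`` (patients x classes mean medication weight) slices.
    The diagonal is forced to zero in every mode.
    """
    n = counts.shape[0]
    if params.combine == "literal_eq4" or params.mode == "class_mean":
        if class_weights is None:
            raise ValueError("class weights required for this weighting mode")
        if np.isnan(class_weights).any():
            bad = [i for i in range(n) if np.isnan(class_weights[i])]
            raise ValueError(f"missing class weight for class indices {bad}")
        pair = 0.5 * (class_weights[:, None] + class_weights[None, :])
        if params.combine == "literal_eq4":
            W = np.where(counts > 0, pair, 0.0)
        else:
            W = counts * pair
    else:  # per_record, multiply_counts
        if active is None or weight_mean is None:
            raise ValueError("per-record weighting needs active and weight_mean")
        X = active.astype(np.float64)
        XW = X * weight_mean
        W = 0.5 * (XW.T @ X + X.T @ XW)
    W = W.astype(float)
    np.fill_diagonal(W, 0.0)
    return W


def daily_networks_from_cube(
    cube: ActivityCube, params: WeightParams | None = None,
    class_weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """All daily count and weighted matrices from an activity cube.

    Returns ``(counts, weighted)`` of shapes (D, n, n); ``counts`` holds
    patient co-activity counts with active-patient diagonals, ``weighted``
    the zero-diagonal weighted adjacency used for centrality.
    """
    params = params or WeightParams()
    D = cube.n_days
    n = len(cube.class_labels)
    counts = np.empty((D, n, n), dtype=np.int64)
    weighted = np.empty((D, n, n), dtype=float)

    need_per_record = params.mode == "per_record" and params.combine == "multiply_counts"
    wmean = cube.weight_mean() if need_per_record else None
    if not need_per_record and class_weights is None:
        raise ValueError("class_weights required for class-mean / literal weighting")

    active = cube.active
    for d in range(D):
        X = active[:, d, :]
        Xf = X.astype(np.float64)
        counts[d] = (Xf.T @ Xf).astype(np.int64)
        weighted[d] = apply_weighting(
            counts[d], params,
            class_weights=class_weights,
            active=X,
            weight_mean=None if wmean is None else wmean[:, d, :].astype(np.float64),
        )
    return counts, weighted


def write_daily_edges(
    counts: np.ndarray,
    weighted: np.ndarray,
    window: Window,
    class_labels: tuple[str, ...],
    edges_path,
    diagonal_path,
) -> None:
    """Long-format CSV output of the daily networks.

    Edges file: ``day,date,class_i,class_j,count,weight`` with i < j
    lexicographically, nonzero rows only; diagonal file:
    ``day,date,class,single_count``.  Matrices are reconstructible
    bit-exactly via :func:`read_daily_edges`.
    """
    n = len(class_labels)
    iu, ju = np.triu_indices(n, k=1)
    order = np.array([class_labels[a] <= class_labels[b] for a, b in zip(iu, ju)])
    ci = np.where(order, iu, ju)
    cj = np.where(order, ju, iu)
    dates = window.dates().strftime("%Y-%m-%d")

    rows = []
    for d in range(counts.shape[0]):
        cvals = counts[d, iu, ju]
        wvals = weighted[d, iu, ju]
        nz = cvals > 0
        for a, b, cv, wv in zip(ci[nz], cj[nz], cvals[nz], wvals[nz]):
            rows.append((d, dates[d], class_labels[a], class_labels[b], int(cv), wv))
    pd.DataFrame(
        rows, columns=["day", "date", "class_i", "class_j", "count", "weight"]
    ).to_csv(edges_path, index=False, float_format="%.17g")

    diag = []
    for d in range(counts.shape[0]):
        for i, lab in enumerate(class_labels):
            v = int(counts[d, i, i])
            if v:
                diag.append((d, dates[d], lab, v))
    pd.DataFrame(diag, columns=["day", "date", "class", "single_count"]).to_csv(
        diagonal_path, index=False
    )


def read_daily_edges(
    edges_path, diagonal_path, window: Window, class_labels: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`write_daily_edges`."""
    n = len(class_labels)
    lut = {lab: i for i, lab in enumerate(class_labels)}
    counts = np.zeros((window.n_days, n, n), dtype=np.int64)
    weighted = np.zeros((window.n_days, n, n), dtype=float)
    e = pd.read_csv(edges_path)
    for r in e.itertuples(index=False):
        i, j = lut[r.class_i], lut[r.class_j]
        counts[r.day, i, j] = counts[r.day, j, i] = r.count
        weighted[r.day, i, j] = weighted[r.day, j, i] = r.weight
    g = pd.read_csv(diagonal_path)
    for day, lab, v in zip(g["day"], g["class"], g["single_count"]):
        counts[day, lut[lab], lut[lab]] = v
    return counts, weighted
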
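"""Eigenvector centrality of daily networks and weekly aggregation.

Centrality solves ``c_i = (1/lambda) * sum_{j != i} W_ji c_j`` for the
dominant eigenpair of the symmetric nonnegative weighted adjacency,
L1-normalised so the centralities sum to 1.  With that normalisation the
uniformly connected (complete, unweighted) network gives every node
exactly 1/n, which serves as the classification baseline: a class is
"high" centrality iff its mean centrality strictly exceeds 1/n.

Computation is by power iteration from the uniform vector; on a
disconnected graph this converges to the dominant component's
eigenvector.  An all-zero matrix yields a missing (NaN) result flagged
as not converged rather than a fabricated uniform vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exposure import Window

__all__ = [
    "CentralityResult",
    "eigenvector_centrality",
    "classify_centrality",
    "daily_centrality",
    "daily_dispensing_metrics",
    "weekly_aggregate",
    "iso_week_label",
]


@dataclass(frozen=True)
class CentralityResult:
    c: np.ndarray  # L1-normalised nonnegative centralities (NaN if not converged)
    lam: float  # leading eigenvalue
    converged: bool
    iterations: int


def eigenvector_centrality(
    W: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000
) -> CentralityResult:
    """Dominant eigenvector of a symmetric nonnegative matrix, sum-1 scaled."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.all(np.isfinite(W)):
        raise ValueError("W contains non-finite entries")
    if (W < 0).any():
        raise ValueError("W contains negative entries")
    if not np.allclose(W, W.T):
        raise ValueError("W must be symmetric")

    n = W.shape[0]
    v = np.full(n, 1.0 / n)
    if not W.any():
        return CentralityResult(np.full(n, np.nan), 0.0, False, 0)

    # iterate on W + sigma*I: same eigenvectors, but the dominant
    # eigenvalue becomes strictly largest in magnitude even on bipartite
    # graphs (lambda_min = -lambda_max), where the unshifted iteration
    # oscillates with period 2
    sigma = float(np.abs(W).max())
    M = W + sigma * np.eye(n)
    for it in range(1, max_iter + 1):
        w = M @ v
        w /= w.sum()  # entries stay positive, so the L1 norm is the sum
        if np.max(np.abs(w - v)) < tol:
            v = w
            lam = float((W @ v).sum() / v.sum())
            return CentralityResult(v, lam, True, it)
        v = w
    lam = float((W @ v).sum() / v.sum())
    return CentralityResult(v, lam, False, max_iter)


def classify_centrality(mean_c: float, n: int) -> str:
    """'high' iff strictly above the uniform baseline 1/n (ties are 'low')."""
    return "high" if mean_c > 1.0 / n else "low"


def daily_centrality(
    weighted: np.ndarray, window: Window, class_labels: tuple[str, ...]
) -> pd.DataFrame:
    """Per-day centrality table: ``date, class, centrality, lambda, converged``."""
    dates = window.dates()
    rows = []
    for d in range(weighted.shape[0]):
        res = eigenvector_centrality(weighted[d])
        for i, lab in enumerate(class_labels):
            rows.append(
                (dates[d], lab, res.c[i], res.lam, res.converged)
            )
    return pd.DataFrame(
        rows, columns=["date", "class", "centrality", "lambda", "converged"]
    )


def daily_dispensing_metrics(records: pd.DataFrame, window: Window) -> pd.DataFrame:
    """Daily dispensing volume and patient counts from raw records.

    ``n_dispensings`` counts dispensing events dated that day,
    ``n_patients`` the distinct patients dispensed to; the ratio is
    their quotient (NaN on empty days).
    """
    dates = pd.to_datetime(records["dispense_date"])
    per = records.assign(_date=dates.dt.normalize())
    g = per.groupby("_date")
    daily = pd.DataFrame(
        {
            "n_dispensings": g.size(),
            "n_patients": g["patient_id"].nunique(),
        }
    )
    daily = daily.reindex(window.dates(), fill_value=0)
    daily.index.name = "date"
    with np.errstate(invalid="ignore", divide="ignore"):
        daily["ratio"] = daily["n_dispensings"] / daily["n_patients"].replace(0, np.nan)
    return daily.reset_index()


def iso_week_label(dates: pd.Series | pd.DatetimeIndex) -> pd.Series:
    """ISO-8601 week labels 'YYYY-Www' (e.g. 2018-01-01 -> '2018-W01')."""
    iso = pd.DatetimeIndex(dates).isocalendar()
    return (
        iso["year"].astype(str) + "-W" + iso["week"].astype(str).str.zfill(2)
    ).reset_index(drop=True)


def weekly_aggregate(
    daily_metrics: pd.DataFrame, centrality: pd.DataFrame
) -> pd.DataFrame:
    """Weekly metrics in long format.

    Counts are summed over the ISO week and the dispensing-to-patient
    ratio recomputed from the weekly sums; centrality is averaged over
    days with converged results (missing if none) and classified against
    the 1/n baseline.  Output columns:
    ``week, n_dispensings, n_patients, ratio, class, mean_centrality, level``.
    """
    dm = daily_metrics.copy()
    dm["week"] = iso_week_label(dm["date"]).to_numpy()
    counts = dm.groupby("week", sort=True).agg(
        n_dispensings=("n_dispensings", "sum"), n_patients=("n_patients", "sum")
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        counts["ratio"] = counts["n_dispensings"] / counts["n_patients"].replace(0, np.nan)

    n_classes = centrality["class"].nunique()
    cen = centrality[centrality["converged"]].copy()
    cen["week"] = iso_week_label(cen["date"]).to_numpy()
    mean_c = (
        cen.groupby(["week", "class"], sort=True)["centrality"].mean().rename("mean_centrality")
    )

    out = counts.join(mean_c.reset_index().set_index("week"), how="left")
    out = out.reset_index()
    out["level"] = [
        classify_centrality(v, n_classes) if np.isfinite(v) else ""
        for v in out["mean_centrality"].fillna(np.nan)
    ]
    return out
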
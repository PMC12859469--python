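"""Detrending, seasonal deconstruction, and ACF/PACF correlograms.

Seasonality is explored on detrended daily and weekly series: daily
series are deconstructed by their weekly period (position = weekday,
instance = ISO week), weekly series by their yearly period (position =
ISO week number, instance = year).  Autocorrelations use the biased
(1/N) autocovariance estimator — positive semidefinite by construction —
and partial autocorrelations the Durbin–Levinson recursion; the
approximate 95% significance band is +-1.96/sqrt(N).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .centrality import iso_week_label

__all__ = ["detrend", "seasonal_deconstruct", "acf_pacf", "moving_average_trend"]

WEEKDAY_NAMES = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


def moving_average_trend(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edges use a symmetrically shrinking window."""
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(values, dtype=float)
    n = len(x)
    h = window // 2
    c = np.concatenate(([0.0], np.cumsum(x)))
    out = np.empty(n)
    for i in range(n):
        k = min(h, i, n - 1 - i)  # shrink symmetrically near the edges
        out[i] = (c[i + k + 1] - c[i - k]) / (2 * k + 1)
    return out


def detrend(
    series: pd.Series,
    method: str = "moving_average",
    window: int = 29,
    ssa_components: tuple[int, ...] = (0, 1),
) -> pd.Series:
    """Remove the slow trend from a series; returns series - trend.

    ``moving_average`` uses a centered window (odd length recommended;
    daily default 29, weekly 13 are sensible).  ``ssa_trend`` extracts
    the leading eigentriples of a singular-spectrum embedding with lag
    ``window`` (two by default — a linear ramp occupies two).
    """
    x = series.to_numpy(dtype=float)
    if len(x) <= window:
        raise ValueError(f"series length {len(x)} must exceed window {window}")
    if method == "moving_average":
        trend = moving_average_trend(x, window)
    elif method == "ssa_trend":
        from .ssa import embed, reconstruct

        L = max(2, min(window, len(x) - 1))
        model = embed(x, L)
        trend = reconstruct(model, ssa_components)
    else:
        raise ValueError("method must be 'moving_average' or 'ssa_trend'")
    return pd.Series(x - trend, index=series.index, name=series.name)


def seasonal_deconstruct(series: pd.Series, period: str) -> pd.DataFrame:
    """Long table (period_instance, position, value) for seasonal overlay.

    ``weekday_by_week`` expects a daily series with a DatetimeIndex:
    instance = ISO week label, position = weekday name Mon..Sun.
    ``week_by_year`` expects a weekly series indexed by 'YYYY-Www'
    labels: instance = year, position = ISO week number.  Every input
    point appears exactly once.
    """
    if period == "weekday_by_week":
        idx = pd.DatetimeIndex(series.index)
        return pd.DataFrame(
            {
                "period_instance": iso_week_label(idx).to_numpy(),
                "position": np.asarray(WEEKDAY_NAMES)[idx.weekday],
                "value": series.to_numpy(),
            }
        )
    if period == "week_by_year":
        labels = pd.Index(series.index.astype(str))
        split = labels.str.extract(r"^(\d{4})-W(\d{2})$")
        if split.isna().any().any():
            raise ValueError("weekly index labels must look like 'YYYY-Www'")
        return pd.DataFrame(
            {
                "period_instance": split[0].astype(int).to_numpy(),
                "position": split[1].astype(int).to_numpy(),
                "value": series.to_numpy(),
            }
        )
    raise ValueError("period must be 'weekday_by_week' or 'week_by_year'")


def acf_pacf(series: pd.Series | np.ndarray, max_lag: int) -> pd.DataFrame:
    """Correlogram table: ``lag, acf, pacf, band`` for lags 0..max_lag.

    ACF is the biased autocovariance ratio; PACF comes from the
    Durbin–Levinson recursion on it (pacf[0] = 1 by convention).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n <= max_lag + 1:
        raise ValueError("series length must exceed max_lag + 1")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        raise ValueError("zero-variance series has no correlogram")

    acf = np.empty(max_lag + 1)
    acf[0] = 1.0
    for k in range(1, max_lag + 1):
        acf[k] = float(xc[k:] @ xc[:-k]) / denom

    # Durbin–Levinson: phi[k, k] is the partial autocorrelation at lag k
    pacf = np.empty(max_lag + 1)
    pacf[0] = 1.0
    phi_prev = np.zeros(0)
    for k in range(1, max_lag + 1):
        if k == 1:
            phi_kk = acf[1]
            phi = np.array([phi_kk])
        else:
            num = acf[k] - phi_prev @ acf[1:k][::-1]
            den = 1.0 - phi_prev @ acf[1:k]
            phi_kk = num / den
            phi = np.concatenate([phi_prev - phi_kk * phi_prev[::-1], [phi_kk]])
        pacf[k] = phi_kk
        phi_prev = phi

    band = 1.96 / np.sqrt(n)
    return pd.DataFrame(
        {"lag": np.arange(max_lag + 1), "acf": acf, "pacf": pacf, "band": band}
    )
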
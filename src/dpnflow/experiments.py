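"""Validation experiments: parameter recovery and numerical cross-checks.

These are the package's own end-to-end checks that the analysis recovers
structure deliberately planted in the synthetic registry (a boosted hub
class, a configured secular trend, the weekday cycle), plus numerical
comparisons of the hand-rolled primitives against independent oracles
(dense eigensolver, brute-force pairwise scans).  Each function is
deterministic given its seed and returns plain numbers.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .atc import ANTIDEPRESSANTS
from .centrality import daily_dispensing_metrics, eigenvector_centrality, iso_week_label
from .coprescription import subgroup_labels, subgroup_run
from .exposure import Window, build_activity_cube, build_exposure
from .networks import WeightParams, daily_networks_from_cube, gaussian_weight
from .seasonality import acf_pacf, detrend
from .simulate import SimulationConfig, simulate_registry
from .ssa import embed, mann_kendall, reconstruct

__all__ = [
    "mean_centrality_by_class",
    "hub_recovery",
    "trend_recovery",
    "weekly_cycle_acf",
    "subgroup_conservation",
    "power_iteration_vs_eigh",
    "ssa_completeness",
    "mann_kendall_bruteforce_mismatches",
    "mann_kendall_type1_error",
]


def _simulated_networks(cfg: SimulationConfig):
    records = simulate_registry(cfg)
    window = Window(cfg.window_start, cfg.window_end)
    params = WeightParams()
    segments = build_exposure(records, window)
    cube = build_activity_cube(
        segments, window,
        patient_ids=np.unique(records["patient_id"].to_numpy()),
        weight_fn=lambda d: gaussian_weight(d, params),
    )
    counts, weighted = daily_networks_from_cube(cube, params)
    return records, cube, counts, weighted


def mean_centrality_by_class(weighted: np.ndarray, class_labels) -> pd.Series:
    """Mean daily eigenvector centrality per class (converged days only)."""
    vals = []
    for d in range(weighted.shape[0]):
        res = eigenvector_centrality(weighted[d])
        if res.converged:
            vals.append(res.c)
    return pd.Series(np.mean(vals, axis=0), index=list(class_labels))


def hub_recovery(
    n_seeds: int = 20,
    n_patients: int = 2000,
    hub_class: str = "Respiratory",
    hub_boost: float = 3.0,
    base_seed: int = 0,
) -> dict:
    """Fraction of seeds where a rate-boosted class lands in the top-2
    mean eigenvector centralities over one simulated year."""
    ranks = []
    for i in range(n_seeds):
        cfg = SimulationConfig(
            n_patients=n_patients,
            window_start=dt.date(2018, 1, 1),
            window_end=dt.date(2018, 12, 31),
            planted_hub_class=hub_class,
            hub_boost=hub_boost,
            seed=(base_seed + 1000 * i) % 2**31,
        )
        _, cube, _, weighted = _simulated_networks(cfg)
        mean_c = mean_centrality_by_class(weighted, cube.class_labels)
        order = mean_c.sort_values(ascending=False).index
        ranks.append(int(list(order).index(hub_class)))
    rate = float(np.mean([r < 2 for r in ranks]))
    return {"rate": rate, "ranks": ranks, "n_seeds": n_seeds}


def trend_recovery(
    n_seeds: int = 20,
    n_patients: int = 500,
    slope: float = 0.05,
    trend_class: str = ANTIDEPRESSANTS,
    p_threshold: float = 0.01,
    base_seed: int = 0,
) -> dict:
    """Fraction of seeds where a configured +slope/year class trend is
    detected (positive S, p < threshold) by Mann–Kendall on the weekly
    dispensing series over the five-year window."""
    hits = 0
    for i in range(n_seeds):
        cfg = SimulationConfig(
            n_patients=n_patients,
            class_trend_slopes={trend_class: slope},
            seed=(base_seed + 1000 * i + 1) % 2**31,
        )
        records = simulate_registry(cfg)
        mask = records["atc_code"].str.startswith("N06A")
        weekly = (
            pd.Series(1.0, index=records.index)[mask]
            .groupby(iso_week_label(records.loc[mask, "dispense_date"]).to_numpy())
            .sum()
        )
        r = mann_kendall(weekly.to_numpy(float))
        hits += r.S > 0 and r.p < p_threshold
    return {"rate": hits / n_seeds, "n_seeds": n_seeds}


def weekly_cycle_acf(n_patients: int = 2000, seed: int = 0) -> dict:
    """acf(7) of detrended daily dispensing on simulator defaults, with the
    +-1.96/sqrt(N) significance band."""
    cfg = SimulationConfig(
        n_patients=n_patients,
        window_start=dt.date(2018, 1, 1),
        window_end=dt.date(2018, 12, 31),
        seed=seed % 2**31,
    )
    records = simulate_registry(cfg)
    window = Window(cfg.window_start, cfg.window_end)
    daily = daily_dispensing_metrics(records, window).set_index("date")[
        "n_dispensings"
    ].astype(float)
    out = acf_pacf(detrend(daily, "moving_average", 29), 7)
    return {"acf7": float(out["acf"].iloc[7]), "band": float(out["band"].iloc[7])}


def subgroup_conservation(n_patients: int = 500, seed: int = 0) -> dict:
    """Largest absolute difference between summed subgroup count matrices
    and the whole-population counts (0 = exact conservation)."""
    cfg = SimulationConfig(
        n_patients=n_patients,
        window_start=dt.date(2018, 1, 1),
        window_end=dt.date(2018, 12, 31),
        seed=seed % 2**31,
    )
    records, cube, counts, _ = _simulated_networks(cfg)
    labels = subgroup_labels(records[["patient_id", "birth_year"]], cube)
    worst = 0
    for pairing in ("age", "polypharmacy"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # a side may be empty at small n
            groups = subgroup_run(cube, labels, pairing, WeightParams())
        total = np.zeros_like(counts)
        for res in groups.values():
            if res["counts"] is not None:
                total += res["counts"]
        worst = max(worst, int(np.abs(total - counts).max()))
    return {"max_abs_diff": worst, "n_patients": n_patients}


def power_iteration_vs_eigh(n_matrices: int = 100, n: int = 24, seed: int = 0) -> dict:
    """Max L-infinity gap between power-iteration centrality and the dense
    symmetric eigensolver on random nonnegative matrices."""
    rng = np.random.default_rng(seed % 2**31)
    worst = 0.0
    for _ in range(n_matrices):
        A = rng.random((n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        res = eigenvector_centrality(A)
        _, vecs = np.linalg.eigh(A)
        v = np.abs(vecs[:, -1])
        v /= v.sum()
        worst = max(worst, float(np.max(np.abs(res.c - v))))
    return {"max_linf": worst, "n_matrices": n_matrices}


def ssa_completeness(n_series: int = 100, length: int = 261, seed: int = 0) -> dict:
    """Worst relative error of all-eigentriple SSA reconstruction at both
    the yearly lag (52) and the maximal lag (N//2)."""
    rng = np.random.default_rng(seed % 2**31)
    worst = 0.0
    for _ in range(n_series):
        x = rng.normal(size=length)
        for L in (52, length // 2):
            m = embed(x, L)
            r = reconstruct(m, range(len(m.s)))
            worst = max(worst, float(np.max(np.abs(r - x)) / np.max(np.abs(x))))
    return {"max_rel_error": worst, "n_series": n_series}


def mann_kendall_bruteforce_mismatches(
    n_series: int = 200, length: int = 10, seed: int = 0
) -> dict:
    """Number of random series where the S statistic disagrees with an
    explicit double loop (0 = exact agreement)."""
    rng = np.random.default_rng(seed % 2**31)
    mism = 0
    for _ in range(n_series):
        x = rng.integers(0, 6, size=length).astype(float)
        r = mann_kendall(x)
        s = sum(
            np.sign(x[j] - x[i])
            for i in range(length)
            for j in range(i + 1, length)
        )
        mism += int(r.S != int(s))
    return {"mismatches": mism, "n_series": n_series}


def mann_kendall_type1_error(
    n_replicates: int = 2000, length: int = 100, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Empirical rejection rate of Mann–Kendall on white noise."""
    rng = np.random.default_rng(seed % 2**31)
    rej = sum(
        mann_kendall(rng.normal(size=length)).p < alpha for _ in range(n_replicates)
    )
    return {"rate": rej / n_replicates, "n_replicates": n_replicates}
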
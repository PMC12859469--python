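"""End-to-end pipeline: registry -> exposure -> networks -> centrality ->
co-prescription statistics -> seasonality -> SSA decomposition.

Every stage logs its input/output row counts, all outputs are plain CSV,
and a manifest records the configuration hash, seed and per-stage counts
so that identical config + seed reproduces identical tables.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atc import ANTIDEPRESSANTS, ANXIOLYTICS, AtcClassMap, default_class_map
from .centrality import (
    daily_centrality,
    daily_dispensing_metrics,
    iso_week_label,
    weekly_aggregate,
)
from .coprescription import subgroup_labels, subgroup_run, yearly_summary
from .exposure import Window, build_activity_cube, build_exposure
from .networks import (
    WeightParams,
    class_mean_weights,
    daily_networks_from_cube,
    gaussian_weight,
    write_daily_edges,
)
from .registry import CohortSpec, filter_cohort, read_registry, write_registry
from .seasonality import acf_pacf, detrend, seasonal_deconstruct
from .simulate import SimulationConfig, simulate_registry
from .ssa import mann_kendall, two_stage_ssa

__all__ = ["PipelineConfig", "run_pipeline", "verify_outputs"]

log = logging.getLogger("dpnflow")


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on, with study defaults."""

    output_dir: str = "dpn_output"
    registry_path: str | None = None  # None -> simulate
    window_start: dt.date = dt.date(2018, 1, 1)
    window_end: dt.date = dt.date(2022, 12, 31)
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    weight: dict = field(default_factory=dict)  # sigma, mode, combine, peak_normalized
    refill_policy: str = "union"
    subgroup_pairings: tuple[str, ...] = ("age", "polypharmacy", "combined")
    ssa_L1: int = 52
    ssa_components: int = 25
    ssa_trend_components: tuple[int, ...] = (0,)
    detrend_window_daily: int = 29
    max_lag_daily: int = 60
    save_registry: bool = True
    save_daily_edges: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("window_start", "window_end"):
            if key in d and isinstance(d[key], str):
                d[key] = dt.date.fromisoformat(d[key])
        for key in ("subgroup_pairings", "ssa_trend_components"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["window_start"] = self.window_start.isoformat()
        d["window_end"] = self.window_end.isoformat()
        d["subgroup_pairings"] = list(self.subgroup_pairings)
        d["ssa_trend_components"] = list(self.ssa_trend_components)
        return d


def _slug(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]", "_", name.replace("<", "lt").replace(">=", "ge"))


def _weekly_series(values: pd.Series, dates: pd.Series) -> pd.Series:
    week = iso_week_label(dates).to_numpy()
    out = pd.Series(values.to_numpy(), index=week).groupby(level=0, sort=True).sum()
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    cfg = config
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cmap = default_class_map()
    window = Window(cfg.window_start, cfg.window_end)
    counts_log: dict[str, int] = {}
    started = dt.datetime.now().isoformat(timespec="seconds")

    # stage: registry
    if cfg.registry_path is not None:
        records, rejections = read_registry(cfg.registry_path)
        if rejections:
            log.warning("registry: %d rows rejected", len(rejections))
        counts_log["registry_rejected_rows"] = len(rejections)
    else:
        sim_cfg = SimulationConfig(
            window_start=cfg.window_start,
            window_end=cfg.window_end,
            seed=cfg.seed,
            **cfg.simulation,
        )
        records = simulate_registry(sim_cfg)
        if cfg.save_registry:
            write_registry(records, out / "registry.csv")
    counts_log["registry_rows"] = len(records)
    log.info("registry: %d records", len(records))
    if records.empty:
        raise RuntimeError("stage registry: no records")

    # stage: cohort
    spec = CohortSpec(
        window_start=cfg.window_start, window_end=cfg.window_end, **cfg.cohort
    )
    cohort = filter_cohort(records, spec, cmap)
    counts_log["cohort_rows"] = len(cohort)
    counts_log["cohort_patients"] = cohort["patient_id"].nunique()
    log.info("cohort: %d records, %d patients",
             len(cohort), counts_log["cohort_patients"])
    if cohort.empty:
        raise RuntimeError("stage cohort: empty cohort")

    # stage: exposure
    segments = build_exposure(cohort, window, cmap, refill_policy=cfg.refill_policy)
    counts_log["exposure_segments"] = len(segments)
    log.info("exposure: %d segments", len(segments))

    params = WeightParams(**cfg.weight)
    cube = build_activity_cube(
        segments, window, cmap,
        patient_ids=np.unique(cohort["patient_id"].to_numpy()),
        weight_fn=lambda d: gaussian_weight(d, params),
    )

    # stage: networks
    cls_w = class_mean_weights(segments, cmap, params)
    need_cw = not (params.mode == "per_record" and params.combine == "multiply_counts")
    counts, weighted = daily_networks_from_cube(
        cube, params, class_weights=cls_w if need_cw else None
    )
    if cfg.save_daily_edges:
        write_daily_edges(
            counts, weighted, window, cmap.class_labels,
            out / "network_daily_edges.csv", out / "network_daily_diagonal.csv",
        )
    counts_log["network_days"] = counts.shape[0]
    log.info("networks: %d days", counts.shape[0])

    # stage: centrality + weekly metrics
    cen = daily_centrality(weighted, window, cmap.class_labels)
    cen_out = cen.copy()
    cen_out["date"] = pd.DatetimeIndex(cen_out["date"]).strftime("%Y-%m-%d")
    cen_out.to_csv(out / "centrality_daily.csv", index=False, float_format="%.17g")
    daily_metrics = daily_dispensing_metrics(cohort, window)
    weekly = weekly_aggregate(daily_metrics, cen)
    weekly.to_csv(out / "metrics_weekly.csv", index=False, float_format="%.17g")
    counts_log["weekly_rows"] = len(weekly)
    log.info("centrality: %d daily rows, %d weekly rows", len(cen), len(weekly))

    # stage: co-prescription + subgroups
    ysum = yearly_summary(cohort, cube, (ANTIDEPRESSANTS, ANXIOLYTICS), cmap)
    ysum.to_csv(out / "coprescription_yearly.csv", index=False, float_format="%.17g")
    labels = subgroup_labels(cohort[["patient_id", "birth_year"]], cube)
    labels.to_csv(out / "subgroups.csv", index=False)
    counts_log["coprescription_rows"] = len(ysum)
    for pairing in cfg.subgroup_pairings:
        groups = subgroup_run(
            cube, labels, pairing, params,
            class_weights=cls_w if need_cw else None,
        )
        for gname, res in groups.items():
            if res["weekly_centrality"] is None:
                continue
            stem = f"subgroup_{pairing}_{_slug(gname)}"
            res["weekly_centrality"].to_csv(
                out / f"{stem}_weekly_centrality.csv", index=False, float_format="%.17g"
            )
            write_daily_edges(
                res["counts"], res["weighted"], window, cmap.class_labels,
                out / f"{stem}_edges.csv", out / f"{stem}_diagonal.csv",
            )
    log.info("subgroups: pairings %s", list(cfg.subgroup_pairings))

    # stage: seasonality
    daily = daily_metrics.set_index("date")["n_dispensings"].astype(float)
    weekly_total = _weekly_series(
        daily_metrics["n_dispensings"], daily_metrics["date"]
    ).astype(float)
    daily_dt = detrend(daily, "moving_average", cfg.detrend_window_daily)
    weekly_dt = detrend(weekly_total, "moving_average", 13)
    correlograms = []
    for name, series, lag in (
        ("dispensings_daily_detrended", daily_dt, cfg.max_lag_daily),
        ("dispensings_weekly_detrended", weekly_dt, min(60, len(weekly_dt) - 2)),
    ):
        cg = acf_pacf(series, lag)
        cg.insert(0, "series", name)
        correlograms.append(cg)
    pd.concat(correlograms).to_csv(
        out / "correlogram.csv", index=False, float_format="%.17g"
    )
    longs = []
    for name, tbl in (
        ("dispensings_daily", seasonal_deconstruct(daily_dt, "weekday_by_week")),
        ("dispensings_weekly", seasonal_deconstruct(weekly_dt, "week_by_year")),
    ):
        tbl.insert(0, "series", name)
        longs.append(tbl)
    pd.concat(longs).to_csv(
        out / "seasonal_long.csv", index=False, float_format="%.17g"
    )

    # stage: SSA decomposition + trend tests
    rec_labels = cmap.map_series(cohort["atc_code"])
    ones = pd.Series(1.0, index=cohort.index)
    ssa_inputs: dict[str, pd.Series] = {"dispensings_total": weekly_total}
    for focal in (ANTIDEPRESSANTS, ANXIOLYTICS):
        mask = rec_labels == focal
        ssa_inputs[f"dispensings_{_slug(focal)}"] = _weekly_series(
            ones[mask], cohort.loc[mask, "dispense_date"]
        ).reindex(weekly_total.index, fill_value=0.0)
    wk_cen = cen[cen["converged"]].copy()
    wk_cen["week"] = iso_week_label(wk_cen["date"]).to_numpy()
    for focal in (ANTIDEPRESSANTS, ANXIOLYTICS):
        s = (
            wk_cen[wk_cen["class"] == focal]
            .groupby("week", sort=True)["centrality"].mean()
        )
        ssa_inputs[f"centrality_{_slug(focal)}"] = s

    comp_rows, share_rows, trend_rows = [], [], []
    for name, series in ssa_inputs.items():
        x = series.to_numpy(float)
        if len(x) < 2 * cfg.ssa_L1 or not np.all(np.isfinite(x)):
            log.warning("ssa: skipping %s (too short or missing values)", name)
            continue
        dec = two_stage_ssa(
            x, L1=cfg.ssa_L1, n_components=cfg.ssa_components,
            trend_components=cfg.ssa_trend_components,
        )
        weeks = series.index.to_numpy()
        named = {"trend": dec.trend, "remainder": dec.remainder,
                 "reconstruction": dec.reconstruction}
        named.update({f"F{i + 1}": dec.components[i] for i in range(len(dec.components))})
        for comp, vals in named.items():
            comp_rows.extend((name, w, comp, v) for w, v in zip(weeks, vals))
        share_rows.append((name, "trend", dec.trend_share))
        share_rows.extend(
            (name, f"F{i + 1}", sh) for i, sh in enumerate(dec.component_shares)
        )
        for variant, values in (("raw", x), ("trend", dec.trend)):
            r = mann_kendall(values)
            trend_rows.append(
                (f"{name}/{variant}", r.S, r.var_S, r.z, r.p, r.direction)
            )
    pd.DataFrame(comp_rows, columns=["series", "week", "component", "value"]).to_csv(
        out / "ssa_components.csv", index=False, float_format="%.17g"
    )
    pd.DataFrame(share_rows, columns=["series", "component", "variance_share"]).to_csv(
        out / "ssa_shares.csv", index=False, float_format="%.17g"
    )
    pd.DataFrame(
        trend_rows, columns=["series", "S", "var_S", "z", "p", "direction"]
    ).to_csv(out / "trend_tests.csv", index=False, float_format="%.17g")
    counts_log["ssa_series"] = len(ssa_inputs)

    hashed = {k: v for k, v in cfg.to_jsonable().items() if k != "output_dir"}
    cfg_json = json.dumps(hashed, sort_keys=True)
    manifest = {
        "package": "dpnflow",
        "version": __version__,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": cfg.to_jsonable(),
        "seed": cfg.seed,
        "row_counts": counts_log,
        "started": started,
        "finished": dt.datetime.now().isoformat(timespec="seconds"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("pipeline finished: %s", out)
    return manifest


def _check(report: list, name: str, passed: bool, detail: str = "") -> None:
    report.append({"check": name, "passed": bool(passed), "detail": detail})


def verify_outputs(output_dir: str | Path) -> list[dict]:
    """Cross-file invariant checks on a completed run directory."""
    out = Path(output_dir)
    report: list[dict] = []
    manifest = json.loads((out / "manifest.json").read_text())
    cfg = PipelineConfig.from_dict(manifest["config"])
    window = Window(cfg.window_start, cfg.window_end)
    cmap = default_class_map()

    cen = pd.read_csv(out / "centrality_daily.csv")
    conv = cen[cen["converged"]]
    sums = conv.groupby("date")["centrality"].sum()
    bad = sums[(sums - 1.0).abs() > 1e-8]
    _check(report, "centrality_rows_sum_to_one", bad.empty,
           f"{len(bad)} dates deviate" if not bad.empty else "")

    weekly = pd.read_csv(out / "metrics_weekly.csv")
    has_data = weekly["n_dispensings"] > 0
    complete = weekly.loc[has_data, ["n_dispensings", "n_patients", "ratio"]].notna().all().all()
    _check(report, "weekly_metrics_complete", bool(complete))

    # subgroup conservation for true partitions
    if cfg.save_daily_edges:
        from .networks import read_daily_edges

        pop_counts, _ = read_daily_edges(
            out / "network_daily_edges.csv", out / "network_daily_diagonal.csv",
            window, cmap.class_labels,
        )
        for pairing, groups in (
            ("age", ("lt65", "ge65")),
            ("polypharmacy", ("non_polypharmacy", "polypharmacy")),
        ):
            if pairing not in cfg.subgroup_pairings:
                continue
            total = np.zeros_like(pop_counts)
            missing = False
            for g in groups:
                stem = out / f"subgroup_{pairing}_{g}_edges.csv"
                if not stem.exists():
                    missing = True
                    continue
                c, _ = read_daily_edges(
                    stem, out / f"subgroup_{pairing}_{g}_diagonal.csv",
                    window, cmap.class_labels,
                )
                total += c
            if missing:  # an empty subgroup writes no file; compare what exists
                ok = (total <= pop_counts).all()
            else:
                ok = (total == pop_counts).all()
            _check(report, f"subgroup_conservation_{pairing}", bool(ok))

    comp = pd.read_csv(out / "ssa_components.csv")
    wk = (
        pd.read_csv(out / "metrics_weekly.csv")
        .groupby("week", sort=True)["n_dispensings"].first()
    )
    piv = comp[comp["series"] == "dispensings_total"].pivot_table(
        index="week", columns="component", values="value", sort=True
    )
    if not piv.empty:
        f_cols = [c for c in piv.columns if re.fullmatch(r"F\d+", c)]
        total = piv["trend"] + piv[f_cols].sum(axis=1) + piv["remainder"]
        ref = wk.reindex(piv.index).astype(float)
        err = float(np.abs(total - ref).max() / max(np.abs(ref).max(), 1.0))
        _check(report, "ssa_additivity", err <= 1e-8, f"max rel err {err:.2e}")
    return report
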
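"""Prescription-day statistics, polypharmacy runs, subgroup networks."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from dpnflow.coprescription import (
    multi_class_days,
    polypharmacy_flags,
    prescription_days,
    same_class_days,
    subgroup_labels,
    subgroup_run,
    yearly_summary,
)
from dpnflow.exposure import Window, build_activity_cube, build_exposure
from dpnflow.networks import WeightParams, daily_networks_from_cube, gaussian_weight


def _cube_from(rows, cmap, window):
    base = {
        "patient_id": "P1", "sex": "female", "birth_year": 1980,
        "atc_code": "N06AB06", "days_supplied": 1, "ddd_ratio": 0.8,
    }
    df = pd.DataFrame([{**base, **r} for r in rows])
    seg = build_exposure(df, window, cmap)
    pids = np.unique(df["patient_id"])
    return build_activity_cube(seg, window, cmap, patient_ids=pids), df


WIN = Window(dt.date(2018, 1, 1), dt.date(2018, 12, 31))

SEVEN_CODES = [
    "N06AB06", "N05BA01", "C10AA01", "A10BA02", "R03AC02", "B01AC06", "M01AE01",
]


class TestPrescriptionDays:
    def test_seven_medications_one_day_is_seven(self, cmap):
        cube, _ = _cube_from(
            [{"atc_code": c, "dispense_date": pd.Timestamp("2018-03-01")}
             for c in SEVEN_CODES],
            cmap, WIN,
        )
        assert prescription_days(cube, "P1") == 7

    def test_no_exposure_is_zero(self, cmap):
        cube, _ = _cube_from(
            [{"dispense_date": pd.Timestamp("2018-03-01")}], cmap, WIN
        )
        assert prescription_days(cube, "P1", start_day=100, end_day=200) == 0

    def test_three_meds_five_days_is_fifteen(self, cmap):
        cube, _ = _cube_from(
            [{"atc_code": c, "dispense_date": pd.Timestamp("2018-03-01"),
              "days_supplied": 5}
             for c in SEVEN_CODES[:3]],
            cmap, WIN,
        )
        assert prescription_days(cube, "P1") == 15


class TestSameAndMultiClass:
    def test_two_antidepressants_one_day(self, cmap):
        cube, _ = _cube_from(
            [
                {"atc_code": "N06AB06", "dispense_date": pd.Timestamp("2018-03-01")},
                {"atc_code": "N06AB04", "dispense_date": pd.Timestamp("2018-03-01")},
            ],
            cmap, WIN,
        )
        assert same_class_days(cube, "Antidepressants") == 2

    def test_single_antidepressant_many_days_is_zero(self, cmap):
        cube, _ = _cube_from(
            [{"dispense_date": pd.Timestamp("2018-03-01"), "days_supplied": 10}],
            cmap, WIN,
        )
        assert same_class_days(cube, "Antidepressants") == 0

    def test_multi_class_counts_non_focal_medications(self, cmap):
        cube, _ = _cube_from(
            [
                {"atc_code": "N06AB06", "dispense_date": pd.Timestamp("2018-03-01")},
                {"atc_code": "C10AA01", "dispense_date": pd.Timestamp("2018-03-01")},
                {"atc_code": "C07AB02", "dispense_date": pd.Timestamp("2018-03-01")},
            ],
            cmap, WIN,
        )
        assert multi_class_days(cube, "Antidepressants") == 2

    def test_focal_alone_is_zero(self, cmap):
        cube, _ = _cube_from(
            [{"dispense_date": pd.Timestamp("2018-03-01"), "days_supplied": 4}],
            cmap, WIN,
        )
        assert multi_class_days(cube, "Antidepressants") == 0

    def test_random_fixture_matches_brute_force(self, cmap, rng):
        codes = ["N06AB06", "N06AB04", "N06AX11", "C10AA01", "A10BA02", "N05BA01"]
        rows = []
        for p in range(8):
            for _ in range(rng.integers(2, 8)):
                rows.append(
                    {
                        "patient_id": f"P{p}",
                        "atc_code": codes[rng.integers(len(codes))],
                        "dispense_date": pd.Timestamp("2018-01-01")
                        + pd.Timedelta(days=int(rng.integers(0, 300))),
                        "days_supplied": int(rng.integers(1, 45)),
                    }
                )
        cube, df = _cube_from(rows, cmap, WIN)

        # brute force over a day grid per patient
        lab = {c: cmap.map_code(c) for c in codes}
        want_same = want_multi = want_total = 0
        for p, g in df.groupby("patient_id"):
            grid = {}
            for r in g.itertuples(index=False):
                s = (pd.Timestamp(r.dispense_date).date() - WIN.start).days
                for d in range(s, min(s + r.days_supplied, WIN.n_days)):
                    grid.setdefault(d, set()).add(r.atc_code)
            for d, active in grid.items():
                focal = [c for c in active if lab[c] == "Antidepressants"]
                other = [c for c in active if lab[c] != "Antidepressants"]
                want_total += len(active)
                if len(focal) >= 2:
                    want_same += len(focal)
                if focal and other:
                    want_multi += len(other)
        assert prescription_days(cube) == want_total
        assert same_class_days(cube, "Antidepressants") == want_same
        assert multi_class_days(cube, "Antidepressants") == want_multi


class TestPolypharmacy:
    def _five_meds(self, days_supplied):
        return [
            {"atc_code": c, "dispense_date": pd.Timestamp("2018-01-01"),
             "days_supplied": days_supplied}
            for c in SEVEN_CODES[:5]
        ]

    def test_thirty_consecutive_days_flags(self, cmap):
        cube, _ = _cube_from(self._five_meds(30), cmap, WIN)
        assert polypharmacy_flags(cube).tolist() == [True]

    def test_twentynine_days_does_not_flag(self, cmap):
        cube, _ = _cube_from(self._five_meds(29), cmap, WIN)
        assert polypharmacy_flags(cube).tolist() == [False]

    def test_interrupted_run_does_not_flag(self, cmap):
        rows = self._five_meds(20) + [
            {"atc_code": c, "dispense_date": pd.Timestamp("2018-01-22"),
             "days_supplied": 20}
            for c in SEVEN_CODES[:5]
        ]
        cube, _ = _cube_from(rows, cmap, WIN)
        assert polypharmacy_flags(cube).tolist() == [False]

    def test_monotone_adding_exposure_never_unflags(self, cmap, rng):
        rows = self._five_meds(35)
        cube, _ = _cube_from(rows, cmap, WIN)
        assert polypharmacy_flags(cube)[0]
        extra = rows + [
            {"atc_code": "J01CA04", "dispense_date": pd.Timestamp("2018-06-01"),
             "days_supplied": int(rng.integers(1, 60))}
        ]
        cube2, _ = _cube_from(extra, cmap, WIN)
        assert polypharmacy_flags(cube2)[0]

    def test_matches_brute_force_run_scan(self, cmap, rng):
        codes = SEVEN_CODES
        rows = []
        for p in range(6):
            for _ in range(12):
                rows.append(
                    {
                        "patient_id": f"P{p}",
                        "atc_code": codes[rng.integers(len(codes))],
                        "dispense_date": pd.Timestamp("2018-01-01")
                        + pd.Timedelta(days=int(rng.integers(0, 300))),
                        "days_supplied": int(rng.integers(10, 60)),
                    }
                )
        cube, df = _cube_from(rows, cmap, WIN)
        got = dict(zip(cube.patient_ids, polypharmacy_flags(cube)))
        for p, g in df.groupby("patient_id"):
            grid = {}
            for r in g.itertuples(index=False):
                s = (pd.Timestamp(r.dispense_date).date() - WIN.start).days
                for d in range(s, min(s + r.days_supplied, WIN.n_days)):
                    grid.setdefault(d, set()).add(r.atc_code)
            best = run = 0
            for d in range(WIN.n_days):
                run = run + 1 if len(grid.get(d, ())) >= 5 else 0
                best = max(best, run)
            assert got[p] == (best >= 30), p


class TestYearlySummaryAndSubgroups:
    def test_summary_matches_brute_force_totals(self, cmap, sim_registry_small):
        cfg, df = sim_registry_small
        sub = df[df["patient_id"].isin(sorted(df["patient_id"].unique())[:50])]
        window = Window(cfg.window_start, cfg.window_end)
        seg = build_exposure(sub, window, cmap)
        cube = build_activity_cube(
            seg, window, cmap, patient_ids=np.unique(sub["patient_id"])
        )
        out = yearly_summary(sub, cube, ("Antidepressants",), cmap)
        y2018 = out[out["year"] == 2018].iloc[0]
        # independent check of the focal totals from the day grid
        import datetime as dtt

        sl = slice(0, (dtt.date(2018, 12, 31) - window.start).days + 1)
        fidx = cube.class_labels.index("Antidepressants")
        nf = cube.counts[:, sl, fidx].astype(int)
        total = cube.counts[:, sl, :].sum(axis=2).astype(int)
        labels = cmap.map_series(sub["atc_code"])
        years = pd.to_datetime(sub["dispense_date"]).dt.year
        cohort = set(sub.loc[(labels == "Antidepressants") & (years == 2018), "patient_id"])
        mask = np.isin(cube.patient_ids, sorted(cohort))
        assert y2018["same_class_total"] == int(np.where(nf >= 2, nf, 0)[mask].sum())
        others = total - nf
        assert y2018["multi_class_total"] == int(
            np.where((nf >= 1) & (others >= 1), others, 0)[mask].sum()
        )
        assert y2018["total_n"] == int(total.sum())

    def test_subgroup_labels_age_group_changes_with_year(self, cmap):
        window = Window(dt.date(2018, 1, 1), dt.date(2020, 12, 31))
        rows = [{"dispense_date": pd.Timestamp("2018-06-01"), "days_supplied": 10}]
        base = {
            "patient_id": "P1", "sex": "female", "birth_year": 1954,
            "atc_code": "N06AB06", "days_supplied": 10, "ddd_ratio": 0.8,
        }
        df = pd.DataFrame([{**base, **r} for r in rows])
        cube = build_activity_cube(build_exposure(df, window, cmap), window, cmap)
        labels = subgroup_labels(df[["patient_id", "birth_year"]], cube)
        by_year = labels.set_index("year")["age_group"]
        assert by_year[2018] == "<65"  # age 64
        assert by_year[2019] == ">=65"

    def test_degenerate_partition_equals_population(self, cmap):
        window = Window(dt.date(2018, 1, 1), dt.date(2018, 3, 31))
        rows = []
        rng = np.random.default_rng(4)
        for p in range(15):
            for code in rng.choice(SEVEN_CODES, size=3, replace=False):
                rows.append(
                    {
                        "patient_id": f"P{p:02d}",
                        "atc_code": code,
                        "dispense_date": pd.Timestamp("2018-01-01")
                        + pd.Timedelta(days=int(rng.integers(0, 60))),
                        "days_supplied": 25,
                    }
                )
        cube, df = _cube_from(rows, cmap, window)
        params = WeightParams()
        cube_w = build_activity_cube(
            build_exposure(df, window, cmap), window, cmap,
            patient_ids=cube.patient_ids,
            weight_fn=lambda d: gaussian_weight(d, params),
        )
        pop_counts, _ = daily_networks_from_cube(cube_w, params)
        labels = subgroup_labels(df[["patient_id", "birth_year"]], cube_w)
        with pytest.warns(UserWarning, match="empty"):
            groups = subgroup_run(cube_w, labels, "age", params)
        # everyone is <65 (birth_year 1980): that group equals the population
        assert np.array_equal(groups["<65"]["counts"], pop_counts)

    def test_two_subgroup_counts_sum_to_population(self, cmap, rng):
        window = Window(dt.date(2018, 1, 1), dt.date(2018, 2, 28))
        rows = []
        for p in range(20):
            rows.append(
                {
                    "patient_id": f"P{p:02d}",
                    "atc_code": SEVEN_CODES[rng.integers(len(SEVEN_CODES))],
                    "dispense_date": pd.Timestamp("2018-01-05"),
                    "days_supplied": 30,
                }
            )
        base = {
            "sex": "female", "atc_code": "N06AB06", "days_supplied": 30,
            "ddd_ratio": 0.8,
        }
        df = pd.DataFrame([{**base, **r} for r in rows])
        df["birth_year"] = np.where(
            np.arange(len(df)) % 2 == 0, 1980, 1950
        )  # half >=65 in 2018
        params = WeightParams()
        cube = build_activity_cube(
            build_exposure(df, window, cmap), window, cmap,
            weight_fn=lambda d: gaussian_weight(d, params),
        )
        pop_counts, _ = daily_networks_from_cube(cube, params)
        labels = subgroup_labels(df[["patient_id", "birth_year"]], cube)
        groups = subgroup_run(cube, labels, "age", params)
        total = groups["<65"]["counts"] + groups[">=65"]["counts"]
        assert np.array_equal(total, pop_counts)
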
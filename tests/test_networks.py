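"""Network construction and DDD Gaussian edge weighting."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from dpnflow.exposure import Window, build_activity_cube, build_exposure
from dpnflow.networks import (
    WeightParams,
    aggregate_population,
    apply_weighting,
    build_individual_daily,
    daily_networks_from_cube,
    edge_weight,
    gaussian_weight,
    read_daily_edges,
    write_daily_edges,
)


class TestIndividualDaily:
    def test_two_classes_one_edge(self, cmap):
        net = build_individual_daily(
            {("N06AB06", "Antidepressants", 0.8), ("N05BA01", "Anxiolytics", 0.5)},
            cmap,
        )
        i = cmap.class_index("Antidepressants")
        j = cmap.class_index("Anxiolytics")
        assert net.adjacency.sum() == 2  # one symmetric edge
        assert net.adjacency[i, j] == net.adjacency[j, i] == 1

    def test_single_class_zero_matrix(self, cmap):
        net = build_individual_daily({"Antidepressants"}, cmap)
        assert not net.adjacency.any()
        assert net.active_classes == (cmap.class_index("Antidepressants"),)

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_edge_count_is_k_choose_2(self, cmap, k):
        labels = list(cmap.class_labels)[:k]
        net = build_individual_daily(set(labels), cmap)
        assert net.adjacency.sum() // 2 == k * (k - 1) // 2
        assert np.array_equal(net.adjacency, net.adjacency.T)
        assert not net.adjacency.diagonal().any()


class TestAggregate:
    def test_sum_of_shared_edge(self, cmap):
        nets = [
            build_individual_daily({"Antidepressants", "Anxiolytics"}, cmap, day=0)
            for _ in range(2)
        ]
        counts = aggregate_population(nets)
        i = cmap.class_index("Antidepressants")
        j = cmap.class_index("Anxiolytics")
        assert counts[i, j] == 2
        assert counts[i, i] == 2  # both patients active in the class

    def test_mixed_days_error(self, cmap):
        nets = [
            build_individual_daily({"Antidepressants", "Anxiolytics"}, cmap, day=0),
            build_individual_daily({"Antidepressants", "Anxiolytics"}, cmap, day=1),
        ]
        with pytest.raises(ValueError, match="mixed"):
            aggregate_population(nets)

    def test_cube_counts_match_per_pair_brute_force(self, cmap, rng):
        # 40 patients, random active classes on one day
        rows = []
        for p in range(40):
            for code in rng.choice(
                ["N06AB06", "N05BA01", "C10AA01", "A10BA02", "R03AC02"],
                size=rng.integers(1, 4), replace=False,
            ):
                rows.append(
                    {
                        "patient_id": f"P{p:02d}", "sex": "female", "birth_year": 1980,
                        "atc_code": code, "dispense_date": pd.Timestamp("2018-01-01"),
                        "days_supplied": 5, "ddd_ratio": 1.0,
                    }
                )
        df = pd.DataFrame(rows)
        window = Window(dt.date(2018, 1, 1), dt.date(2018, 1, 10))
        cube = build_activity_cube(
            build_exposure(df, window), window, cmap, weight_fn=gaussian_weight
        )
        counts, _ = daily_networks_from_cube(cube, WeightParams())
        # brute force pairwise patient counting on day 0
        lab = {code: cmap.map_code(code) for code in df["atc_code"].unique()}
        per_patient = df.groupby("patient_id")["atc_code"].apply(
            lambda s: {lab[c] for c in s}
        )
        n = cmap.n_classes
        want = np.zeros((n, n), dtype=int)
        for classes in per_patient:
            idx = sorted(cmap.class_index(c) for c in classes)
            for a in idx:
                want[a, a] += 1
                for b in idx:
                    if b > a:
                        want[a, b] += 1
                        want[b, a] += 1
        assert np.array_equal(counts[0], want)


class TestGaussianWeight:
    def test_closed_form_at_baseline(self):
        w = gaussian_weight(1.0)
        assert w == pytest.approx(3.0 / math.sqrt(2.0 * math.pi), abs=1e-12)
        assert w == pytest.approx(1.19683, abs=1e-5)

    def test_closed_form_at_zero(self):
        assert gaussian_weight(0.0) == pytest.approx(0.013295, abs=1e-6)

    def test_symmetry_about_baseline(self, rng):
        d = rng.uniform(0, 1, 50)
        np.testing.assert_allclose(gaussian_weight(1 + d), gaussian_weight(1 - d))

    def test_peak_at_one_and_strictly_decreasing(self):
        grid = np.linspace(0.0, 3.0, 301)
        w = gaussian_weight(grid)
        assert grid[np.argmax(w)] == pytest.approx(1.0)
        right = w[grid >= 1.0]
        assert (np.diff(right) < 0).all()

    def test_peak_normalized_mode(self):
        p = WeightParams(peak_normalized=True)
        assert gaussian_weight(1.0, p) == pytest.approx(1.0)

    def test_negative_ddd_rejected(self):
        with pytest.raises(ValueError):
            gaussian_weight(-0.1)


def test_edge_weight_is_average():
    assert edge_weight(0.4, 0.6) == pytest.approx(0.5)
    assert edge_weight(0.7, 0.7) == pytest.approx(0.7)
    grid = np.linspace(0.1, 1.2, 24)
    pair = 0.5 * (grid[:, None] + grid[None, :])
    for i in range(24):
        for j in range(24):
            assert edge_weight(grid[i], grid[j]) == pytest.approx(pair[i, j])


class TestApplyWeighting:
    def test_neutral_weights_reproduce_counts(self):
        counts = np.array([[0, 3, 0], [3, 0, 1], [0, 1, 5]])
        params = WeightParams(mode="class_mean")
        W = apply_weighting(counts, params, class_weights=np.ones(3))
        want = counts.astype(float).copy()
        np.fill_diagonal(want, 0.0)
        np.testing.assert_allclose(W, want)

    def test_multiply_mode_arithmetic(self):
        counts = np.array([[0, 3], [3, 0]])
        W = apply_weighting(
            counts, WeightParams(mode="class_mean"),
            class_weights=np.array([0.4, 0.6]),
        )
        assert W[0, 1] == pytest.approx(1.5)  # 3 * (0.4+0.6)/2

    def test_literal_mode_ignores_counts(self):
        counts = np.array([[0, 3], [3, 0]])
        W = apply_weighting(
            counts, WeightParams(combine="literal_eq4"),
            class_weights=np.array([0.4, 0.6]),
        )
        assert W[0, 1] == pytest.approx(0.5)

    def test_missing_class_weight_errors(self):
        counts = np.array([[0, 1], [1, 0]])
        with pytest.raises(ValueError, match="class weight"):
            apply_weighting(
                counts, WeightParams(mode="class_mean"),
                class_weights=np.array([0.5, np.nan]),
            )

    def test_per_record_equals_class_mean_for_constant_ddd(self, cmap):
        # every dispensing at ddd 0.7 -> per-record and class-mean agree
        rows = []
        rng = np.random.default_rng(3)
        for p in range(20):
            for code in rng.choice(
                ["N06AB06", "N05BA01", "C10AA01", "A10BA02"],
                size=rng.integers(2, 4), replace=False,
            ):
                rows.append(
                    {
                        "patient_id": f"P{p:02d}", "sex": "male", "birth_year": 1975,
                        "atc_code": code, "dispense_date": pd.Timestamp("2018-01-01"),
                        "days_supplied": 10, "ddd_ratio": 0.7,
                    }
                )
        df = pd.DataFrame(rows)
        window = Window(dt.date(2018, 1, 1), dt.date(2018, 1, 20))
        params = WeightParams()
        seg = build_exposure(df, window)
        cube = build_activity_cube(
            seg, window, cmap, weight_fn=lambda d: gaussian_weight(d, params)
        )
        _, w_rec = daily_networks_from_cube(cube, params)
        from dpnflow.networks import class_mean_weights

        cw = class_mean_weights(seg, cmap, params)
        cw = np.nan_to_num(cw, nan=1.0)  # classes absent from the fixture
        _, w_cls = daily_networks_from_cube(
            cube, WeightParams(mode="class_mean"), class_weights=cw
        )
        np.testing.assert_allclose(w_rec, w_cls, atol=1e-9)


class TestInvariants:
    def test_symmetry_and_zero_diagonal_preserved(self, cmap, sim_registry_small):
        cfg, df = sim_registry_small
        window = Window(cfg.window_start, dt.date(2018, 3, 31))
        sub = df[pd.to_datetime(df["dispense_date"]) <= pd.Timestamp(window.end)]
        params = WeightParams()
        cube = build_activity_cube(
            build_exposure(sub, window, cmap), window, cmap,
            weight_fn=lambda d: gaussian_weight(d, params),
        )
        counts, weighted = daily_networks_from_cube(cube, params)
        assert np.array_equal(counts, counts.transpose(0, 2, 1))
        np.testing.assert_allclose(weighted, weighted.transpose(0, 2, 1))
        assert not weighted.diagonal(axis1=1, axis2=2).any()

    def test_doubling_patients_doubles_weighted_entries(self, cmap):
        rows = []
        for p in range(10):
            rows += [
                {
                    "patient_id": f"P{p}", "sex": "female", "birth_year": 1980,
                    "atc_code": code, "dispense_date": pd.Timestamp("2018-01-01"),
                    "days_supplied": 10, "ddd_ratio": 0.5 + 0.1 * p,
                }
                for code in ("N06AB06", "C10AA01")
            ]
        df = pd.DataFrame(rows)
        doubled = pd.concat(
            [df, df.assign(patient_id=df["patient_id"] + "bis")], ignore_index=True
        )
        window = Window(dt.date(2018, 1, 1), dt.date(2018, 1, 15))
        params = WeightParams()
        out = []
        for frame in (df, doubled):
            cube = build_activity_cube(
                build_exposure(frame, window, cmap), window, cmap,
                weight_fn=lambda d: gaussian_weight(d, params),
            )
            out.append(daily_networks_from_cube(cube, params))
        np.testing.assert_allclose(2 * out[0][1], out[1][1], atol=1e-9)
        assert np.array_equal(2 * out[0][0], out[1][0])


def test_edge_list_round_trip(tmp_path, cmap, rng):
    D, n = 5, cmap.n_classes
    counts = rng.integers(0, 4, size=(D, n, n))
    counts = counts + counts.transpose(0, 2, 1)
    weighted = counts * rng.uniform(0.2, 1.0)
    for d in range(D):
        np.fill_diagonal(weighted[d], 0.0)
    window = Window(dt.date(2018, 1, 1), dt.date(2018, 1, 5))
    write_daily_edges(
        counts, weighted, window, cmap.class_labels,
        tmp_path / "e.csv", tmp_path / "d.csv",
    )
    c2, w2 = read_daily_edges(tmp_path / "e.csv", tmp_path / "d.csv", window, cmap.class_labels)
    # off-diagonals round-trip exactly; zero-count cells stay zero
    mask = counts > 0
    assert np.array_equal(counts * mask, c2 * (c2 > 0))
    off = ~np.eye(n, dtype=bool)
    np.testing.assert_allclose(weighted[:, off][counts[:, off] > 0],
                               w2[:, off][counts[:, off] > 0])
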
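"""Variogram estimation, ordinary kriging, suitability classes, thinning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chillmap.spatial import (
    SUITABILITY_CLASSES,
    SuitabilityGrid,
    classify,
    empirical_variogram,
    extract_and_summarize,
    fit_spherical,
    haversine_km,
    krige,
    make_grid,
    spherical,
    thin_occurrences,
)


def brute_force_thin(records, radius_km):
    kept = []
    for r in records.sort_values("id").itertuples(index=False):
        if all(
            haversine_km(r.lat, r.lon, k.lat, k.lon) >= radius_km for k in kept
        ):
            kept.append(r)
    return [k.id for k in kept]


class TestVariogram:
    def test_two_points(self):
        vg = empirical_variogram(
            np.array([[30.0, -90.0], [30.0, -89.0]]), np.array([0.0, 1.0]), n_bins=1
        )
        assert len(vg) == 1
        assert vg["semivariance"].iloc[0] == pytest.approx(0.5)

    def test_constant_field_flat_and_flagged(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(30, 40, 20), rng.uniform(-95, -85, 20)])
        vg = empirical_variogram(pts, np.full(20, 0.4))
        assert (vg["semivariance"] == 0).all()
        assert vg.attrs["flat"]

    def test_simulated_spherical_field_range_recovered(self):
        # seeded Gaussian field with known spherical covariance
        rng = np.random.default_rng(42)
        n = 120
        pts = np.column_stack([rng.uniform(30, 38, n), rng.uniform(-95, -85, n)])
        true = {"nugget": 0.0, "psill": 1.0, "range_km": 300.0}
        D = haversine_km(pts[:, 0, None], pts[:, 1, None], pts[None, :, 0], pts[None, :, 1])
        cov = true["psill"] - spherical(D, 0.0, true["psill"], true["range_km"])
        L = np.linalg.cholesky(cov + 1e-9 * np.eye(n))
        z = L @ rng.standard_normal(n)
        fitted = fit_spherical(empirical_variogram(pts, z, n_bins=15))
        assert abs(fitted["range_km"] - true["range_km"]) <= 0.25 * true["range_km"]


class TestSphericalFit:
    def test_exact_curve_recovered(self):
        h = np.linspace(10, 200, 10)
        g = spherical(h, 0.0, 1.0, 100.0)
        vg = pd.DataFrame({"distance_km": h, "semivariance": g, "n_pairs": 10})
        fit = fit_spherical(vg)
        assert fit["nugget"] == pytest.approx(0.0, abs=1e-6)
        assert fit["psill"] == pytest.approx(1.0, abs=1e-6)
        assert fit["range_km"] == pytest.approx(100.0, abs=1e-3)

    def test_flat_variogram_pure_nugget_fallback(self):
        vg = pd.DataFrame(
            {"distance_km": [10, 20, 30], "semivariance": [0.0, 0.0, 0.0], "n_pairs": 5}
        )
        vg.attrs["flat"] = True
        fit = fit_spherical(vg)
        assert fit["fallback"]

    def test_noisy_variogram_close_to_gridsearch_oracle(self):
        rng = np.random.default_rng(7)
        h = np.linspace(10, 300, 15)
        g = spherical(h, 0.1, 0.8, 150.0) + rng.normal(0, 0.02, 15)
        vg = pd.DataFrame({"distance_km": h, "semivariance": np.clip(g, 0, None),
                           "n_pairs": 50})
        fit = fit_spherical(vg)

        # coarse grid-search oracle over the same weighted objective
        best = None
        for n0 in np.linspace(0, 0.3, 16):
            for p0 in np.linspace(0.3, 1.2, 19):
                for r0 in np.linspace(50, 300, 26):
                    sse = np.sum(50 * (spherical(h, n0, p0, r0) - g) ** 2)
                    if best is None or sse < best[0]:
                        best = (sse, n0, p0, r0)
        assert abs(fit["range_km"] - best[3]) <= 25
        assert abs(fit["psill"] - best[2]) <= 0.15
        assert abs(fit["nugget"] - best[1]) <= 0.1


MODEL = {"nugget": 0.0, "psill": 0.04, "range_km": 400.0}


def station_set(n, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.column_stack([rng.uniform(30, 40, n), rng.uniform(-95, -85, n)])
    vals = rng.uniform(0.1, 0.9, n)
    return pts, vals


class TestKriging:
    def test_exact_at_station_locations(self):
        pts, vals = station_set(8)
        preds = krige(pts, vals, pts, MODEL, k_neighbors=None)
        assert np.allclose(preds, vals, atol=1e-8)

    def test_constant_field_reproduced_everywhere(self):
        pts, _ = station_set(10, seed=1)
        vals = np.full(10, 0.37)
        grid = make_grid((30, 40), (-95, -85), 2.0)
        preds = krige(pts, vals, grid, MODEL)
        assert np.allclose(preds, 0.37, atol=1e-8)

    def test_neighbor_solution_matches_dense_oracle(self):
        # with k >= n the 12-neighbour path must equal the dense solve
        pts, vals = station_set(5, seed=3)
        grid = make_grid((31, 39), (-94, -86), 2.0)
        a = krige(pts, vals, grid, MODEL, k_neighbors=12, clip=None)
        b = krige(pts, vals, grid, MODEL, k_neighbors=None, clip=None)
        assert np.allclose(a, b, atol=1e-8)

    def test_weights_sum_to_one(self):
        pts, vals = station_set(20, seed=4)
        grid = make_grid((31, 39), (-94, -86), 2.0)
        _, weights = krige(pts, vals, grid, MODEL, k_neighbors=12, return_weights=True)
        for w in weights:
            assert np.sum(w) == pytest.approx(1.0, abs=1e-8)

    def test_predictions_clipped_to_unit_interval(self):
        pts, vals = station_set(15, seed=5)
        grid = make_grid((30, 40), (-95, -85), 1.0)
        preds = krige(pts, vals, grid, MODEL)
        assert np.nanmin(preds) >= 0.0 and np.nanmax(preds) <= 1.0


class TestClassify:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.0, "highly suitable"),
            (0.25, "highly suitable"),
            (0.26, "moderately suitable"),
            (0.50, "moderately suitable"),
            (0.51, "moderately unsuitable"),
            (0.75, "moderately unsuitable"),
            (0.9, "highly unsuitable"),
            (0.95, "highly unsuitable"),
            (0.96, "completely unsuitable"),
            (1.0, "completely unsuitable"),
        ],
    )
    def test_printed_boundaries(self, value, label):
        assert classify(value) == label

    def test_out_of_range_rejected(self):
        for bad in (-0.01, 1.01):
            with pytest.raises(ValueError):
                classify(bad)

    @given(st.floats(0, 1))
    @settings(max_examples=300, deadline=None)
    def test_partition(self, v):
        # every value gets exactly one class, and that class's interval
        # actually contains it
        label = classify(v)
        matches = [
            lab
            for lab, lo, hi in SUITABILITY_CLASSES
            if (v == 0.0 and lo == 0.0) or lo < v <= hi
        ]
        assert matches == [label]


class TestThinning:
    def two_points_km_apart(self, km):
        return pd.DataFrame(
            {
                "id": ["a", "b"],
                "lat": [30.0, 30.0 + km / 111.19],
                "lon": [-90.0, -90.0],
            }
        )

    def test_close_pair_thins_to_one(self):
        assert len(thin_occurrences(self.two_points_km_apart(10), 15)) == 1

    def test_distant_pair_kept(self):
        assert len(thin_occurrences(self.two_points_km_apart(20), 15)) == 2

    def test_matches_bruteforce_oracle_and_min_distance(self):
        from chillmap.synthetic import gen_occurrences

        recs = gen_occurrences(
            200,
            clusters=((30, -90, 10.0), (31, -88, 25.0), (33.5, -91, 5.0)),
            seed=17,
        )
        kept = thin_occurrences(recs, 15.0)
        assert list(kept["id"]) == brute_force_thin(recs, 15.0)
        pts = kept[["lat", "lon"]].to_numpy()
        D = haversine_km(pts[:, 0, None], pts[:, 1, None], pts[None, :, 0], pts[None, :, 1])
        np.fill_diagonal(D, np.inf)
        assert D.min() >= 15.0

    def test_invariant_to_duplication(self):
        from chillmap.synthetic import gen_occurrences

        recs = gen_occurrences(50, clusters=((30, -90, 20.0),), seed=2)
        once = thin_occurrences(recs, 15.0)
        doubled = thin_occurrences(pd.concat([recs, recs]), 15.0)
        assert list(once["id"]) == list(doubled["id"])


def toy_grid(mortality):
    lats = [30.0, 30.5, 31.0]
    lons = [-90.0, -89.5]
    rows = []
    i = 0
    for la in lats:
        for lo in lons:
            rows.append({"lat": la, "lon": lo, "mortality": mortality[i],
                         "class": classify(mortality[i])})
            i += 1
    return SuitabilityGrid(pd.DataFrame(rows), resolution=0.5)


class TestExtract:
    def test_uniform_low_mortality(self):
        grid = toy_grid([0.1] * 6)
        recs = pd.DataFrame(
            {"id": [f"r{i}" for i in range(10)],
             "lat": np.linspace(30, 31, 10), "lon": np.full(10, -89.75)}
        )
        per, summary = extract_and_summarize(grid, recs)
        assert summary["percent_by_class"]["highly suitable"] == 100.0
        assert summary["percent_suitable"] == 100.0
        assert len(per) == 10

    def test_mixed_field_percentages_equal_hand_count(self):
        morts = [0.1, 0.3, 0.6, 0.8, 0.97, 0.2]
        grid = toy_grid(morts)
        # one record dead-centre on each cell
        recs = grid.table.reset_index().rename(columns={"index": "id"})[
            ["id", "lat", "lon"]
        ]
        per, summary = extract_and_summarize(grid, recs)
        hand = {lab: 0 for lab, _, _ in SUITABILITY_CLASSES}
        for m in morts:
            hand[classify(m)] += 1
        for lab, n in hand.items():
            assert summary["percent_by_class"][lab] == pytest.approx(100 * n / 6)
        assert summary["percent_suitable"] == pytest.approx(100 * 3 / 6)

    def test_record_outside_grid_excluded(self):
        grid = toy_grid([0.1] * 6)
        recs = pd.DataFrame(
            {"id": ["in", "out"], "lat": [30.0, 45.0], "lon": [-90.0, -70.0]}
        )
        per, summary = extract_and_summarize(grid, recs)
        assert summary["n_used"] == 1 and summary["n_outside"] == 1

    def test_empty_record_set(self):
        grid = toy_grid([0.1] * 6)
        per, summary = extract_and_summarize(grid, pd.DataFrame(columns=["id", "lat", "lon"]))
        assert summary["n_used"] == 0
        assert per.empty
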
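import numpy as np
import pandas as pd
import pytest

from ridge2reef.core_io.config import BrtConfig
from ridge2reef.core_io.grid import Grid, PointTable
from ridge2reef.reef_models import (
    FOURTH_ROOT,
    SQRT,
    ModelTable,
    back_transform,
    bilinear_sample,
    build_model_table,
    evaluate_predictions,
    filter_correlated,
    fit_brt,
    fit_hierarchy,
    moran_residuals,
    predict_map,
    sample_predictors,
    transform_response,
)

FAST = BrtConfig(
    learning_rates=(0.1,), tree_complexities=(2,), bag_fractions=(1.0,),
    max_trees=150, folds=5, seed=0,
)


def grid(values, cell=60.0):
    values = np.asarray(values, dtype=float)
    return Grid(values, cell, (0.0, values.shape[0] * cell), float("nan"), "test")


def make_table(X, y, names, indicator="coral", transform=SQRT):
    frame = pd.DataFrame(X, columns=names)
    frame[indicator] = y
    frame["x"] = np.arange(len(y), dtype=float)
    frame["y"] = np.arange(len(y), dtype=float)[::-1]
    return build_model_table(frame, indicator, names, transform)


class TestTransforms:
    def test_roundtrip(self):
        y = np.array([0.0, 4.0, 25.0])
        np.testing.assert_allclose(back_transform(transform_response(y, SQRT), SQRT), y)
        np.testing.assert_allclose(
            back_transform(transform_response(y, FOURTH_ROOT), FOURTH_ROOT), y
        )

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            transform_response(np.array([-1.0]), SQRT)


class TestBilinear:
    def test_cell_center_exact(self):
        g = grid(np.arange(9, dtype=float).reshape(3, 3))
        x, y = g.xy(1, 2)
        assert bilinear_sample(g, np.array([x]), np.array([y]))[0] == 5.0

    def test_midpoint_between_cells(self):
        g = grid(np.array([[0.0, 1.0]]))
        x0, y0 = g.xy(0, 0)
        x1, _ = g.xy(0, 1)
        mid = bilinear_sample(g, np.array([(x0 + x1) / 2]), np.array([y0]))[0]
        assert mid == pytest.approx(0.5)

    def test_off_grid_nan(self):
        g = grid(np.ones((2, 2)))
        assert np.isnan(bilinear_sample(g, np.array([-500.0]), np.array([-500.0]))[0])


class TestSamplePredictors:
    def test_sampling_joins_attributes(self):
        g = grid(np.full((4, 4), 2.5))
        pts = PointTable(
            np.arange(3), np.array([90.0, 150.0, 210.0]),
            np.array([90.0, 150.0, 150.0]),
            pd.DataFrame({"coral": [1.0, 2.0, 3.0]}),
        )
        out = sample_predictors({"depth": g}, pts)
        assert list(out["depth"]) == [2.5, 2.5, 2.5]
        assert "coral" in out.columns

    def test_too_many_dropped_raises(self):
        vals = np.full((4, 4), np.nan)
        vals[0, 0] = 1.0
        g = grid(vals)
        pts = PointTable(
            np.arange(4),
            np.array([30.0, 200.0, 210.0, 220.0]),
            np.array([210.0, 30.0, 40.0, 50.0]),
        )
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            sample_predictors({"depth": g}, pts)


class TestFilterCorrelated:
    def test_identical_columns_one_dropped(self, rng):
        a = rng.normal(size=100)
        frame = pd.DataFrame({"a": a, "b": a, "c": rng.normal(size=100)})
        kept = filter_correlated(frame, ["a", "b", "c"], 0.7)
        assert "c" in kept
        assert len(kept) == 2

    def test_uncorrelated_all_kept(self, rng):
        frame = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        kept = filter_correlated(frame, list("abcd"), 0.7)
        assert kept == list("abcd")

    def test_chain_drops_middle(self, rng):
        # r(A,B) ~ .9, r(B,C) ~ .9, r(A,C) low -> B has the largest mean |r|
        # noise scale 0.8: r(a,b)=r(b,c)=1/sqrt(1.64)≈0.78 > 0.7 while
        # r(a,c)=1/1.64≈0.61 < 0.7
        n = 4000
        b = rng.normal(size=n)
        a = b + rng.normal(scale=0.8, size=n)
        c = b + rng.normal(scale=0.8, size=n)
        frame = pd.DataFrame({"a": a, "b": b, "c": c})
        kept = filter_correlated(frame, ["a", "b", "c"], 0.7)
        assert "b" not in kept
        assert set(kept) == {"a", "c"}

    def test_single_predictor_rejected(self, rng):
        frame = pd.DataFrame({"a": rng.normal(size=10)})
        with pytest.raises(ValueError):
            filter_correlated(frame, ["a"], 0.7)


class TestFitBrt:
    def test_constant_response_null_model(self, rng):
        X = rng.normal(size=(60, 3))
        y = np.full(60, 9.0)
        table = make_table(X, y, ["p1", "p2", "p3"])
        with pytest.warns(UserWarning):
            model = fit_brt(table, FAST)
        assert model.pde == 0.0
        assert model.cv_pde == 0.0

    def test_single_driver_recovery(self, rng):
        X = rng.uniform(0, 1, size=(120, 3))
        y = (10.0 * X[:, 0]) ** 2  # sqrt(y) = 10 * p1, noiseless, monotone up
        table = make_table(X, y, ["p1", "p2", "p3"])
        model = fit_brt(table, FAST)
        assert model.relative_influence["p1"] > 90.0
        assert model.curve_direction("p1") == 1

    def test_decreasing_driver_direction(self, rng):
        X = rng.uniform(0, 1, size=(120, 2))
        y = (10.0 * (1 - X[:, 1])) ** 2
        table = make_table(X, y, ["p1", "p2"])
        model = fit_brt(table, FAST)
        assert model.curve_direction("p2") == -1

    def test_determinism(self, rng):
        X = rng.uniform(0, 1, size=(80, 3))
        y = (5 * X[:, 0] + rng.normal(0, 0.5, 80)).clip(0) ** 2
        table = make_table(X, y, ["p1", "p2", "p3"])
        cfg = BrtConfig(learning_rates=(0.1,), tree_complexities=(2,),
                        bag_fractions=(0.6,), max_trees=100, folds=5, seed=3)
        m1 = fit_brt(table, cfg)
        m2 = fit_brt(table, cfg)
        assert m1.n_trees == m2.n_trees
        assert m1.pde == m2.pde
        assert m1.relative_influence == m2.relative_influence

    def test_influence_sums_to_100(self, rng):
        X = rng.uniform(0, 1, size=(80, 4))
        y = (3 * X[:, 0] + 2 * X[:, 1] + rng.normal(0, 0.2, 80)).clip(0) ** 2
        table = make_table(X, y, list("abcd"))
        model = fit_brt(table, FAST)
        assert sum(model.relative_influence.values()) == pytest.approx(100.0, abs=0.01)

    def test_nonfinite_response_rejected(self, rng):
        X = rng.normal(size=(60, 2))
        y = np.full(60, 4.0)
        y[0] = np.nan
        frame = pd.DataFrame(X, columns=["a", "b"])
        frame["coral"] = y
        table = ModelTable("coral", SQRT, frame, ["a", "b"], np.array([]), np.array([]))
        with pytest.raises(ValueError):
            fit_brt(table, FAST)

    def test_too_few_rows(self, rng):
        X = rng.normal(size=(10, 2))
        table = make_table(X, np.abs(X[:, 0]), ["a", "b"])
        with pytest.raises(ValueError):
            fit_brt(table, BrtConfig(folds=10))


class TestMoran:
    def test_null_centered_on_expectation(self, rng):
        n = 100
        stats = []
        for _ in range(40):
            x = rng.uniform(0, 100, n)
            y = rng.uniform(0, 100, n)
            z = rng.normal(size=n)
            i_stat, p = moran_residuals(z, x, y)
            stats.append(i_stat)
        assert np.mean(stats) == pytest.approx(-1.0 / (n - 1), abs=0.01)

    def test_clustered_detected(self, rng):
        n = 80
        x = rng.uniform(0, 100, n)
        y = rng.uniform(0, 100, n)
        i_stat, p = moran_residuals(x.copy(), x, y)  # value = x coordinate
        assert i_stat > 0.1
        assert p < 0.01

    def test_degenerate_n(self):
        with pytest.raises(ValueError):
            moran_residuals(np.array([1.0, 2.0]), np.array([0, 1.0]), np.array([0, 1.0]))

    def test_coincident_coordinates_rejected(self, rng):
        x = np.zeros(12)
        y = np.zeros(12)
        with pytest.raises(ValueError):
            moran_residuals(rng.normal(size=12), x, y)


class TestHierarchy:
    def _frame(self, rng, n=150):
        drivers = pd.DataFrame(
            rng.uniform(0, 1, size=(n, 3)), columns=["tss", "depth", "slope"]
        )
        frame = drivers.copy()
        frame["x"] = rng.uniform(0, 1000, n)
        frame["y"] = rng.uniform(0, 1000, n)
        frame["cca"] = (2 + 1.0 * drivers["depth"]) ** 2
        frame["coral"] = (6 - 4 * drivers["tss"]) ** 2
        frame["macroalgae"] = (1 + drivers["tss"]) ** 2
        frame["turf"] = (3 - drivers["tss"]) ** 2
        # fish built from coral cover only
        for ind in ("browsers", "grazers", "scrapers", "predators"):
            frame[ind] = (1.0 + 0.05 * frame["coral"]) ** 4
        return frame

    def test_model_set_sizes(self, rng):
        frame = self._frame(rng)
        models = fit_hierarchy(frame, ["tss", "depth", "slope"], FAST)
        benthic = [m for m in models.values() if m.transform == SQRT]
        fish = [m for m in models.values() if m.transform == FOURTH_ROOT]
        assert len(benthic) == 4
        assert len(fish) == 4

    def test_fish_driven_by_coral_recovered(self, rng):
        frame = self._frame(rng)
        models = fit_hierarchy(frame, ["tss", "depth", "slope"], FAST)
        for ind in ("browsers", "predators"):
            infl = models[ind].relative_influence
            assert max(infl, key=infl.get) == "coral"

    def test_removing_benthos_lowers_fish_cv_pde(self, rng):
        frame = self._frame(rng)
        # add noise so the ablation has headroom to matter
        frame["browsers"] *= np.exp(rng.normal(0, 0.05, len(frame)))
        full = fit_hierarchy(frame, ["tss", "depth", "slope"], FAST)
        ablated_table = build_model_table(
            frame, "browsers", ["depth", "slope"], FOURTH_ROOT
        )
        ablated = fit_brt(ablated_table, FAST)
        assert ablated.cv_pde < full["browsers"].cv_pde


class TestPredictMap:
    def _model(self, rng):
        X = rng.uniform(0, 1, size=(100, 2))
        y = (8 * X[:, 0]) ** 2
        return fit_brt(make_table(X, y, ["depth", "slope"]), FAST)

    def test_constant_predictors_constant_map(self, rng):
        model = self._model(rng)
        grids = {"depth": grid(np.full((5, 5), 0.5)), "slope": grid(np.full((5, 5), 0.5))}
        out = predict_map(model, grids)
        assert np.nanstd(out.values) == 0.0

    def test_deep_cells_nodata(self, rng):
        model = self._model(rng)
        depth = np.full((4, 4), 10.0)
        depth[0, 0] = 30.0  # beyond the 22 m survey limit
        grids = {"depth": grid(depth), "slope": grid(np.full((4, 4), 0.3))}
        out = predict_map(model, grids, max_depth=22.0)
        assert np.isnan(out.values[0, 0])
        assert np.isfinite(out.values[1, 1])

    def test_benthic_clipped_to_100(self, rng):
        X = rng.uniform(0, 1, size=(100, 1))
        y = np.full(100, 95.0) + X[:, 0] * 5
        model = fit_brt(make_table(X, y, ["v"], indicator="coral"), FAST)
        out = predict_map(model, {"v": grid(np.full((3, 3), 0.9))}, max_depth=1e9)
        assert np.nanmax(out.values) <= 100.0

    def test_missing_predictor_grid(self, rng):
        model = self._model(rng)
        with pytest.raises(KeyError):
            predict_map(model, {"depth": grid(np.ones((2, 2)))})


class TestEvaluate:
    def test_perfect_prediction_r2_one(self, rng):
        vals = rng.uniform(0, 50, (6, 6))
        g = grid(vals)
        rows = np.repeat(np.arange(1, 5), 3)
        cols = np.tile(np.arange(1, 4), 4)
        xs = g.origin[0] + (cols + 0.5) * g.cell_size
        ys = g.origin[1] - (rows + 0.5) * g.cell_size
        obs = vals[rows, cols]
        pts = PointTable(np.arange(len(xs)), xs, ys, pd.DataFrame({"coral": obs}))
        r2, p = evaluate_predictions(g, pts, "coral")
        assert r2 == pytest.approx(1.0)
        assert p < 1e-6

    def test_constant_prediction_r2_zero(self, rng):
        g = grid(np.full((6, 6), 5.0))
        xs = rng.uniform(60, 300, 12)
        ys = rng.uniform(60, 300, 12)
        pts = PointTable(
            np.arange(12), xs, ys, pd.DataFrame({"coral": rng.uniform(0, 9, 12)})
        )
        with pytest.warns(UserWarning):
            r2, p = evaluate_predictions(g, pts, "coral")
        assert r2 == 0.0

    def test_too_few_points(self, rng):
        g = grid(np.ones((3, 3)))
        pts = PointTable(np.arange(2), np.array([90.0, 100.0]),
                         np.array([90.0, 100.0]),
                         pd.DataFrame({"coral": [1.0, 2.0]}))
        with pytest.raises(ValueError):
            evaluate_predictions(g, pts, "coral")
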
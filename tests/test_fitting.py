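"""Differential-evolution fitting, bootstrap, and holdout splitting."""

import numpy as np
import pandas as pd
import pytest

from phenoscale.fitting import (
    DESettings,
    bootstrap_fit,
    fit_differential_evolution,
    holdout_split,
    rmse,
)
from phenoscale.models import FixedGDDModel, GDDModel, NaiveModel

from conftest import random_series


def stack_series(series_list):
    return np.stack([np.concatenate([s.temps, [s.latitude]]) for s in series_list])


@pytest.fixture(scope="module")
def series_bank():
    rng = np.random.default_rng(777)
    return stack_series([random_series(rng) for _ in range(40)])


class TestRMSE:
    def test_perfect_predictions(self):
        assert rmse([100, 110], [100, 110]) == 0.0

    def test_direct_arithmetic(self):
        # residuals 3 and -4: sqrt((9+16)/2)
        assert rmse([103, 96], [100, 100]) == pytest.approx(np.sqrt(12.5))

    def test_no_event_penalty(self):
        assert rmse([np.nan], [100]) == 1000.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rmse([], [])


class TestHoldoutSplit:
    def _events(self, n, species="sp1"):
        return pd.DataFrame({
            "species": species, "phenophase_class": "budburst", "site_id": "s1",
            "individual_id": [f"i{k}" for k in range(n)], "year": 2015,
            "doy": np.linspace(90, 120, n),
        })

    def test_twenty_percent_of_30(self):
        split = holdout_split(self._events(30), seed=1)
        assert len(split.test_events) == 6
        assert len(split.train_events) == 24

    def test_round_half_even_on_31(self):
        split = holdout_split(self._events(31), seed=1)
        assert len(split.test_events) == 6

    def test_disjoint_and_exhaustive(self):
        ev = self._events(30)
        split = holdout_split(ev, seed=3)
        assert set(split.train_events.index).isdisjoint(split.test_events.index)
        assert len(split.train_events) + len(split.test_events) == len(ev)

    def test_deterministic_given_seed(self):
        ev = self._events(25)
        a = holdout_split(ev, seed=9)
        b = holdout_split(ev, seed=9)
        pd.testing.assert_frame_equal(a.test_events, b.test_events)

    def test_stratified_per_group(self):
        ev = pd.concat([self._events(20, "sp1"), self._events(10, "sp2")],
                       ignore_index=True)
        split = holdout_split(ev, seed=2)
        counts = split.test_events.groupby("species").size()
        assert counts["sp1"] == 4 and counts["sp2"] == 2

    def test_tiny_group_refused(self):
        with pytest.raises(ValueError, match="need >= 5"):
            holdout_split(self._events(4), seed=0)


class TestDifferentialEvolution:
    def test_naive_optimum_is_the_mean(self, series_bank):
        X = series_bank[:3]
        y = np.array([100.0, 110.0, 120.0])
        model = NaiveModel(n_bootstrap=2, random_state=0)
        res = fit_differential_evolution(
            model.predict_with_params, X, y, model.resolved_bounds(), seed=0
        )
        assert res.x[0] == pytest.approx(110.0, abs=0.1)

    def test_fixed_gdd_matches_grid_search_oracle(self, series_bank):
        truth = {"f_star": 200.0}
        model = FixedGDDModel()
        y = model.predict_with_params(series_bank, truth)
        assert not np.isnan(y).any()
        res = fit_differential_evolution(
            model.predict_with_params, series_bank, y,
            model.resolved_bounds(), seed=4,
        )
        # independent 1-D grid search over the requirement
        grid = np.arange(0.0, 1000.0, 0.5)
        scores = [rmse(model.predict_with_params(series_bank, {"f_star": g}), y)
                  for g in grid]
        best = grid[int(np.argmin(scores))]
        assert res.fun <= min(scores) + 1e-9
        assert res.x[0] == pytest.approx(best, abs=2.0)
        assert abs(res.x[0] - 200.0) <= 2.0

    def test_gdd_generate_and_refit_rmse_below_one_day(self, series_bank):
        truth = {"t1": 10.0, "t_base": 5.0, "f_star": 150.0}
        model = GDDModel()
        y = model.predict_with_params(series_bank, truth)
        assert not np.isnan(y).any()
        res = fit_differential_evolution(
            model.predict_with_params, series_bank, y,
            model.resolved_bounds(),
            settings=DESettings(maxiter=300), seed=5,
        )
        # parameters may trade off; the fit itself must be near-perfect
        assert res.fun < 1.0
        assert res.fun <= rmse(model.predict_with_params(series_bank, truth), y) + 1e-3

    def test_linear_model_de_agrees_with_least_squares(self, series_bank):
        from phenoscale.models import LinearModel, spring_mean_of

        rng = np.random.default_rng(8)
        model = LinearModel()
        tmean = spring_mean_of(series_bank)
        y = 120.0 - 3.0 * tmean + rng.normal(0, 1.5, size=tmean.size)
        res = fit_differential_evolution(
            model.predict_with_params, series_bank, y,
            model.resolved_bounds(), seed=6,
        )
        slope, intercept = np.polyfit(tmean, y, 1)
        assert res.x[0] == pytest.approx(intercept, abs=0.5)
        assert res.x[1] == pytest.approx(slope, abs=0.1)

    def test_same_seed_is_bit_reproducible(self, series_bank):
        model = FixedGDDModel()
        y = model.predict_with_params(series_bank, {"f_star": 300.0})
        runs = [
            fit_differential_evolution(
                model.predict_with_params, series_bank, y,
                model.resolved_bounds(), seed=11,
            ).x
            for _ in range(2)
        ]
        assert np.array_equal(runs[0], runs[1])

    def test_infinite_bounds_rejected(self, series_bank):
        model = FixedGDDModel()
        with pytest.raises(ValueError, match="bounds"):
            fit_differential_evolution(
                model.predict_with_params, series_bank[:2], [100, 101],
                [(0, np.inf)], seed=0,
            )


class TestBootstrap:
    def test_smoke_run_stores_requested_vectors(self, series_bank):
        model = FixedGDDModel()
        y = model.predict_with_params(series_bank[:10], {"f_star": 200.0})
        vecs, failures = bootstrap_fit(
            model.predict_with_params, series_bank[:10], y,
            model.resolved_bounds(), reps=10, seed=1,
        )
        assert vecs.shape == (10, 1)
        assert failures == 0

    def test_degenerate_dataset_zero_spread(self, series_bank):
        # identical repeated observations: every resample is the same dataset
        X = np.repeat(series_bank[:1], 8, axis=0)
        model = FixedGDDModel()
        y = model.predict_with_params(X, {"f_star": 200.0})
        vecs, _ = bootstrap_fit(
            model.predict_with_params, X, y, model.resolved_bounds(),
            reps=6, seed=2,
        )
        assert np.ptp(vecs, axis=0) == pytest.approx(0.0)

    def test_spread_shrinks_with_sample_size(self):
        rng = np.random.default_rng(42)
        model = FixedGDDModel(maxiter=150)
        big = stack_series([random_series(rng) for _ in range(120)])
        y_big = model.predict_with_params(big, {"f_star": 200.0})
        y_big = y_big + rng.normal(0, 2, size=y_big.size)
        spreads = []
        for n in (15, 120):
            vecs, _ = bootstrap_fit(
                model.predict_with_params, big[:n], y_big[:n],
                model.resolved_bounds(), settings=DESettings(maxiter=150),
                reps=15, seed=3,
            )
            spreads.append(vecs[:, 0].std())
        assert spreads[1] < spreads[0]


class TestEstimatorFit:
    def test_fitted_attributes_and_mean_of_bootstraps(self, series_bank):
        model = FixedGDDModel(n_bootstrap=5, random_state=0)
        y = model.predict_with_params(series_bank[:12], {"f_star": 250.0})
        model.fit(series_bank[:12], y)
        assert model.params_["f_star"] == pytest.approx(250.0, abs=20.0)
        assert model.bootstrap_params_.shape == (5, 1)
        assert model.rmse_train_ < 2.0
        point = model.predict(series_bank[:12], method="point")
        boot = model.predict(series_bank[:12], method="bootstrap_mean")
        assert np.all(np.isfinite(boot))
        assert np.allclose(point, boot, atol=3.0)

    def test_predict_before_fit_raises(self, series_bank):
        from sklearn.exceptions import NotFittedError
        with pytest.raises(NotFittedError):
            FixedGDDModel().predict(series_bank[:2])
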
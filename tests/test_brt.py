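import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from benthosdm.brt import (
    BRTModel,
    BRTParams,
    bernoulli_deviance,
    fit_brt_step,
    percent_deviance_explained,
    predict_surface,
    tune_grid,
)
from benthosdm.grids import GridSurface
from benthosdm.predictors import PredictorStack


def make_sites(X, y, names):
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "presence", y)
    df.insert(0, "y", 0.0)
    df.insert(0, "x", 0.0)
    df.insert(0, "site_id", [f"s{i}" for i in range(len(y))])
    return df


class TestDeviance:
    def test_hand_computed_deviance(self):
        # -2 * [ln 0.9 + 3 ln 0.9] = 0.8429 to 4 s.f.
        d = bernoulli_deviance([1, 0, 0, 0], [0.9, 0.1, 0.1, 0.1])
        assert d == pytest.approx(0.8429, abs=5e-5)

    def test_closed_forms(self):
        assert bernoulli_deviance([0], [0.5]) == pytest.approx(2 * np.log(2))
        assert bernoulli_deviance([1], [1 - 1e-9]) == pytest.approx(0.0, abs=1e-8)

    def test_empty_and_mismatched_vectors_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bernoulli_deviance([], [])
        with pytest.raises(ValueError, match="equal length"):
            bernoulli_deviance([1, 0], [0.5])


class TestPDE:
    def test_hand_computed_pde(self):
        # null deviance at mean 0.25 is 4.4987; residual 0.8429
        pde = percent_deviance_explained([1, 0, 0, 0], [0.9, 0.1, 0.1, 0.1])
        assert pde == pytest.approx(1 - 0.8429 / 4.4987, abs=1e-4)

    def test_null_prediction_gives_zero(self):
        obs = np.array([1, 0, 0, 0, 1, 0])
        assert percent_deviance_explained(obs, np.full(6, obs.mean())) == pytest.approx(0.0)

    def test_perfect_prediction_gives_one(self):
        obs = np.array([1, 0, 0, 1])
        assert percent_deviance_explained(obs, obs.astype(float)) == pytest.approx(1.0, abs=1e-7)

    def test_single_class_obs_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            percent_deviance_explained([1, 1, 1], [0.9, 0.9, 0.9])

    def test_constant_off_mean_prediction_has_nonpositive_pde(self, rng):
        obs = rng.binomial(1, 0.3, size=200)
        assert percent_deviance_explained(obs, np.full(200, 0.5)) <= 0.0


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(lr=0.0), dict(lr=-0.1), dict(tc=0), dict(tc=2.5), dict(bf=0.0),
         dict(bf=1.2), dict(step_size=0), dict(max_trees=10, step_size=50),
         dict(fold_count=1)],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BRTParams(**kwargs)


class TestFitBrtStep:
    def separable(self, rng, n=200):
        x = rng.uniform(-1, 1, size=(n, 2))
        y = (x[:, 0] > 0).astype(int)
        return make_sites(x, y, ["a", "b"])

    def test_perfect_separation_reaches_auc_one(self, rng):
        from benthosdm.thresholds import auc

        train = self.separable(rng)
        params = BRTParams(lr=0.1, tc=2, bf=1.0, step_size=10, max_trees=200,
                           fold_count=5, seed=3)
        model, cv_pde = fit_brt_step(train, params, ["a", "b"])
        pred = model.predict(train)
        assert auc(train.presence.to_numpy(), pred) == 1.0
        assert cv_pde > 0.5

    def test_single_class_training_rejected(self, rng):
        x = rng.uniform(size=(40, 2))
        train = make_sites(x, np.zeros(40, dtype=int), ["a", "b"])
        with pytest.raises(ValueError, match="single class"):
            fit_brt_step(train, BRTParams(fold_count=5), ["a", "b"])

    def test_stratified_folds_partition_rows(self, rng):
        y = rng.binomial(1, 0.3, size=100)
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=1)
        held_out = np.concatenate(
            [va for _, va in skf.split(np.zeros((100, 1)), y)]
        )
        assert sorted(held_out) == list(range(100))

    def test_seeded_determinism(self, rng):
        train = self.separable(rng, n=120)
        params = BRTParams(lr=0.05, tc=2, bf=0.6, step_size=10, max_trees=100,
                           fold_count=5, seed=9)
        m1, pde1 = fit_brt_step(train, params, ["a", "b"])
        m2, pde2 = fit_brt_step(train, params, ["a", "b"])
        assert pde1 == pde2
        assert m1.n_trees_selected == m2.n_trees_selected
        assert m1.to_json() == m2.to_json()

    def test_training_deviance_monotone_without_bagging(self, rng):
        # deterministic gradient steps (bf = 1): training deviance cannot rise
        x = rng.uniform(-1, 1, size=(150, 3))
        y = rng.binomial(1, expit(2 * x[:, 0] - x[:, 1]))
        if y.sum() in (0, len(y)):
            pytest.skip("degenerate draw")
        from benthosdm.brt import _make_backend

        params = BRTParams(lr=0.05, tc=3, bf=1.0, step_size=10, max_trees=150,
                           fold_count=5, seed=2)
        est = _make_backend(params, 150, 0)
        est.fit(x, y)
        devs = [bernoulli_deviance(y, expit(raw.ravel()))
                for raw in est.staged_decision_function(x)]
        assert np.all(np.diff(devs) <= 1e-9)


class TestModelRepresentation:
    def small_stack(self):
        g = GridSurface(np.linspace(0, 9, 12).reshape(3, 4), cell_size=2.0)
        return PredictorStack(names=["a"], grids={"a": g}, family={"a": "spectral"})

    def test_zero_tree_model_predicts_uniform_intercept(self):
        model = BRTModel.constant(0.3, ["a"])
        surf = predict_surface(model, self.small_stack())
        np.testing.assert_allclose(surf.values, 0.3)

    def test_single_split_tree_gives_two_valued_surface(self):
        # one manual stump: a < 5 -> +1.2, else -0.7, intercept logit(0.5)=0
        tree = {
            "feature": np.array([0, -2, -2]),
            "threshold": np.array([5.0, -2.0, -2.0]),
            "children_left": np.array([1, -1, -1]),
            "children_right": np.array([2, -1, -1]),
            "value": np.array([0.0, 1.2, -0.7]),
        }
        model = BRTModel(
            intercept=0.0, trees=[tree], params=BRTParams(), n_trees_selected=1,
            predictor_names=["a"],
        )
        surf = predict_surface(model, self.small_stack())
        grid = self.small_stack().grids["a"].values
        expected = np.where(grid <= 5.0, expit(1.2), expit(-0.7))
        np.testing.assert_allclose(surf.values, expected)

    def test_surface_values_stay_in_unit_interval(self, rng, small_seascape):
        x = rng.uniform(-1, 1, size=(100, 2))
        y = (x[:, 0] + 0.3 * rng.standard_normal(100) > 0).astype(int)
        params = BRTParams(lr=0.1, tc=2, bf=1.0, step_size=10, max_trees=50,
                           fold_count=5, seed=1)
        model, _ = fit_brt_step(make_sites(x, y, ["a", "b"]), params, ["a", "b"])
        g1 = GridSurface(rng.uniform(-2, 2, (5, 5)), cell_size=2.0)
        g2 = GridSurface(rng.uniform(-2, 2, (5, 5)), cell_size=2.0)
        stack = PredictorStack(names=["a", "b"], grids={"a": g1, "b": g2},
                               family={"a": "spectral", "b": "spectral"})
        surf = predict_surface(model, stack)
        assert np.all((surf.values > 0) & (surf.values < 1))

    def test_missing_predictor_error_names_it(self):
        model = BRTModel.constant(0.5, ["a", "missing_one"])
        with pytest.raises(KeyError, match="missing_one"):
            predict_surface(model, self.small_stack())

    def test_json_round_trip_preserves_predictions(self, rng):
        x = rng.uniform(-1, 1, size=(150, 3))
        y = rng.binomial(1, expit(2 * x[:, 0]))
        params = BRTParams(lr=0.05, tc=3, bf=0.8, step_size=10, max_trees=100,
                           fold_count=5, seed=4)
        model, _ = fit_brt_step(make_sites(x, y, ["a", "b", "c"]), params, ["a", "b", "c"])
        clone = BRTModel.from_json(model.to_json())
        xs = rng.uniform(-1, 1, size=(60, 3))
        np.testing.assert_allclose(clone.predict(xs), model.predict(xs), atol=1e-12)

    def test_stored_rules_match_backend_probabilities(self, rng):
        # the explicit-traversal path and the sklearn backend must agree
        x = rng.uniform(-1, 1, size=(150, 3))
        y = rng.binomial(1, expit(2 * x[:, 0] - x[:, 2]))
        params = BRTParams(lr=0.05, tc=4, bf=1.0, step_size=25, max_trees=100,
                           fold_count=5, seed=5)
        model, _ = fit_brt_step(make_sites(x, y, ["a", "b", "c"]), params, ["a", "b", "c"])
        xs = rng.uniform(-1, 1, size=(80, 3))
        backend_prob = model._backend.predict_proba(xs)[:, 1]
        np.testing.assert_allclose(model.predict(xs), backend_prob, atol=1e-10)


class TestTuneGrid:
    def noisy_sites(self, rng, n=160):
        x = rng.uniform(-1, 1, size=(n, 3))
        y = rng.binomial(1, expit(1.5 * x[:, 0]))
        return make_sites(x, y, ["a", "b", "c"])

    def test_default_grid_enumerates_36_combinations(self):
        from benthosdm.brt import DEFAULT_BF_VALUES, DEFAULT_LR_VALUES, DEFAULT_TC_VALUES

        n = len(DEFAULT_LR_VALUES) * len(DEFAULT_TC_VALUES) * len(DEFAULT_BF_VALUES)
        assert n == 36

    def test_single_combination_grid_returns_it(self, rng):
        train = self.noisy_sites(rng)
        res = tune_grid(train, [0.05], [2], [0.8], fold_count=5, step_size=20,
                        max_trees=60, seed=1, predictor_names=["a", "b", "c"])
        assert len(res.rows) == 1
        assert res.best == (0.05, 2, 0.8)

    def test_rows_cover_full_cartesian_grid(self, rng):
        train = self.noisy_sites(rng)
        res = tune_grid(train, [0.1, 0.05], [2, 3], [0.8], fold_count=5,
                        step_size=20, max_trees=40, seed=1,
                        predictor_names=["a", "b", "c"])
        assert len(res.rows) == 4
        assert set(zip(res.rows.lr, res.rows.tc)) == {(0.1, 2), (0.1, 3), (0.05, 2), (0.05, 3)}
        best_row = res.rows[(res.rows.lr == res.best[0]) & (res.rows.tc == res.best[1])
                            & (res.rows.bf == res.best[2])]
        assert best_row.mean_cv_pde.iloc[0] == res.rows[~res.rows.failed].mean_cv_pde.max()

    def test_empty_value_list_rejected(self, rng):
        with pytest.raises(ValueError, match="non-empty"):
            tune_grid(self.noisy_sites(rng), [], [2], [0.5])
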
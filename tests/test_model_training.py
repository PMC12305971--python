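"""Grids, CART fitting, the numpy MLP, and representative-aware weighted CV."""

import numpy as np
import pandas as pd
import pytest

import strideboard.model_training as mt
from strideboard.explanation import export_tree
from strideboard.mlp import MLPRegressor
from strideboard.model_training import (
    cv_evaluate,
    dt_grid,
    fit_dt,
    fit_mlp,
    grid_search,
    load_bundle,
    mlp_grid,
    save_bundle,
)


class TestGrids:
    def test_dt_grid_enumeration(self):
        cells = dt_grid()
        assert len(cells) == 3 * 2 * 6 * 3 == 108
        assert len({tuple(sorted(c.items())) for c in cells}) == 108

    def test_mlp_base_grid_enumeration(self):
        cells = mlp_grid()
        assert len(cells) == 2 * 2 * 3 == 12
        assert {c["output_activation"] for c in cells} == {"linear", "relu"}

    def test_refined_rates_scanned_when_smallest_base_rate_wins(self, monkeypatch):
        """If 1e-5 wins the base grid, seven finer rates are additionally
        evaluated with architecture and activation fixed."""
        evaluated = []

        def fake_cv(family, hp, *a, **k):
            evaluated.append(hp["learning_rate"])
            return 1.0 if hp["learning_rate"] == 1e-5 else 0.0

        monkeypatch.setattr(mt, "cv_evaluate", fake_cv)
        table = pd.DataFrame({"x": np.arange(30.0), "leg": [0, 1, 2] * 10})
        model = grid_search("leg", "mlp", table, ("x",),
                            weights=pd.Series(1.0, index=table.index),
                            rep_index=pd.Index([]), seed=0, mlp_epochs=1)
        assert len(evaluated) == 12 + 7
        assert set(mt.MLP_REFINED_RATES) <= set(evaluated)
        assert model.hyperparameters["learning_rate"] in (
            1e-5, *mt.MLP_REFINED_RATES)


class TestDecisionTree:
    def test_pure_labels_single_node(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        hp = {"max_features": None, "splitter": "best",
              "min_weight_fraction": 0.0, "max_depth": 5}
        tree = fit_dt(X, np.full(20, 2.0), np.ones(20), hp)
        assert tree.tree_.node_count == 1
        assert tree.predict(X[:1])[0] == pytest.approx(2.0)

    def test_depth_cap_respected(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 5))
        y = rng.normal(size=200)
        hp = {"max_features": None, "splitter": "best",
              "min_weight_fraction": 0.0, "max_depth": 3}
        tree = fit_dt(X, y, np.ones(200), hp)
        assert tree.get_depth() <= 3

    def test_step_function_split_found(self):
        """1-D step at x = 0.5: a depth-1 best-split tree puts its threshold
        where a brute-force scan of all split points would."""
        x = np.linspace(0, 1, 50)[:, None]
        y = (x.ravel() > 0.5).astype(float)
        hp = {"max_features": None, "splitter": "best",
              "min_weight_fraction": 0.0, "max_depth": 1}
        tree = fit_dt(x, y, np.ones(50), hp)
        # brute force: best threshold is any point in the gap around 0.5
        lo = x.ravel()[y == 0].max()
        hi = x.ravel()[y == 1].min()
        assert lo <= tree.tree_.threshold[0] <= hi

    def test_doubling_weight_equals_duplicating_pair(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 4))
        y = rng.normal(size=40)
        hp = {"max_features": None, "splitter": "best",
              "min_weight_fraction": 0.0, "max_depth": 4}
        w = np.ones(40)
        w[7] = 2.0
        dup_X = np.vstack([X, X[7:8]])
        dup_y = np.append(y, y[7])
        t_weighted = fit_dt(X, y, w, hp, seed=0)
        t_duplicated = fit_dt(dup_X, dup_y, np.ones(41), hp, seed=0)
        feats = [f"f{i}" for i in range(4)]

        def same(a, b):  # identical splits; node values to float tolerance
            assert a.get("feature") == b.get("feature")
            assert a["prediction"] == pytest.approx(b["prediction"])
            if "feature" in a:
                assert a["threshold"] == pytest.approx(b["threshold"])
                same(a["left"], b["left"])
                same(a["right"], b["right"])

        same(export_tree(t_weighted, feats), export_tree(t_duplicated, feats))
        assert np.allclose(t_weighted.predict(X), t_duplicated.predict(X))


class TestMLP:
    def _toy(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 3))
        y = 2.0 * X[:, 0] - 1.0 * X[:, 1] + 0.5
        return X, y

    def test_training_reduces_loss(self):
        X, y = self._toy()
        at_init = MLPRegressor(epochs=0, seed=1).fit(X, y)
        trained = MLPRegressor(epochs=200, seed=1).fit(X, y)
        loss0 = np.mean((at_init.predict(X) - y) ** 2)
        loss1 = np.mean((trained.predict(X) - y) ** 2)
        assert loss1 < loss0

    def test_linear_capacity(self):
        """Noiseless linear target, linear output unit: train R^2 >= 0.95."""
        from sklearn.metrics import r2_score

        X, y = self._toy()
        hp = {"hidden_layers": (16, 8), "output_activation": "linear",
              "learning_rate": 1e-3}
        model = fit_mlp(X, y, np.ones(len(y)), hp, seed=0, epochs=300)
        assert r2_score(y, model.predict(X)) >= 0.95

    def test_seed_reproducibility(self):
        X, y = self._toy()
        a = MLPRegressor(epochs=50, seed=7).fit(X, y).predict(X)
        b = MLPRegressor(epochs=50, seed=7).fit(X, y).predict(X)
        assert np.array_equal(a, b)

    def test_relu_output_is_nonnegative(self):
        X, y = self._toy()
        model = MLPRegressor(output_activation="relu", epochs=50, seed=0).fit(X, y - 10)
        assert (model.predict(X) >= 0).all()

    def test_sample_weights_steer_the_fit(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 1))
        y = np.where(np.arange(100) < 50, 5.0, -5.0)
        w_first = np.where(np.arange(100) < 50, 100.0, 0.01)
        m = MLPRegressor(hidden_layers=(8,), epochs=200, seed=0).fit(X, y, w_first)
        assert m.predict(X).mean() > 2.0  # pulled toward the heavy half


class TestCrossValidation:
    @staticmethod
    def _linear_dataset(n=40, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 3, size=(n, 1))
        y = np.round(X.ravel())  # noiseless monotone labels
        return X, y

    def test_learnable_toy_reaches_high_cv_r2(self):
        X, y = self._linear_dataset()
        hp = {"max_features": None, "splitter": "best",
              "min_weight_fraction": 0.0, "max_depth": 3}
        score = cv_evaluate("dt", hp, X, y, np.ones(len(y)),
                            rep_mask=np.zeros(len(y), bool), k=10, seed=0)
        assert score >= 0.9

    def test_representative_pairs_never_scored(self, monkeypatch):
        """Audit by id: rows flagged as representative are reinserted into
        training and never appear in any validation score."""
        X, y = self._linear_dataset(n=60)
        X[:, 0] = np.arange(60)  # column doubles as row id
        y = np.arange(60) % 4
        rep_mask = np.zeros(60, bool)
        rep_mask[::5] = True
        seen_val, seen_train = [], []

        class Stub:
            def predict(self, Xv):
                seen_val.extend(Xv[:, 0].tolist())
                return np.zeros(len(Xv))

        def fake_fit(family, Xt, yt, wt, hp, seed, mlp_epochs, mlp_batch):
            seen_train.append(set(Xt[:, 0].tolist()))
            return Stub()

        monkeypatch.setattr(mt, "_fit", fake_fit)
        cv_evaluate("dt", {}, X, y, np.ones(60), rep_mask, k=5, seed=0)
        rep_ids = set(np.flatnonzero(rep_mask).astype(float))
        assert rep_ids.isdisjoint(seen_val)
        assert all(rep_ids <= tr for tr in seen_train)  # reinserted every fold

    def test_all_representative_rows_leaves_nothing_to_score(self):
        X, y = self._linear_dataset()
        with pytest.raises(RuntimeError):
            cv_evaluate("dt", {"max_features": None, "splitter": "best",
                               "min_weight_fraction": 0.0, "max_depth": 3},
                        X, y, np.ones(len(y)), rep_mask=np.ones(len(y), bool),
                        k=5, seed=0)


class TestGridSearchAndBundles:
    @staticmethod
    def _table(n=60, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"a": rng.uniform(0, 3, n), "b": rng.normal(0, 1, n)})
        df["speed"] = np.round(df["a"]).astype(int)
        df["patient_id"] = [f"p{i//3}" for i in range(n)]
        return df

    def test_grid_search_deterministic_and_within_grid(self):
        table = self._table()
        w = pd.Series(1.0, index=table.index)
        kwargs = dict(weights=w, rep_index=pd.Index([]), k=5, seed=3)
        m1 = grid_search("speed", "dt", table, ("a", "b"), **kwargs)
        m2 = grid_search("speed", "dt", table, ("a", "b"), **kwargs)
        assert m1.hyperparameters == m2.hyperparameters
        assert len(m1.cv_results) == 108
        assert any(m1.hyperparameters == {k: c[k] for k in c} for c in dt_grid())

    def test_empty_feature_set_rejected(self):
        table = self._table()
        with pytest.raises(ValueError):
            grid_search("speed", "dt", table, (), weights=pd.Series(1.0, index=table.index),
                        rep_index=pd.Index([]), seed=0)

    @pytest.mark.parametrize("family", ["dt", "mlp"])
    def test_bundle_round_trip_preserves_predictions(self, tmp_path, family):
        table = self._table()
        w = pd.Series(1.0, index=table.index)
        if family == "dt":
            model = grid_search("speed", family, table, ("a", "b"), weights=w,
                                rep_index=pd.Index([]), k=5, seed=1)
        else:
            hp = {"hidden_layers": (16, 8), "output_activation": "linear",
                  "learning_rate": 1e-3}
            predictor = fit_mlp(table[["a", "b"]].to_numpy(), table["speed"].to_numpy(),
                                np.ones(len(table)), hp, seed=0, epochs=30)
            model = mt.TrainedScoreModel(target="speed", family="mlp",
                                         hyperparameters=hp, predictor=predictor,
                                         features=("a", "b"))
        save_bundle(model, tmp_path / "bundle")
        back = load_bundle(tmp_path / "bundle")
        assert back.target == "speed" and back.family == family
        assert np.allclose(back.predict(table), model.predict(table))
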
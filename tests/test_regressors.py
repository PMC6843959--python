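import numpy as np
import pandas as pd
import pytest

from coastpop.covariates import FEATURE_ORDER
from coastpop.geodata import GridSpec, Raster
from coastpop.regressors import (BaggedTreeEnsemble, M5ModelTree, TrainingTable,
                                 best_sdr_split, fit_m5, fit_rf,
                                 permutation_importance, predict_raster)


def make_table(X, y, names=None):
    names = names or tuple(f"f{i}" for i in range(X.shape[1]))
    df = pd.DataFrame(X, columns=list(names))
    df.insert(0, "unit_id", np.arange(len(y)))
    df["y"] = y
    return TrainingTable(df, feature_names=tuple(names))


class TestBaggedEnsemble:
    def test_constant_target(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3))
        y = np.full(30, 7.5)
        m = fit_rf(make_table(X, y), n_trees=50, seed=0)
        np.testing.assert_allclose(m.predict(rng.normal(size=(5, 3))), 7.5)
        assert m.oob_mse == pytest.approx(0.0, abs=1e-20)

    def test_recovers_linear_signal(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 4))
        y = 2 * X[:, 0] - X[:, 1] + 0.5 * X[:, 2]
        m = fit_rf(make_table(X, y), n_trees=300, seed=1)
        oob_r2 = 1 - m.oob_mse / y.var()
        assert oob_r2 > 0.9

    def test_predictions_bounded_by_training_range(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        m = fit_rf(make_table(X, y), n_trees=100, seed=2)
        queries = rng.normal(scale=50.0, size=(200, 3))  # far outside training
        pred = m.predict(queries)
        assert pred.min() >= m.y_min - 1e-12
        assert pred.max() <= m.y_max + 1e-12

    def test_deterministic_in_seed(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 3))
        y = X[:, 0] + rng.normal(size=40)
        t = make_table(X, y)
        a = fit_rf(t, n_trees=60, seed=9)
        b = fit_rf(t, n_trees=60, seed=9)
        q = rng.normal(size=(10, 3))
        np.testing.assert_array_equal(a.predict(q), b.predict(q))
        assert a.oob_mse == b.oob_mse

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="10"):
            fit_rf(make_table(np.zeros((5, 2)), np.arange(5.0)))


class TestPermutationImportance:
    def test_noise_feature_scores_near_zero(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(20 + seed)
            X = rng.normal(size=(150, 3))
            y = 3 * X[:, 0] + rng.normal(scale=0.2, size=150)  # f1, f2 pure noise
            m = fit_rf(make_table(X, y), n_trees=200, seed=seed)
            imp = permutation_importance(m, None, n_repeats=5, seed=seed)
            s = imp.set_index("feature")["pct_inc_mse"]
            if abs(s["f1"]) < s["f0"] / 10 and abs(s["f2"]) < s["f0"] / 10:
                hits += 1
        assert hits >= 4

    def test_zero_repeats_rejected(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 2))
        m = fit_rf(make_table(X, X[:, 0]), n_trees=20, seed=0)
        with pytest.raises(ValueError, match="n_repeats"):
            permutation_importance(m, None, n_repeats=0)

    def test_unfitted_rejected(self):
        from coastpop.regressors import FittedModel
        empty = FittedModel("rf", BaggedTreeEnsemble(), ("a",), 0, 1)
        with pytest.raises(ValueError, match="not fitted"):
            permutation_importance(empty, None)


class TestM5ModelTree:
    def test_linear_data_collapses_to_single_ols_rule(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 2))
        y = 2 * X[:, 0] - X[:, 1]
        m = fit_m5(make_table(X, y))
        assert len(m.rules) == 1
        coef, *_ = np.linalg.lstsq(np.column_stack([X, np.ones(100)]), y, rcond=None)
        q = rng.normal(size=(30, 2))
        np.testing.assert_allclose(m.predict(q), q @ coef[:2] + coef[2], atol=1e-6)

    def test_step_split_found_by_exhaustive_sdr_search(self):
        rng = np.random.default_rng(6)
        x = np.sort(rng.uniform(-1, 1, 20)).reshape(-1, 1)
        y = np.where(x[:, 0] < 0, 0.0, 10.0)
        j, t, _ = best_sdr_split(x, y, 1)
        # independent exhaustive oracle over all candidate thresholds
        best = (None, -np.inf)
        xs = np.sort(x[:, 0])
        for i in range(19):
            if xs[i] == xs[i + 1]:
                continue
            thr = (xs[i] + xs[i + 1]) / 2
            left, right = y[x[:, 0] <= thr], y[x[:, 0] > thr]
            sdr = y.std() - (len(left) * left.std() + len(right) * right.std()) / 20
            if sdr > best[1]:
                best = (thr, sdr)
        assert j == 0
        assert t == pytest.approx(best[0])

    def test_min_leaf_at_least_n_gives_single_global_linear_rule(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 2))
        y = X[:, 0] + 3 * X[:, 1] + rng.normal(scale=0.01, size=8)
        m = fit_m5(make_table(X, y), min_leaf=10)
        assert len(m.rules) == 1
        assert set(m.rules[0]["features"]) == {0, 1}

    def test_constant_target_single_constant_rule(self):
        X = np.random.default_rng(8).normal(size=(10, 2))
        m = fit_m5(make_table(X, np.full(10, 4.0)))
        assert len(m.rules) == 1
        np.testing.assert_allclose(m.predict(X), 4.0)

    def test_tiebreak_prefers_lowest_feature_index(self):
        x = np.linspace(-1, 1, 12)
        X = np.column_stack([x, x])  # identical columns
        y = np.where(x < 0, 0.0, 5.0)
        j, t, _ = best_sdr_split(X, y, 1)
        assert j == 0

    def test_structure_matches_greedy_oracle_unpruned(self):
        """With pruning and smoothing off and min_leaf 1, the grown tree equals
        an independently coded greedy SDR recursion on small data."""
        rng = np.random.default_rng(9)
        X = rng.normal(size=(12, 2))
        y = rng.normal(size=12)

        def oracle(X, y, root_sd):
            if len(y) < 2 or y.std() < 0.05 * root_sd:
                return None
            n, p = X.shape
            best = None
            for jj in range(p):
                order = np.argsort(X[:, jj], kind="stable")
                xs, ys = X[order, jj], y[order]
                for i in range(n - 1):
                    if xs[i] == xs[i + 1]:
                        continue
                    thr = (xs[i] + xs[i + 1]) / 2
                    nl = i + 1
                    sdr = y.std() - (nl * ys[:nl].std() + (n - nl) * ys[nl:].std()) / n
                    if best is None or sdr > best[2] + 1e-12:
                        best = (jj, thr, sdr)
            if best is None:
                return None
            jj, thr, _ = best
            lsel = X[:, jj] <= thr
            return (jj, thr, oracle(X[lsel], y[lsel], root_sd),
                    oracle(X[~lsel], y[~lsel], root_sd))

        tree = M5ModelTree(min_leaf=1, prune=False, smooth=False)
        tree.fit(X, y)

        def shape(node):
            if node is None or node.is_leaf:
                return None
            return (node.feature, node.threshold,
                    shape(node.left), shape(node.right))

        assert shape(tree.root_) == oracle(X, y, y.std())

    def test_varimp_bounded_and_covers_all_features(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(80, 4))
        y = np.where(X[:, 0] > 0, 2.0, -1.0) + X[:, 1]
        m = fit_m5(make_table(X, y))
        vi = m.importance.set_index("feature")["var_imp_pct"]
        assert len(vi) == 4
        assert ((vi >= 0) & (vi <= 100)).all()
        assert vi["f0"] > 0


class TestPredictRaster:
    def _stack(self, n=6, seed=0):
        from coastpop.covariates import CovariateStack
        rng = np.random.default_rng(seed)
        spec = GridSpec(n, n, 0.0, n * 100.0, 100.0, "t")
        layers = {name: Raster(spec, rng.normal(size=(n, n)))
                  for name in FEATURE_ORDER}
        return CovariateStack(layers)

    def _model(self, stack, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(30, 6))
        y = X[:, 0] + rng.normal(size=30)
        return fit_rf(make_table(X, y, names=FEATURE_ORDER), n_trees=30, seed=seed)

    def test_matches_scalar_predictions(self):
        stack = self._stack()
        model = self._model(stack)
        out = predict_raster(model, stack)
        X = stack.to_matrix()
        np.testing.assert_array_equal(out.values.ravel(), model.predict(X))

    def test_nodata_feature_propagates(self):
        stack = self._stack()
        stack.layers["ntl"].values[2, 3] = np.nan
        out = predict_raster(self._model(stack), stack)
        assert np.isnan(out.values[2, 3])
        assert np.isfinite(out.values[0, 0])

    def test_domain_mask_respected(self):
        stack = self._stack()
        domain = np.zeros(stack.spec.shape, dtype=bool)
        domain[0, :] = True
        out = predict_raster(self._model(stack), stack, domain=domain)
        assert np.isfinite(out.values[0]).all()
        assert np.isnan(out.values[1:]).all()

    def test_feature_name_mismatch(self):
        stack = self._stack()
        rng = np.random.default_rng(1)
        model = fit_rf(make_table(rng.normal(size=(30, 2)), rng.normal(size=30)),
                       n_trees=10, seed=0)
        with pytest.raises(ValueError, match="feature"):
            predict_raster(model, stack)
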
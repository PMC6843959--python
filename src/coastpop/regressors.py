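"""County-level log-density regression engines.

Two engines mirror common practice in dasymetric mapping:

* :class:`BaggedTreeEnsemble` — a bagged regression-tree ensemble (a random
  forest in the regression convention: per-split feature subsampling with
  mtry = ceil(p/3)) with out-of-bag (OOB) error and permutation importance
  reported as %IncMSE.
* :class:`M5ModelTree` — an M5'-style rule-based model tree: greedy splits by
  standard-deviation reduction (SDR), least-squares linear models in the
  leaves over the features used in each leaf's subtree, pessimistic-error
  pruning and leaf-to-root smoothing, with usage-based importance (VarImp %)
  as popularised by Cubist.

A fitted ensemble can only interpolate — every prediction is an average of
training targets and therefore lies inside the training-target range — while
the model tree's linear leaves extrapolate beyond it. That contrast matters
downstream: it decides whether the weight surface can exceed the densities
seen at training time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .covariates import CovariateStack, FEATURE_ORDER
from .geodata import Raster

__all__ = [
    "TrainingTable",
    "FittedModel",
    "BaggedTreeEnsemble",
    "M5ModelTree",
    "fit_rf",
    "fit_m5",
    "permutation_importance",
    "predict_raster",
]


@dataclass(eq=False)
class TrainingTable:
    """One row per coarse admin unit: zonal-mean covariates and y = ln density."""

    frame: pd.DataFrame  # columns: unit_id, <features...>, y
    feature_names: tuple[str, ...] = FEATURE_ORDER
    n_dropped_zero_pop: int = 0
    n_dropped_missing: int = 0

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(self.feature_names)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["y"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# Bagged regression-tree ensemble
# ---------------------------------------------------------------------------


class BaggedTreeEnsemble:
    """Bootstrap-aggregated regression trees with per-split feature subsampling.

    Each tree is grown on a bootstrap sample; roughly one third of the rows
    are out of the bag for any tree and provide an internal error estimate
    (``oob_mse_``) without a set-aside test set.
    """

    def __init__(self, n_trees: int = 500, mtry: int | None = None,
                 min_samples_leaf: int = 1, seed: int = 0):
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_samples_leaf = min_samples_leaf
        self.seed = seed
        self.trees_: list[DecisionTreeRegressor] = []
        self.oob_masks_: list[np.ndarray] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaggedTreeEnsemble":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if n < 10:
            raise ValueError("need at least 10 training rows")
        if np.all(X.std(axis=0) == 0) and y.std() > 0:
            raise ValueError("all features are constant")
        mtry = self.mtry if self.mtry is not None else max(1, math.ceil(p / 3))
        rng = np.random.default_rng(self.seed)
        self.trees_ = []
        self.oob_masks_ = []
        for _ in range(self.n_trees):
            idx = rng.integers(0, n, size=n)
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            tree = DecisionTreeRegressor(
                max_features=mtry,
                min_samples_leaf=self.min_samples_leaf,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
            self.oob_masks_.append(oob)
        self._X = X
        self._y = y
        self.y_min_ = float(y.min())
        self.y_max_ = float(y.max())
        self.oob_prediction_, self.oob_mse_ = self._oob_mse(X)
        return self

    def _oob_mse(self, X: np.ndarray) -> tuple[np.ndarray, float]:
        n = X.shape[0]
        acc = np.zeros(n)
        cnt = np.zeros(n)
        for tree, oob in zip(self.trees_, self.oob_masks_):
            if oob.any():
                acc[oob] += tree.predict(X[oob])
                cnt[oob] += 1
        with np.errstate(invalid="ignore"):
            pred = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
        covered = cnt > 0
        mse = float(np.mean((pred[covered] - self._y[covered]) ** 2)) if covered.any() else 0.0
        return pred, mse

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.trees_:
            raise ValueError("model is not fitted")
        X = np.asarray(X, dtype=float)
        out = np.zeros(X.shape[0])
        for tree in self.trees_:
            out += tree.predict(X)
        return out / len(self.trees_)


def _perm_importance_pct_inc_mse(model: BaggedTreeEnsemble, n_repeats: int,
                                 seed: int) -> np.ndarray:
    X, n = model._X, model._X.shape[0]
    base = model.oob_mse_
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    scores = np.zeros(p)
    for j in range(p):
        incs = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(n), j]
            _, mse = model._oob_mse(Xp)
            incs.append(100.0 * (mse - base) / base if base > 0 else 0.0)
        scores[j] = float(np.mean(incs))
    return scores


# ---------------------------------------------------------------------------
# M5'-style model tree
# ---------------------------------------------------------------------------


@dataclass
class _LinModel:
    """Least-squares linear model on a subset of features."""

    features: tuple[int, ...]
    coef: np.ndarray  # aligned with features
    intercept: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.full(X.shape[0], self.intercept)
        for f, c in zip(self.features, self.coef):
            out += c * X[:, f]
        return out

    @property
    def n_params(self) -> int:
        return len(self.features) + 1


def _fit_lin(X: np.ndarray, y: np.ndarray, features: tuple[int, ...]) -> _LinModel:
    if not features:
        return _LinModel((), np.zeros(0), float(y.mean()))
    A = np.column_stack([X[:, list(features)], np.ones(len(y))])
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    return _LinModel(features, sol[:-1], float(sol[-1]))


@dataclass(eq=False)
class _Node:
    idx: np.ndarray  # training-row indices at this node
    feature: int | None = None
    threshold: float | None = None
    left: "_Node | None" = None
    right: "_Node | None" = None
    model: _LinModel | None = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


def _sd(y: np.ndarray) -> float:
    return float(np.std(y))


def best_sdr_split(X: np.ndarray, y: np.ndarray, min_leaf: int):
    """Exhaustive greedy SDR split search.

    Returns (feature, threshold, sdr) maximising
    sd(S) - sum_i |S_i|/|S| * sd(S_i), ties broken by lowest feature index
    then lowest threshold, or None if no admissible split exists.
    """
    n, p = X.shape
    sd_all = _sd(y)
    best = None
    for j in range(p):
        order = np.argsort(X[:, j], kind="stable")
        xs, ys = X[order, j], y[order]
        distinct = np.nonzero(np.diff(xs) > 0)[0]
        for i in distinct:
            n_left = i + 1
            if n_left < min_leaf or n - n_left < min_leaf:
                continue
            t = 0.5 * (xs[i] + xs[i + 1])
            sdr = sd_all - (n_left * _sd(ys[:n_left]) + (n - n_left) * _sd(ys[n_left:])) / n
            if best is None or sdr > best[2] + 1e-12:
                best = (j, t, sdr)
    return best


class M5ModelTree:
    """An M5'-style model tree with rule extraction and usage importance."""

    SD_STOP_FRACTION = 0.05  # stop splitting when node sd < 5% of root sd
    SMOOTH_K = 15.0

    def __init__(self, min_leaf: int = 4, prune: bool = True, smooth: bool = True):
        self.min_leaf = min_leaf
        self.prune = prune
        self.smooth = smooth
        self.root_: _Node | None = None

    # -- growing ------------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "M5ModelTree":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if n == 0:
            raise ValueError("empty training data")
        if np.std(y) == 0:
            # degenerate input: a single constant rule
            self.root_ = _Node(np.arange(n), model=_LinModel((), np.zeros(0), float(y[0])))
            self._X, self._y = X, y
            return self
        self._X, self._y = X, y
        self._root_sd = _sd(y)
        self.root_ = self._grow(np.arange(n))
        if self.root_.is_leaf:
            # the stopping rule forbade any split: one global linear rule
            self.root_.model = _fit_lin(X, y, tuple(range(p)))
        else:
            self._attach_models(self.root_)
            if self.prune:
                self._prune(self.root_)
        return self

    def _grow(self, idx: np.ndarray) -> _Node:
        y = self._y[idx]
        if len(idx) < 2 * self.min_leaf or _sd(y) < self.SD_STOP_FRACTION * self._root_sd:
            return _Node(idx)
        split = best_sdr_split(self._X[idx], y, self.min_leaf)
        if split is None:
            return _Node(idx)
        j, t, _ = split
        left = idx[self._X[idx, j] <= t]
        right = idx[self._X[idx, j] > t]
        node = _Node(idx, feature=j, threshold=t)
        node.left = self._grow(left)
        node.right = self._grow(right)
        return node

    def _subtree_features(self, node: _Node) -> tuple[int, ...]:
        feats: set[int] = set()

        def rec(nd: _Node) -> None:
            if not nd.is_leaf:
                feats.add(nd.feature)
                rec(nd.left)
                rec(nd.right)

        rec(node)
        return tuple(sorted(feats))

    def _attach_models(self, node: _Node) -> None:
        """Fit a linear model at every node on the features its subtree tests."""
        feats = self._subtree_features(node)
        node.model = _fit_lin(self._X[node.idx], self._y[node.idx], feats)
        if not node.is_leaf:
            self._attach_models(node.left)
            self._attach_models(node.right)

    # -- pruning ------------------------------------------------------------

    def _penalized_err(self, node: _Node) -> float:
        n = len(node.idx)
        resid = self._y[node.idx] - node.model.predict(self._X[node.idx])
        mae = float(np.mean(np.abs(resid)))
        nu = node.model.n_params
        factor = (n + nu) / (n - nu) if n > nu else 1e6
        return mae * factor

    def _prune(self, node: _Node) -> float:
        """Bottom-up pessimistic pruning; returns the node's error estimate."""
        own = self._penalized_err(node)
        if node.is_leaf:
            return own
        n = len(node.idx)
        err_l = self._prune(node.left)
        err_r = self._prune(node.right)
        subtree = (len(node.left.idx) * err_l + len(node.right.idx) * err_r) / n
        if own <= subtree + 1e-12:
            node.feature = None
            node.threshold = None
            node.left = None
            node.right = None
            return own
        return subtree

    # -- prediction ---------------------------------------------------------

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.root_ is None:
            raise ValueError("model is not fitted")
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0])
        self._predict_into(self.root_, X, np.arange(X.shape[0]), out)
        return out

    def _predict_into(self, node: _Node, X: np.ndarray, rows: np.ndarray,
                      out: np.ndarray) -> None:
        if rows.size == 0:
            return
        if node.is_leaf:
            out[rows] = node.model.predict(X[rows])
            return
        go_left = X[rows, node.feature] <= node.threshold
        for child, sel in ((node.left, go_left), (node.right, ~go_left)):
            sub = rows[sel]
            if sub.size == 0:
                continue
            self._predict_into(child, X, sub, out)
            if self.smooth:
                # classic leaf-to-root smoothing: blend the child-side value
                # with this node's model, weighted by the child's support
                n_child = len(child.idx)
                q = node.model.predict(X[sub])
                out[sub] = (n_child * out[sub] + self.SMOOTH_K * q) / (n_child + self.SMOOTH_K)

    # -- rules and importance ----------------------------------------------

    def rules(self) -> list[dict]:
        """Leaf rules: conjunction of path conditions plus the leaf model."""
        out: list[dict] = []

        def rec(node: _Node, conds: list[tuple[int, str, float]]) -> None:
            if node.is_leaf:
                out.append(
                    {
                        "conditions": list(conds),
                        "features": node.model.features,
                        "coef": node.model.coef.tolist(),
                        "intercept": node.model.intercept,
                        "n": int(len(node.idx)),
                    }
                )
                return
            rec(node.left, conds + [(node.feature, "<=", node.threshold)])
            rec(node.right, conds + [(node.feature, ">", node.threshold)])

        rec(self.root_, [])
        return out

    def var_imp(self, p: int) -> np.ndarray:
        """Cubist-style VarImp(%): for each feature, the mean of the share of
        training rows whose covering rule tests it in a condition and the
        share whose leaf model uses it."""
        n = len(self._y)
        cond_rows = np.zeros(p)
        model_rows = np.zeros(p)

        def rec(node: _Node, cond_feats: frozenset[int]) -> None:
            if node.is_leaf:
                for f in cond_feats:
                    cond_rows[f] += len(node.idx)
                for f, c in zip(node.model.features, node.model.coef):
                    if c != 0.0:
                        model_rows[f] += len(node.idx)
                return
            rec(node.left, cond_feats | {node.feature})
            rec(node.right, cond_feats | {node.feature})

        rec(self.root_, frozenset())
        return 0.5 * (100.0 * cond_rows / n + 100.0 * model_rows / n)


# ---------------------------------------------------------------------------
# Public fitting API
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class FittedModel:
    """A fitted regression engine plus its provenance and diagnostics."""

    kind: str  # "rf" | "m5"
    estimator: object
    feature_names: tuple[str, ...]
    y_min: float
    y_max: float
    importance: pd.DataFrame | None = None
    oob_mse: float | None = None
    rules: list | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))


def fit_rf(table: TrainingTable, n_trees: int = 500, mtry: int | None = None,
           seed: int = 0) -> FittedModel:
    """Fit the bagged-tree ensemble on a county training table."""
    ens = BaggedTreeEnsemble(n_trees=n_trees, mtry=mtry, seed=seed)
    ens.fit(table.X, table.y)
    return FittedModel(
        kind="rf",
        estimator=ens,
        feature_names=table.feature_names,
        y_min=ens.y_min_,
        y_max=ens.y_max_,
        oob_mse=ens.oob_mse_,
    )


def permutation_importance(model: FittedModel, table: TrainingTable,
                           n_repeats: int = 10, seed: int = 0) -> pd.DataFrame:
    """%IncMSE permutation importance on the out-of-bag samples.

    For each feature, the OOB MSE is recomputed with that feature's column
    randomly permuted; the score is the mean percent increase over
    ``n_repeats`` independent permutations.
    """
    if model.kind != "rf":
        raise ValueError("permutation importance is defined for the bagged ensemble")
    ens = model.estimator
    if not getattr(ens, "trees_", None):
        raise ValueError("model is not fitted")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    scores = _perm_importance_pct_inc_mse(ens, n_repeats, seed)
    imp = pd.DataFrame({"feature": list(model.feature_names), "pct_inc_mse": scores})
    model.importance = imp
    return imp


def fit_m5(table: TrainingTable, min_leaf: int = 4, prune: bool = True,
           smooth: bool = True) -> FittedModel:
    """Fit the M5'-style rule-based model tree on a county training table."""
    tree = M5ModelTree(min_leaf=min_leaf, prune=prune, smooth=smooth)
    tree.fit(table.X, table.y)
    p = len(table.feature_names)
    imp = pd.DataFrame(
        {"feature": list(table.feature_names), "var_imp_pct": tree.var_imp(p)}
    )
    y = table.y
    return FittedModel(
        kind="m5",
        estimator=tree,
        feature_names=table.feature_names,
        y_min=float(y.min()),
        y_max=float(y.max()),
        importance=imp,
        rules=tree.rules(),
    )


def predict_raster(model: FittedModel, stack: CovariateStack,
                   domain: np.ndarray | None = None) -> Raster:
    """Apply a fitted model cell-wise to the covariate stack.

    ``domain`` (boolean array) optionally restricts prediction, e.g. to land;
    cells outside it, or with any nodata feature, come out as nodata.
    """
    if tuple(model.feature_names) != tuple(stack.feature_names):
        raise ValueError(
            f"feature mismatch: model {model.feature_names} vs stack {stack.feature_names}"
        )
    mask = stack.valid_mask()
    if domain is not None:
        mask = mask & domain
    X = stack.to_matrix(mask)
    out = np.full(stack.spec.shape, np.nan)
    if X.shape[0]:
        out[mask] = model.predict(X)
    return Raster(stack.spec, out, float("nan"))
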
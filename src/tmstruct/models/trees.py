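"""Windowed tree models: random forests and gradient boosting.

Trees have no notion of sequence context, so the L x 40 feature stack is
expanded into explicit sliding windows (zero-padded past the termini)
before fitting.  Random forests are grown 100 trees at a time until the
validation score stops improving, over an exhaustive grid of the feature
fraction, minimum leaf size and window size; gradient boosting uses a
random search over its regularisation hyperparameters with early stopping
on the validation set.
"""

from __future__ import annotations

import itertools

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .specs import SearchSpace, TargetDef, TreeParams

__all__ = ["windowize", "WindowedTreeModel", "train_rf", "train_gbm"]


def windowize(features, w: int) -> np.ndarray:
    """Expand an L x F matrix into L rows of w*F window-concatenated
    values, zero-padded beyond the termini."""
    if w % 2 == 0 or w < 1:
        raise ValueError("window size must be odd and positive")
    X = np.asarray(features, dtype=float)
    L, F = X.shape
    half = (w - 1) // 2
    out = np.zeros((L, w * F))
    for k in range(w):
        off = k - half
        lo, hi = max(0, -off), min(L, L - off)
        if lo < hi:
            out[lo:hi, k * F:(k + 1) * F] = X[lo + off:hi + off]
    return out


class _ConstantModel:
    """Fallback when the training labels are degenerate (single class)."""

    def __init__(self, value, dim):
        self.value, self.dim = value, dim

    def predict(self, X):
        n = len(X)
        if self.dim == 1:
            return np.full(n, float(self.value))
        out = np.zeros((n, self.dim))
        out[:, int(self.value)] = 1.0
        return out


class WindowedTreeModel:
    """A fitted tree model for one target, bundled with its window size.

    ``predict(onehot, profile)`` matches the network interface: it stacks
    the features, windowizes with the model's own ``w`` and returns a
    per-residue array ((L, K) probabilities for categorical targets).
    """

    def __init__(self, estimator, target: TargetDef, w: int, params=None,
                 classes=None):
        self.estimator = estimator
        self.target = target
        self.w = w
        self.params = params
        # original class labels per probability column (classifiers may have
        # been fitted on re-encoded labels when a class was absent)
        self.classes = classes

    def _proba_classes(self):
        if self.classes is not None:
            return [int(c) for c in self.classes]
        return [int(c) for c in getattr(self.estimator, "classes_", [])]

    def _predict_rows(self, X):
        t = self.target
        if isinstance(self.estimator, _ConstantModel):
            return self.estimator.predict(X)
        if t.kind == "linear":
            return self.estimator.predict(X)
        proba = self.estimator.predict_proba(X)
        classes = self._proba_classes()
        if t.kind == "binary":
            return proba[:, classes.index(1)] if 1 in classes else np.zeros(len(X))
        out = np.zeros((len(X), t.dim))
        for j, cls in enumerate(classes):
            out[:, cls] = proba[:, j]
        return out

    def predict(self, onehot, profile):
        X = windowize(np.hstack([onehot, profile]), self.w)
        out = {self.target.name: self._predict_rows(X)}
        return out


def _flatten(samples, target: TargetDef, w: int):
    """Stack windowed rows and labels over all samples, masked."""
    Xs, ys = [], []
    for s in samples:
        m = np.asarray(s["masks"][target.name], dtype=bool)
        if not m.any():
            continue
        feats = windowize(np.hstack([s["onehot"], s["profile"]]), w)
        y = np.asarray(s["targets"][target.name])
        if target.kind == "categorical":
            y = y.argmax(axis=1)
        Xs.append(feats[m])
        ys.append(y[m])
    if not Xs:
        raise ValueError(f"no unmasked residues for target {target.name!r}")
    return np.vstack(Xs), np.concatenate(ys)


def _val_score(model: WindowedTreeModel, Xv, yv):
    """Validation loss (lower is better): MSE or error rate."""
    pred = model._predict_rows(Xv)
    if model.target.kind == "linear":
        return float(((pred - yv) ** 2).mean())
    if model.target.kind == "binary":
        return float(((pred > 0.5).astype(int) != yv).mean())
    return float((pred.argmax(axis=1) != yv).mean())


def train_rf(train, val, target: TargetDef, grid: dict | None = None,
             seed: int = 0, tree_step: int = 100, max_trees: int = 500):
    """Grid-search a random forest for one target.

    ``grid`` maps 'n_features' / 'n_min_samples' / 'w' to candidate lists
    and is searched exhaustively; for each combination the forest grows in
    ``tree_step`` increments (warm start) until the validation score no
    longer improves.  Split criteria are squared error (regression) and
    Gini impurity (classification).  Returns (model, info).
    """
    grid = grid or {"n_features": [0.5], "n_min_samples": [1], "w": [5]}
    best = None
    for n_feat, n_min, w in itertools.product(
            grid["n_features"], grid["n_min_samples"], grid["w"]):
        X, y = _flatten(train, target, w)
        Xv, yv = _flatten(val, target, w)
        kwargs = dict(n_estimators=0, warm_start=True, max_features=n_feat,
                      min_samples_leaf=n_min, bootstrap=True,
                      random_state=seed, n_jobs=1)
        if target.kind == "linear":
            est = RandomForestRegressor(criterion="squared_error", **kwargs)
        else:
            if np.unique(y).size < 2:
                est = _ConstantModel(y[0], target.dim if target.kind == "categorical" else 1)
                model = WindowedTreeModel(est, target, w)
                score = _val_score(model, Xv, yv)
                if best is None or score < best[0]:
                    best = (score, model, {"n_features": n_feat,
                                           "n_min_samples": n_min, "w": w,
                                           "n_trees": 0})
                continue
            est = RandomForestClassifier(criterion="gini", **kwargs)
        model = WindowedTreeModel(est, target, w)
        prev = np.inf
        n_trees = 0
        while n_trees < max_trees:
            est.n_estimators = n_trees + tree_step
            est.fit(X, y)
            score = _val_score(model, Xv, yv)
            n_trees = est.n_estimators
            if score >= prev:
                break
            prev = score
        combo = {"n_features": n_feat, "n_min_samples": n_min, "w": w,
                 "n_trees": n_trees}
        if best is None or prev < best[0]:
            best = (prev, model, combo)
    score, model, combo = best
    model.params = combo
    return model, {"val_score": score, **combo}


def _default_gbm_space(seed=0):
    return SearchSpace(values={
        "w": [5], "n_features": [0.8], "n_samples": [0.8],
        "r": [0.1, 0.3], "n_depth": [3, 4], "gamma": [0.0],
        "n_min_child_weight": [1.0],
    }, n_trials=2, seed=seed)


def train_gbm(train, val, target: TargetDef, space: SearchSpace | None = None,
              seed: int = 0, max_trees: int = 200, early_stopping_rounds: int = 10):
    """Random-search a gradient boosting machine for one target.

    Each trial draws (w, n_features, n_samples, r, n_depth, gamma,
    n_min_child_weight) uniformly from the candidate lists, boosts with
    validation-based early stopping, and the best trial by validation
    score is returned (ties keep the earlier draw).
    """
    import xgboost as xgb

    space = space or _default_gbm_space(seed)
    rng = np.random.default_rng(space.seed)
    best = None
    for trial in range(space.n_trials):
        draw = {k: v[rng.integers(len(v))] for k, v in space.values.items()}
        w = int(draw.get("w", 5))
        X, y = _flatten(train, target, w)
        Xv, yv = _flatten(val, target, w)
        kwargs = dict(
            n_estimators=max_trees,
            learning_rate=float(draw.get("r", 0.1)),
            max_depth=int(draw.get("n_depth", 4)),
            subsample=float(draw.get("n_samples", 1.0)),
            colsample_bytree=float(draw.get("n_features", 1.0)),
            gamma=float(draw.get("gamma", 0.0)),
            min_child_weight=float(draw.get("n_min_child_weight", 1.0)),
            random_state=seed,
            n_jobs=1,
            early_stopping_rounds=early_stopping_rounds,
            verbosity=0,
        )
        if target.kind == "linear":
            est = xgb.XGBRegressor(objective="reg:squarederror", **kwargs)
        elif np.unique(y).size < 2:
            est = _ConstantModel(y[0], target.dim if target.kind == "categorical" else 1)
            model = WindowedTreeModel(est, target, w, draw)
            score = _val_score(model, Xv, yv)
            if best is None or score < best[0]:
                best = (score, model, draw)
            continue
        elif target.kind == "binary":
            est = xgb.XGBClassifier(objective="binary:logistic", **kwargs)
        else:
            est = xgb.XGBClassifier(objective="multi:softprob", **kwargs)
        classes = None
        fit_y, fit_yv = y, yv
        if target.kind != "linear":
            # xgboost needs contiguous 0..K-1 labels
            classes, fit_y = np.unique(y, return_inverse=True)
            lut = {int(c): i for i, c in enumerate(classes)}
            fit_yv = np.array([lut.get(int(v), 0) for v in yv])
        est.fit(X, fit_y, eval_set=[(Xv, fit_yv)], verbose=False)
        model = WindowedTreeModel(est, target, w, draw, classes=classes)
        score = _val_score(model, Xv, yv)
        if best is None or score < best[0]:
            best = (score, model, draw)
    score, model, draw = best
    return model, {"val_score": score, **draw}
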
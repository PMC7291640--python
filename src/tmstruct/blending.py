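"""Stacked-generalization blending of the five base model families.

Within each cross-validation fold, the base models (conv, dconv, lstm
networks plus the windowed RF and GBM) predict the fold's validation bin;
those predictions train one meta-model per target -- a linear regression
for continuous targets, a logistic regression for binary and categorical
targets -- which amounts to a learned weighted average of the families.
The final predictor averages the five fold meta-models' outputs
(renormalizing categorical rows), so each target group is backed by
5 folds x (5 base + 1 meta) = 30 models.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression, Ridge

from .models.specs import TARGETS, TargetDef

__all__ = [
    "MetaModel", "FoldEnsemble", "BlendedEnsemble",
    "fit_meta", "predict_blend", "count_models",
    "save_ensemble", "load_ensemble",
]

#: Canonical base-family order for meta-model design matrices.
BASE_FAMILIES = ("conv", "dconv", "lstm", "rf", "gbm")


class MetaModel:
    """Linear/logistic combiner over the base families' predictions."""

    def __init__(self, target: TargetDef, families, estimator, classes=None,
                 constant=None):
        self.target = target
        self.families = tuple(families)
        self.estimator = estimator
        self.classes = classes
        self.constant = constant

    def _design(self, base_preds: dict) -> np.ndarray:
        cols = []
        for fam in self.families:
            p = np.asarray(base_preds[fam], dtype=float)
            cols.append(p.reshape(len(p), -1))
        return np.hstack(cols)

    def predict(self, base_preds: dict) -> np.ndarray:
        X = self._design(base_preds)
        t = self.target
        if self.constant is not None:
            if t.kind == "categorical":
                out = np.zeros((len(X), t.dim))
                out[:, int(self.constant)] = 1.0
                return out
            return np.full(len(X), float(self.constant))
        if t.kind == "linear":
            return self.estimator.predict(X)
        proba = self.estimator.predict_proba(X)
        if t.kind == "binary":
            classes = [int(c) for c in self.estimator.classes_]
            return proba[:, classes.index(1)]
        out = np.zeros((len(X), t.dim))
        for j, cls in enumerate(self.estimator.classes_):
            out[:, int(cls)] = proba[:, j]
        return out


def fit_meta(base_preds: dict, observed, target: TargetDef, mask=None) -> MetaModel:
    """Fit the meta-model for one target from held-out base predictions.

    ``base_preds`` maps family name to a per-residue array ((n, K)
    probabilities for categorical targets, giving 5K meta features);
    ``observed`` is the true target ((n, K) one-hot for categorical).
    Continuous targets use a least-squares fit with a tiny quadratic
    penalty so constant predictor columns (common at small scale) stay
    well-posed; discrete targets use (multinomial) logistic regression.
    """
    families = [f for f in BASE_FAMILIES if f in base_preds] or sorted(base_preds)
    y = np.asarray(observed, dtype=float)
    m = np.ones(len(y), dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    meta = MetaModel(target, families, None)
    X = meta._design(base_preds)[m]
    if target.kind == "categorical":
        y_lab = y.argmax(axis=1)[m]
    else:
        y_lab = y[m]
    if target.kind == "linear":
        est = Ridge(alpha=1e-6)
        est.fit(X, y_lab)
        meta.estimator = est
        return meta
    if np.unique(y_lab).size < 2:
        meta.constant = y_lab[0]
        return meta
    est = LogisticRegression(C=1e4, max_iter=2000)
    est.fit(X, y_lab.astype(int))
    meta.estimator = est
    return meta


@dataclass
class FoldEnsemble:
    """Base models and per-target meta-models of one fold, one group."""

    fold_index: int
    base_models: dict          # family -> model with .predict(onehot, profile)
    meta_models: dict          # target name -> MetaModel

    def predict(self, onehot, profile) -> dict:
        base = {fam: model.predict(onehot, profile)
                for fam, model in self.base_models.items()}
        out = {}
        for name, meta in self.meta_models.items():
            per_family = {fam: base[fam][name] for fam in base}
            out[name] = meta.predict(per_family)
        return out


@dataclass
class BlendedEnsemble:
    """Fold ensembles per target group; prediction averages fold outputs."""

    folds_by_group: dict = field(default_factory=dict)  # group -> [FoldEnsemble]
    metadata: dict = field(default_factory=dict)


def predict_blend(ensemble: BlendedEnsemble, onehot, profile) -> dict:
    """Final blended prediction: the arithmetic mean of the fold
    meta-models' outputs, with categorical rows renormalized to sum 1."""
    out = {}
    for group, folds in ensemble.folds_by_group.items():
        if not folds:
            raise ValueError(f"no folds for group {group!r}")
        acc: dict = {}
        for fold in folds:
            for name, pred in fold.predict(onehot, profile).items():
                acc.setdefault(name, []).append(np.asarray(pred, dtype=float))
        for name, preds in acc.items():
            mean = np.mean(preds, axis=0)
            if TARGETS[name].kind == "categorical":
                mean = mean / np.clip(mean.sum(axis=1, keepdims=True), 1e-12, None)
            out[name] = mean
    return out


def count_models(ensemble: BlendedEnsemble, group: str) -> int:
    """Total models behind one group: folds x (base families + 1 meta)."""
    folds = ensemble.folds_by_group.get(group, [])
    if not folds:
        return 0
    n_base = len(folds[0].base_models)
    return len(folds) * (n_base + 1)


def save_ensemble(ensemble: BlendedEnsemble, directory) -> Path:
    """Write a manifest (JSON) plus the pickled models; returns the
    manifest path."""
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "ensemble.pkl", "wb") as fh:
        pickle.dump(ensemble, fh)
    manifest = {
        "groups": {
            group: {
                "n_folds": len(folds),
                "families": sorted(folds[0].base_models) if folds else [],
                "targets": sorted(folds[0].meta_models) if folds else [],
                "n_models": count_models(ensemble, group),
            }
            for group, folds in ensemble.folds_by_group.items()
        },
        "models_file": "ensemble.pkl",
        **ensemble.metadata,
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def load_ensemble(directory) -> BlendedEnsemble:
    directory = Path(directory)
    if not (directory / "manifest.json").exists():
        raise FileNotFoundError(f"no manifest.json under {directory}")
    with open(directory / "ensemble.pkl", "rb") as fh:
        return pickle.load(fh)
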
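"""Evaluation metrics for continuous and discrete per-residue targets.

Continuous: MAE, MSE, RMSE, Pearson and Spearman correlations.
Discrete: accuracy, precision, recall, F1, Matthews correlation, and a
rank-statistic ROC AUC.  Undefined ratios (zero denominators) are reported
as NaN rather than raised.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import rankdata

from .targets import SS3_CLASSES, TOPOLOGY_CLASSES, TargetBundle

__all__ = [
    "mae", "mse", "rmse", "pearson", "spearman",
    "confusion_counts", "classification_metrics", "roc_auc",
    "evaluate_bundle",
]


def _xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("observed and predicted lengths differ")
    if x.size == 0:
        raise ValueError("empty input")
    return x, y


def mae(x, y) -> float:
    x, y = _xy(x, y)
    return float(np.abs(y - x).mean())


def mse(x, y) -> float:
    x, y = _xy(x, y)
    return float(((y - x) ** 2).mean())


def rmse(x, y) -> float:
    return math.sqrt(mse(x, y))


def pearson(x, y) -> float:
    x, y = _xy(x, y)
    if x.size < 2:
        raise ValueError("correlation needs n >= 2")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = math.sqrt(float((dx ** 2).sum() * (dy ** 2).sum()))
    if denom == 0:
        return float("nan")
    return float((dx * dy).sum() / denom)


def spearman(x, y) -> float:
    """Pearson correlation on midrank-transformed data."""
    x, y = _xy(x, y)
    return pearson(rankdata(x), rankdata(y))


def confusion_counts(y_true, y_pred):
    """(TP, TN, FP, FN) for binary 0/1 labels."""
    t = np.asarray(y_true).astype(int)
    p = np.asarray(y_pred).astype(int)
    tp = int(((t == 1) & (p == 1)).sum())
    tn = int(((t == 0) & (p == 0)).sum())
    fp = int(((t == 0) & (p == 1)).sum())
    fn = int(((t == 1) & (p == 0)).sum())
    return tp, tn, fp, fn


def classification_metrics(tp, tn, fp, fn) -> dict:
    """ACC, P, R, F1, MCC from confusion counts; NaN where undefined.

    Accuracy is the standard (TP+TN)/total.
    """
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion table")
    acc = (tp + tn) / total
    p = tp / (tp + fp) if tp + fp > 0 else float("nan")
    r = tp / (tp + fn) if tp + fn > 0 else float("nan")
    f1 = 2 * p * r / (p + r) if p + r > 0 else float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else float("nan")
    return {"ACC": acc, "P": p, "R": r, "F1": f1, "MCC": mcc}


def roc_auc(scores, labels) -> float:
    """Probability that a random positive outranks a random negative
    (ties count 0.5), computed from midranks."""
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels).astype(int)
    n_pos = int((lab == 1).sum())
    n_neg = int((lab == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = rankdata(s)
    return float((ranks[lab == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _circular_diff(a_deg, b_deg):
    d = np.abs(np.asarray(a_deg) - np.asarray(b_deg)) % 360.0
    return np.minimum(d, 360.0 - d)


def _continuous_report(x, y):
    return {
        "MAE": mae(x, y), "MSE": mse(x, y), "RMSE": rmse(x, y),
        "r_p": pearson(x, y) if len(np.atleast_1d(x)) > 1 else float("nan"),
        "r_s": spearman(x, y) if len(np.atleast_1d(x)) > 1 else float("nan"),
    }


def _angle_report(x_scaled, y_scaled):
    """Angle errors in degrees on the circle; correlations on the scaled values."""
    x_deg = np.asarray(x_scaled) * 180.0
    y_deg = np.asarray(y_scaled) * 180.0
    d = _circular_diff(x_deg, y_deg)
    return {
        "MAE": float(d.mean()), "MSE": float((d ** 2).mean()),
        "RMSE": math.sqrt(float((d ** 2).mean())),
        "r_p": pearson(x_scaled, y_scaled) if len(d) > 1 else float("nan"),
        "r_s": spearman(x_scaled, y_scaled) if len(d) > 1 else float("nan"),
        "difference": "circular",
    }


def _categorical_report(y_true_onehot, y_prob, classes):
    t_idx = np.asarray(y_true_onehot).argmax(axis=1)
    p_idx = np.asarray(y_prob).argmax(axis=1)  # ties -> lowest class index
    report = {"ACC": float((t_idx == p_idx).mean()), "per_class": {}}
    for j, cls in enumerate(classes):
        tp, tn, fp, fn = confusion_counts(t_idx == j, p_idx == j)
        cm = classification_metrics(tp, tn, fp, fn)
        try:
            cm["AUC"] = roc_auc(np.asarray(y_prob)[:, j], (t_idx == j).astype(int))
        except ValueError:
            cm["AUC"] = float("nan")
        report["per_class"][cls] = cm
    return report


def _binary_report(y_true, y_prob):
    pred = (np.asarray(y_prob) > 0.5).astype(int)
    tp, tn, fp, fn = confusion_counts(y_true, pred)
    report = classification_metrics(tp, tn, fp, fn)
    try:
        report["AUC"] = roc_auc(y_prob, y_true)
    except ValueError:
        report["AUC"] = float("nan")
    return report


def evaluate_bundle(predictions: dict, bundle: TargetBundle) -> dict:
    """Full metric report for all ten targets.

    ``predictions`` maps target name to an array shaped like the bundle's
    target (1-D for scalars, (L, K) probabilities for categoricals).
    Masked residues are excluded.  z errors are reported in Angstrom and
    angle errors in degrees (circular difference); secondary structure is
    additionally evaluated on non-membrane residues only (``ss3_nontm``),
    since transmembrane stretches are almost uniformly helical and inflate
    the accuracy.
    """
    report = {}
    is_tms = np.array([lab == "TMS" for lab in bundle.topo_labels])
    for name in TargetBundle.TARGET_NAMES:
        if name not in predictions:
            continue
        m = bundle.masks[name]
        if not m.any():
            report[name] = {"n": 0}
            continue
        pred = np.asarray(predictions[name])
        truth = bundle.target(name)
        if name == "z":
            rep = _continuous_report(truth[m] * 25.0, pred[m] * 25.0)
            rep["units"] = "angstrom"
        elif name in ("phi", "psi"):
            rep = _angle_report(truth[m], pred[m])
            rep["units"] = "degrees"
        elif name in ("flex_cont", "rsa_mono", "rsa_cplx", "rsa_change"):
            rep = _continuous_report(truth[m], pred[m])
        elif name == "flex_bin":
            rep = _binary_report(truth[m], pred[m])
        elif name == "topo":
            rep = _categorical_report(truth[m], pred[m], TOPOLOGY_CLASSES)
        elif name == "ss3":
            rep = _categorical_report(truth[m], pred[m], SS3_CLASSES)
            mm = m & ~is_tms
            if mm.any():
                report["ss3_nontm"] = _categorical_report(
                    truth[mm], pred[mm], SS3_CLASSES
                )
                report["ss3_nontm"]["n"] = int(mm.sum())
        rep["n"] = int(m.sum())
        report[name] = rep
    return report
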
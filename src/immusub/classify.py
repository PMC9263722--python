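"""Multinomial logistic subtype classifier on module activities.

A softmax regression with the reference class pinned at zero, fitted by
maximizing the multinomial log-likelihood with a small ridge penalty on
the weights (intercepts unpenalized) — the penalty keeps coefficients
finite on separable data.  Features are standardized internally and the
transform stored with the model, so it transfers across cohorts on the
module-activity scale.  Evaluation is one-vs-rest: per-class AUROC (the
Mann-Whitney statistic, ties counted 1/2) and AUPRC (step-interpolated
precision-recall), as implemented in scikit-learn.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.metrics import average_precision_score, confusion_matrix, roc_auc_score

from .consensus import SubtypeLabels
from .transfer import ActivityMatrix

__all__ = ["MultinomialModel", "ClassifierEval", "fit_multinomial", "predict_proba", "evaluate_ovr"]

log = logging.getLogger(__name__)


@dataclass
class MultinomialModel:
    """Reference-class softmax regression over module activities."""

    class_ids: list  # reference class first
    module_ids: list
    coefficients: np.ndarray  # (n_classes - 1) x (n_modules + 1); column 0 = intercept
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    ridge: float
    converged: bool = True
    metadata: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        doc = {
            "class_ids": list(self.class_ids),
            "module_ids": list(self.module_ids),
            "coefficients": self.coefficients.tolist(),
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "ridge": self.ridge,
            "converged": self.converged,
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MultinomialModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            class_ids=doc["class_ids"],
            module_ids=doc["module_ids"],
            coefficients=np.asarray(doc["coefficients"], float),
            feature_mean=np.asarray(doc["feature_mean"], float),
            feature_sd=np.asarray(doc["feature_sd"], float),
            ridge=doc["ridge"],
            converged=doc["converged"],
            metadata=doc.get("metadata", {}),
        )


@dataclass
class ClassifierEval:
    """One-vs-rest performance summary."""

    auroc: pd.Series  # per class; NaN where the class is absent
    auprc: pd.Series
    macro_auroc: float
    macro_auprc: float
    confusion: pd.DataFrame  # rows true, columns predicted (argmax)

    def to_tsv(self, path) -> None:
        pd.DataFrame({"auroc": self.auroc, "auprc": self.auprc}).to_csv(
            path, sep="\t", index_label="class"
        )


def _design(activity: ActivityMatrix, module_ids, mean, sd) -> np.ndarray:
    missing = set(module_ids) - set(activity.module_ids)
    if missing:
        raise ValueError(f"activity matrix lacks modules: {sorted(missing)}")
    X = activity.activities.loc[list(module_ids)].T.to_numpy(float)
    return (X - mean) / sd


def _nll_grad(theta, X1, Y, ridge, n_classes):
    """Penalized negative log-likelihood and gradient.

    ``theta`` holds the (n_classes - 1) x p coefficient block row-major;
    the reference class (index 0) is fixed at zero.  Ridge applies to the
    weights only, not intercepts.
    """
    n, p = X1.shape
    B = theta.reshape(n_classes - 1, p)
    scores = np.zeros((n, n_classes))
    scores[:, 1:] = X1 @ B.T
    scores -= scores.max(axis=1, keepdims=True)
    expS = np.exp(scores)
    P = expS / expS.sum(axis=1, keepdims=True)
    loglik = np.log(P[np.arange(n), Y] + 1e-300).sum()
    pen = 0.5 * ridge * (B[:, 1:] ** 2).sum()
    G = np.zeros_like(B)
    for c in range(1, n_classes):
        resid = (Y == c).astype(float) - P[:, c]
        G[c - 1] = -(resid @ X1)
    G[:, 1:] += ridge * B[:, 1:]
    return -(loglik) + pen, G.ravel()


def fit_multinomial(
    activity: ActivityMatrix,
    labels: SubtypeLabels,
    reference: str | None = None,
    ridge: float = 1e-4,
    max_iter: int = 500,
    gtol: float = 1e-6,
) -> MultinomialModel:
    """Fit the reference-class softmax model on module activities.

    ``reference`` defaults to the first class in sorted label order.
    Convergence is declared when the gradient sup-norm falls below
    ``gtol``; otherwise the model is returned with ``converged=False`` and
    a warning.
    """
    lab = labels.subtype_of_sample.reindex(activity.sample_ids).dropna()
    classes = sorted(lab.unique())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if any((lab == c).sum() < 2 for c in classes):
        raise ValueError("each class needs >= 2 samples")
    if reference is None:
        reference = classes[0]
    if reference not in classes:
        raise ValueError(f"reference class {reference!r} not among {classes}")
    class_ids = [reference] + [c for c in classes if c != reference]

    A = activity.activities[lab.index]
    X = A.T.to_numpy(float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        log.warning("dropping %d zero-variance modules", int((~keep).sum()))
    module_ids = [m for m, k in zip(activity.module_ids, keep) if k]
    Xs = (X[:, keep] - mean[keep]) / sd[keep]
    X1 = np.column_stack([np.ones(len(Xs)), Xs])
    Y = np.array([class_ids.index(c) for c in lab])
    n_classes, p = len(class_ids), X1.shape[1]

    res = minimize(
        _nll_grad,
        np.zeros((n_classes - 1) * p),
        args=(X1, Y, ridge, n_classes),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol * 1e-2, "ftol": 1e-14},
    )
    _, grad = _nll_grad(res.x, X1, Y, ridge, n_classes)
    converged = bool(np.abs(grad).max() < gtol)
    if not converged:
        warnings.warn("multinomial fit did not reach gradient tolerance")
    return MultinomialModel(
        class_ids=class_ids,
        module_ids=module_ids,
        coefficients=res.x.reshape(n_classes - 1, p),
        feature_mean=mean[keep],
        feature_sd=sd[keep],
        ridge=ridge,
        converged=converged,
        metadata={"n": int(len(Y)), "n_iter": int(res.nit)},
    )


def predict_proba(model: MultinomialModel, activity: ActivityMatrix) -> pd.DataFrame:
    """Softmax class probabilities (rows = samples, columns = classes)."""
    Xs = _design(activity, model.module_ids, model.feature_mean, model.feature_sd)
    X1 = np.column_stack([np.ones(len(Xs)), Xs])
    scores = np.zeros((len(Xs), len(model.class_ids)))
    scores[:, 1:] = X1 @ model.coefficients.T
    scores -= scores.max(axis=1, keepdims=True)
    expS = np.exp(scores)
    P = expS / expS.sum(axis=1, keepdims=True)
    return pd.DataFrame(P, index=activity.sample_ids, columns=model.class_ids)


def predict_labels(model: MultinomialModel, activity: ActivityMatrix) -> SubtypeLabels:
    proba = predict_proba(model, activity)
    return SubtypeLabels(proba.idxmax(axis=1), provenance="classifier")


def evaluate_ovr(y_true: pd.Series, proba: pd.DataFrame) -> ClassifierEval:
    """One-vs-rest AUROC/AUPRC per class plus argmax confusion matrix.

    Classes absent from ``y_true`` get NaN metrics (reported as missing,
    not zero) and are left out of the macro averages.
    """
    y_true = pd.Series(y_true).reindex(proba.index)
    if y_true.isna().any():
        raise ValueError("labels missing for some samples")
    auroc, auprc = {}, {}
    for c in proba.columns:
        pos = (y_true == c).to_numpy(int)
        if pos.sum() == 0 or pos.sum() == len(pos):
            auroc[c] = np.nan
            auprc[c] = np.nan
            continue
        auroc[c] = roc_auc_score(pos, proba[c].to_numpy(float))
        auprc[c] = average_precision_score(pos, proba[c].to_numpy(float))
    auroc = pd.Series(auroc)
    auprc = pd.Series(auprc)
    pred = proba.idxmax(axis=1)
    classes = list(proba.columns)
    cm = confusion_matrix(y_true, pred, labels=classes)
    return ClassifierEval(
        auroc=auroc,
        auprc=auprc,
        macro_auroc=float(auroc.mean()),
        macro_auprc=float(auprc.mean()),
        confusion=pd.DataFrame(cm, index=classes, columns=classes),
    )
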
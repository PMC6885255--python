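"""Subtype classifiers and imbalance-aware evaluation.

Four classifiers are used throughout: logistic regression (LR), linear
support vector machine (SVM), random forest (RF) and gradient boosting
decision trees (GBDT), plus a majority-vote ensemble over the four.  The
cohort is imbalanced across the four molecular subtypes, so evaluation
reports per-class precision/recall/F1 alongside the pooled accuracy; the
headline precision/recall/F1 are macro averages (weighted averages are
also emitted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "MODEL_IDS",
    "ENSEMBLE_TIE_PRIORITY",
    "ModelConfig",
    "ClassReport",
    "build_estimator",
    "make_cv",
    "crossval_evaluate",
    "class_report",
    "ensemble_predict",
    "crossval_ensemble",
]

MODEL_IDS = ("lr", "svm", "rf", "gbdt")

#: Residual tie-break order for the ensemble vote, strongest model first.
ENSEMBLE_TIE_PRIORITY = ("gbdt", "svm", "rf", "lr")


@dataclass
class ModelConfig:
    """Classifier configuration with documented defaults.

    LR: L2 penalty, C = 1.  SVM: linear kernel, C = 1.  RF: 500 trees.
    GBDT: 300 boosting stages, learning rate 0.1, depth 3.  The ``params``
    mapping overrides estimator keyword arguments.
    """

    model_id: str
    seed: int = 0
    svm_probability: bool = False
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS + ("ensemble",):
            raise ValueError(f"unknown model_id {self.model_id!r}")


def build_estimator(model_id: str, seed: int = 0, svm_probability: bool = False,
                    **params):
    """Construct a fresh (unfitted) classifier.

    Linear models are wrapped in a z-scoring pipeline; tree ensembles
    consume raw features.
    """
    if model_id == "lr":
        # L2 penalty (the estimator default), C = 1
        kw = dict(C=1.0, max_iter=5000, random_state=seed)
        kw.update(params)
        return make_pipeline(StandardScaler(), LogisticRegression(**kw))
    if model_id == "svm":
        kw = dict(kernel="linear", C=1.0, random_state=seed)
        if svm_probability:
            kw["probability"] = True
        kw.update(params)
        return make_pipeline(StandardScaler(), SVC(**kw))
    if model_id == "rf":
        kw = dict(n_estimators=500, random_state=seed, n_jobs=1)
        kw.update(params)
        return RandomForestClassifier(**kw)
    if model_id == "gbdt":
        kw = dict(n_estimators=300, learning_rate=0.1, max_depth=3, random_state=seed)
        kw.update(params)
        return GradientBoostingClassifier(**kw)
    raise ValueError(f"unknown model_id {model_id!r}")


def make_cv(scheme, seed: int = 0):
    """Build a CV splitter from ``"kfold:K"`` or ``"loo"`` (or pass through
    an existing splitter).  Stratified k-fold with a fixed shuffle seed is
    the fast default; leave-one-case-out is the fidelity mode."""
    if not isinstance(scheme, str):
        return scheme
    if scheme == "loo":
        return LeaveOneOut()
    if scheme.startswith("kfold:"):
        k = int(scheme.split(":", 1)[1])
        return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    raise ValueError(f"unknown CV scheme {scheme!r}")


@dataclass
class ClassReport:
    """Pooled evaluation in the shape of a per-subtype metrics table."""

    classes: list[str]
    accuracy: float
    per_class: pd.DataFrame            # index = class; precision/recall/f1/support
    macro: dict
    weighted: dict
    confusion: np.ndarray              # (k, k) counts, rows = true class

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "accuracy": self.accuracy,
            "per_class": {
                str(c): {k: float(v) for k, v in row.items()}
                for c, row in self.per_class.iterrows()
            },
            "macro": {k: float(v) for k, v in self.macro.items()},
            "weighted": {k: float(v) for k, v in self.weighted.items()},
            "confusion": self.confusion.tolist(),
        }

    def to_markdown(self) -> str:
        lines = ["| Subtype | Precision | Recall | F1-score |", "|---|---|---|---|"]
        for c, row in self.per_class.iterrows():
            lines.append(f"| {c} | {row['precision']:.2f} | {row['recall']:.2f} | {row['f1']:.2f} |")
        lines.append(
            f"| macro | {self.macro['precision']:.2f} | {self.macro['recall']:.2f} "
            f"| {self.macro['f1']:.2f} |"
        )
        lines.append(f"\nAccuracy: {self.accuracy:.2f}")
        return "\n".join(lines)


def class_report(y_true, y_pred, classes=None) -> ClassReport:
    """Per-class precision/recall/F1, macro/weighted averages, confusion matrix.

    Zero-denominator metrics are reported as 0 with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("empty or mismatched label arrays")
    if classes is None:
        classes = sorted(np.unique(np.concatenate([y_true, y_pred])).tolist())
    conf = confusion_matrix(y_true, y_pred, labels=classes)
    if (conf.sum(axis=0) == 0).any() or (conf.sum(axis=1) == 0).any():
        warnings.warn("zero-denominator class metrics reported as 0")
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0
    )
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "support": support},
        index=list(classes),
    )
    macro = {"precision": float(prec.mean()), "recall": float(rec.mean()), "f1": float(f1.mean())}
    w = support / support.sum()
    weighted = {
        "precision": float((prec * w).sum()),
        "recall": float((rec * w).sum()),
        "f1": float((f1 * w).sum()),
    }
    return ClassReport(
        classes=list(classes),
        accuracy=float(np.trace(conf) / conf.sum()),
        per_class=per_class,
        macro=macro,
        weighted=weighted,
        confusion=conf,
    )


def crossval_evaluate(config: ModelConfig, table: pd.DataFrame, cv="kfold:5",
                      label_col: str = "label") -> ClassReport:
    """Cross-validated evaluation with out-of-fold predictions pooled into a
    single confusion matrix (deterministic under the configured seed)."""
    y = table[label_col].to_numpy()
    X = table.drop(columns=[label_col]).to_numpy()
    cv_obj = make_cv(cv, seed=config.seed)
    classes = sorted(np.unique(y).tolist())
    if isinstance(cv_obj, StratifiedKFold):
        counts = pd.Series(y).value_counts()
        if counts.min() < cv_obj.get_n_splits():
            raise ValueError(
                "a class has fewer samples than folds; use stratification with "
                "fewer folds or leave-one-out"
            )
    y_pred = np.empty_like(y)
    for train, test in cv_obj.split(X, y):
        if len(np.unique(y[train])) < len(classes):
            raise ValueError(
                "a class is absent from a training fold; use a stratified scheme"
            )
        if config.model_id == "ensemble":
            fitted = _fit_all(X[train], y[train], config)
            y_pred[test] = ensemble_predict(fitted, X[test])
        else:
            est = build_estimator(
                config.model_id, seed=config.seed,
                svm_probability=config.svm_probability, **config.params
            )
            est.fit(X[train], y[train])
            y_pred[test] = est.predict(X[test])
    return class_report(y, y_pred, classes=classes)


def _fit_all(X, y, config: ModelConfig) -> dict:
    fitted = {}
    for m in MODEL_IDS:
        params = config.params.get(m, {}) if config.params else {}
        est = build_estimator(m, seed=config.seed,
                              svm_probability=config.svm_probability and m == "svm",
                              **params)
        est.fit(X, y)
        fitted[m] = est
    return fitted


def _mean_proba(fitted: dict, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    acc = np.zeros((X.shape[0], classes.size))
    n = 0
    for est in fitted.values():
        final = est[-1] if hasattr(est, "steps") else est
        if not hasattr(final, "predict_proba"):
            continue
        try:
            p = est.predict_proba(X)
        except AttributeError:
            continue
        cols = {c: i for i, c in enumerate(final.classes_)}
        aligned = np.zeros_like(acc)
        for j, c in enumerate(classes):
            if c in cols:
                aligned[:, j] = p[:, cols[c]]
        acc += aligned
        n += 1
    return acc / max(n, 1)


def ensemble_predict(fitted: dict, X) -> np.ndarray:
    """Majority vote over fitted models.

    Vote ties are broken by the highest mean predicted class probability
    (over the models exposing probabilities); residual ties fall back to a
    fixed model-priority order (GBDT, SVM, RF, LR).
    """
    if len(fitted) < 2:
        raise ValueError("ensemble needs >= 2 fitted models")
    X = np.asarray(X)
    preds = {m: est.predict(X) for m, est in fitted.items()}
    first = next(iter(fitted.values()))
    final = first[-1] if hasattr(first, "steps") else first
    classes = np.asarray(sorted(set(np.concatenate(list(preds.values())).tolist()))
                         if not hasattr(final, "classes_") else final.classes_)
    votes = np.zeros((X.shape[0], classes.size), dtype=int)
    cls_index = {c: i for i, c in enumerate(classes)}
    for p in preds.values():
        for i, c in enumerate(p):
            votes[i, cls_index[c]] += 1
    proba = _mean_proba(fitted, X, classes)

    out = np.empty(X.shape[0], dtype=classes.dtype)
    priority = [m for m in ENSEMBLE_TIE_PRIORITY if m in preds]
    for i in range(X.shape[0]):
        vmax = votes[i].max()
        tied = np.nonzero(votes[i] == vmax)[0]
        if tied.size == 1:
            out[i] = classes[tied[0]]
            continue
        pvals = proba[i, tied]
        best = tied[pvals == pvals.max()]
        if best.size == 1:
            out[i] = classes[best[0]]
            continue
        best_set = {classes[b] for b in best}
        chosen = None
        for m in priority:
            if preds[m][i] in best_set:
                chosen = preds[m][i]
                break
        out[i] = chosen if chosen is not None else classes[best[0]]
    return out


def crossval_ensemble(table: pd.DataFrame, cv="kfold:5", seed: int = 0,
                      label_col: str = "label", params: dict | None = None) -> ClassReport:
    """Convenience wrapper: cross-validated majority-vote ensemble report."""
    config = ModelConfig("ensemble", seed=seed, params=params or {})
    return crossval_evaluate(config, table, cv=cv, label_col=label_col)
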
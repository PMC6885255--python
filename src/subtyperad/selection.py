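"""Recursive feature elimination, single-model and multi-model (mmRFE).

Traditional RFE repeatedly fits one model, ranks the surviving features by
that model's importance and removes the least important.  Different models
keep different subsets, so a subset tuned to one classifier can degrade the
others.  mmRFE instead lets every model rank the features each iteration,
sums each feature's rank position across models into a composite score, and
eliminates by the composite ranking; every model's cross-validated accuracy
is recorded at every subset size, and the subset finally selected is the one
all models agree is good (max-min accuracy above a threshold θ).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import cross_val_predict

from .modeling import MODEL_IDS, build_estimator, make_cv

__all__ = [
    "ImportanceRanking",
    "EliminationRecord",
    "EliminationTrace",
    "SelectionRule",
    "SelectionResult",
    "model_importance",
    "composite_rank",
    "rfe",
    "mmrfe",
]


@dataclass
class ImportanceRanking:
    """Features of one model ordered importance-descending."""

    model_id: str
    ordered_features: list[str]

    def position(self, feature: str) -> int:
        return self.ordered_features.index(feature)


@dataclass
class EliminationRecord:
    """State of one elimination iteration, before the removal it records."""

    features: list[str]
    accuracies: dict[str, float]          # per-model CV accuracy on `features`
    removed: list[str]
    composite_order: list[str] | None = None

    def to_dict(self) -> dict:
        return {
            "features": self.features,
            "accuracies": self.accuracies,
            "removed": self.removed,
            "composite_order": self.composite_order,
        }


@dataclass
class EliminationTrace:
    """Full audit trail of an elimination run."""

    model_ids: list[str]
    step: int
    records: list[EliminationRecord] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def to_json(self, path) -> None:
        payload = {
            "model_ids": self.model_ids,
            "step": self.step,
            "records": [r.to_dict() for r in self.records],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "EliminationTrace":
        with open(path) as fh:
            payload = json.load(fh)
        trace = cls(model_ids=payload["model_ids"], step=payload["step"])
        trace.records = [EliminationRecord(**r) for r in payload["records"]]
        return trace


@dataclass
class SelectionRule:
    """Acceptance rule for candidate subsets: every model must reach
    ``min_accuracy``; among qualifiers the max-min-accuracy subset wins,
    ties resolved by higher mean accuracy, then by smaller subset."""

    min_accuracy: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_accuracy <= 1.01:
            raise ValueError("min_accuracy must be in [0, 1] (or slightly above to force emptiness)")


@dataclass
class SelectionResult:
    """Outcome of mmRFE subset selection.

    ``selected`` is empty when no iteration met the rule; ``best_available``
    then still points at the max-min-accuracy subset for inspection.
    """

    selected: list[str]
    selected_accuracies: dict[str, float]
    best_available: list[str]
    best_available_accuracies: dict[str, float]

    @property
    def is_empty(self) -> bool:
        return not self.selected


def _xy(table: pd.DataFrame, label_col: str):
    y = table[label_col].to_numpy()
    X = table.drop(columns=[label_col])
    return X, y


def model_importance(model_id: str, table: pd.DataFrame, label_col: str = "label",
                     seed: int = 0, params: dict | None = None) -> ImportanceRanking:
    """Rank the feature columns of ``table`` by one model's importance.

    Linear models (LR, linear SVM) use the mean over classes of the absolute
    standardised coefficients (features are z-scored before the fit); tree
    ensembles (RF, GBDT) use impurity-based importances.  Ties keep column
    order.
    """
    X, y = _xy(table, label_col)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 features")
    if len(np.unique(y)) < 2:
        raise ValueError("need >= 2 classes")
    est = build_estimator(model_id, seed=seed, **(params or {}))
    est.fit(X.to_numpy(), y)
    final = est[-1] if hasattr(est, "steps") else est
    if hasattr(final, "coef_"):
        imp = np.abs(np.atleast_2d(final.coef_)).mean(axis=0)
    else:
        imp = np.asarray(final.feature_importances_, dtype=float)
    if not np.all(np.isfinite(imp)):
        raise ValueError(f"non-finite importances from {model_id}")
    order = np.argsort(-imp, kind="stable")      # stable: ties keep column order
    return ImportanceRanking(model_id, [X.columns[i] for i in order])


def composite_rank(rankings: list[ImportanceRanking]) -> list[str]:
    """Combine per-model rankings by summing each feature's rank position.

    Lower summed position = more important.  Ties are broken by the best
    single-model position, then by label order of the first ranking.
    The result is invariant to the order the rankings are supplied in.
    """
    if not rankings:
        raise ValueError("no rankings supplied")
    base = rankings[0].ordered_features
    feature_set = set(base)
    for r in rankings[1:]:
        if set(r.ordered_features) != feature_set:
            raise ValueError("rankings cover different feature sets")
    positions = {f: [r.position(f) for r in rankings] for f in base}
    label_order = {f: i for i, f in enumerate(sorted(base))}
    return sorted(base, key=lambda f: (sum(positions[f]), min(positions[f]), label_order[f]))


def _cv_accuracy(model_id: str, X: pd.DataFrame, y, cv, seed: int,
                 params: dict | None = None) -> float:
    est = build_estimator(model_id, seed=seed, **(params or {}))
    pred = cross_val_predict(clone(est), X.to_numpy(), y, cv=cv)
    return float(np.mean(pred == y))


def rfe(model_id: str, table: pd.DataFrame, step: int = 1, cv="kfold:5",
        label_col: str = "label", seed: int = 0,
        model_params: dict | None = None) -> EliminationTrace:
    """Single-model recursive feature elimination down to one feature.

    Each iteration fits the model on the surviving features, records its
    cross-validated accuracy, and removes the ``step`` least-important
    features.  With p features and step 1 the trace holds p − 1 records.
    """
    return _eliminate([model_id], table, step, cv, label_col, seed, model_params or {})


def _eliminate(model_ids, table, step, cv, label_col, seed,
               model_params: dict | None = None) -> EliminationTrace:
    model_params = model_params or {}
    if step < 1:
        raise ValueError("step must be >= 1")
    X, y = _xy(table, label_col)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 features")
    cv_obj = make_cv(cv, seed=seed)
    trace = EliminationTrace(model_ids=list(model_ids), step=step)
    current = list(X.columns)
    while len(current) > 1:
        sub = table[current + [label_col]]
        rankings = [model_importance(m, sub, label_col, seed=seed,
                                     params=model_params.get(m)) for m in model_ids]
        order = composite_rank(rankings) if len(rankings) > 1 else rankings[0].ordered_features
        accs = {m: _cv_accuracy(m, sub.drop(columns=[label_col]), y, cv_obj, seed,
                                params=model_params.get(m)) for m in model_ids}
        n_remove = min(step, len(current) - 1)
        removed = order[-n_remove:][::-1]        # worst first
        trace.records.append(
            EliminationRecord(
                features=list(current),
                accuracies=accs,
                removed=list(removed),
                composite_order=list(order) if len(rankings) > 1 else None,
            )
        )
        current = [f for f in order if f not in set(removed)]
    return trace


def mmrfe(model_ids: list[str], table: pd.DataFrame, step: int = 1, cv="kfold:5",
          rule: SelectionRule | None = None, label_col: str = "label",
          seed: int = 0,
          model_params: dict | None = None) -> tuple[EliminationTrace, SelectionResult]:
    """Multi-model RFE: composite elimination plus robust subset selection.

    Every iteration each model ranks all surviving features; the composite
    rank (summed positions) decides which ``step`` features are eliminated;
    every model's CV accuracy on the current subset is recorded.  Candidate
    subsets are the iterations where every model reached ``rule.min_accuracy``;
    the selected subset maximises the minimum per-model accuracy (ties →
    higher mean, then smaller subset).  With no qualifying iteration an
    empty selection is returned alongside the best available subset.
    """
    if len(model_ids) < 2:
        raise ValueError("mmRFE needs >= 2 models")
    for m in model_ids:
        if m not in MODEL_IDS:
            raise ValueError(f"unknown model {m!r}")
    rule = rule or SelectionRule()
    trace = _eliminate(model_ids, table, step, cv, label_col, seed, model_params)

    def key(rec: EliminationRecord):
        accs = list(rec.accuracies.values())
        return (min(accs), np.mean(accs), -len(rec.features))

    best = max(trace.records, key=key)
    qualifiers = [r for r in trace.records
                  if min(r.accuracies.values()) >= rule.min_accuracy]
    if qualifiers:
        chosen = max(qualifiers, key=key)
        result = SelectionResult(
            selected=list(chosen.features),
            selected_accuracies=dict(chosen.accuracies),
            best_available=list(best.features),
            best_available_accuracies=dict(best.accuracies),
        )
    else:
        result = SelectionResult(
            selected=[],
            selected_accuracies={},
            best_available=list(best.features),
            best_available_accuracies=dict(best.accuracies),
        )
    return trace, result
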
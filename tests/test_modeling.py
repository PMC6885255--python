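"""Classifier evaluation, per-class metrics, ensemble voting."""

import itertools

import numpy as np
import pandas as pd
import pytest

from subtyperad.modeling import (
    ENSEMBLE_TIE_PRIORITY,
    ModelConfig,
    class_report,
    crossval_evaluate,
    ensemble_predict,
)
from subtyperad.phantom import planted_feature_table


def _table(n=200, p=12, informative=6, sep=3.0, seed=0, proportions=None):
    X, y, _ = planted_feature_table(n, p, informative, class_proportions=proportions,
                                    class_sep=sep, seed=seed)
    t = X.copy()
    t["label"] = y.to_numpy()
    return t


class TestClassReport:
    def test_perfect_prediction(self):
        y = ["A", "B", "C", "D"] * 5
        rep = class_report(y, y)
        assert rep.accuracy == 1.0
        assert (rep.per_class[["precision", "recall", "f1"]] == 1.0).all().all()
        assert np.trace(rep.confusion) == 20

    def test_majority_collapse_two_class(self):
        y_true = ["A"] * 60 + ["B"] * 40
        y_pred = ["A"] * 100
        with pytest.warns(UserWarning):
            rep = class_report(y_true, y_pred)
        assert rep.per_class.loc["A", "precision"] == pytest.approx(0.6)
        assert rep.per_class.loc["A", "recall"] == 1.0
        assert rep.per_class.loc["B", "recall"] == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_confusion_arithmetic(self, seed):
        rng = np.random.default_rng(seed)
        classes = ["A", "B", "C", "D"]
        y_true = rng.choice(classes, 120)
        y_pred = rng.choice(classes, 120)
        rep = class_report(y_true, y_pred, classes=classes)
        conf = np.zeros((4, 4), int)
        for t, p in zip(y_true, y_pred):
            conf[classes.index(t), classes.index(p)] += 1
        assert np.array_equal(rep.confusion, conf)
        assert rep.accuracy == pytest.approx(np.trace(conf) / 120)
        for i, c in enumerate(classes):
            tp = conf[i, i]
            fp = conf[:, i].sum() - tp
            fn = conf[i, :].sum() - tp
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            assert rep.per_class.loc[c, "precision"] == pytest.approx(prec)
            assert rep.per_class.loc[c, "recall"] == pytest.approx(rec)

    def test_invariants(self):
        rng = np.random.default_rng(9)
        y_true = rng.choice(list("ABCD"), 80)
        y_pred = rng.choice(list("ABCD"), 80)
        rep = class_report(y_true, y_pred)
        assert rep.confusion.sum(axis=1).tolist() == rep.per_class["support"].tolist()
        assert rep.macro["f1"] <= rep.per_class["f1"].max() + 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            class_report([], [])


class TestCrossval:
    def test_separable_classes_high_accuracy(self):
        t = _table(n=240, sep=3.0)
        rep = crossval_evaluate(ModelConfig("lr", seed=0), t, cv="kfold:5")
        assert rep.accuracy >= 0.95

    def test_loo_pools_n_predictions(self):
        t = _table(n=40, p=8, informative=4)
        rep = crossval_evaluate(ModelConfig("lr", seed=0), t, cv="loo")
        assert rep.confusion.sum() == 40

    def test_deterministic_under_seed(self):
        t = _table(n=120)
        a = crossval_evaluate(ModelConfig("rf", seed=5, params={"n_estimators": 30}), t)
        b = crossval_evaluate(ModelConfig("rf", seed=5, params={"n_estimators": 30}), t)
        assert np.array_equal(a.confusion, b.confusion)

    def test_too_few_per_class_for_folds_raises(self):
        t = _table(n=16, proportions=(0.25, 0.25, 0.25, 0.25))
        with pytest.raises(ValueError, match="fewer samples than folds|stratif"):
            crossval_evaluate(ModelConfig("lr"), t, cv="kfold:5")


class _Stub:
    """Minimal fitted-classifier stand-in for vote-rule enumeration."""

    def __init__(self, labels, proba=None, classes=("A", "B", "C", "D")):
        self.labels = np.asarray(labels)
        self.classes_ = np.asarray(classes)
        self._proba = proba

    def predict(self, X):
        return self.labels[: len(X)]

    def predict_proba(self, X):
        if self._proba is None:
            raise AttributeError("no probabilities")
        return np.tile(self._proba, (len(X), 1))


class TestEnsemble:
    def test_unanimous_vote(self):
        fitted = {m: _Stub(["B"]) for m in ("lr", "svm", "rf", "gbdt")}
        assert ensemble_predict(fitted, np.zeros((1, 3)))[0] == "B"

    def test_probability_breaks_two_two_tie(self):
        proba_c = np.array([0.1, 0.1, 0.7, 0.1])
        fitted = {
            "lr": _Stub(["A"], proba=proba_c),
            "svm": _Stub(["A"]),
            "rf": _Stub(["C"], proba=proba_c),
            "gbdt": _Stub(["C"], proba=proba_c),
        }
        assert ensemble_predict(fitted, np.zeros((1, 3)))[0] == "C"

    def test_residual_tie_uses_model_priority(self):
        flat = np.full(4, 0.25)
        fitted = {
            "lr": _Stub(["A"], proba=flat),
            "svm": _Stub(["B"], proba=flat),
            "rf": _Stub(["A"], proba=flat),
            "gbdt": _Stub(["B"], proba=flat),
        }
        # 2-2 tie, equal probabilities -> priority order starts with gbdt
        assert ENSEMBLE_TIE_PRIORITY[0] == "gbdt"
        assert ensemble_predict(fitted, np.zeros((1, 3)))[0] == "B"

    def test_unique_mode_always_wins(self):
        classes = ["A", "B", "C", "D"]
        flat = np.full(4, 0.25)
        for votes in itertools.product(classes, repeat=4):
            counts = {c: votes.count(c) for c in classes}
            top = max(counts.values())
            modes = [c for c, n in counts.items() if n == top]
            fitted = {
                m: _Stub([v], proba=flat)
                for m, v in zip(("lr", "svm", "rf", "gbdt"), votes)
            }
            got = ensemble_predict(fitted, np.zeros((1, 2)))[0]
            if len(modes) == 1:
                assert got == modes[0]
            else:
                assert got in modes

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            ensemble_predict({"lr": _Stub(["A"])}, np.zeros((1, 2)))

    def test_crossval_ensemble_beats_chance_on_separable_data(self):
        t = _table(n=160, sep=3.0)
        rep = crossval_evaluate(
            ModelConfig(
                "ensemble",
                seed=0,
                params={"rf": {"n_estimators": 30}, "gbdt": {"n_estimators": 20}},
            ),
            t,
            cv="kfold:3",
        )
        assert rep.accuracy >= 0.9
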
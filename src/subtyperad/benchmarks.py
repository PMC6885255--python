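"""Experiment harness: self-contained synthetic benchmarks.

These routines bundle the study designs that exercise the whole pipeline on
phantom data — the segmentation comparison of dynamic-Otsu versus fixed
thresholds, the planted-feature mmRFE recovery study with the clinical
cohort imbalance, the permutation null for the classifiers, and the
end-to-end determinism run.  Every routine is deterministic given its seed
and returns plain dictionaries of measured quantities.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .modeling import ModelConfig, crossval_evaluate
from .phantom import PhantomSpec, generate_case, planted_feature_table
from .segmentation import GrowOptions, dice, region_grow, region_grow_fixed
from .selection import SelectionRule, mmrfe, rfe

__all__ = [
    "segmentation_benchmark",
    "mmrfe_recovery_benchmark",
    "null_model_benchmark",
    "determinism_benchmark",
]

#: Sized-down tree ensembles for elimination studies (the elimination loop
#: refits every model at every subset size; accuracies saturate well below
#: the default ensemble sizes on the planted benchmark).
FAST_MODEL_PARAMS = {
    "rf": {"n_estimators": 100},
    "gbdt": {"n_estimators": 50},
}


def segmentation_benchmark(
    n_cases: int = 50,
    seed: int = 0,
    contrast_range: tuple[float, float] = (60.0, 180.0),
    noise_sd: float = 4.0,
    fixed_thresholds: tuple = (20, 30, 40, 50),
) -> dict:
    """Mean Dice of dynamic-Otsu growing versus fixed thresholds.

    Each case draws its lesion/background contrast uniformly from
    ``contrast_range``, so no single fixed threshold suits every case while
    the dynamic threshold adapts per case.  Returns mean Dice for the
    dynamic mode and for each fixed T, over ``n_cases`` phantoms.
    """
    rng = np.random.default_rng(seed)
    labels = ["A", "B", "C", "D"]
    dyn_scores = []
    fixed_scores = {t: [] for t in fixed_thresholds}
    for i in range(n_cases):
        contrast = rng.uniform(*contrast_range)
        spec = PhantomSpec(
            n_cases=4,
            background_level=30.0,
            lesion_baseline=30.0 + contrast,
            noise_sd=noise_sd,
            rng_seed=seed,
        )
        label = labels[i % 4]
        case = generate_case(spec, label, rng, case_id=f"bench_{i:03d}")
        image = case.phases[0]      # pre-contrast phase: contrast is the drawn value
        dyn = region_grow(image, case.roi, GrowOptions())
        dyn_scores.append(dice(dyn, case.truth_mask))
        for t in fixed_thresholds:
            try:
                m = region_grow_fixed(image, case.roi, t)
                fixed_scores[t].append(dice(m, case.truth_mask))
            except ValueError:
                fixed_scores[t].append(0.0)
    return {
        "n_cases": n_cases,
        "mean_dice_dynamic": float(np.mean(dyn_scores)),
        "mean_dice_fixed": {str(t): float(np.mean(v)) for t, v in fixed_scores.items()},
        "best_fixed": float(max(np.mean(v) for v in fixed_scores.values())),
    }


def mmrfe_recovery_benchmark(
    seed: int = 0,
    n_samples: int = 640,
    n_features: int = 60,
    n_informative: int = 10,
    step: int = 5,
    cv: str = "kfold:3",
    theta: float = 0.8,
    model_ids: tuple = ("lr", "svm", "rf", "gbdt"),
    model_params: dict | None = None,
) -> dict:
    """Planted-feature recovery and cross-model stability of mmRFE.

    Generates the planted table at the clinical class imbalance, runs mmRFE
    and each model's own single-model RFE, and reports how many planted
    features the mmRFE subset recovers plus each model's accuracy on the
    mmRFE subset versus its own RFE optimum.
    """
    if model_params is None:
        model_params = FAST_MODEL_PARAMS
    X, y, informative = planted_feature_table(
        n_samples, n_features, n_informative, seed=seed
    )
    table = X.copy()
    table["label"] = y.to_numpy()

    trace, result = mmrfe(
        list(model_ids), table, step=step, cv=cv,
        rule=SelectionRule(theta), seed=seed, model_params=model_params,
    )
    subset = result.selected or result.best_available
    subset_accs = result.selected_accuracies or result.best_available_accuracies
    recovered = sorted(set(subset) & set(informative))

    own_optimum = {}
    for m in model_ids:
        tr = rfe(m, table, step=step, cv=cv, seed=seed,
                 model_params={m: model_params.get(m, {})})
        own_optimum[m] = max(r.accuracies[m] for r in tr.records)
    return {
        "n_samples": n_samples,
        "subset_size": len(subset),
        "informative": informative,
        "recovered": recovered,
        "n_recovered": len(recovered),
        "mmrfe_accuracies": {m: float(a) for m, a in subset_accs.items()},
        "rfe_optimum_accuracies": {m: float(a) for m, a in own_optimum.items()},
        "max_accuracy_gap": float(
            max(own_optimum[m] - subset_accs[m] for m in model_ids)
        ),
    }


def null_model_benchmark(
    seed: int = 0,
    n_samples: int = 400,
    n_features: int = 20,
    model_id: str = "lr",
    cv: str = "kfold:5",
) -> dict:
    """Permutation null: shuffled labels on balanced 4-class data.

    Pooled CV accuracy should fall inside the central 99% binomial band
    around chance (0.25 for four balanced classes).
    """
    X, y, _ = planted_feature_table(
        n_samples, n_features, n_informative=5,
        class_proportions=(0.25, 0.25, 0.25, 0.25), seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    table = X.copy()
    table["label"] = rng.permutation(y.to_numpy())
    report = crossval_evaluate(ModelConfig(model_id, seed=seed), table, cv=cv)
    from scipy import stats

    lo, hi = stats.binom.interval(0.99, n_samples, 0.25)
    return {
        "n_samples": n_samples,
        "accuracy": report.accuracy,
        "band_low": float(lo / n_samples),
        "band_high": float(hi / n_samples),
        "inside_band": bool(lo / n_samples <= report.accuracy <= hi / n_samples),
    }


def determinism_benchmark(out_root, seed: int = 0, n_cases: int = 16) -> dict:
    """Two full pipeline runs from one seed; compares artifact bytes."""
    from .pipeline import RunConfig, run_pipeline

    out_root = Path(out_root)
    spec = PhantomSpec(n_cases=n_cases, rng_seed=seed)
    config = RunConfig(
        phantom=spec,
        selection_mode="rfe:lr",
        selection_step=40,
        cv="kfold:2",
        classifier="lr",
        seed=seed,
    )
    digests = []
    for name in ("run_a", "run_b"):
        run_dir = run_pipeline(dataclasses.replace(config), out_root / name)
        digests.append(
            {
                "features": (run_dir / "features.csv").read_bytes(),
                "report": (run_dir / "report.json").read_bytes(),
            }
        )
    return {
        "n_cases": n_cases,
        "features_identical": digests[0]["features"] == digests[1]["features"],
        "report_identical": digests[0]["report"] == digests[1]["report"],
    }
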
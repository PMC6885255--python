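# subtyperad

Radiomics pipeline for recognising breast-cancer molecular subtypes
(luminal A, luminal B, HER-2 over-expressing, basal-like) from dynamic
contrast-enhanced MRI (DCE-MRI). It is aimed at medical-image-analysis
researchers who want a fully reproducible, desk-scale testbed for the
whole chain:

1. **Phantom cohorts** — synthetic multi-phase cases with known
   ground-truth lesion masks, loose rectangular ROI annotations,
   class-dependent shape/texture/kinetic structure, and the imbalanced
   four-subtype composition (183/241/143/70 over 637 cases) of a clinical
   cohort.
2. **Segmentation** — seeded region growing from the ROI centroid. The
   growth threshold is found per case by Otsu's method on the ROI patch
   (no per-case tuning); the classical fixed-threshold criterion
   |I(p) − I(seed)| < T is included as the baseline. Masks are scored by
   the Dice coefficient S = 2|X∩Y|/(|X|+|Y|).
3. **Features** — a fixed 146-value schema per lesion over three phases:
   GLCM statistics (energy, contrast, correlation, entropy, inverse
   difference moment) averaged over four directions; 31 retained LBP
   histogram bins per phase; pixel-wise and whole-lesion enhancement
   kinetics ER = S_i/S_0, AR = (S_i − S_0)/S_0·100%; first-order
   statistics; and NRL-based morphology (tightness P²/4πA, roundness
   4πA/P², roughness, smoothness, area).
4. **Selection** — single-model recursive feature elimination (RFE) and
   multi-model RFE (**mmRFE**): every model ranks the surviving features
   each iteration, rank positions are summed into a composite score,
   elimination follows the composite, and the subset finally selected is
   the one on which *all* models clear an accuracy threshold
   (max-min rule).
5. **Classification** — logistic regression, linear SVM, random forest
   and gradient boosting, plus a majority-vote ensemble; evaluation pools
   out-of-fold predictions into one confusion matrix and reports
   per-class precision/recall/F1 alongside accuracy, since the cohort is
   imbalanced.

See `docs/methods.md` for the model details and design decisions.

## Worked example

```python
import numpy as np, pandas as pd
from subtyperad import PhantomSpec, generate_cohort, region_grow, dice, extract_all
from subtyperad.features import drop_invalid_columns
from subtyperad.modeling import ModelConfig, crossval_evaluate

spec = PhantomSpec(n_cases=60, rng_seed=11)
cases, manifest = generate_cohort(spec)
print("class counts:", manifest["class_counts"])

rows, scores = [], []
for case in cases:
    mask = region_grow(case.phases[1], case.roi)   # segment phase T1
    scores.append(dice(mask, case.truth_mask))
    rows.append({"label": case.label, **extract_all(case.phases, mask).to_dict()})
print(f"mean dice: {np.mean(scores):.3f}")

table = drop_invalid_columns(pd.DataFrame(rows))
report = crossval_evaluate(ModelConfig("gbdt", seed=11,
                                       params={"n_estimators": 50}),
                           table, cv="kfold:5")
print(report.to_markdown())
```

prints

```
class counts: {'A': 17, 'B': 23, 'C': 13, 'D': 7}
mean dice: 0.999
| Subtype | Precision | Recall | F1-score |
|---|---|---|---|
| A | 1.00 | 1.00 | 1.00 |
| B | 1.00 | 1.00 | 1.00 |
| C | 1.00 | 1.00 | 1.00 |
| D | 1.00 | 1.00 | 1.00 |
| macro | 1.00 | 1.00 | 1.00 |

Accuracy: 1.00
```

The class counts are the largest-remainder allocation of the clinical
proportions at n = 60. Mean Dice 0.999 says the dynamic-threshold growing
recovers the ground-truth masks almost exactly on these phantoms, and the
perfect cross-validated classification reflects that the default class
profiles are widely separated *by construction* — the phantoms measure
whether the pipeline recovers structure that is present, not how separable
real subtypes are. Narrow the kinetic/shape/texture profiles in
`PhantomSpec` to make the task arbitrarily hard.

The same pipeline is available from the shell:

```sh
subtyperad simulate --out run/ --seed 11 --n-cases 60
subtyperad segment  --images run/images --annotations run/manifest.json \
                    --reference-masks run/truth_masks --out run/masks
subtyperad extract  --images run/images --masks run/masks \
                    --annotations run/manifest.json --out run/features.csv
subtyperad select   --features run/features.csv --mode mmrfe --out run/trace.json
subtyperad classify --features run/features.csv --subset run/trace.subset.txt \
                    --model gbdt --out run/report.json
# or everything at once, with stage resume:
subtyperad run --out run/ --seed 11
```

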
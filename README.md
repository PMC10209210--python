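# neocbr

Case-based reasoning (CBR) for two linked questions that neonatologists face
at NICU admission: **will this neonate survive**, and **how long will they
stay**?  Instead of fitting a parametric model, a CBR system answers a new
problem by retrieving the most similar previously solved cases from a case
base and reusing their outcomes — and it keeps learning, because every solved
case whose real outcome is later confirmed is retained into the case base.

`neocbr` is a library plus a `neocbr` command-line tool implementing the
whole cycle for clinical tabular data:

- **Expert weights** — aggregate neonatologists' 5-point importance ratings:
  keep risk factors that at least 60% of the panel rates important (4) or
  very important (5), weight each by its mean rating, and normalize the
  weights to sum to one.  Two expert-elicited schemas ship with the package:
  17 mortality risk factors and 13 length-of-stay (LOS) risk factors (birth
  weight and gestational age continuous, the rest boolean).
- **Preprocessing** — class-conditional imputation (mean if the within-class
  sample passes Shapiro–Wilk normality, otherwise median; class-majority for
  booleans), min–max normalization to [0, 1], and SMOTE balancing of the
  rare death class (~9% of admissions).
- **Retrieval / reuse** — exact k-nearest-neighbor scan under the weighted
  Euclidean distance

  ```
  d(x, y) = sqrt( Σ wᵢ² (xᵢ − yᵢ)² / Σ wᵢ² )
  ```

  with similarity shown as 100·(1 − d)%.  Survival is predicted by majority
  vote of the k neighbors (k = 1: the nearest case's outcome); LOS by the
  similarity-weighted mean of neighbor stays.
- **Revise / retain** — solved cases wait in a temporary store with the
  system's prediction (and the expert's solution when the prediction was
  rejected); once the actual discharge outcome is recorded the case is
  promoted to the permanent case base, which then requires refitting before
  the next retrieval.
- **Evaluation** — 80/20 split, confusion matrix with *alive* as the
  positive class, and the full metric suite: accuracy, precision,
  sensitivity, specificity, F-score, Matthews correlation coefficient (MCC)
  and Cohen's kappa for survival; RMSE in days for LOS.
- **Synthetic cohorts** — the registry the system was developed on is
  confidential, so a generator produces cohorts with the same coarse
  structure (~9% mortality, right-skewed LOS averaging ~15 days in 0–191,
  ~1% missingness) with a tunable class separation (`effect_size`), letting
  every stage run end to end.

## Worked example

Simulate a registry-sized cohort, split it 80/20, SMOTE-balance the
development case base and score nearest-neighbor survival prediction on the
held-out 20%:

```bash
neocbr simulate --task survival --n 1682 --seed 7 --out cohort.csv
neocbr evaluate --task survival --casebase cohort.csv --k 1 --balanced --seed 7
```

```json
{
  "task": "survival",
  "k": 1,
  "balanced": true,
  "seed": 7,
  "n_dev": 1346,
  "n_test": 336,
  "metrics": {
    "accuracy": 94.64,
    "precision": 94.6,
    "sensitivity": 99.67,
    "specificity": 54.05,
    "f_score": 0.971,
    "mcc": 0.695,
    "kappa": 0.663,
    "rmse": null
  },
  "confusion": { "tp": 298, "fn": 1, "fp": 17, "tn": 20 }
}
```

Reading the numbers: of 336 held-out neonates, 298 survivors and 20 deaths
were predicted correctly.  Sensitivity (survivor recall) is near-perfect at
99.67% while specificity (death recall) is 54.05% — the characteristic
pattern of nearest-neighbor prediction with a rare death class, and the
reason the development case base is SMOTE-balanced.  MCC and kappa summarize
agreement beyond chance on the imbalanced test set.

The same cohort generator drives the LOS task:

```bash
neocbr simulate --task los --n 1682 --seed 7 --out los.csv
neocbr evaluate --task los --casebase los.csv --k 3 --seed 7
```

reports `"rmse": 16.88` days over the same 1346/336 split.

The Python API mirrors the CLI:

```python
from neocbr import default_schema, read_casebase, split, evaluate

schema = default_schema("survival")
cb = read_casebase("cohort.csv", schema)
dev, test = split(cb, 0.8, seed=7)
report = evaluate(dev, test, k=1, balanced=True, seed=7)
print(report.rounded())
```

## Layout

| module | responsibility |
|---|---|
| `neocbr.case_model` | schemas, cases, case bases; CSV/JSON I/O; shipped default schemas |
| `neocbr.weights` | rating aggregation: agreement threshold, mean weights, normalization |
| `neocbr.preprocess` | imputation, min–max fitting/normalization, SMOTE |
| `neocbr.retrieval` | weighted Euclidean distance, KNN retrieval, survival/LOS reuse |
| `neocbr.lifecycle` | temporary store, outcome recording, promotion to the case base |
| `neocbr.evaluation` | splits, confusion matrix, metric suite, RMSE, end-to-end harness |
| `neocbr.synthetic` | cohort and rating-matrix generators |
| `neocbr.cli` | `neocbr` command with `simulate / weights / preprocess / predict / evaluate / retain` |

See `docs/methods.md` for the model, its assumptions, the tunable
parameters and the known limitations.
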
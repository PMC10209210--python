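"""Train/test splitting and performance metrics.

Survival predictions are scored against a confusion matrix with **alive as
the positive class** (the registry cohorts are ~91% alive, so sensitivity is
dominated by alive cases and specificity by the rare deaths), from which the
usual suite is derived: accuracy, precision, sensitivity, specificity
(reported as percentages), F-score, Matthews correlation coefficient and
Cohen's kappa.  LOS predictions are scored by RMSE in days.

A metric whose denominator is zero is reported as ``None`` (undefined),
never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .case_model import ALIVE, CaseBase, ValidationError
from .preprocess import impute_case, normalize_matrix, preprocess_casebase
from .retrieval import Prediction, RetrievalResult, pairwise_distances, predict_los, predict_survival

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "split",
    "confusion",
    "classification_metrics",
    "rmse",
    "evaluate",
]


@dataclass
class ConfusionMatrix:
    """Binary confusion counts; alive = positive."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValidationError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class MetricsReport:
    """Classification metrics (percentages for the first four) or LOS RMSE."""

    accuracy: Optional[float] = None
    precision: Optional[float] = None
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    f_score: Optional[float] = None
    mcc: Optional[float] = None
    kappa: Optional[float] = None
    rmse: Optional[float] = None
    confusion: Optional[ConfusionMatrix] = None

    def rounded(self) -> dict:
        """Table-style rounding: percentages to 2 decimals, unitless
        coefficients to 3, RMSE to 2."""
        out = {}
        for name, nd in [
            ("accuracy", 2), ("precision", 2), ("sensitivity", 2), ("specificity", 2),
            ("f_score", 3), ("mcc", 3), ("kappa", 3), ("rmse", 2),
        ]:
            v = getattr(self, name)
            out[name] = None if v is None else round(v, nd)
        return out


def split(cb: CaseBase, fraction: float = 0.8, seed: Optional[int] = None) -> tuple[CaseBase, CaseBase]:
    """Random disjoint-and-exhaustive partition into development and test
    case bases; the development size is round-half-up of ``fraction * n``."""
    if not (0.0 < fraction < 1.0):
        raise ValidationError("fraction must be in (0,1)")
    n = len(cb.cases)
    if n < 2:
        raise ValidationError("need at least 2 cases to split")
    n_dev = int(math.floor(fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    dev_idx = set(perm[:n_dev].tolist())
    dev = CaseBase(schema=cb.schema, cases=[c for i, c in enumerate(cb.cases) if i in dev_idx])
    test = CaseBase(schema=cb.schema, cases=[c for i, c in enumerate(cb.cases) if i not in dev_idx])
    return dev, test


def confusion(preds: Sequence[str], actuals: Sequence[str]) -> ConfusionMatrix:
    """Tally a confusion matrix from alive/dead labels (alive = positive)."""
    if len(preds) != len(actuals):
        raise ValidationError("prediction and actual lists differ in length")
    tp = fn = fp = tn = 0
    for p, a in zip(preds, actuals):
        if a == ALIVE:
            tp, fn = (tp + 1, fn) if p == ALIVE else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if p == ALIVE else (fp, tn + 1)
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def _safe_div(num: float, den: float) -> Optional[float]:
    return None if den == 0 else num / den


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Derive the seven-metric suite from a confusion matrix.

    accuracy = (tp+tn)/total, precision = tp/(tp+fp),
    sensitivity = tp/(tp+fn), specificity = tn/(tn+fp),
    F = 2PR/(P+R), MCC = (tp*tn - fp*fn)/sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)),
    kappa = (p_o - p_e)/(1 - p_e) with the usual marginal chance agreement.
    """
    tp, fn, fp, tn = cm.tp, cm.fn, cm.fp, cm.tn
    total = cm.total
    acc = (tp + tn) / total
    prec = _safe_div(tp, tp + fp)
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    if prec is None or sens is None or (prec + sens) == 0:
        f = None
    else:
        f = 2 * prec * sens / (prec + sens)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = None if mcc_den == 0 else (tp * tn - fp * fn) / mcc_den
    p_o = acc
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (total * total)
    kappa = None if p_e == 1 else (p_o - p_e) / (1 - p_e)
    return MetricsReport(
        accuracy=100 * acc,
        precision=None if prec is None else 100 * prec,
        sensitivity=None if sens is None else 100 * sens,
        specificity=None if spec is None else 100 * spec,
        f_score=f,
        mcc=mcc,
        kappa=kappa,
        confusion=cm,
    )


def rmse(preds: Sequence[float], actuals: Sequence[float]) -> float:
    """Root mean square error in days."""
    if len(preds) != len(actuals) or len(preds) == 0:
        raise ValidationError("prediction and actual lists must be equal-length and non-empty")
    p = np.asarray(preds, float)
    a = np.asarray(actuals, float)
    return float(np.sqrt(np.mean((p - a) ** 2)))


def _batch_predict(cb_dev: CaseBase, cb_test: CaseBase, k: int) -> list[Prediction]:
    """Retrieve + reuse for every test case against the development base.

    Equivalent to calling :func:`neocbr.retrieval.retrieve` per case, but
    normalizes both bases once and ranks from a single distance matrix.
    """
    perm = cb_dev.permanent_cases
    if not (1 <= k <= len(perm)):
        raise ValidationError(f"k={k} out of range for a {len(perm)}-case base")
    stats, schema = cb_dev.stats, cb_dev.schema
    dev_m = normalize_matrix([impute_case(c, stats) for c in perm], stats, schema)
    test_m = normalize_matrix([impute_case(c, stats) for c in cb_test.cases], stats, schema)
    w = np.array(schema.weights)
    d = pairwise_distances(test_m, dev_m, w)
    ids = [c.id for c in perm]
    predict = predict_survival if schema.task == "survival" else predict_los
    preds = []
    for row in d:
        order = sorted(range(len(ids)), key=lambda i: (row[i], ids[i]))[:k]
        rr = RetrievalResult(
            neighbors=[(ids[i], float(row[i]), 100.0 * (1.0 - float(row[i]))) for i in order],
            k=k,
        )
        preds.append(predict(rr, cb_dev))
    return preds


def evaluate(
    cb_dev: CaseBase,
    cb_test: CaseBase,
    task: Optional[str] = None,
    k: int = 1,
    balanced: bool = False,
    seed: Optional[int] = None,
) -> MetricsReport:
    """Score the reasoner on a held-out test set.

    The development base is imputed, min-max fitted and (optionally)
    SMOTE-balanced; the test set is never resampled and never used for
    fitting — test cases are imputed from the development base's pooled
    statistics and normalized with its bounds.
    """
    if cb_dev.schema is not cb_test.schema and (
        cb_dev.schema.task != cb_test.schema.task
        or cb_dev.schema.feature_names != cb_test.schema.feature_names
    ):
        raise ValidationError("development and test case bases must share a schema")
    task = task or cb_dev.schema.task
    if task != cb_dev.schema.task:
        raise ValidationError(f"task {task!r} does not match schema task {cb_dev.schema.task!r}")
    dev = cb_dev if cb_dev.fitted and not balanced else preprocess_casebase(
        cb_dev, balanced=balanced, seed=seed
    )
    preds = _batch_predict(dev, cb_test, k)
    actuals = [c.outcome for c in cb_test.cases]
    if any(a is None for a in actuals):
        raise ValidationError("every test case needs a recorded outcome")
    if task == "survival":
        cm = confusion([p.value for p in preds], actuals)
        return classification_metrics(cm)
    return MetricsReport(rmse=rmse([p.value for p in preds], actuals))
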
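"""Weighted Euclidean retrieval and the reuse step.

The similarity between a new case ``x`` and a stored case ``y`` is derived
from the weighted Euclidean distance

    d(x, y) = sqrt( sum_i w_i^2 (x_i - y_i)^2 / sum_i w_i^2 )

computed on min-max normalized feature vectors, so d is bounded in [0,1] and
the similarity shown to the user is ``100 * (1 - d)`` percent.  Retrieval is
an exact k-nearest-neighbor scan over the permanent case base (case bases at
clinical-registry scale do not need approximate indexing); distance ties
break on ascending case id for determinism.

Reuse: the survival prediction is the majority vote of the k neighbors
(nearest neighbor breaks vote ties; k = 1 reduces to the nearest case's
outcome), and the LOS prediction is the similarity-weighted mean of neighbor
stays, rounded to whole days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .case_model import ALIVE, DEAD, Case, CaseBase, ValidationError
from .preprocess import impute_case, normalize, normalize_matrix

__all__ = [
    "RetrievalResult",
    "Prediction",
    "weighted_distance",
    "pairwise_distances",
    "retrieve",
    "predict_survival",
    "predict_los",
]


@dataclass
class RetrievalResult:
    """Ranked neighbors: (case id, distance in [0,1], similarity percent)."""

    neighbors: list[tuple[str, float, float]]
    k: int

    @property
    def ids(self) -> list[str]:
        return [n[0] for n in self.neighbors]


@dataclass
class Prediction:
    task: str
    value: Union[str, int]
    neighbor_ids: list[str] = field(default_factory=list)
    approval: str = "unapproved"  # approved | unapproved

    def __post_init__(self) -> None:
        if self.task == "los" and int(self.value) < 0:
            raise ValidationError("LOS prediction must be >= 0")


def weighted_distance(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted Euclidean distance between normalized vectors.

    Scale-invariant in ``w`` (only weight ratios matter) and bounded by 1
    when all coordinates lie in [0,1].
    """
    x, y, w = np.asarray(x, float), np.asarray(y, float), np.asarray(w, float)
    if not (x.shape == y.shape == w.shape):
        raise ValidationError("x, y and w must have equal lengths")
    ws = np.sum(w**2)
    if ws == 0:
        raise ValidationError("weight vector must not be all zero")
    return float(np.sqrt(np.sum(w**2 * (x - y) ** 2) / ws))


def pairwise_distances(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Distance matrix between row vectors of ``a`` (n x d) and ``b`` (m x d)."""
    w = np.asarray(w, float)
    ws = np.sum(w**2)
    if ws == 0:
        raise ValidationError("weight vector must not be all zero")
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt(np.einsum("ijk,k->ij", diff**2, w**2) / ws)


def _rank(distances: np.ndarray, ids: list[str], k: int) -> list[tuple[str, float, float]]:
    order = sorted(range(len(ids)), key=lambda i: (distances[i], ids[i]))[:k]
    return [(ids[i], float(distances[i]), 100.0 * (1.0 - float(distances[i]))) for i in order]


def retrieve(new_case: Case, cb: CaseBase, k: int) -> RetrievalResult:
    """Exact KNN scan of the permanent case base for the k most similar
    cases; the new case is imputed from pooled statistics and normalized
    with the case base's fitted bounds."""
    perm = cb.permanent_cases
    if not perm:
        raise ValidationError("case base is empty")
    if not cb.fitted:
        raise ValidationError("case base is not preprocessed (or its statistics are stale)")
    if not (1 <= k <= len(perm)):
        raise ValidationError(f"k={k} out of range for a {len(perm)}-case base")
    x = normalize(impute_case(new_case, cb.stats), cb.stats, cb.schema)
    m = normalize_matrix([impute_case(c, cb.stats) for c in perm], cb.stats, cb.schema)
    w = np.array(cb.schema.weights)
    d = pairwise_distances(x[None, :], m, w)[0]
    return RetrievalResult(neighbors=_rank(d, [c.id for c in perm], k), k=k)


def predict_survival(rr: RetrievalResult, cb: CaseBase) -> Prediction:
    """Majority vote over the retrieved neighbors' alive/dead outcomes,
    with vote ties resolved by the nearest neighbor."""
    if cb.schema.task != "survival":
        raise ValidationError("predict_survival requires a survival-task case base")
    outcomes = []
    for cid, _, _ in rr.neighbors:
        o = cb.case(cid).outcome
        if o is None:
            raise ValidationError(f"neighbor {cid!r} has no recorded outcome")
        outcomes.append(o)
    n_alive = outcomes.count(ALIVE)
    n_dead = outcomes.count(DEAD)
    if n_alive > n_dead:
        value = ALIVE
    elif n_dead > n_alive:
        value = DEAD
    else:
        value = outcomes[0]  # tie -> nearest neighbor decides
    return Prediction(task="survival", value=value, neighbor_ids=rr.ids)


def predict_los(rr: RetrievalResult, cb: CaseBase) -> Prediction:
    """Similarity-weighted mean of the neighbors' stays, rounded half-up to
    whole days; if every similarity is zero, falls back to the plain mean."""
    if cb.schema.task != "los":
        raise ValidationError("predict_los requires a LOS-task case base")
    stays, sims = [], []
    for cid, _, sim in rr.neighbors:
        o = cb.case(cid).outcome
        if o is None:
            raise ValidationError(f"neighbor {cid!r} has no recorded outcome")
        stays.append(float(o))
        sims.append(sim)
    total = sum(sims)
    if total > 0:
        est = sum(s * los for s, los in zip(sims, stays)) / total
    else:
        est = sum(stays) / len(stays)
    return Prediction(task="los", value=int(math.floor(est + 0.5)), neighbor_ids=rr.ids)
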
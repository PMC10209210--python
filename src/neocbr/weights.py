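"""Expert-rating aggregation into similarity weights.

A panel of neonatologists rates candidate risk factors on a 5-point
importance scale.  A factor is retained when at least 60% of raters call it
important (a rating of 4) or very important (5).  The per-factor mean rating
is then taken as the raw weight and linearly normalized so the retained
weights sum to one — the scale on which the shipped default schemas are
expressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "RatingMatrix",
    "agreement_fraction",
    "select_features",
    "compute_weights",
]

AGREEMENT_CUTOFF = 4  # ratings of 4 or 5 count as agreement on importance


@dataclass
class RatingMatrix:
    """Complete raters x factors matrix of integer ratings in 1..5."""

    raters: list[str]
    factors: list[str]
    ratings: np.ndarray  # shape (n_raters, n_factors), dtype int

    def __post_init__(self) -> None:
        self.ratings = np.asarray(self.ratings)
        if self.ratings.shape != (len(self.raters), len(self.factors)):
            raise ValueError("ratings shape does not match raters x factors")
        if self.ratings.size and not (
            np.issubdtype(self.ratings.dtype, np.integer)
            and self.ratings.min() >= 1
            and self.ratings.max() <= 5
        ):
            raise ValueError("ratings must be integers in 1..5 with no missing entries")

    def column(self, factor: str) -> np.ndarray:
        try:
            j = self.factors.index(factor)
        except ValueError:
            raise KeyError(f"unknown factor {factor!r}") from None
        return self.ratings[:, j]

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "RatingMatrix":
        """Read a ratings CSV: rows = raters (first column = rater id),
        columns = factors."""
        df = pd.read_csv(path, index_col=0)
        return cls(
            raters=[str(r) for r in df.index],
            factors=[str(c) for c in df.columns],
            ratings=df.to_numpy(dtype=int),
        )


def agreement_fraction(rm: RatingMatrix, factor: str) -> float:
    """Fraction of raters scoring ``factor`` as important or very important
    (rating >= 4)."""
    col = rm.column(factor)
    return float(np.count_nonzero(col >= AGREEMENT_CUTOFF)) / len(col)


def select_features(rm: RatingMatrix, threshold: float = 0.60) -> list[str]:
    """Factors whose agreement fraction meets the threshold (>=, so ties at
    exactly the cutoff are retained), in input order."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0,1], got {threshold}")
    return [f for f in rm.factors if agreement_fraction(rm, f) >= threshold]


def compute_weights(rm: RatingMatrix, selected: list[str]) -> dict[str, float]:
    """Mean rating of each selected factor, normalized to sum to one.

    Sum-normalization (rather than min-max) keeps every retained weight
    strictly positive and preserves the ratio structure of the mean ratings.
    """
    if not selected:
        raise ValueError("empty selection")
    unknown = [f for f in selected if f not in rm.factors]
    if unknown:
        raise KeyError(f"unknown factor(s) {unknown}")
    means = {f: float(rm.column(f).mean()) for f in selected}
    total = sum(means.values())
    return {f: m / total for f, m in means.items()}
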
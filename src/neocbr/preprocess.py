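"""Case-base preprocessing: imputation, min-max normalization, SMOTE.

Missing values are imputed class-conditionally: within each outcome class a
continuous feature is filled with the class mean when the class sample looks
normal (Shapiro-Wilk at alpha = 0.05) and with the class median otherwise;
a boolean feature is filled with the class majority value.  New problems,
whose class is by definition unknown, are filled from pooled statistics.

Continuous features are min-max normalized to [0,1] using bounds fitted on
the development case base only; out-of-range values in later cases clip.

The dead class is roughly ten times rarer than the alive class, so the
retrieval case base can be balanced with SMOTE: synthetic minority cases are
drawn on the segment between a minority case and one of its k nearest
minority neighbors (weighted Euclidean distance in normalized space),
``s = x + u (nn - x)`` with ``u ~ Uniform(0,1)``.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np
from scipy import stats as sps

from .case_model import Case, CaseBase, FitStats, ValidationError

__all__ = [
    "ImputationError",
    "impute",
    "impute_case",
    "fit_minmax",
    "normalize",
    "normalize_matrix",
    "smote_balance",
    "preprocess_casebase",
]

SHAPIRO_ALPHA = 0.05
POOLED = "__pooled__"


class ImputationError(ValueError):
    """A feature has no observed values to impute from."""


def _continuous_fill(values: np.ndarray) -> tuple[float, dict]:
    """Mean if the sample passes Shapiro-Wilk normality, else median.

    Samples of size < 3 (the test's minimum) and constant samples default to
    the median, which equals the mean in the constant case anyway.
    """
    mean = float(np.mean(values))
    median = float(np.median(values))
    if len(values) < 3 or np.ptp(values) == 0:
        return median, {"mean": mean, "median": median, "normal": False, "n": len(values)}
    _, p = sps.shapiro(values)
    normal = bool(p > SHAPIRO_ALPHA)
    return (mean if normal else median), {
        "mean": mean, "median": median, "normal": normal, "n": len(values),
    }


def _boolean_fill(values: np.ndarray) -> tuple[float, dict]:
    """Majority value within the class; a 50/50 tie fills with 1."""
    ratio = float(np.mean(values))
    majority = 1.0 if ratio >= 0.5 else 0.0
    return majority, {"ratio": ratio, "majority": majority, "n": len(values)}


def _class_labels(cb: CaseBase) -> list:
    """Imputation strata.  The survival task conditions on the alive/dead
    class; the LOS outcome is a day count, not a class, so LOS-task
    imputation pools all cases."""
    if cb.schema.task != "survival":
        return []
    return sorted({c.outcome for c in cb.permanent_cases if c.outcome is not None})


def _fit_imputation(cb: CaseBase) -> FitStats:
    st = cb.stats if cb.stats is not None else FitStats()
    labels = _class_labels(cb)
    perm = cb.permanent_cases
    for spec in cb.schema.features:
        fill_fn = _continuous_fill if spec.kind == "continuous" else _boolean_fill
        strata: list[tuple[str, list[Case]]] = [
            (str(lab), [c for c in perm if c.outcome == lab]) for lab in labels
        ]
        strata.append((POOLED, perm))
        for label, members in strata:
            obs = np.array(
                [c.values[spec.name] for c in members if c.values[spec.name] is not None],
                dtype=float,
            )
            if obs.size == 0:
                raise ImputationError(
                    f"feature {spec.name!r} is entirely missing within class {label!r}"
                )
            fill, detail = fill_fn(obs)
            if label == POOLED:
                st.pooled_fill[spec.name] = fill
            else:
                st.class_fill.setdefault(label, {})[spec.name] = fill
            st.detail.setdefault(spec.name, {})[label] = detail
    return st


def impute(cb: CaseBase) -> CaseBase:
    """Return a copy of the case base with every missing cell filled.

    Cases with a known outcome use their class-conditional fill value; cases
    without one (new problems) use the pooled fill.  Non-missing cells are
    never altered.
    """
    out = cb.copy()
    st = _fit_imputation(out)
    for c in out.cases:
        label = str(c.outcome) if (out.schema.task == "survival" and c.outcome is not None) else None
        fills = st.class_fill.get(label, st.pooled_fill) if label else st.pooled_fill
        for name in c.missing_features():
            c.values[name] = fills[name]
    out.stats = st
    return out


def impute_case(case: Case, stats: FitStats) -> Case:
    """Fill a single (new-problem) case from pooled statistics."""
    if not stats.pooled_fill:
        raise ValidationError("imputation statistics not fitted")
    filled = replace(case, values=dict(case.values))
    for name in filled.missing_features():
        filled.values[name] = stats.pooled_fill[name]
    return filled


def fit_minmax(cb: CaseBase) -> FitStats:
    """Fit per-feature min-max bounds over the permanent cases.

    Boolean features are pinned to [0,1] so normalization is the identity on
    them.  The fitted stats are attached to the case base.
    """
    perm = cb.permanent_cases
    if not perm:
        raise ValidationError("cannot fit min-max bounds on an empty case base")
    st = cb.stats if cb.stats is not None else FitStats()
    for spec in cb.schema.features:
        if spec.kind == "boolean":
            st.lo[spec.name], st.hi[spec.name] = 0.0, 1.0
            continue
        obs = [c.values[spec.name] for c in perm]
        if any(v is None for v in obs):
            raise ValidationError(
                f"feature {spec.name!r} still has missing values; impute first"
            )
        st.lo[spec.name] = float(min(obs))
        st.hi[spec.name] = float(max(obs))
    st.stale = False
    cb.stats = st
    return st


def _bounds(schema, stats: FitStats) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([stats.lo[f.name] for f in schema.features])
    hi = np.array([stats.hi[f.name] for f in schema.features])
    return lo, hi


def normalize(case: Case, stats: FitStats, schema) -> np.ndarray:
    """Map a fully imputed case to its normalized vector in [0,1]^d.

    ``v = (x - lo) / (hi - lo)`` clipped to [0,1]; a constant feature
    (lo == hi) maps to 0.
    """
    if not stats.minmax_fitted:
        raise ValidationError("min-max statistics not fitted")
    missing = case.missing_features()
    if missing:
        raise ValidationError(f"case {case.id!r} has missing values: {missing}")
    x = np.array([case.values[f.name] for f in schema.features], dtype=float)
    lo, hi = _bounds(schema, stats)
    span = hi - lo
    v = np.where(span > 0, (x - lo) / np.where(span > 0, span, 1.0), 0.0)
    return np.clip(v, 0.0, 1.0)


def normalize_matrix(cases: list[Case], stats: FitStats, schema) -> np.ndarray:
    """Vectorized :func:`normalize` over a list of imputed cases."""
    if not stats.minmax_fitted:
        raise ValidationError("min-max statistics not fitted")
    names = [f.name for f in schema.features]
    x = np.array([[c.values[n] for n in names] for c in cases], dtype=float)
    if np.isnan(x).any():
        raise ValidationError("cases still contain missing values; impute first")
    lo, hi = _bounds(schema, stats)
    span = hi - lo
    v = np.where(span > 0, (x - lo) / np.where(span > 0, span, 1.0), 0.0)
    return np.clip(v, 0.0, 1.0)


def _denormalize(v: np.ndarray, schema, stats: FitStats) -> dict[str, float]:
    lo, hi = _bounds(schema, stats)
    raw = lo + v * (hi - lo)
    out = {}
    for j, spec in enumerate(schema.features):
        out[spec.name] = float(round(raw[j])) if spec.kind == "boolean" else float(raw[j])
    return out


def smote_balance(cb: CaseBase, k_neighbors: int = 5, seed: Optional[int] = None) -> CaseBase:
    """Equalize the survival classes by synthesizing minority cases.

    Each synthetic case interpolates, in normalized feature space, between a
    randomly chosen minority case ``x`` and one of its ``k_neighbors``
    nearest minority-class neighbors under the weighted Euclidean distance:
    ``s = x + u (nn - x)``, ``u ~ Uniform(0,1)``.  Synthetic booleans round
    to {0,1}; synthetic cases are flagged and carry their parents' ids.
    Original cases are retained unchanged.
    """
    from .retrieval import pairwise_distances  # local import avoids a cycle

    if cb.schema.task != "survival":
        raise ValidationError("SMOTE balancing requires the binary survival task")
    if k_neighbors < 1:
        raise ValidationError("k_neighbors must be >= 1")
    if not cb.fitted:
        raise ValidationError("case base must be imputed and min-max fitted before SMOTE")

    out = cb.copy()
    perm = out.permanent_cases
    labels = sorted({c.outcome for c in perm})
    if len(labels) != 2:
        raise ValidationError("SMOTE needs exactly two outcome classes")
    counts = {lab: sum(1 for c in perm if c.outcome == lab) for lab in labels}
    minority = min(labels, key=lambda lab: (counts[lab], str(lab)))
    majority = max(labels, key=lambda lab: (counts[lab], str(lab)))
    n_syn = counts[majority] - counts[minority]
    if counts[minority] < 2:
        raise ValidationError("minority class must have at least 2 cases")
    if n_syn == 0:
        return out

    minority_cases = [c for c in perm if c.outcome == minority]
    m = normalize_matrix(minority_cases, out.stats, out.schema)
    w = np.array(out.schema.weights)
    d = pairwise_distances(m, m, w)
    np.fill_diagonal(d, np.inf)
    k = min(k_neighbors, len(minority_cases) - 1)
    nn_idx = np.argsort(d, axis=1, kind="stable")[:, :k]

    rng = np.random.default_rng(seed)
    for i in range(n_syn):
        base = rng.integers(len(minority_cases))
        nn = nn_idx[base, rng.integers(k)]
        u = rng.uniform()
        v = m[base] + u * (m[nn] - m[base])
        values = _denormalize(v, out.schema, out.stats)
        out.cases.append(
            Case(
                id=f"smote-{i:05d}",
                values=values,
                outcome=minority,
                status="permanent",
                synthetic=True,
                parents=(minority_cases[base].id, minority_cases[nn].id),
            )
        )
    return out


def preprocess_casebase(
    cb: CaseBase,
    balanced: bool = False,
    k_neighbors: int = 5,
    seed: Optional[int] = None,
) -> CaseBase:
    """Impute, fit min-max bounds and optionally SMOTE-balance in one call."""
    out = impute(cb)
    fit_minmax(out)
    if balanced:
        out = smote_balance(out, k_neighbors=k_neighbors, seed=seed)
    return out
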
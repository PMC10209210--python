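"""Domain types and I/O for case bases.

A *case base* is the library of previously solved NICU cases that the
case-based reasoner searches: one row per neonate, a mix of continuous
(birth weight, gestational age) and boolean risk-factor features, plus a
known outcome (``alive``/``dead`` for the survival task, non-negative
integer days for the length-of-stay task).

Case bases are read from and written to plain comma-delimited CSV; feature
schemas (ordered feature definitions with expert-elicited weights) travel
as JSON.  Two default schemas ship with the package: 17 mortality risk
factors and 13 LOS risk factors, each with its normalized importance
weight.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

__all__ = [
    "ALIVE",
    "DEAD",
    "Case",
    "CaseBase",
    "FeatureSpec",
    "FitStats",
    "Schema",
    "SchemaMismatchError",
    "ValidationError",
    "default_schema",
    "read_casebase",
    "write_casebase",
]

ALIVE = "alive"
DEAD = "dead"

#: tokens that parse as a missing cell (besides the empty string)
MISSING_TOKENS = {"", "na"}
#: accepted spellings for boolean raw values
TRUE_TOKENS = {"1", "yes", "true"}
FALSE_TOKENS = {"0", "no", "false"}


class ValidationError(ValueError):
    """A value violates a domain invariant (named row/column where known)."""


class SchemaMismatchError(ValueError):
    """A file's columns do not match the schema."""


@dataclass
class FeatureSpec:
    """One feature: its kind, importance weight and (fitted) min-max bounds.

    The weight is the expert-elicited normalized importance used in the
    weighted Euclidean distance; ``lo``/``hi`` stay unset until min-max
    statistics are fitted on a case base.
    """

    name: str
    kind: str  # "continuous" | "boolean"
    weight: float
    lo: Optional[float] = None
    hi: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "boolean"):
            raise ValidationError(f"feature {self.name!r}: unknown kind {self.kind!r}")
        if not (self.weight > 0):
            raise ValidationError(f"feature {self.name!r}: weight must be > 0")
        if self.lo is not None and self.hi is not None and self.lo > self.hi:
            raise ValidationError(f"feature {self.name!r}: lo > hi")


@dataclass
class Schema:
    """Ordered feature list for one prediction task.

    Feature order is authoritative: distance computation always follows
    schema order regardless of column order in any particular file.
    """

    task: str  # "survival" | "los"
    features: list[FeatureSpec]
    outcome_name: str

    def __post_init__(self) -> None:
        if self.task not in ("survival", "los"):
            raise ValidationError(f"unknown task {self.task!r}")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate feature names in schema")
        total = sum(f.weight for f in self.features)
        if not (0.99 <= total <= 1.01):
            raise ValidationError(f"feature weights sum to {total:.4f}, expected ~1")

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def weights(self) -> list[float]:
        return [f.weight for f in self.features]

    def feature(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def to_json(self, path: Union[str, Path]) -> Path:
        payload = {
            "task": self.task,
            "outcome_name": self.outcome_name,
            "features": [
                {"name": f.name, "kind": f.kind, "weight": f.weight}
                for f in self.features
            ],
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "Schema":
        payload = json.loads(Path(path).read_text())
        feats = [
            FeatureSpec(name=f["name"], kind=f["kind"], weight=float(f["weight"]))
            for f in payload["features"]
        ]
        return cls(task=payload["task"], features=feats, outcome_name=payload["outcome_name"])


@dataclass
class Case:
    """One neonate: raw feature values, outcome and lifecycle status.

    ``values`` maps every schema feature name to a raw value or ``None``
    (missing).  The outcome is ``"alive"``/``"dead"`` for the survival task,
    a non-negative integer number of days for the LOS task, or ``None`` for
    a new, not-yet-solved problem.
    """

    id: str
    values: dict[str, Optional[float]]
    outcome: Union[str, int, None] = None
    status: str = "permanent"  # permanent | temporary_approved | temporary_unapproved
    synthetic: bool = False
    parents: Optional[tuple[str, str]] = None  # SMOTE parent ids, if synthetic

    def missing_features(self) -> list[str]:
        return [k for k, v in self.values.items() if v is None]


@dataclass
class FitStats:
    """Preprocessing statistics fitted on a (permanent) case base.

    Holds per-feature min-max bounds and class-conditional imputation fill
    values (mean or median for continuous features depending on a normality
    test; majority value for booleans), plus pooled fill values used for new
    problems whose class is unknown.
    """

    lo: dict[str, float] = field(default_factory=dict)
    hi: dict[str, float] = field(default_factory=dict)
    class_fill: dict[str, dict[str, float]] = field(default_factory=dict)
    pooled_fill: dict[str, float] = field(default_factory=dict)
    # audit detail: per feature x class -> {"mean","median","normal"} or
    # {"ratio","majority"} for booleans
    detail: dict[str, dict] = field(default_factory=dict)
    stale: bool = False

    @property
    def minmax_fitted(self) -> bool:
        return bool(self.lo)

    def to_json(self, path: Union[str, Path]) -> Path:
        payload = {
            "lo": self.lo,
            "hi": self.hi,
            "class_fill": self.class_fill,
            "pooled_fill": self.pooled_fill,
            "detail": self.detail,
            "stale": self.stale,
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "FitStats":
        d = json.loads(Path(path).read_text())
        return cls(
            lo=d["lo"], hi=d["hi"], class_fill=d["class_fill"],
            pooled_fill=d["pooled_fill"], detail=d.get("detail", {}),
            stale=d.get("stale", False),
        )


@dataclass
class CaseBase:
    """Schema + stored cases + (once preprocessed) fitted statistics."""

    schema: Schema
    cases: list[Case] = field(default_factory=list)
    stats: Optional[FitStats] = None

    def __len__(self) -> int:
        return len(self.cases)

    @property
    def fitted(self) -> bool:
        return self.stats is not None and self.stats.minmax_fitted and not self.stats.stale

    @property
    def permanent_cases(self) -> list[Case]:
        return [c for c in self.cases if c.status == "permanent"]

    def case(self, case_id: str) -> Case:
        for c in self.cases:
            if c.id == case_id:
                return c
        raise KeyError(case_id)

    def copy(self) -> "CaseBase":
        return CaseBase(
            schema=self.schema,
            cases=[replace(c, values=dict(c.values)) for c in self.cases],
            stats=self.stats,
        )

    def mark_stale(self) -> None:
        if self.stats is not None:
            self.stats.stale = True


# --------------------------------------------------------------------------
# Shipped default schemas: expert-elicited normalized weights.

_MORTALITY_WEIGHTS: list[tuple[str, str, float]] = [
    ("Asphyxia", "boolean", 0.0631),
    ("BW", "continuous", 0.0645),
    ("CHD", "boolean", 0.0602),
    ("GA", "continuous", 0.0631),
    ("Intubation", "boolean", 0.0545),
    ("IVH", "boolean", 0.0545),
    ("Mechanical ventilation", "boolean", 0.0573),
    ("Mother chronic disease", "boolean", 0.0545),
    ("NEC", "boolean", 0.0588),
    ("Prenatal care", "boolean", 0.0559),
    ("Preterm birth", "boolean", 0.0659),
    ("Pulmonary hemorrhage", "boolean", 0.0588),
    ("RDS", "boolean", 0.0588),
    ("Sepsis", "boolean", 0.0602),
    ("SGA", "boolean", 0.0573),
    ("Steroid use", "boolean", 0.0545),
    ("Surfactant administration", "boolean", 0.0573),
]

_LOS_WEIGHTS: list[tuple[str, str, float]] = [
    ("BW", "continuous", 0.0837),
    ("CHD", "boolean", 0.0819),
    ("GA", "continuous", 0.0837),
    ("Mechanical ventilation", "boolean", 0.0744),
    ("Multiple gestation", "boolean", 0.0726),
    ("NEC", "boolean", 0.0800),
    ("NEC therapy", "boolean", 0.0763),
    ("Prenatal care", "boolean", 0.0707),
    ("Pulmonary hemorrhage", "boolean", 0.0856),
    ("RDS", "boolean", 0.0744),
    ("Sepsis", "boolean", 0.0782),
    ("SGA", "boolean", 0.0707),
    ("Steroid use", "boolean", 0.0670),
]


def default_schema(task: str) -> Schema:
    """Return the shipped schema for ``"survival"`` (17 features) or
    ``"los"`` (13 features), with the expert-panel normalized weights."""
    if task == "survival":
        feats = [FeatureSpec(n, k, w) for n, k, w in _MORTALITY_WEIGHTS]
        return Schema(task="survival", features=feats, outcome_name="outcome")
    if task == "los":
        feats = [FeatureSpec(n, k, w) for n, k, w in _LOS_WEIGHTS]
        return Schema(task="los", features=feats, outcome_name="los_days")
    raise ValidationError(f"unknown task {task!r}")


# --------------------------------------------------------------------------
# Parsing helpers


def _is_missing(token: str) -> bool:
    return token.strip().lower() in MISSING_TOKENS


def _parse_boolean(token: str, row: int, col: str) -> float:
    t = token.strip().lower()
    if t in TRUE_TOKENS:
        return 1.0
    if t in FALSE_TOKENS:
        return 0.0
    raise ValidationError(f"row {row}, column {col!r}: {token!r} is not a boolean (0/1/Yes/No)")


def _parse_continuous(token: str, row: int, col: str) -> float:
    try:
        v = float(token)
    except ValueError:
        raise ValidationError(f"row {row}, column {col!r}: {token!r} is not numeric") from None
    if not math.isfinite(v) or v < 0:
        raise ValidationError(f"row {row}, column {col!r}: value must be a finite non-negative real")
    return v


def parse_outcome(token: str, task: str, row: int = -1) -> Union[str, int, None]:
    """Parse an outcome cell: alive/dead (also 1/0) or integer days."""
    if _is_missing(token):
        return None
    t = token.strip().lower()
    if task == "survival":
        if t in ("alive", "1"):
            return ALIVE
        if t in ("dead", "0"):
            return DEAD
        raise ValidationError(f"row {row}, outcome: {token!r} is not alive/dead")
    try:
        days = int(float(t))
    except ValueError:
        raise ValidationError(f"row {row}, outcome: {token!r} is not a day count") from None
    if days < 0 or float(t) != days:
        raise ValidationError(f"row {row}, outcome: LOS must be a non-negative integer, got {token!r}")
    return days


def read_casebase(path: Union[str, Path], schema: Schema) -> CaseBase:
    """Read a case-base CSV whose header holds the schema's feature names
    plus the outcome column (and an optional leading ``id`` column).

    Blank cells and the literal ``NA`` (any case) parse as missing; booleans
    accept 0/1 and Yes/No.  Row order is preserved.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    has_id = bool(cols) and cols[0] == "id"
    expected = set(schema.feature_names) | {schema.outcome_name} | ({"id"} if has_id else set())
    unknown = [c for c in cols if c not in expected]
    if unknown:
        raise SchemaMismatchError(f"unknown column(s) {unknown} for task {schema.task!r}")
    absent = [c for c in schema.feature_names + [schema.outcome_name] if c not in cols]
    if absent:
        raise SchemaMismatchError(f"missing column(s) {absent}")

    cases: list[Case] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(cols, row))
        values: dict[str, Optional[float]] = {}
        for spec in schema.features:
            token = rec[spec.name]
            if _is_missing(token):
                values[spec.name] = None
            elif spec.kind == "boolean":
                values[spec.name] = _parse_boolean(token, i, spec.name)
            else:
                values[spec.name] = _parse_continuous(token, i, spec.name)
        outcome = parse_outcome(rec[schema.outcome_name], schema.task, i)
        cid = rec["id"] if has_id else f"case-{i}"
        cases.append(Case(id=cid, values=values, outcome=outcome))
    return CaseBase(schema=schema, cases=cases)


def _format_value(v: Optional[float], kind: str) -> str:
    if v is None:
        return ""
    if kind == "boolean":
        return str(int(round(v)))
    return repr(float(v)) if float(v) != int(v) else str(int(v))


def write_casebase(cb: CaseBase, path: Union[str, Path]) -> Path:
    """Write the case base to CSV; read(write(cb)) round-trips raw values,
    outcomes and missing markers."""
    schema = cb.schema
    rows = []
    for c in cb.cases:
        rec: dict[str, str] = {"id": c.id}
        for spec in schema.features:
            rec[spec.name] = _format_value(c.values.get(spec.name), spec.kind)
        if c.outcome is None:
            rec[schema.outcome_name] = ""
        else:
            rec[schema.outcome_name] = str(c.outcome)
        rows.append(rec)
    columns = ["id"] + schema.feature_names + [schema.outcome_name]
    df = pd.DataFrame(rows, columns=columns, dtype=str)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def cases_from_frame(df: pd.DataFrame, schema: Schema) -> Iterable[Case]:
    """Build cases from an in-memory numeric DataFrame (NaN = missing)."""
    for i, row in df.iterrows():
        values = {
            f.name: (None if pd.isna(row[f.name]) else float(row[f.name]))
            for f in schema.features
        }
        raw = row[schema.outcome_name]
        if pd.isna(raw):
            outcome: Union[str, int, None] = None
        elif schema.task == "survival":
            outcome = raw
        else:
            outcome = int(raw)
        yield Case(id=f"case-{i}", values=values, outcome=outcome)
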
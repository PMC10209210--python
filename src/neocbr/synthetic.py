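"""Synthetic NICU cohorts and expert-rating matrices.

The registry the reasoner was built for is confidential, so this module
generates cohorts with the same coarse statistical structure: ~9% mortality,
a right-skewed length of stay averaging ~15 days with a 0-191 day range,
birth weight and gestational age as continuous features, boolean risk
factors that are more frequent among neonates who die, and sparse (~1%)
completely-at-random missingness.

The generative model is deliberately simple — class-conditional Gaussians
for the continuous features and class-conditional Bernoullis for the
booleans — so that a single ``effect_size`` knob (the between-class shift in
within-class standard deviations, and the same shift on the log-odds of each
risk factor) controls how separable the classes are.  LOS is log-normal with
log-linear terms in the number of risk factors present and in a continuous
severity score (standardized birth-weight and gestational-age shortfall), so
the features the retriever sees carry a learnable stay signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .case_model import ALIVE, DEAD, Case, CaseBase, Schema, ValidationError
from .weights import RatingMatrix

__all__ = ["CohortConfig", "generate_cohort", "generate_ratings"]

# class-conditional feature model (alive-class parameters)
BW_MEAN, BW_SD, BW_RANGE = 3200.0, 600.0, (500.0, 5000.0)  # grams
GA_MEAN, GA_SD, GA_RANGE = 38.0, 2.5, (22.0, 42.0)  # weeks
RISK_RATE_ALIVE = 0.15  # baseline Bernoulli rate of each boolean risk factor
LOS_RISK_SLOPE = 0.30  # log-days per boolean risk factor present
LOS_SEVERITY_SLOPE = 0.50  # log-days per unit of continuous severity (low BW/GA)
LOS_LOG_SD = 0.35  # residual sd on the log scale


@dataclass
class CohortConfig:
    """Cohort-level generator settings (defaults emulate the development
    registry: 9% mortality, mean stay 15 days capped at 191, ~1% missing)."""

    n: int
    mortality_rate: float = 0.09
    los_mean: float = 15.0
    los_max: int = 191
    effect_size: float = 2.0
    missing_rate: float = 0.01
    seed: int = 0
    ga_bw_correlation: float = 0.0  # optional within-class GA-BW correlation

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("cohort size must be >= 2")
        for name in ("mortality_rate", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0,1]")
        if not (self.los_max >= self.los_mean >= 0):
            raise ValidationError("need los_max >= los_mean >= 0")
        if not (-1.0 < self.ga_bw_correlation < 1.0):
            raise ValidationError("ga_bw_correlation must be in (-1,1)")
        if 0 < self.mortality_rate and self.mortality_rate * self.n < 1:
            raise ValidationError("infeasible config: expected dead count below 1")


def _shifted_rate(base: float, effect: float) -> float:
    """Raise a Bernoulli rate by ``effect`` on the log-odds scale."""
    logit = math.log(base / (1 - base)) + effect
    return 1.0 / (1.0 + math.exp(-logit))


def generate_cohort(cfg: CohortConfig, schema: Schema) -> CaseBase:
    """Generate a cohort as a raw (unpreprocessed) case base.

    Dead-class continuous features shift down by ``effect_size`` standard
    deviations; boolean risk-factor rates shift up by ``effect_size`` on the
    log-odds scale.  LOS is log-normal, calibrated at generation time so the
    pre-clipping sample mean equals ``los_mean``, then rounded to whole days
    and clipped to [0, los_max].  Fully reproducible under ``seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    dead = rng.random(n) < cfg.mortality_rate

    names = schema.feature_names
    cols: dict[str, np.ndarray] = {}
    # shared latent for the optional within-class GA-BW correlation; each
    # continuous feature loads sqrt(|rho|) on it so the achieved pairwise
    # correlation equals rho (second and later features take rho's sign)
    rho = cfg.ga_bw_correlation
    load = math.sqrt(abs(rho))
    z = rng.standard_normal(n)
    n_cont_seen = 0
    for spec in schema.features:
        if spec.kind == "continuous":
            mean, sd, (lo, hi) = {
                "BW": (BW_MEAN, BW_SD, BW_RANGE),
                "GA": (GA_MEAN, GA_SD, GA_RANGE),
            }.get(spec.name, (BW_MEAN, BW_SD, BW_RANGE))
            sign = 1.0 if (n_cont_seen == 0 or rho >= 0) else -1.0
            n_cont_seen += 1
            eps = sign * load * z + math.sqrt(1 - abs(rho)) * rng.standard_normal(n)
            x = mean + sd * eps
            x = x - dead * cfg.effect_size * sd
            cols[spec.name] = np.clip(x, lo, hi)
        else:
            p_dead = _shifted_rate(RISK_RATE_ALIVE, cfg.effect_size)
            p = np.where(dead, p_dead, RISK_RATE_ALIVE)
            cols[spec.name] = (rng.random(n) < p).astype(float)

    risk_count = np.asarray(
        sum(cols[s.name] for s in schema.features if s.kind == "boolean"), float
    )
    # continuous severity: standardized shortfall in BW and GA (sicker = higher)
    severity = np.zeros(n)
    sev_terms = 0
    for name, mean, sd in (("BW", BW_MEAN, BW_SD), ("GA", GA_MEAN, GA_SD)):
        if name in cols:
            severity += (mean - cols[name]) / sd
            sev_terms += 1
    if sev_terms:
        severity /= sev_terms
    eta = (
        LOS_RISK_SLOPE * risk_count
        + LOS_SEVERITY_SLOPE * severity
        + LOS_LOG_SD * rng.standard_normal(n)
    )
    mu = math.log(cfg.los_mean) - math.log(float(np.mean(np.exp(eta)))) if cfg.los_mean > 0 else -math.inf
    los = np.clip(np.floor(np.exp(mu + eta) + 0.5), 0, cfg.los_max).astype(int)

    # MCAR missingness over feature cells only
    miss = rng.random((n, len(names))) < cfg.missing_rate

    cases = []
    for i in range(n):
        values = {
            name: (None if miss[i, j] else float(cols[name][i]))
            for j, name in enumerate(names)
        }
        outcome = (DEAD if dead[i] else ALIVE) if schema.task == "survival" else int(los[i])
        cases.append(Case(id=f"sim-{i:05d}", values=values, outcome=outcome))
    return CaseBase(schema=schema, cases=cases)


def generate_ratings(
    n_raters: int, factors: list[str], n_important: int, seed: int = 0
) -> RatingMatrix:
    """Build a complete rating matrix in which exactly ``n_important``
    factors reach 60% agreement (ratings of 4-5) and the rest do not."""
    if n_raters < 2:
        raise ValidationError("need at least 2 raters")
    if not (0 <= n_important <= len(factors)):
        raise ValidationError("n_important must be between 0 and the number of factors")
    rng = np.random.default_rng(seed)
    cutoff = math.ceil(0.6 * n_raters)  # smallest agreeing count meeting the rule
    ratings = np.empty((n_raters, len(factors)), dtype=int)
    for j in range(len(factors)):
        if j < n_important:
            n_agree = int(rng.integers(cutoff, n_raters + 1))
        else:
            n_agree = int(rng.integers(0, cutoff))
        col = np.concatenate(
            [
                rng.integers(4, 6, size=n_agree),  # important / very important
                rng.integers(1, 4, size=n_raters - n_agree),
            ]
        )
        ratings[:, j] = rng.permutation(col)
    return RatingMatrix(
        raters=[f"rater-{i}" for i in range(n_raters)],
        factors=list(factors),
        ratings=ratings,
    )
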
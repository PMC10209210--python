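"""Imputation, min-max normalization and SMOTE balancing."""

from collections import Counter

import numpy as np
import pytest

from neocbr.case_model import ALIVE, DEAD, Case, CaseBase, ValidationError
from neocbr.preprocess import (
    ImputationError,
    fit_minmax,
    impute,
    impute_case,
    normalize,
    preprocess_casebase,
    smote_balance,
)
from neocbr.synthetic import CohortConfig, generate_cohort

from conftest import make_case


def cb_with(toy_schema, rows):
    cases = [make_case(i, toy_schema, v, o) for i, (v, o) in enumerate(rows)]
    return CaseBase(schema=toy_schema, cases=cases)


class TestImpute:
    def test_symmetric_class_sample_fills_with_mean(self, toy_schema):
        rows = [
            ((2000, 30, 1), DEAD),
            ((2200, 30, 1), DEAD),
            ((2400, 30, 1), DEAD),
            ((None, 30, 1), DEAD),
            ((3300, 39, 0), ALIVE),
            ((3400, 39, 0), ALIVE),
            ((3500, 40, 0), ALIVE),
        ]
        out = impute(cb_with(toy_schema, rows))
        assert out.cases[3].values["BW"] == pytest.approx(2200)

    def test_skewed_class_sample_fails_normality_and_uses_median(self, toy_schema):
        # {1,1,1,1,100} fails Shapiro-Wilk at alpha=0.05 (p ~ 1e-4) -> median 1
        rows = [((v, 30, 1), DEAD) for v in (1, 1, 1, 1, 100)] + [
            ((None, 30, 1), DEAD),
            ((3300, 39, 0), ALIVE),
            ((3400, 39, 0), ALIVE),
            ((3500, 40, 0), ALIVE),
        ]
        out = impute(cb_with(toy_schema, rows))
        assert out.cases[5].values["BW"] == pytest.approx(1.0)

    def test_boolean_filled_with_class_majority(self, toy_schema):
        rows = [((3000, 38, 1), ALIVE)] * 4 + [
            ((3000, 38, 0), ALIVE),
            ((3000, 38, None), ALIVE),
            ((1000, 28, 0), DEAD),
            ((1100, 28, 0), DEAD),
        ]
        out = impute(cb_with(toy_schema, rows))
        assert out.cases[5].values["RDS"] == 1.0  # 80% of alive class is 1

    def test_imputation_is_class_conditional_not_pooled(self, toy_schema):
        rows = [
            ((2000, 30, 1), DEAD),
            ((2000, 30, 1), DEAD),
            ((None, 30, 1), DEAD),
            ((4000, 40, 0), ALIVE),
            ((4000, 40, 0), ALIVE),
            ((4000, 40, 0), ALIVE),
        ]
        out = impute(cb_with(toy_schema, rows))
        assert out.cases[2].values["BW"] == pytest.approx(2000)  # dead class, not 3200

    def test_new_problem_without_outcome_uses_pooled_statistics(self, toy_schema):
        rows = [
            ((2000, 30, 1), DEAD),
            ((2000, 30, 1), DEAD),
            ((4000, 40, 0), ALIVE),
            ((4000, 40, 0), ALIVE),
            ((None, 35, 0), None),
        ]
        out = impute(cb_with(toy_schema, rows))
        assert out.cases[4].values["BW"] == pytest.approx(3000)  # pooled mean/median

    def test_nonmissing_cells_never_altered(self, toy_casebase):
        before = {c.id: dict(c.values) for c in toy_casebase.cases}
        out = impute(toy_casebase)
        for c in out.cases:
            for k, v in before[c.id].items():
                if v is not None:
                    assert c.values[k] == v

    def test_feature_entirely_missing_in_class_raises(self, toy_schema):
        rows = [
            ((None, 30, 1), DEAD),
            ((None, 29, 1), DEAD),
            ((3300, 39, 0), ALIVE),
            ((3400, 39, 0), ALIVE),
        ]
        with pytest.raises(ImputationError, match="BW"):
            impute(cb_with(toy_schema, rows))

    def test_impute_case_fills_from_pooled(self, toy_casebase, toy_schema):
        out = impute(toy_casebase)
        new = make_case(99, toy_schema, (None, 38, 0))
        filled = impute_case(new, out.stats)
        assert filled.values["BW"] == out.stats.pooled_fill["BW"]
        assert new.values["BW"] is None  # original untouched


class TestMinMaxNormalize:
    def test_bounds_are_observed_extremes(self, toy_schema):
        rows = [((500, 30, 0), ALIVE), ((4000, 40, 1), DEAD)]
        cb = cb_with(toy_schema, rows)
        st = fit_minmax(cb)
        assert (st.lo["BW"], st.hi["BW"]) == (500, 4000)

    def test_boolean_bounds_pinned_to_unit(self, toy_schema):
        cb = cb_with(toy_schema, [((3000, 38, 0), ALIVE), ((3100, 39, 0), ALIVE)])
        st = fit_minmax(cb)
        assert (st.lo["RDS"], st.hi["RDS"]) == (0.0, 1.0)

    def test_constant_feature_has_lo_equal_hi_and_maps_to_zero(self, toy_schema):
        cb = cb_with(toy_schema, [((3000, 38, 0), ALIVE), ((3000, 39, 1), DEAD)])
        st = fit_minmax(cb)
        assert st.lo["BW"] == st.hi["BW"] == 3000
        v = normalize(cb.cases[0], st, toy_schema)
        assert v[0] == 0.0

    def test_extremes_and_midpoint(self, toy_schema):
        cb = cb_with(toy_schema, [((500, 30, 0), ALIVE), ((4000, 40, 1), DEAD)])
        st = fit_minmax(cb)
        mid = make_case(9, toy_schema, (2250, 35, 1))
        v = normalize(mid, st, toy_schema)
        assert v[0] == pytest.approx(0.5)
        assert normalize(cb.cases[0], st, toy_schema)[0] == 0.0
        assert normalize(cb.cases[1], st, toy_schema)[0] == 1.0

    def test_out_of_range_value_clips(self, toy_schema):
        cb = cb_with(toy_schema, [((500, 30, 0), ALIVE), ((4000, 40, 1), DEAD)])
        st = fit_minmax(cb)
        big = make_case(9, toy_schema, (4500, 35, 1))
        assert normalize(big, st, toy_schema)[0] == 1.0

    def test_normalization_identity_on_booleans(self, toy_casebase, toy_schema):
        st = fit_minmax(toy_casebase)
        for c in toy_casebase.cases:
            assert normalize(c, st, toy_schema)[2] == c.values["RDS"]

    def test_empty_casebase_rejected(self, toy_schema):
        with pytest.raises(ValidationError):
            fit_minmax(CaseBase(schema=toy_schema))

    def test_unfitted_stats_rejected(self, toy_schema, toy_casebase):
        from neocbr.case_model import FitStats

        with pytest.raises(ValidationError):
            normalize(toy_casebase.cases[0], FitStats(), toy_schema)


class TestSmote:
    def _prepped(self, toy_schema, rows):
        cb = cb_with(toy_schema, rows)
        return preprocess_casebase(cb)

    def test_identical_minority_pair_yields_identical_synthetics(self, toy_schema):
        rows = [((1000, 28, 1), DEAD)] * 2 + [((3000 + i, 38, 0), ALIVE) for i in range(6)]
        out = smote_balance(self._prepped(toy_schema, rows), seed=0)
        syn = [c for c in out.cases if c.synthetic]
        assert len(syn) == 4
        for c in syn:
            assert c.values["BW"] == pytest.approx(1000)
            assert c.values["RDS"] == 1.0

    def test_exact_class_parity_and_originals_retained(self, toy_casebase):
        out = smote_balance(preprocess_casebase(toy_casebase), seed=1)
        counts = Counter(c.outcome for c in out.permanent_cases)
        assert counts[ALIVE] == counts[DEAD]
        originals = [c for c in out.cases if not c.synthetic]
        assert len(originals) == len(toy_casebase)
        assert all(c.outcome == DEAD for c in out.cases if c.synthetic)

    def test_seeded_run_is_bit_reproducible(self, toy_casebase):
        a = smote_balance(preprocess_casebase(toy_casebase), seed=7)
        b = smote_balance(preprocess_casebase(toy_casebase), seed=7)
        for ca, cb_ in zip(a.cases, b.cases):
            assert ca.values == cb_.values

    def test_synthetic_coordinates_lie_between_parents(self, toy_schema, rng):
        rows = [((float(rng.uniform(600, 1800)), float(rng.uniform(25, 32)), 1), DEAD) for _ in range(8)]
        rows += [((float(rng.uniform(2800, 4000)), float(rng.uniform(36, 41)), 0), ALIVE) for _ in range(30)]
        out = smote_balance(self._prepped(toy_schema, rows), seed=3)
        by_id = {c.id: c for c in out.cases}
        for c in out.cases:
            if not c.synthetic:
                continue
            p1, p2 = (by_id[p] for p in c.parents)
            for name in ("BW", "GA"):  # continuous coords: convex combination
                lo = min(p1.values[name], p2.values[name]) - 1e-9
                hi = max(p1.values[name], p2.values[name]) + 1e-9
                assert lo <= c.values[name] <= hi

    def test_registry_scale_generates_majority_minus_minority_synthetics(self, survival_schema):
        cohort = generate_cohort(
            CohortConfig(n=1346, mortality_rate=0.09, missing_rate=0.0, seed=5), survival_schema
        )
        for i, c in enumerate(cohort.cases):  # force the registry class counts
            c.outcome = DEAD if i < 121 else ALIVE
        out = smote_balance(preprocess_casebase(cohort), seed=5)
        assert sum(1 for c in out.cases if c.synthetic) == 1225 - 121
        counts = Counter(c.outcome for c in out.permanent_cases)
        assert counts[ALIVE] == counts[DEAD] == 1225

    def test_minority_below_two_rejected(self, toy_schema):
        rows = [((1000, 28, 1), DEAD)] + [((3000, 38, 0), ALIVE)] * 4
        with pytest.raises(ValidationError):
            smote_balance(self._prepped(toy_schema, rows), seed=0)

    def test_k_below_one_rejected(self, toy_casebase):
        with pytest.raises(ValidationError):
            smote_balance(preprocess_casebase(toy_casebase), k_neighbors=0, seed=0)

    def test_los_task_rejected(self, toy_los_schema):
        cases = [
            Case(id=f"c{i}", values={"BW": 3000.0 + i, "RDS": 0.0}, outcome=i) for i in range(4)
        ]
        cb = CaseBase(schema=toy_los_schema, cases=cases)
        with pytest.raises(ValidationError):
            smote_balance(preprocess_casebase(cb), seed=0)
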
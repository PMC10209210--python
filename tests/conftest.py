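import numpy as np
import pytest

from neocbr.case_model import ALIVE, DEAD, Case, CaseBase, FeatureSpec, Schema, default_schema


@pytest.fixture(scope="session")
def survival_schema():
    return default_schema("survival")


@pytest.fixture(scope="session")
def los_schema():
    return default_schema("los")


@pytest.fixture
def toy_schema():
    """Small 3-feature survival schema for hand-computable examples."""
    return Schema(
        task="survival",
        features=[
            FeatureSpec("BW", "continuous", 0.4),
            FeatureSpec("GA", "continuous", 0.3),
            FeatureSpec("RDS", "boolean", 0.3),
        ],
        outcome_name="outcome",
    )


@pytest.fixture
def toy_los_schema():
    return Schema(
        task="los",
        features=[
            FeatureSpec("BW", "continuous", 0.5),
            FeatureSpec("RDS", "boolean", 0.5),
        ],
        outcome_name="los_days",
    )


def make_case(i, schema, values, outcome=None, **kw):
    return Case(id=f"c{i:03d}", values=dict(zip(schema.feature_names, values)), outcome=outcome, **kw)


@pytest.fixture
def toy_casebase(toy_schema):
    """Six fully observed cases, 4 alive / 2 dead."""
    rows = [
        ((3200, 39, 0), ALIVE),
        ((2900, 38, 0), ALIVE),
        ((3500, 40, 0), ALIVE),
        ((3100, 37, 1), ALIVE),
        ((900, 27, 1), DEAD),
        ((1200, 29, 1), DEAD),
    ]
    cases = [make_case(i, toy_schema, v, o) for i, (v, o) in enumerate(rows)]
    return CaseBase(schema=toy_schema, cases=cases)


@pytest.fixture
def rng():
    return np.random.default_rng(20230524)
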
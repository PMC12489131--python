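import numpy as np
import pandas as pd
import pytest

import fuzzyprofiles as fp


@pytest.fixture(scope="session")
def default_cohort():
    """One discovery cohort drawn from the default planted-profile spec."""
    spec = fp.SyntheticSpec(n_per_cohort={"DISC": 1000}, seed=11)
    tables, truth = fp.generate(spec)
    return spec, tables[0], truth


@pytest.fixture(scope="session")
def standardized_features(default_cohort):
    _, table, _ = default_cohort
    X = fp.residualize(table).features
    return (X - X.mean()) / X.std(ddof=0)


@pytest.fixture(scope="session")
def fitted_model(standardized_features):
    model, memberships = fp.fit_fcm(standardized_features, 4, seed=5, n_init=4)
    return model, memberships


def make_table(n=12, seed=0, diagnoses=(), environment=()):
    """Small hand-checkable cohort table."""
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "cohort": "A",
        "timepoint": "t1",
        "age": rng.normal(120, 8, n),
        "sex": rng.choice(["F", "M"], n),
        "ethnicity": rng.choice(["A", "B"], n),
        "handedness": rng.choice(["R", "L"], n),
    })
    for f in fp.CohortSchema().features:
        frame[f] = rng.normal(size=n)
    for d in diagnoses:
        frame[d] = rng.integers(0, 2, n)
    for e in environment:
        frame[e] = rng.normal(size=n)
    schema = fp.CohortSchema(diagnoses=tuple(diagnoses), environment=tuple(environment))
    return fp.CohortTable(frame, schema)
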
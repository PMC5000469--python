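"""Shared fixtures: small schemas and hand-built cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from attrirules.cohort import Cohort, CovariateSchema, Variable


@pytest.fixture(scope="session")
def tiny_schema() -> CovariateSchema:
    """A reduced withdrawal-study schema for hand-built cohorts."""
    return CovariateSchema(
        variables=(
            Variable("country", "categorical",
                     levels=("Finland", "Sweden", "United States")),
            Variable("smoking", "categorical", levels=("no", "yes")),
            Variable("dad_participation", "categorical", levels=("yes", "no")),
            Variable("maternal_age", "continuous", lo=15, hi=50),
            Variable("anxiety_score", "continuous", lo=20, hi=80),
            Variable("negative_life_events", "count", lo=0),
            Variable("n_missing", "count", lo=0, derived=True),
        ),
        outcome_name="withdrawn",
    )


def make_cohort(schema: CovariateSchema, rows: list[dict]) -> Cohort:
    """Build a cohort from row dicts; absent keys become missing cells."""
    cols = {name: [r.get(name, np.nan) for r in rows]
            for name in (*schema.observed_names, schema.outcome_name)}
    return Cohort(schema, pd.DataFrame(cols))


@pytest.fixture()
def hand_cohort(tiny_schema) -> Cohort:
    """Six records exercising every variable kind plus missingness."""
    rows = [
        dict(country="Finland", smoking="no", dad_participation="yes",
             maternal_age=31.0, anxiety_score=40.0, negative_life_events=1,
             withdrawn=0),
        dict(country="Sweden", smoking="yes", dad_participation="no",
             maternal_age=24.0, anxiety_score=50.0, negative_life_events=3,
             withdrawn=1),
        dict(country="United States", smoking="no", dad_participation="no",
             maternal_age=27.0, anxiety_score=46.0, negative_life_events=0,
             withdrawn=1),
        dict(country="United States", smoking="yes", dad_participation="yes",
             maternal_age=35.0, anxiety_score=60.0, negative_life_events=2,
             withdrawn=0),
        dict(country="Sweden", smoking="no", dad_participation="no",
             maternal_age=29.0, negative_life_events=0,  # anxiety missing
             withdrawn=0),
        dict(country="Finland", dad_participation="yes",  # smoking missing
             maternal_age=41.0, anxiety_score=33.0, negative_life_events=5,
             withdrawn=1),
    ]
    return make_cohort(tiny_schema, rows)
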
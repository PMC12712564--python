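"""Shared fixtures: small synthetic cohorts and the bundled code map."""

import numpy as np
import pandas as pd
import pytest

from ehrshift.ingest import CodeMap, batch_by_year, harmonize_codes
from ehrshift.synthetic import default_code_map, default_scenario, generate_cohort


@pytest.fixture(scope="session")
def code_map() -> CodeMap:
    return CodeMap(default_code_map())


@pytest.fixture(scope="session")
def null_cohort():
    scenario = default_scenario("null", n_per_year=400, seed=11)
    return scenario, generate_cohort(scenario)


@pytest.fixture(scope="session")
def null_batches(null_cohort, code_map):
    _, table = null_cohort
    features = harmonize_codes(table, code_map)
    return batch_by_year(features)


@pytest.fixture(scope="session")
def null_features(null_cohort, code_map):
    _, table = null_cohort
    return harmonize_codes(table, code_map)


def toy_feature_table(
    n_per_year: int = 60,
    years: tuple[int, ...] = (2008, 2009, 2010),
    seed: int = 0,
    pattern: str = "noise",
) -> pd.DataFrame:
    """Hand-built FeatureTable with two binary features and a numeric age.

    ``pattern="separable"`` makes the outcome equal the first feature (any
    sensible classifier is perfect); ``"xor"`` makes it the XOR of the two
    features (a depth-1 model cannot learn it); ``"noise"`` is independent.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for year in years:
        f1 = rng.integers(0, 2, n_per_year)
        f2 = rng.integers(0, 2, n_per_year)
        age = rng.uniform(20, 90, n_per_year).round(1)
        if pattern == "separable":
            outcome = f1
        elif pattern == "xor":
            outcome = f1 ^ f2
        else:
            outcome = (rng.random(n_per_year) < 0.2).astype(int)
        for i in range(n_per_year):
            rows.append(
                {
                    "admission_id": f"T{year}{i:04d}",
                    "year": year,
                    "outcome": int(outcome[i]),
                    "chapter::alpha": int(f1[i]),
                    "chapter::beta": int(f2[i]),
                    "age": float(age[i]),
                }
            )
    return pd.DataFrame(rows)
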
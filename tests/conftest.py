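import numpy as np
import pandas as pd
import pytest

from dietfrail import TruthParams, load_taxonomy, simulate_cohort
from dietfrail.simulate import generate_cohort


@pytest.fixture(scope="session")
def taxonomy():
    return load_taxonomy()


@pytest.fixture(scope="session")
def cohort_2k():
    """Fully simulated cohort (diet, frailty, covariates, survival), n=2000."""
    return simulate_cohort(TruthParams(n=2000, seed=42))


@pytest.fixture(scope="session")
def raw_cohort_2k():
    """Cohort without survival columns, n=2000."""
    return generate_cohort(TruthParams(n=2000, seed=7))


def brute_force_quantile(values, x, n_categories):
    """Independent rank-based quantile categorizer used as test oracle.

    Midrank percentile (count below + half the ties, over n) with strict
    greater-than cuts at the equal-probability boundaries.
    """
    values = list(values)
    n = len(values)
    out = []
    for xi in x:
        less = sum(v < xi for v in values)
        eq = sum(v == xi for v in values)
        p = (less + 0.5 * eq) / n
        cat = 1
        for j in range(1, n_categories):
            if p > j / n_categories:
                cat += 1
        out.append(cat)
    return np.array(out)


@pytest.fixture(scope="session")
def intake_row():
    """Single hand-constructed male intake row hitting known AHEI cutpoints."""
    return pd.DataFrame([
        {
            "vegetables": 2.5, "fruit": 2.0, "fruit_juice": 0.25, "whole_grains": 45.0,
            "refined_grains": 1.0, "potatoes": 0.5, "ssb": 0.25, "nuts": 0.25,
            "legumes": 0.25, "tea_coffee": 3.0, "vegetable_oils": 1.0, "sweets": 1.0,
            "red_meat": 0.5, "processed_meat": 0.25, "fish": 0.5, "eggs": 0.5,
            "dairy_low_fat": 1.0, "dairy_high_fat": 0.5, "animal_fat": 0.2,
            "misc_animal": 0.2, "alcohol_g": 14.0, "sodium_mg": 2224.5,
            "trans_fat_pct": 2.25, "pufa_pct": 6.0, "pufa_g": 14.0, "mufa_g": 30.0,
            "sfa_g": 25.0, "n3_g": 0.125, "fiber_g": 18.0, "vitamin_c_mg": 100.0,
            "energy_kcal": 2056.0, "sex": "male",
        }
    ])
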
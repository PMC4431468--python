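import numpy as np
import pandas as pd
import pytest

from safref.cohort import Cohort, validate_cohort
from safref.reference import load_reference_grid
from safref.simulate import default_generator_config, generate_cohort


@pytest.fixture(scope="session")
def reference_grid():
    return load_reference_grid()


@pytest.fixture(scope="session")
def default_config():
    return default_generator_config()


@pytest.fixture(scope="session")
def cohort(default_config):
    """One default-calibrated synthetic cohort, reused across the suite."""
    return generate_cohort(default_config, seed=1)


def make_cohort(saf, gender=None, age=None, sr=None, **overrides) -> Cohort:
    """Minimal valid cohort for unit tests: consistent anthropometrics,
    caller-controlled SAF/gender/age/SR."""
    saf = np.asarray(saf, float)
    n = len(saf)
    df = pd.DataFrame({
        "id": [f"T{i:04d}" for i in range(n)],
        "gender": gender if gender is not None else ["M"] * n,
        "age": age if age is not None else [40] * n,
        "nationality": "Saudi",
        "height": 1.70,
        "weight": 80.0,
        "bmi": 80.0 / 1.70**2,
        "waist": 100.0,
        "hip": 105.0,
        "whr": 100.0 / 105.0,
        "sbp": 120.0,
        "dbp": 80.0,
        "sr": sr if sr is not None else [9.0] * n,
        "saf": saf,
        "diabetes": False,
        "hypertension": False,
        "smoking": False,
        "exercise": "none",
    })
    for key, val in overrides.items():
        df[key] = val
    validate_cohort(df)
    return Cohort(df=df, provenance="unit-test fixture")
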
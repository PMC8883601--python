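import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_records(
    calcium,
    ids=None,
    days=None,
    age=30.0,
    sex="female",
    pregnant=False,
    water=None,
    weight=None,
):
    """Assemble a recall frame from parallel arrays (one row per person-day)."""
    calcium = np.asarray(calcium, dtype=float)
    n = calcium.size
    if ids is None:
        ids = [f"i{j:04d}" for j in range(n)]
    if days is None:
        days = np.ones(n, dtype=int)
    return pd.DataFrame(
        {
            "id": ids,
            "age_years": age,
            "sex": sex,
            "pregnant": pregnant,
            "day": days,
            "calcium_mg": calcium,
            "water_l": np.nan if water is None else water,
            "weight": 1.0 if weight is None else weight,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
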
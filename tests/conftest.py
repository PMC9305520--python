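import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from hdps import CohortTable, DimensionTable, HDPSConfig, generate_study, run_hdps
from hdps.simulate import small_config

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tiny_cohort() -> CohortTable:
    """Ten patients, five exposed, hand-checkable."""
    n = 10
    return CohortTable(
        pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "index_date": pd.Timestamp("2020-06-01"),
                "exposure": [1, 1, 1, 1, 1, 0, 0, 0, 0, 0],
                "event": [1, 0, 1, 0, 0, 1, 0, 0, 0, 0],
                "followup_time": np.linspace(30, 300, n),
                "age_std": np.linspace(-1, 1, n),
                "sex": [0, 1] * 5,
            }
        ),
        predefined=["age_std", "sex"],
    )


def make_dimension(records, name="clinical") -> DimensionTable:
    return DimensionTable(
        name, pd.DataFrame(records, columns=["patient_id", "code", "date"])
    )


@pytest.fixture(scope="session")
def small_study():
    """One simulated confounded study at the scaled-down reference size."""
    return generate_study(small_config(seed=11))


@pytest.fixture(scope="session")
def small_run(small_study):
    cohort, dims, _ = small_study
    return run_hdps(cohort, dims, HDPSConfig(k=30))
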
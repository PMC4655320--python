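import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from popscreen.classification import classify_cohort
from popscreen.growth import GrowthStandard
from popscreen.synthesis import CohortParams, generate_cohort

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_efw_std() -> GrowthStandard:
    """Internally consistent toy EFW-for-GA standard: median 100*GA grams,
    SD 10*GA, natural working scale."""
    return GrowthStandard(
        name="toy_efw",
        kind="efw_for_ga",
        working_scale="natural",
        ga_domain=(14.0, 42.0),
        _location=lambda ga, sex: 100.0 * ga,
        _scale=lambda ga, sex: 10.0 * ga,
    )


@pytest.fixture(scope="session")
def toy_bw_table() -> pd.DataFrame:
    """Toy birthweight reference, linear in GA so interpolation is exact:
    male mean 100*GA, female mean 95*GA, constant SD 400/380."""
    rows = []
    for ga in range(24, 44):
        rows.append({"ga_weeks": ga, "sex": "male", "mean_g": 100.0 * ga, "sd_g": 400.0})
        rows.append({"ga_weeks": ga, "sex": "female", "mean_g": 95.0 * ga, "sd_g": 380.0})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def toy_bw_std(toy_bw_table) -> GrowthStandard:
    return GrowthStandard.from_birthweight_table(toy_bw_table, name="toy_bw")


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortParams(seed=1))


@pytest.fixture(scope="session")
def default_classified(default_cohort):
    c = default_cohort
    return classify_cohort(c.scans, c.outcomes, c.maternal)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortParams(n_subjects=600, seed=11))
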
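from datetime import datetime

import pandas as pd
import pytest

from cews.cohort import CohortConfig, generate_cohort
from cews.io import builtin_definition
from cews.model import ObservationSet
from cews.outcomes import ClinicalEvent


@pytest.fixture(scope="session")
def mcews():
    return builtin_definition("mcews")


@pytest.fixture(scope="session")
def mcews_o2():
    return builtin_definition("mcews_o2")


@pytest.fixture(scope="session")
def ccews():
    return builtin_definition("ccews")


@pytest.fixture(scope="session")
def news():
    return builtin_definition("news")


@pytest.fixture
def median_obs():
    """Observation at the development-set medians; scores 0 on every variable."""
    return ObservationSet(
        admission_id="a1", timestamp=datetime(2015, 3, 1, 8, 0),
        heart_rate=82, respiratory_rate=17, systolic_bp=123, diastolic_bp=70,
        temperature=36.3, spo2=97, avpu="A", on_oxygen=False)


@pytest.fixture(scope="session")
def small_cohort():
    """Session-wide synthetic cohort for cross-module tests."""
    return generate_cohort(CohortConfig(n_admissions=800, seed=11))


def events_from_frame(frame: pd.DataFrame) -> list[ClinicalEvent]:
    return [ClinicalEvent(str(r.admission_id), str(r.event_type),
                          pd.Timestamp(r.timestamp).to_pydatetime())
            for r in frame.itertuples(index=False)]
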
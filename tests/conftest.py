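import numpy as np
import pandas as pd
import pytest

from avisurvey import survey_data as sd
from avisurvey import synthetic_data as syn


def make_minimal_dataset() -> sd.SurveyDataset:
    """1 site, 1 survey, 1 detection."""
    sites = pd.DataFrame([{
        "site_id": "s1", "region": "BC", "mountain": "M1", "habitat": "montane",
        "elevation": 1200.0, "canopy_cover": 70.0, "understory_cover": 20.0,
        "shrub_cover": 10.0, "ground_cover": 40.0, "has_aru": True,
    }])
    surveys = pd.DataFrame([{
        "survey_id": "v1", "site_id": "s1", "method": "PC",
        "date": "2019-06-01", "hours_after_sunrise": 1.0, "wind_score": 0,
        "day_index": 1, "hour_index": pd.NA, "round_index": 1,
        "canopy_at_survey": 70.0,
    }])
    detections = pd.DataFrame([{"survey_id": "v1", "species": "sp1"}])
    families = pd.DataFrame([{"species": "sp1", "family": "fam1"}])
    known = pd.DataFrame([{"habitat": "montane", "species": "sp1"}])
    return sd.SurveyDataset(sites, surveys, detections, families, known)


@pytest.fixture
def minimal_dataset():
    return make_minimal_dataset()


@pytest.fixture(scope="session")
def bc_dataset():
    return syn.generate_scenario("BC", seed=1)


@pytest.fixture(scope="session")
def chile_dataset():
    return syn.generate_scenario("Chile", seed=2)


def random_incidence(rng: np.random.Generator, T: int | None = None,
                     S: int | None = None) -> sd.IncidenceFrequencies:
    """Small random incidence matrix guaranteed non-empty."""
    T = T or int(rng.integers(2, 9))
    S = S or int(rng.integers(1, 7))
    while True:
        M = rng.random((T, S)) < rng.uniform(0.2, 0.8)
        if M.any():
            return sd.IncidenceFrequencies.from_matrix("rand", M)
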
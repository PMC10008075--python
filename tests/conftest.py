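import numpy as np
import pandas as pd
import pytest

from parosim import Cohort, simulate_cohort
from parosim.config import SimulationConfig


def tiny_tables():
    """Hand-written 2-participant x 3-descriptor cohort."""
    responses = pd.DataFrame(
        {
            "participant_id": ["p1", "p1", "p1", "p2", "p2", "p2"],
            "descriptor_id": ["a", "b", "c", "a", "b", "c"],
            "response": [
                "normal",
                "qualitatively_different",
                "odorless",
                "unknown",
                "normal",
                "qualitatively_different",
            ],
        }
    )
    descriptors = pd.DataFrame(
        {
            "descriptor_id": ["a", "b", "c"],
            "label": ["coffee", "fish", "rose"],
            "oai": [1.2, 0.3, -0.5],
            "osi": [0.1, 0.9, 0.4],
            "valence": [6.0, 3.0, 8.0],
            "arousal": [4.0, 5.0, 3.0],
            "olfactory": [4.5, 3.0, 4.0],
            "gustatory": [4.0, 3.5, 0.5],
        }
    )
    participants = pd.DataFrame(
        {
            "participant_id": ["p1", "p2"],
            "age": [44.0, 57.0],
            "sex": ["F", "M"],
            "bmi": [24.0, 28.0],
            "tdi": [18.5, 25.0],
            "threshold": [2.0, 5.0],
            "duration_months": [6.0, 14.0],
            "parosmia_intensity": [7.0, 3.0],
            "parosmia_frequency": ["daily", "not_daily"],
            "parosmia_consequences": [1.0, 0.0],
            "parosmia_valence": [-4.0, -1.0],
            "subjective_impairment": [8.0, np.nan],
            "importance_olfaction": [22.0, 15.0],
            "depression_adsl": [12.0, 30.0],
        }
    )
    return responses, descriptors, participants


@pytest.fixture
def tiny_cohort():
    return Cohort(*tiny_tables()).validate()


@pytest.fixture
def tiny_cohort_files(tmp_path):
    responses, descriptors, participants = tiny_tables()
    paths = {}
    for name, df in (
        ("responses", responses),
        ("descriptors", descriptors),
        ("participants", participants),
    ):
        p = tmp_path / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort (48 patients, 38 descriptors)."""
    return simulate_cohort(SimulationConfig(), seed=1)


def small_config(**overrides) -> SimulationConfig:
    cfg = SimulationConfig(n_participants=6, n_descriptors=5)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg.validate()
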
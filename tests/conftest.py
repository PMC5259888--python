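import numpy as np
import pandas as pd
import pytest

from prev2inc.simulate import (
    default_standard_population,
    mi_like_scenario,
    survival_table_from_scenario,
)


@pytest.fixture(scope="session")
def scenario():
    """Deterministic MI-like default scenario (7 waves, 10 strata)."""
    return mi_like_scenario()


@pytest.fixture(scope="session")
def scenario_survival(scenario):
    return survival_table_from_scenario(scenario)


@pytest.fixture(scope="session")
def scenario_standard(scenario):
    return default_standard_population(scenario)


@pytest.fixture
def two_stratum_tables():
    """Minimal matched prevalence/survival tables for two strata."""
    prev0 = pd.DataFrame(
        {
            "sex": ["F", "M"],
            "age_lo": [35.0, 35.0],
            "age_hi": [45.0, 45.0],
            "wave_start_year": [1999, 1999],
            "wave_label": ["1999–2000", "1999–2000"],
            "p": [0.0, 0.02],
            "n": [400, 400],
        }
    )
    prevT = prev0.assign(
        wave_start_year=2001, wave_label="2001–2002", p=[0.01, 0.035]
    )
    surv = pd.DataFrame(
        {
            "sex": ["F", "M"],
            "age_lo": [35.0, 35.0],
            "age_hi": [45.0, 45.0],
            "SP": [0.9, 0.85],
            "SN": [0.99, 0.985],
            "T": [2.0, 2.0],
        }
    )
    return prev0, prevT, surv


def stratum_weights(scenario, standard):
    """Standard-population weights aligned to the scenario's strata order."""
    counts = standard.table.set_index(["sex", "age_lo"])["count"]
    w = np.array(
        [counts.loc[(s, lo)] for s, lo in zip(scenario.strata["sex"], scenario.strata["age_lo"])],
        dtype=float,
    )
    return w / w.sum()
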
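import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from hipdd import synth

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> synth.SimulationConfig:
    """A desk-sized registry: 25 municipalities, 3 treated, 12 years."""
    return synth.SimulationConfig(
        n_municipalities=25,
        n_treated=3,
        year_start=1999,
        year_end=2010,
        intervention_year=2005,
        population_mean=900.0,
        population_sd=400.0,
        decoy_rate=0.3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    panel, truth = synth.simulate_panel(small_config)
    return panel, truth


def make_panel_slice(rates: dict, population: int = 1000,
                     treated: set = frozenset()) -> pd.DataFrame:
    """Build a one-stratum panel from {municipality_id: {year: rate}}."""
    rows = []
    for mid, series in rates.items():
        for year, rate in series.items():
            rows.append({
                "municipality_id": mid,
                "year": year,
                "age_group": "65+",
                "sex": "both",
                "cases": rate * population / 1e5,
                "population": population,
                "rate": float(rate),
                "treated": mid in treated,
            })
    return pd.DataFrame(rows)
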
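import numpy as np
import pandas as pd
import pytest

from luciav.cohorts import Cohort, LandState, RegionState
from luciav.config import biome_params
from luciav.forcing import SCHEDULE_COLUMNS, ClimateAnomalySeries, TransitionSchedule


@pytest.fixture
def tropical_params():
    """Tropical biome parameters with climate sensitivities switched off."""
    return biome_params("tropical")


@pytest.fixture
def forest_region(tropical_params):
    """100 Mha intact forest + 50 Mha intact grass + 50 Mha old agriculture."""
    p = tropical_params
    cohorts = [
        Cohort("intact_forest", age=300, area=100.0, agb=p.b_max,
               bgb=p.b_max * p.root_shoot, litter=p.litter_eq_forest, soil=p.soil_eq_forest),
        Cohort("intact_grass", age=300, area=50.0, agb=p.grass_b_max,
               bgb=p.grass_b_max * p.root_shoot, soil=p.soil_eq_grass),
        Cohort("permanent_agri", age=300, area=50.0, soil=p.soil_eq_agri),
    ]
    return RegionState(params=p, cohorts=cohorts)


@pytest.fixture
def forest_state(forest_region):
    return LandState({"tropics": forest_region}, year=1850)


def zero_climate(n_years: int, start_year: int = 1850) -> ClimateAnomalySeries:
    years = start_year + np.arange(n_years)
    return ClimateAnomalySeries(years, np.zeros(n_years), np.zeros(n_years))


def schedule_from_events(events, years, region="tropics") -> TransitionSchedule:
    """Build a TransitionSchedule from (year, kind, amount) event dicts."""
    col_of = {
        "clear": "area_deforested",
        "grass_to_agri": "area_grass_to_agri",
        "abandon_to_grass": "area_agri_to_grass",
        "abandon_to_forest": "area_afforested",
        "fuel": "fuelwood_harvest",
        "industrial": "industrialwood_harvest",
    }
    table = pd.DataFrame({"year": years, "region": region})
    for c in SCHEDULE_COLUMNS[2:]:
        table[c] = 0.0
    table = table.set_index("year")
    for ev in events:
        table.loc[ev["year"], col_of[ev["kind"]]] += ev["amount"]
    return TransitionSchedule(table.reset_index())
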
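"""Delimited-text readers and writers for the interchange tables.

All tables are plain comma-separated text with a header row, "." as the
decimal point and no thousands separators.  Column orders are fixed:

* climate:  year, tas_anom, wet_anom
* schedule: year, region, area_deforested, area_afforested,
  area_grass_to_agri, area_agri_to_grass, fuelwood_harvest,
  industrialwood_harvest, sc_rotation_area
* budget:   year, e_fuel, s_air, s_ocean
* fluxes:   year, e_fire, e_wood, e_legacy, s_recov, e_luc, s_intact, s_net
* land-state snapshot: region, land_class, age, age_bin, area, agb, bgb,
  litter, soil, soil_legacy (one row per cohort)
"""

from __future__ import annotations

import pandas as pd

from .cohorts import Cohort, LandState, RegionParams, RegionState
from .fluxes import FLUX_COLUMNS
from .forcing import (
    SCHEDULE_COLUMNS,
    BudgetSeries,
    ClimateAnomalySeries,
    TransitionSchedule,
)

__all__ = [
    "write_climate",
    "read_climate",
    "write_schedule",
    "read_schedule",
    "write_budget",
    "read_budget",
    "write_fluxes",
    "read_fluxes",
    "write_state",
    "read_state",
]

STATE_COLUMNS = [
    "region",
    "land_class",
    "age",
    "age_bin",
    "area",
    "agb",
    "bgb",
    "litter",
    "soil",
    "soil_legacy",
]


def write_climate(series: ClimateAnomalySeries, path: str) -> None:
    series.to_frame().to_csv(path, index=False)


def read_climate(path: str) -> ClimateAnomalySeries:
    return ClimateAnomalySeries.from_frame(pd.read_csv(path))


def write_schedule(schedule: TransitionSchedule, path: str) -> None:
    schedule.table[SCHEDULE_COLUMNS].to_csv(path, index=False)


def read_schedule(path: str) -> TransitionSchedule:
    return TransitionSchedule(pd.read_csv(path))


def write_budget(budget: BudgetSeries, path: str) -> None:
    budget.to_frame().to_csv(path, index=False)


def read_budget(path: str) -> BudgetSeries:
    return BudgetSeries.from_frame(pd.read_csv(path))


def write_fluxes(fluxes: pd.DataFrame, path: str) -> None:
    df = fluxes.reset_index() if "year" not in fluxes.columns else fluxes
    df[FLUX_COLUMNS].to_csv(path, index=False)


def read_fluxes(path: str) -> pd.DataFrame:
    return pd.read_csv(path)[FLUX_COLUMNS]


def write_state(state: LandState, path: str) -> None:
    rows = []
    for name, region in state.regions.items():
        for c in region.cohorts:
            rows.append(
                {
                    "region": name,
                    "land_class": c.land_class,
                    "age": c.age,
                    "age_bin": c.age_bin,
                    "area": c.area,
                    "agb": c.agb,
                    "bgb": c.bgb,
                    "litter": c.litter,
                    "soil": c.soil,
                    "soil_legacy": c.soil_legacy,
                }
            )
    pd.DataFrame(rows, columns=STATE_COLUMNS).to_csv(path, index=False)


def read_state(
    path: str, params: dict[str, RegionParams], year: int = 0
) -> LandState:
    """Rebuild a land state from a snapshot; region parameters are supplied
    by the caller (they are configuration, not state)."""
    df = pd.read_csv(path)
    regions: dict[str, RegionState] = {}
    for name, sub in df.groupby("region"):
        cohorts = [
            Cohort(
                row["land_class"],
                age=int(row["age"]),
                area=float(row["area"]),
                agb=float(row["agb"]),
                bgb=float(row["bgb"]),
                litter=float(row["litter"]),
                soil=float(row["soil"]),
                soil_legacy=float(row["soil_legacy"]),
            )
            for _, row in sub.iterrows()
        ]
        regions[name] = RegionState(params=params[name], cohorts=cohorts)
    return LandState(regions, year=year)
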
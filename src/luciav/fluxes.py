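"""Annual flux accounting and the year-by-year simulator.

The component fluxes follow the bookkeeping decomposition of net land-use
emissions::

    E_LUC = E_fire + E_wood + E_legacy - S_recov
    S_net = S_Intact - E_LUC

with E terms positive toward the atmosphere and S terms positive toward the
land.  Every flux computed here corresponds one-to-one to a change of a
carbon stock (cohort pools, wood-product pools), so total carbon is conserved
to rounding error over a run of any length.

Climate modulation is linear in the anomalies and clipped at zero: uptake
terms scale with ``g = max(0, 1 + alpha_T T' + alpha_W W')`` and
heterotrophic-respiration terms with ``h = max(0, 1 + beta_T T' - beta_W W')``.
With all coefficients zero the simulator degenerates to a pure bookkeeping
model whose output is a sum of fixed per-event response curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import cohorts as ck
from .cohorts import (
    AGRI_CLASSES,
    INTACT_CLASSES,
    MHA_MG_TO_PG,
    SECONDARY_CLASSES,
    ClassSens,
    LandState,
    RegionState,
)
from .forcing import ClimateAnomalySeries, TransitionSchedule
from .wood import WoodProductPools

__all__ = [
    "FLUX_COLUMNS",
    "SimulationOptions",
    "SimulationResult",
    "climate_factor_uptake",
    "climate_factor_respiration",
    "decay_wood_products",
    "legacy_emission",
    "recovery_sink",
    "intact_sink",
    "aggregate",
    "run_simulation",
    "linear_ramp",
]

#: column order of the flux interchange table
FLUX_COLUMNS = ["year", "e_fire", "e_wood", "e_legacy", "s_recov", "e_luc", "s_intact", "s_net"]


def climate_factor_uptake(t_anom: float, w_anom: float, sens: ClassSens) -> float:
    """Uptake multiplier ``g = max(0, 1 + alpha_T T' + alpha_W W')``."""
    if not (np.isfinite(t_anom) and np.isfinite(w_anom)):
        raise ValueError("climate anomalies must be finite")
    return sens.uptake(t_anom, w_anom)


def climate_factor_respiration(t_anom: float, w_anom: float, sens: ClassSens) -> float:
    """Respiration multiplier ``h = max(0, 1 + beta_T T' - beta_W W')``."""
    if not (np.isfinite(t_anom) and np.isfinite(w_anom)):
        raise ValueError("climate anomalies must be finite")
    return sens.respiration(t_anom, w_anom)


def decay_wood_products(pools: WoodProductPools, year: int | None = None) -> tuple[WoodProductPools, float]:
    """Advance the product pools one year; return ``(pools, e_wood)`` in Pg C."""
    return pools, pools.step()


def legacy_emission(region: RegionState, t_anom: float, w_anom: float) -> float:
    """Net emission over agricultural land (opposite of agricultural NBP), Pg C.

    Decomposition of the inherited litter and legacy-soil pools (first-order,
    respiration-modulated) plus the background respiration/uptake imbalance
    of the standing agriculture.  The background net uptake is added to the
    agricultural soil pool so the flux matches a stock change exactly.
    Permanent (pre-industrial) agriculture is included by definition.
    """
    p = region.params
    s = p.sens.agri
    h = s.respiration(t_anom, w_anom)
    g = s.uptake(t_anom, w_anom)
    e_legacy = 0.0
    for c in region.cohorts:
        if c.land_class not in AGRI_CLASSES:
            continue
        litter_em = min(p.k_litter * c.litter * h, c.litter)
        legacy_em = min(p.k_soil_legacy * c.soil_legacy * h, c.soil_legacy)
        net_bg = p.npp_agri * g - p.rh_agri * h  # Mg C/ha; may be negative
        if c.soil + net_bg < 0.0:
            net_bg = -c.soil
        c.litter -= litter_em
        c.soil_legacy -= legacy_em
        c.soil += net_bg
        e_legacy += c.area * (litter_em + legacy_em - net_bg) * MHA_MG_TO_PG
    return e_legacy


def recovery_sink(
    region: RegionState, t_anom: float, w_anom: float, biomass_uptake: float
) -> float:
    """NBP of recovering secondary forest, grassland and fallow, Pg C.

    ``biomass_uptake`` is the regrowth increment already applied by
    :func:`luciav.cohorts.regrow_and_age`.  On top of it the secondary litter
    pool decays (respiration-modulated) and the soil pool relaxes toward the
    class equilibrium (uptake-modulated); inherited legacy soil keeps
    decaying.  The result may be negative shortly after a disturbance, when
    slash decomposition outweighs regrowth.
    """
    p = region.params
    s = p.sens.secondary
    h = s.respiration(t_anom, w_anom)
    g = s.uptake(t_anom, w_anom)
    s_recov = biomass_uptake
    for c in region.cohorts:
        if c.land_class not in SECONDARY_CLASSES:
            continue
        soil_eq = p.soil_eq_grass if c.land_class == "secondary_grass" else p.soil_eq_forest
        litter_em = min(p.k_litter * c.litter * h, c.litter)
        legacy_em = min(p.k_soil_legacy * c.soil_legacy * h, c.soil_legacy)
        soil_up = p.k_soil_legacy * max(0.0, soil_eq - c.soil) * g
        c.litter -= litter_em
        c.soil_legacy -= legacy_em
        c.soil += soil_up
        s_recov += c.area * (soil_up - litter_em - legacy_em) * MHA_MG_TO_PG
    return s_recov


def intact_sink(
    region: RegionState, t_anom: float, w_anom: float, background_rate: float
) -> float:
    """Environmental-change sink over intact forest and grassland, Pg C.

    ``background_rate`` (Mg C ha-1 yr-1) is an exogenous, slowly rising
    uptake standing in for CO2 fertilization, climate trends and nitrogen
    deposition; it is modulated by the intact uptake multiplier and banked in
    the intact soil pool.
    """
    if background_rate < 0:
        raise ValueError("background sink rate must be non-negative")
    g = region.params.sens.intact.uptake(t_anom, w_anom)
    s_intact = 0.0
    for c in region.cohorts:
        if c.land_class not in INTACT_CLASSES:
            continue
        up = background_rate * g
        c.soil += up
        s_intact += c.area * up * MHA_MG_TO_PG
    return s_intact


def aggregate(components: pd.DataFrame) -> pd.DataFrame:
    """Fill ``e_luc`` and ``s_net`` from the component fluxes.

    ``components`` must hold per-year ``e_fire``, ``e_wood``, ``e_legacy``,
    ``s_recov`` and ``s_intact`` columns indexed or keyed by year.
    """
    df = components.copy()
    if "year" in df.columns:
        df = df.set_index("year")
    required = ["e_fire", "e_wood", "e_legacy", "s_recov", "s_intact"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing component columns {missing}")
    if df.index.duplicated().any():
        raise ValueError("component series misaligned: duplicate years")
    df["e_luc"] = df["e_fire"] + df["e_wood"] + df["e_legacy"] - df["s_recov"]
    df["s_net"] = df["s_intact"] - df["e_luc"]
    return df.reset_index()[FLUX_COLUMNS]


def linear_ramp(start_year: int, end_year: int, r0: float, r1: float) -> Callable[[int], float]:
    """Background-sink trajectory rising linearly from ``r0`` to ``r1`` Mg C/ha/yr."""

    def rate(year: int) -> float:
        if end_year == start_year:
            return r1
        f = np.clip((year - start_year) / (end_year - start_year), 0.0, 1.0)
        return r0 + (r1 - r0) * float(f)

    return rate


@dataclass
class SimulationOptions:
    """Run-time switches of the simulator.

    ``mode='sc'`` activates the shifting-cultivation rotation (tropical
    regions, ``sc_rotation``-year cycle); ``bookkeeping=True`` zeroes all
    climate sensitivities, reducing the run to a classical bookkeeping model;
    ``wood_decay`` selects the product-pool release mode.
    """

    mode: str = "baseline"
    wood_decay: str = "uniform"
    bookkeeping: bool = False
    sc_rotation: int = 20
    promote_threshold: float = 0.9
    background_rate: Callable[[int], float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("baseline", "sc"):
            raise ValueError("mode must be 'baseline' or 'sc'")
        if self.wood_decay not in ("exponential", "uniform"):
            raise ValueError("wood_decay must be 'exponential' or 'uniform'")


@dataclass
class SimulationResult:
    fluxes: pd.DataFrame
    diagnostics: pd.DataFrame
    state: LandState

    def flux_series(self, name: str) -> pd.Series:
        return self.fluxes.set_index("year")[name]


def run_simulation(
    state: LandState,
    schedule: TransitionSchedule,
    climate: ClimateAnomalySeries,
    options: SimulationOptions | None = None,
) -> SimulationResult:
    """Run the cohort simulator year by year over the climate span.

    Within each year the operation order is: land-use transitions and
    harvest, the optional shifting-cultivation step, wood-product release,
    regrowth and aging, agricultural/secondary/intact flux accounting, and
    intact promotion.  The run is deterministic given the forcing.
    """
    options = options or SimulationOptions()
    state = state.copy()
    if options.bookkeeping:
        for r in state.regions.values():
            r.params.sens = r.params.sens.zeroed()
    for r in state.regions.values():
        r.pools.decay_mode = options.wood_decay
    bg_rate = options.background_rate or (lambda year: 0.0)

    years = climate.years
    sched_years = set(int(y) for y in schedule.years)
    rows = []
    diag_rows = []
    for year in years:
        year = int(year)
        t_anom, w_anom = climate.at(year)
        e_fire = e_wood = e_legacy = s_recov = s_intact = 0.0
        for name, region in state.regions.items():
            if year in sched_years:
                ev = schedule.events_for(year, name)
            else:
                ev = None
            if ev is not None:
                ef, _ = ck.apply_clearing(region, float(ev["area_deforested"]), "cropland")
                e_fire += ef
                ck.apply_grass_agri_transition(
                    region, float(ev["area_grass_to_agri"]), "to_agri"
                )
                ck.apply_abandonment(
                    region, float(ev["area_agri_to_grass"]), target="secondary_grass"
                )
                ck.apply_abandonment(
                    region, float(ev["area_afforested"]), target="secondary_forest"
                )
                ef, _ = ck.harvest_wood(region, float(ev["fuelwood_harvest"]), "fuel", year)
                e_fire += ef
                ck.harvest_wood(region, float(ev["industrialwood_harvest"]), "industrial", year)
                if options.mode == "sc" and region.params.biome == "tropical":
                    ef, _ = ck.step_shifting_cultivation(
                        region, float(ev["sc_rotation_area"]), options.sc_rotation
                    )
                    e_fire += ef
            _, ew = decay_wood_products(region.pools, year)
            e_wood += ew
            uptake = ck.regrow_and_age(region, t_anom, w_anom)
            e_legacy += legacy_emission(region, t_anom, w_anom)
            s_recov += recovery_sink(region, t_anom, w_anom, uptake)
            s_intact += intact_sink(region, t_anom, w_anom, bg_rate(year))
            ck.promote_to_intact(region, options.promote_threshold)
        state.year = year
        rows.append(
            {
                "year": year,
                "e_fire": e_fire,
                "e_wood": e_wood,
                "e_legacy": e_legacy,
                "s_recov": s_recov,
                "s_intact": s_intact,
            }
        )
        area_intact = sum(r.area_of(*INTACT_CLASSES) for r in state.regions.values())
        area_sec = sum(r.area_of(*SECONDARY_CLASSES) for r in state.regions.values())
        area_agri = sum(r.area_of(*AGRI_CLASSES) for r in state.regions.values())
        diag_rows.append(
            {
                "year": year,
                "area_intact": area_intact,
                "area_secondary": area_sec,
                "area_agri": area_agri,
                "nbp_intact_per_mha": s_intact / area_intact if area_intact > 0 else np.nan,
                "nbp_secondary_per_mha": s_recov / area_sec if area_sec > 0 else np.nan,
                "nbp_agri_per_mha": -e_legacy / area_agri if area_agri > 0 else np.nan,
                "land_carbon_pg": state.carbon_pg(),
                "product_pool_pg": sum(r.pools.total() for r in state.regions.values()),
            }
        )
    fluxes = aggregate(pd.DataFrame(rows))
    return SimulationResult(fluxes, pd.DataFrame(diag_rows), state)
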
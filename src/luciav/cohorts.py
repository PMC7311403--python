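"""Sub-grid land state: age cohorts per land class, and land-use transitions.

The land surface of each region is represented as a list of cohorts — one
land class at one age, carrying an area (Mha) and carbon densities
(Mg C ha-1) for aboveground biomass, belowground biomass, litter/slash, soil,
and a "legacy" soil pool inherited from a former land class.  All land-use
operations conserve area exactly and conserve carbon exactly: whatever leaves
the vegetation either goes to the atmosphere (returned as a flux increment in
Pg C), to a litter pool, or to the wood-product pools.

Clearing drains intact forest first, then secondary forest from the oldest
cohort down; grassland/agriculture conversions burn nothing and draw young
cohorts first; wood harvest starts from intact forest and moves to younger
cohorts.  Secondary vegetation regrows along a Chapman–Richards potential
curve and is promoted back to the intact class once its aboveground biomass
exceeds 90% of the maximum attainable value.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .wood import WoodProductPools

__all__ = [
    "MHA_MG_TO_PG",
    "FOREST_AGE_BINS",
    "RegionParams",
    "ClassSens",
    "SensitivityParams",
    "Cohort",
    "RegionState",
    "LandState",
    "chapman_richards",
    "promotion_age",
    "apply_clearing",
    "apply_grass_agri_transition",
    "apply_abandonment",
    "harvest_wood",
    "regrow_and_age",
    "promote_to_intact",
    "step_shifting_cultivation",
    "relabel_secondary_fraction",
]

#: 1 Mha x 1 Mg C ha-1 = 1e6 ha * 1 Mg C/ha = 1e6 Mg C = 1e-3 Pg C
MHA_MG_TO_PG = 1.0e-3

#: upper edges of the six forest age bins (years); the last bin is open
FOREST_AGE_BINS = (10, 20, 40, 70, 150, math.inf)

FOREST_CLASSES = ("intact_forest", "secondary_forest", "fallow_secondary")
GRASS_CLASSES = ("intact_grass", "secondary_grass")
AGRI_CLASSES = ("cropland", "pasture", "permanent_agri")
LAND_CLASSES = FOREST_CLASSES + GRASS_CLASSES + AGRI_CLASSES

#: classes whose net biome production counts toward the recovery sink
SECONDARY_CLASSES = ("secondary_forest", "fallow_secondary", "secondary_grass")
INTACT_CLASSES = ("intact_forest", "intact_grass")


@dataclass
class ClassSens:
    """Linear climate-sensitivity coefficients of one land-class group.

    The uptake multiplier is ``g = max(0, 1 + alpha_t*T' + alpha_w*W')``
    (alpha_t < 0: warm years depress uptake) and the heterotrophic-respiration
    multiplier is ``h = max(0, 1 + beta_t*T' - beta_w*W')`` (warm and dry
    years enhance decomposition).
    """

    alpha_t: float = 0.0
    alpha_w: float = 0.0
    beta_t: float = 0.0
    beta_w: float = 0.0

    def uptake(self, t_anom: float, w_anom: float) -> float:
        return max(0.0, 1.0 + self.alpha_t * t_anom + self.alpha_w * w_anom)

    def respiration(self, t_anom: float, w_anom: float) -> float:
        return max(0.0, 1.0 + self.beta_t * t_anom - self.beta_w * w_anom)


@dataclass
class SensitivityParams:
    """Per-land-class-group climate sensitivities (agricultural > secondary > intact)."""

    agri: ClassSens = field(default_factory=ClassSens)
    secondary: ClassSens = field(default_factory=ClassSens)
    intact: ClassSens = field(default_factory=ClassSens)

    def zeroed(self) -> "SensitivityParams":
        """Bookkeeping limit: all climate responses switched off."""
        return SensitivityParams()

    def for_class(self, land_class: str) -> ClassSens:
        if land_class in AGRI_CLASSES:
            return self.agri
        if land_class in SECONDARY_CLASSES:
            return self.secondary
        return self.intact


@dataclass
class RegionParams:
    """Biome-level parameters of one region.

    Densities are Mg C ha-1, rates yr-1, areas Mha.  ``b_max`` is the maximum
    attainable aboveground biomass; the regrowth curve is Chapman–Richards
    ``B_pot(a) = b_max * (1 - exp(-k a))**theta`` with ``k`` calibrated per
    biome so the 90%-of-maximum intact threshold is crossed near the biome
    age (70/90/160 yr for tropical/temperate/boreal).
    """

    biome: str = "tropical"
    b_max: float = 150.0
    root_shoot: float = 0.25
    growth_k: float = 0.042424
    growth_theta: float = 2.0
    f_burn: float = 0.5
    soil_eq_forest: float = 100.0
    soil_eq_agri: float = 60.0
    soil_eq_grass: float = 80.0
    litter_eq_forest: float = 6.0
    k_litter: float = 0.3
    k_soil_legacy: float = 0.06
    intact_age: float = 70.0
    grass_b_max: float = 4.0
    grass_k: float = 0.297
    wood_frac: float = 0.8
    product_split_10: float = 0.5
    npp_agri: float = 5.0
    rh_agri: float = 5.0
    sens: SensitivityParams = field(default_factory=SensitivityParams)

    def __post_init__(self) -> None:
        if self.biome not in ("tropical", "temperate", "boreal"):
            raise ValueError(f"unknown biome {self.biome!r}")
        if self.b_max <= 0:
            raise ValueError("b_max must be positive")
        if not 0.0 <= self.f_burn <= 1.0:
            raise ValueError("f_burn must lie in [0, 1]")
        for name in ("k_litter", "k_soil_legacy"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if not 0.0 <= self.product_split_10 <= 1.0:
            raise ValueError("product_split_10 must lie in [0, 1]")

    def b_pot(self, age: float, land_class: str = "secondary_forest") -> float:
        if land_class == "secondary_grass":
            return chapman_richards(age, self.grass_b_max, self.grass_k, self.growth_theta)
        return chapman_richards(age, self.b_max, self.growth_k, self.growth_theta)

    def class_b_max(self, land_class: str) -> float:
        return self.grass_b_max if land_class in GRASS_CLASSES else self.b_max


def chapman_richards(age: float, b_max: float, k: float, theta: float) -> float:
    """Potential aboveground biomass at a given stand age (Mg C ha-1)."""
    if age <= 0:
        return 0.0
    return b_max * (1.0 - math.exp(-k * age)) ** theta


def promotion_age(params: RegionParams, threshold: float = 0.9) -> int:
    """First integer age at which the potential curve reaches ``threshold * b_max``."""
    # invert (1 - exp(-k a))**theta = threshold
    a = -math.log(1.0 - threshold ** (1.0 / params.growth_theta)) / params.growth_k
    return int(math.ceil(a))


@dataclass
class Cohort:
    """One land class at one age: area plus carbon densities."""

    land_class: str
    age: int = 0
    area: float = 0.0  # Mha
    agb: float = 0.0  # Mg C ha-1 aboveground biomass
    bgb: float = 0.0  # Mg C ha-1 belowground biomass
    litter: float = 0.0  # Mg C ha-1 litter/slash
    soil: float = 0.0  # Mg C ha-1 soil carbon
    soil_legacy: float = 0.0  # Mg C ha-1 excess soil inherited from prior class

    def __post_init__(self) -> None:
        if self.land_class not in LAND_CLASSES:
            raise ValueError(f"unknown land class {self.land_class!r}")
        for name in ("area", "agb", "bgb", "litter", "soil", "soil_legacy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def age_bin(self) -> int:
        """Reporting bin: six bins for forest classes, two for herbaceous."""
        if self.land_class in FOREST_CLASSES:
            if self.land_class == "intact_forest":
                return len(FOREST_AGE_BINS) - 1
            for i, edge in enumerate(FOREST_AGE_BINS):
                if self.age <= edge:
                    return i
        # herbaceous: bin 1 = permanent/intact, bin 0 = post-transition
        return 1 if self.land_class in ("intact_grass", "permanent_agri") else 0

    def carbon_pg(self) -> float:
        """Total carbon stock of the cohort (Pg C)."""
        dens = self.agb + self.bgb + self.litter + self.soil + self.soil_legacy
        return self.area * dens * MHA_MG_TO_PG


@dataclass
class RegionState:
    params: RegionParams
    cohorts: list[Cohort] = field(default_factory=list)
    pools: WoodProductPools = field(default_factory=WoodProductPools)

    def total_area(self) -> float:
        return sum(c.area for c in self.cohorts)

    def area_of(self, *classes: str) -> float:
        return sum(c.area for c in self.cohorts if c.land_class in classes)

    def carbon_pg(self) -> float:
        return sum(c.carbon_pg() for c in self.cohorts) + self.pools.total()

    def drop_empty(self, tol: float = 1e-12) -> None:
        self.cohorts = [c for c in self.cohorts if c.area > tol]

    def merge_same_age(self) -> None:
        """Merge cohorts sharing (class, age) with area-weighted densities.

        Mass-conserving: summed area times the area-weighted mean density
        equals the sum of the individual pools exactly.
        """
        groups: dict[tuple[str, int], list[Cohort]] = {}
        for c in self.cohorts:
            groups.setdefault((c.land_class, c.age), []).append(c)
        merged: list[Cohort] = []
        for (cls, age), cs in groups.items():
            if len(cs) == 1:
                merged.append(cs[0])
                continue
            area = sum(c.area for c in cs)
            if area <= 0:
                continue
            kw = {}
            for pool in ("agb", "bgb", "litter", "soil", "soil_legacy"):
                kw[pool] = sum(c.area * getattr(c, pool) for c in cs) / area
            merged.append(Cohort(cls, age=age, area=area, **kw))
        self.cohorts = merged


@dataclass
class LandState:
    """Closed-system land state: regions of cohorts plus wood-product pools."""

    regions: dict[str, RegionState]
    year: int = 1850

    def copy(self) -> "LandState":
        return copy.deepcopy(self)

    def total_area(self) -> float:
        return sum(r.total_area() for r in self.regions.values())

    def carbon_pg(self) -> float:
        return sum(r.carbon_pg() for r in self.regions.values())


# ---------------------------------------------------------------------------
# transition operations
# ---------------------------------------------------------------------------


def _clearing_order(region: RegionState) -> list[Cohort]:
    """Intact forest first, then secondary forest oldest to youngest."""
    intact = [c for c in region.cohorts if c.land_class == "intact_forest"]
    secondary = sorted(
        (c for c in region.cohorts if c.land_class in ("secondary_forest", "fallow_secondary")),
        key=lambda c: -c.age,
    )
    return intact + secondary


def _drain_to_agri(
    region: RegionState,
    donors: list[Cohort],
    area: float,
    target: str,
    burn: bool,
) -> tuple[float, float]:
    """Move ``area`` Mha from donor cohorts into a new age-0 agri cohort.

    Returns ``(e_fire, litter_transfer)`` in Pg C.  With ``burn`` a fraction
    ``f_burn`` of the donors' aboveground biomass is emitted immediately;
    everything else (unburned AGB, roots, donor litter) lands in the new
    cohort's litter pool.  Donor soil up to the agricultural equilibrium stays
    as soil; the excess becomes the legacy soil pool.
    """
    p = region.params
    remaining = area
    e_fire = 0.0
    litter_c = 0.0  # Pg
    soil_c = 0.0
    legacy_c = 0.0
    for donor in donors:
        if remaining <= 1e-12:
            break
        take = min(donor.area, remaining)
        if take <= 0:
            continue
        f_burn = p.f_burn if burn else 0.0
        e_fire += take * donor.agb * f_burn * MHA_MG_TO_PG
        litter_c += take * (donor.agb * (1.0 - f_burn) + donor.bgb + donor.litter) * MHA_MG_TO_PG
        donor_soil = donor.soil + donor.soil_legacy
        soil_c += take * min(donor_soil, p.soil_eq_agri) * MHA_MG_TO_PG
        legacy_c += take * max(0.0, donor_soil - p.soil_eq_agri) * MHA_MG_TO_PG
        donor.area -= take
        remaining -= take
    cleared = area - remaining
    if cleared > 1e-12:
        region.cohorts.append(
            Cohort(
                target,
                age=0,
                area=cleared,
                agb=0.0,
                bgb=0.0,
                litter=litter_c / cleared / MHA_MG_TO_PG,
                soil=soil_c / cleared / MHA_MG_TO_PG,
                soil_legacy=legacy_c / cleared / MHA_MG_TO_PG,
            )
        )
    region.drop_empty()
    return e_fire, litter_c


def apply_clearing(
    region: RegionState, area: float, target: str = "cropland"
) -> tuple[float, float]:
    """Clear forest into agricultural land.

    Intact forest is cleared first, then secondary forest from the oldest
    cohort downwards.  A fraction ``f_burn`` of the cleared aboveground
    biomass is emitted in the clearing year (returned as ``e_fire`` in Pg C);
    unburned residues and root biomass are transferred to the new
    agricultural cohort's litter pool (returned as ``litter_transfer``).
    """
    if area < 0:
        raise ValueError("clearing area must be non-negative")
    if area <= 1e-12:
        return 0.0, 0.0
    if target not in AGRI_CLASSES:
        raise ValueError(f"clearing target must be agricultural, got {target!r}")
    avail = region.area_of(*FOREST_CLASSES)
    if area > avail + 1e-9:
        raise ValueError(
            f"requested clearing of {area:g} Mha exceeds available forest "
            f"{avail:g} Mha (deficit {area - avail:g} Mha)"
        )
    return _drain_to_agri(region, _clearing_order(region), min(area, avail), target, burn=True)


def apply_grass_agri_transition(
    region: RegionState, area: float, direction: str, target: str = "cropland"
) -> float:
    """Convert natural grassland to agriculture (``to_agri``) or abandon
    agriculture to grassland (``abandon``); no fire in either direction.

    Young cohorts are drawn first in both directions.  Returns the biomass
    transferred to the recipient litter pool (Pg C).
    """
    if area < 0:
        raise ValueError("area must be non-negative")
    if area <= 1e-12:
        return 0.0
    if direction == "to_agri":
        donors = sorted(
            (c for c in region.cohorts if c.land_class in GRASS_CLASSES),
            key=lambda c: (c.land_class == "intact_grass", c.age),
        )
        avail = region.area_of(*GRASS_CLASSES)
        if area > avail + 1e-9:
            raise ValueError(
                f"requested conversion of {area:g} Mha exceeds available grassland {avail:g} Mha"
            )
        _, litter = _drain_to_agri(region, donors, area, target, burn=False)
        return litter
    if direction == "abandon":
        return apply_abandonment(region, area, target="secondary_grass")
    raise ValueError(f"direction must be 'to_agri' or 'abandon', got {direction!r}")


def apply_abandonment(
    region: RegionState, area: float, target: str = "secondary_grass"
) -> float:
    """Abandon agricultural land into a recovering class (no fire).

    Young agricultural cohorts are drawn first.  Donor biomass and litter move
    into the new cohort's litter pool; soil and legacy soil are carried over.
    Returns the litter transfer in Pg C.
    """
    if area < 0:
        raise ValueError("area must be non-negative")
    if area <= 1e-12:
        return 0.0
    if target not in ("secondary_grass", "secondary_forest"):
        raise ValueError("abandonment target must be secondary_grass or secondary_forest")
    donors = sorted(
        (c for c in region.cohorts if c.land_class in AGRI_CLASSES),
        key=lambda c: (c.land_class == "permanent_agri", c.age),
    )
    avail = region.area_of(*AGRI_CLASSES)
    if area > avail + 1e-9:
        raise ValueError(
            f"requested abandonment of {area:g} Mha exceeds agricultural area {avail:g} Mha"
        )
    remaining = area
    litter_c = soil_c = legacy_c = 0.0
    for donor in donors:
        if remaining <= 1e-12:
            break
        take = min(donor.area, remaining)
        litter_c += take * (donor.agb + donor.bgb + donor.litter) * MHA_MG_TO_PG
        soil_c += take * donor.soil * MHA_MG_TO_PG
        legacy_c += take * donor.soil_legacy * MHA_MG_TO_PG
        donor.area -= take
        remaining -= take
    taken = area - remaining
    if taken > 1e-12:
        region.cohorts.append(
            Cohort(
                target,
                age=0,
                area=taken,
                litter=litter_c / taken / MHA_MG_TO_PG,
                soil=soil_c / taken / MHA_MG_TO_PG,
                soil_legacy=legacy_c / taken / MHA_MG_TO_PG,
            )
        )
    region.drop_empty()
    return litter_c


def harvest_wood(
    region: RegionState, mass: float, kind: str, year: int
) -> tuple[float, float]:
    """Harvest a prescribed woody mass (Pg C) from forest.

    Harvest starts from intact forest and moves to younger cohorts.  The
    merchantable fraction ``wood_frac`` of aboveground biomass supplies the
    harvested mass; branches/leaves and roots go to the litter pool of the
    harvested area, which re-enters the youngest secondary-forest cohort.

    Fuel wood is emitted in the harvest year (returned as ``e_fire``);
    industrial wood enters the 10- and 100-year product pools according to
    ``product_split_10`` (returned as ``product_input``).
    """
    if kind not in ("fuel", "industrial"):
        raise ValueError("kind must be 'fuel' or 'industrial'")
    if mass < 0:
        raise ValueError("harvest mass must be non-negative")
    if mass <= 1e-15:
        return 0.0, 0.0
    p = region.params
    donors = _clearing_order(region)
    harvestable = sum(c.area * c.agb * p.wood_frac for c in donors) * MHA_MG_TO_PG
    if mass > harvestable + 1e-9:
        raise ValueError(
            f"requested harvest of {mass:g} Pg C exceeds harvestable wood {harvestable:g} Pg C"
        )
    remaining = mass
    litter_c = soil_c = 0.0
    harvested_area = 0.0
    for donor in donors:
        if remaining <= 1e-15:
            break
        wood_per_mha = donor.agb * p.wood_frac * MHA_MG_TO_PG  # Pg per Mha
        if wood_per_mha <= 0:
            continue
        take = min(donor.area, remaining / wood_per_mha)
        got = take * wood_per_mha
        litter_c += take * (donor.agb * (1.0 - p.wood_frac) + donor.bgb + donor.litter) * MHA_MG_TO_PG
        soil_c += take * (donor.soil + donor.soil_legacy) * MHA_MG_TO_PG
        donor.area -= take
        harvested_area += take
        remaining -= got
    harvested = mass - remaining
    if harvested_area > 1e-12:
        region.cohorts.append(
            Cohort(
                "secondary_forest",
                age=0,
                area=harvested_area,
                litter=litter_c / harvested_area / MHA_MG_TO_PG,
                soil=soil_c / harvested_area / MHA_MG_TO_PG,
            )
        )
    region.drop_empty()
    if kind == "fuel":
        return harvested, 0.0
    region.pools.add_vintage(year, harvested * p.product_split_10, tau=10)
    region.pools.add_vintage(year, harvested * (1.0 - p.product_split_10), tau=100)
    return 0.0, harvested


def regrow_and_age(region: RegionState, t_anom: float, w_anom: float) -> float:
    """Grow secondary vegetation one year and advance all cohort ages.

    The aboveground increment of a secondary cohort at age ``a`` is the
    potential-curve step ``B_pot(a+1) - B_pot(a)`` scaled by the secondary
    uptake multiplier and clipped at ``b_max``; belowground biomass grows in
    the root:shoot proportion.  Returns the biomass uptake (Pg C), which is
    one ingredient of the recovery sink.  Litter/soil dynamics are handled by
    the flux-accounting step.
    """
    p = region.params
    g = p.sens.secondary.uptake(t_anom, w_anom)
    uptake = 0.0
    for c in region.cohorts:
        if c.land_class in SECONDARY_CLASSES:
            b_max = p.class_b_max(c.land_class)
            growth_class = "secondary_grass" if c.land_class == "secondary_grass" else c.land_class
            pot_inc = p.b_pot(c.age + 1, growth_class) - p.b_pot(c.age, growth_class)
            inc = min(max(0.0, pot_inc * g), max(0.0, b_max - c.agb))
            c.agb += inc
            c.bgb += inc * p.root_shoot
            uptake += c.area * inc * (1.0 + p.root_shoot) * MHA_MG_TO_PG
        c.age += 1
    region.merge_same_age()
    return uptake


def promote_to_intact(region: RegionState, threshold: float = 0.9) -> float:
    """Reclassify recovered secondary vegetation as intact.

    Secondary forest whose aboveground biomass reaches ``threshold * b_max``
    becomes intact forest (and recovering grassland likewise becomes intact
    grassland).  Fallow cohorts in a shifting-cultivation rotation are never
    promoted.  Returns the promoted area (Mha).
    """
    p = region.params
    promoted = 0.0
    for c in region.cohorts:
        if c.land_class == "secondary_forest" and c.agb >= threshold * p.b_max:
            c.land_class = "intact_forest"
            promoted += c.area
        elif c.land_class == "secondary_grass" and c.agb >= threshold * p.grass_b_max:
            c.land_class = "intact_grass"
            promoted += c.area
    return promoted


def step_shifting_cultivation(
    region: RegionState, sc_area: float, rotation: int = 20
) -> tuple[float, float]:
    """Advance the shifting-cultivation rotation by one year.

    ``sc_area`` Mha of existing cropland enters fallow (young cropland
    first); the cropland is replaced by re-clearing mature fallow cohorts
    (age >= ``rotation``, oldest first) with the usual clearing fire, and
    only a remaining deficit is met by clearing intact/old forest.  Returns
    ``(e_fire, new_intact_cleared)`` in (Pg C, Mha).
    """
    if region.params.biome != "tropical":
        raise ValueError("shifting cultivation is modelled for tropical regions only")
    if rotation < 2:
        raise ValueError("rotation length must be >= 2 years")
    if sc_area < 0:
        raise ValueError("sc_area must be non-negative")
    if sc_area <= 1e-12:
        return 0.0, 0.0
    # 1. cropland -> fallow (young cropland first; permanent agriculture last)
    crop_avail = region.area_of("cropland")
    to_fallow = min(sc_area, crop_avail)
    if to_fallow > 1e-12:
        donors = sorted(
            (c for c in region.cohorts if c.land_class == "cropland"), key=lambda c: c.age
        )
        remaining = to_fallow
        litter_c = soil_c = legacy_c = 0.0
        for donor in donors:
            if remaining <= 1e-12:
                break
            take = min(donor.area, remaining)
            litter_c += take * (donor.agb + donor.bgb + donor.litter) * MHA_MG_TO_PG
            soil_c += take * donor.soil * MHA_MG_TO_PG
            legacy_c += take * donor.soil_legacy * MHA_MG_TO_PG
            donor.area -= take
            remaining -= take
        region.cohorts.append(
            Cohort(
                "fallow_secondary",
                age=0,
                area=to_fallow,
                litter=litter_c / to_fallow / MHA_MG_TO_PG,
                soil=soil_c / to_fallow / MHA_MG_TO_PG,
                soil_legacy=legacy_c / to_fallow / MHA_MG_TO_PG,
            )
        )
        region.drop_empty()
    # 2. replace the cropland: mature fallow first, then intact/old forest
    e_fire = 0.0
    need = to_fallow
    mature = sorted(
        (c for c in region.cohorts if c.land_class == "fallow_secondary" and c.age >= rotation),
        key=lambda c: -c.age,
    )
    mature_area = sum(c.area for c in mature)
    recycle = min(need, mature_area)
    if recycle > 1e-12:
        ef, _ = _drain_to_agri(region, mature, recycle, "cropland", burn=True)
        e_fire += ef
    deficit = need - recycle
    new_clearing = 0.0
    if deficit > 1e-12:
        ef, _ = apply_clearing(region, deficit, target="cropland")
        e_fire += ef
        new_clearing = deficit
    return e_fire, new_clearing


def relabel_secondary_fraction(region: RegionState, secondary_fraction: float) -> None:
    """Post-hoc relabeling of forest composition to a target secondary share.

    Adjusts the intact/secondary forest split to ``secondary_fraction`` of
    total forest area by relabeling the oldest secondary cohorts as intact
    (or the required intact area as oldest-bin secondary).  The source
    analysis fixes the 2015 composition at 81% primary / 19% secondary
    without describing the adjustment algorithm; this area relabeling is this
    package's own minimal realization and changes no carbon pools.
    """
    if not 0.0 <= secondary_fraction <= 1.0:
        raise ValueError("secondary_fraction must lie in [0, 1]")
    forest = region.area_of("intact_forest", "secondary_forest")
    if forest <= 0:
        return
    target_sec = secondary_fraction * forest
    current_sec = region.area_of("secondary_forest")
    delta = current_sec - target_sec
    if abs(delta) <= 1e-9:
        return
    if delta > 0:
        # too much secondary: promote oldest secondary area
        donors = sorted(
            (c for c in region.cohorts if c.land_class == "secondary_forest"),
            key=lambda c: -c.age,
        )
        new_class = "intact_forest"
    else:
        donors = [c for c in region.cohorts if c.land_class == "intact_forest"]
        new_class = "secondary_forest"
        delta = -delta
    for donor in donors:
        if delta <= 1e-12:
            break
        take = min(donor.area, delta)
        donor.area -= take
        region.cohorts.append(replace(copy.copy(donor), area=take, land_class=new_class))
        delta -= take
    region.drop_empty()
    region.merge_same_age()
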
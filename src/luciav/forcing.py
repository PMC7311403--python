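"""Synthetic forcing: climate anomalies, land-use schedules, global budgets.

The simulator and the attribution pipeline are driven by three annual tables:

* a climate table with tropical temperature anomalies ``tas_anom`` (K) and a
  dimensionless moisture anomaly ``wet_anom`` — generated as a correlated
  bivariate AR(1) process so that hot years tend to be dry (El Nino-like) and
  cool years wet (La Nina-like);
* a land-use transition schedule (areas cleared, abandoned, converted, and
  wood-harvest masses), optionally smoothed into 5-year constant blocks the
  way FAO-derived deforestation reconstructions are;
* a global carbon-budget table (fossil emissions, atmospheric growth, ocean
  sink) whose residual land sink equals a prescribed series by construction.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClimateAnomalySeries",
    "TransitionSchedule",
    "BudgetSeries",
    "generate_climate",
    "generate_schedule",
    "generate_budget",
    "SCHEDULE_COLUMNS",
]

#: column order of a transition schedule table (one row per year and region)
SCHEDULE_COLUMNS = [
    "year",
    "region",
    "area_deforested",
    "area_afforested",
    "area_grass_to_agri",
    "area_agri_to_grass",
    "fuelwood_harvest",
    "industrialwood_harvest",
    "sc_rotation_area",
]

_AREA_COLUMNS = SCHEDULE_COLUMNS[2:]


@dataclass
class ClimateAnomalySeries:
    """Annual temperature (K) and moisture (dimensionless) anomalies."""

    years: np.ndarray
    tas_anom: np.ndarray
    wet_anom: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.tas_anom = np.asarray(self.tas_anom, dtype=float)
        self.wet_anom = np.asarray(self.wet_anom, dtype=float)
        if not (len(self.years) == len(self.tas_anom) == len(self.wet_anom)):
            raise ValueError("years, tas_anom and wet_anom must have equal length")
        if len(self.years) and np.any(np.diff(self.years) != 1):
            raise ValueError("years must be strictly consecutive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.years, "tas_anom": self.tas_anom, "wet_anom": self.wet_anom}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ClimateAnomalySeries":
        return cls(
            df["year"].to_numpy(), df["tas_anom"].to_numpy(), df["wet_anom"].to_numpy()
        )

    def at(self, year: int) -> tuple[float, float]:
        i = int(year) - int(self.years[0])
        if i < 0 or i >= len(self.years):
            raise KeyError(f"year {year} outside climate series")
        return float(self.tas_anom[i]), float(self.wet_anom[i])


@dataclass
class BudgetSeries:
    """Annual global carbon budget terms, all in Pg C yr-1.

    ``e_fuel`` is fossil + cement emissions, ``s_air`` the atmospheric CO2
    growth and ``s_ocean`` the ocean sink; sinks are positive when removing
    carbon from the atmosphere.
    """

    years: np.ndarray
    e_fuel: np.ndarray
    s_air: np.ndarray
    s_ocean: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.e_fuel = np.asarray(self.e_fuel, dtype=float)
        self.s_air = np.asarray(self.s_air, dtype=float)
        self.s_ocean = np.asarray(self.s_ocean, dtype=float)
        n = len(self.years)
        if not (len(self.e_fuel) == len(self.s_air) == len(self.s_ocean) == n):
            raise ValueError("budget series must have equal lengths")
        if np.any(self.e_fuel < 0):
            raise ValueError("fossil emissions must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "e_fuel": self.e_fuel,
                "s_air": self.s_air,
                "s_ocean": self.s_ocean,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BudgetSeries":
        return cls(
            df["year"].to_numpy(),
            df["e_fuel"].to_numpy(),
            df["s_air"].to_numpy(),
            df["s_ocean"].to_numpy(),
        )


@dataclass
class TransitionSchedule:
    """Per-year, per-region land-use events (areas in Mha, masses in Pg C)."""

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=SCHEDULE_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in SCHEDULE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"schedule table missing columns {missing}")
        self.table = self.table[SCHEDULE_COLUMNS].reset_index(drop=True)
        if (self.table[_AREA_COLUMNS].to_numpy() < 0).any():
            raise ValueError("schedule entries must be non-negative")
        for _, sub in self.table.groupby("region"):
            yrs = np.sort(sub["year"].unique())
            if len(yrs) and np.any(np.diff(yrs) != 1):
                raise ValueError("schedule years must form a contiguous range")

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.table["year"].unique())

    @property
    def regions(self) -> list[str]:
        return sorted(self.table["region"].unique())

    def events_for(self, year: int, region: str) -> pd.Series:
        sub = self.table[(self.table["year"] == year) & (self.table["region"] == region)]
        if sub.empty:
            return pd.Series(0.0, index=_AREA_COLUMNS)
        return sub.iloc[0][_AREA_COLUMNS].astype(float)


def generate_climate(
    n_years: int,
    ar1_coef: float = 0.5,
    innovation_sd: float = 0.17,
    trend: float = 0.0,
    wet_coupling: float = -0.6,
    wet_sd: float = 1.0,
    start_year: int = 1850,
    seed: int = 0,
) -> ClimateAnomalySeries:
    """Generate an El Nino-like bivariate AR(1) anomaly series.

    ``tas_anom`` follows a stationary AR(1) process with autoregressive
    coefficient ``ar1_coef`` and Gaussian innovations of standard deviation
    ``innovation_sd`` (K), plus a linear ``trend`` (K per year). ``wet_anom``
    is a second AR(1) process whose innovations correlate with the
    temperature innovations at ``wet_coupling`` (default -0.6: hot years are
    dry).  Both series are centred on their sample mean before being
    returned.
    """
    if n_years < 2:
        raise ValueError("n_years must be >= 2")
    for name, v in {
        "ar1_coef": ar1_coef,
        "innovation_sd": innovation_sd,
        "trend": trend,
        "wet_coupling": wet_coupling,
        "wet_sd": wet_sd,
    }.items():
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    if abs(ar1_coef) >= 1:
        raise ValueError("|ar1_coef| must be < 1 for a stationary AR(1) process")
    if abs(wet_coupling) > 1:
        raise ValueError("|wet_coupling| must be <= 1")

    rng = np.random.default_rng(seed)
    # correlated innovation pairs; wet innovations scaled so sd(wet) ~ wet_sd
    z = rng.standard_normal((n_years, 2))
    eps_t = innovation_sd * z[:, 0]
    rho = wet_coupling
    eps_w_unit = rho * z[:, 0] + np.sqrt(1.0 - rho**2) * z[:, 1]
    eps_w = wet_sd * np.sqrt(1.0 - ar1_coef**2) * eps_w_unit
    if innovation_sd == 0.0:
        eps_w[:] = 0.0  # zero-noise world is fully deterministic

    tas = np.empty(n_years)
    wet = np.empty(n_years)
    t_prev = w_prev = 0.0
    for i in range(n_years):
        t_prev = ar1_coef * t_prev + eps_t[i]
        w_prev = ar1_coef * w_prev + eps_w[i]
        tas[i] = t_prev
        wet[i] = w_prev
    tas = tas + trend * np.arange(n_years)
    tas -= tas.mean()
    wet -= wet.mean()
    years = start_year + np.arange(n_years)
    return ClimateAnomalySeries(years, tas, wet)


def _blocked(values: np.ndarray, block: int) -> np.ndarray:
    """Replace each ``block``-year stretch by its first value (FAO-style smoothing)."""
    out = values.copy()
    for i in range(0, len(values), block):
        out[i : i + block] = values[i]
    return out


def generate_schedule(
    n_years: int,
    profile: str = "hn_like_rise_decline",
    seed: int = 0,
    region: str = "tropics",
    start_year: int = 1850,
    block_years: int = 5,
    defor_base: float = 3.0,
    defor_peak: float = 9.0,
    peak_year: int = 1975,
    peak_width: float = 60.0,
    block_noise_sd: float = 0.15,
    abandon_frac: float = 0.25,
    afforest_frac: float = 0.10,
    grass_conv: float = 2.0,
    fuelwood_end: float = 0.45,
    industrialwood_end: float = 0.30,
    sc_area: float = 0.0,
    pulse_year: int | None = None,
    pulse_area: float = 10.0,
) -> TransitionSchedule:
    """Generate a land-use transition schedule for one region.

    Profiles
    --------
    ``none``
        All-zero schedule.
    ``constant``
        Constant annual rates (``defor_base`` Mha/yr deforested, plus the
        derived abandonment/afforestation/harvest terms).
    ``pulse``
        A single clearing of ``pulse_area`` Mha in ``pulse_year`` (default:
        second year); everything else zero.
    ``hn_like_rise_decline``
        Deforestation rises from ``defor_base`` toward a mid-20th-century
        peak and declines afterwards, held piecewise-constant over
        ``block_years``-year blocks with mild multiplicative block noise —
        mimicking the 5-yearly smoothing of FAO-derived reconstructions.
        Wood-harvest masses ramp up monotonically; abandonment and
        afforestation scale with past clearing.
    """
    known = {"constant", "hn_like_rise_decline", "pulse", "none"}
    if profile not in known:
        raise ValueError(f"unknown profile {profile!r}; expected one of {sorted(known)}")
    years = start_year + np.arange(n_years)
    zero = np.zeros(n_years)
    cols = {c: zero.copy() for c in _AREA_COLUMNS}

    if profile == "pulse":
        py = pulse_year if pulse_year is not None else start_year + 1
        cols["area_deforested"][py - start_year] = pulse_area
    elif profile == "constant":
        cols["area_deforested"] += defor_base
        cols["area_agri_to_grass"] += abandon_frac * defor_base
        cols["area_afforested"] += afforest_frac * defor_base
        cols["area_grass_to_agri"] += grass_conv
        cols["fuelwood_harvest"] += fuelwood_end
        cols["industrialwood_harvest"] += industrialwood_end
        cols["sc_rotation_area"] += sc_area
    elif profile == "hn_like_rise_decline":
        rng = np.random.default_rng(seed)
        t = years.astype(float)
        defor = defor_base + defor_peak * np.exp(-(((t - peak_year) / peak_width) ** 2))
        noise = np.exp(rng.normal(0.0, block_noise_sd, size=n_years))
        defor = _blocked(defor * noise, block_years)
        ramp = np.linspace(0.15, 1.0, n_years)
        cols["area_deforested"] = defor
        cols["area_agri_to_grass"] = _blocked(abandon_frac * defor * ramp, block_years)
        cols["area_afforested"] = _blocked(afforest_frac * defor * ramp, block_years)
        cols["area_grass_to_agri"] = _blocked(
            grass_conv * ramp * np.exp(rng.normal(0.0, block_noise_sd, size=n_years)),
            block_years,
        )
        cols["fuelwood_harvest"] = fuelwood_end * np.linspace(0.2, 1.0, n_years)
        cols["industrialwood_harvest"] = industrialwood_end * np.linspace(0.15, 1.0, n_years)
        if sc_area > 0:
            # shifting cultivation ramps up in the 20th century
            sc = sc_area * np.clip((t - (start_year + 0.45 * n_years)) / (0.3 * n_years), 0, 1)
            cols["sc_rotation_area"] = sc

    table = pd.DataFrame({"year": years, "region": region, **cols})
    return TransitionSchedule(table)


def generate_budget(
    snet_target: np.ndarray | pd.Series,
    years: np.ndarray | None = None,
    e_fuel_level: float | np.ndarray = 10.0,
    ocean_fraction: float = 0.25,
    seed: int = 0,
    start_year: int = 1959,
) -> BudgetSeries:
    """Construct a global budget whose residual land sink equals ``snet_target``.

    ``e_fuel`` is either a constant level or a supplied series; the ocean sink
    is ``ocean_fraction * e_fuel`` and the atmospheric growth closes the
    budget exactly: ``s_air = e_fuel - s_ocean - snet_target``.
    """
    if isinstance(snet_target, pd.Series):
        if years is None and np.issubdtype(np.asarray(snet_target.index).dtype, np.integer):
            years = snet_target.index.to_numpy()
        snet_target = snet_target.to_numpy()
    snet = np.asarray(snet_target, dtype=float)
    n = len(snet)
    if years is None:
        years = start_year + np.arange(n)
    years = np.asarray(years, dtype=int)
    if len(years) != n:
        raise ValueError("years and snet_target lengths differ")
    e_fuel = np.broadcast_to(np.asarray(e_fuel_level, dtype=float), (n,)).copy()
    if len(np.atleast_1d(np.asarray(e_fuel_level))) not in (1, n):
        raise ValueError("e_fuel_level must be scalar or match snet_target length")
    s_ocean = ocean_fraction * e_fuel
    s_air = e_fuel - s_ocean - snet
    return BudgetSeries(years, e_fuel, s_air, s_ocean)
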
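"""Residual global carbon-budget accounting.

The net land sink follows from the atmospheric mass balance::

    S_net = E_FUEL - S_AIR - S_OCEAN

and the intact-land sink is obtained as the residual once land-use emissions
are known::

    S_Intact = S_net + E_LUC

Sinks are positive when they remove carbon from the atmosphere; emission
terms are positive toward the atmosphere.  Both relations are exact linear
identities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forcing import BudgetSeries

__all__ = ["ResidualResult", "net_land_sink", "residual_intact_sink"]


@dataclass
class ResidualResult:
    """Residual-budget land sinks with an optional ±1 s.d. band."""

    years: np.ndarray
    s_net: np.ndarray
    s_intact_residual: np.ndarray
    uncertainty_band: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.years)
        if not (len(self.s_net) == len(self.s_intact_residual) == n):
            raise ValueError("series lengths differ")
        if self.uncertainty_band is not None and len(self.uncertainty_band) != n:
            raise ValueError("uncertainty band length differs")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"year": self.years, "s_net": self.s_net, "s_intact": self.s_intact_residual}
        )
        if self.uncertainty_band is not None:
            df["s_intact_sd"] = self.uncertainty_band
        return df


def net_land_sink(budget: BudgetSeries) -> pd.Series:
    """Net land sink ``S_net = E_FUEL - S_AIR - S_OCEAN`` (Pg C yr-1)."""
    s_net = budget.e_fuel - budget.s_air - budget.s_ocean
    return pd.Series(s_net, index=pd.Index(budget.years, name="year"), name="s_net")


def residual_intact_sink(
    s_net: pd.Series,
    e_luc: pd.Series,
    s_net_sd: pd.Series | None = None,
    e_luc_sd: pd.Series | None = None,
) -> ResidualResult:
    """Intact sink as the budget residual ``S_Intact = S_net + E_LUC``.

    Both inputs must be year-indexed and cover the same years.  Optional
    per-year standard deviations are combined in quadrature.
    """
    s_net = pd.Series(s_net)
    e_luc = pd.Series(e_luc)
    if len(s_net) != len(e_luc) or not np.array_equal(
        np.asarray(s_net.index), np.asarray(e_luc.index)
    ):
        raise ValueError("s_net and e_luc series are misaligned")
    s_intact = s_net + e_luc
    band = None
    if s_net_sd is not None or e_luc_sd is not None:
        v1 = np.square(np.asarray(s_net_sd, dtype=float)) if s_net_sd is not None else 0.0
        v2 = np.square(np.asarray(e_luc_sd, dtype=float)) if e_luc_sd is not None else 0.0
        band = np.sqrt(v1 + v2)
    return ResidualResult(
        np.asarray(s_net.index), s_net.to_numpy(), s_intact.to_numpy(), band
    )
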
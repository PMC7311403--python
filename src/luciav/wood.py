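"""Industrial wood-product pools with 10- and 100-year residence times.

Each harvest adds a vintage (input year, initial mass) to the 10-year or the
100-year pool.  Two release modes are supported:

* ``exponential`` — every year each vintage emits ``remaining * (1 - e^{-1/tau})``
  and retains ``remaining * e^{-1/tau}``, so after ``t`` annual steps a
  vintage retains ``e^{-t/tau}`` of its initial mass;
* ``uniform`` — every vintage emits ``initial / tau`` per year and is
  exhausted after exactly ``tau`` steps.

Both modes release the full vintage as t -> infinity.  Release starts in the
harvest year itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["WoodProductVintage", "WoodProductPools"]


@dataclass
class WoodProductVintage:
    year: int
    initial: float  # Pg C
    remaining: float  # Pg C
    steps: int = 0


@dataclass
class WoodProductPools:
    """10- and 100-year wood-product reservoirs with per-vintage tracking."""

    vintages_10: list[WoodProductVintage] = field(default_factory=list)
    vintages_100: list[WoodProductVintage] = field(default_factory=list)
    decay_mode: str = "uniform"

    def __post_init__(self) -> None:
        if self.decay_mode not in ("exponential", "uniform"):
            raise ValueError("decay_mode must be 'exponential' or 'uniform'")

    def add_vintage(self, year: int, mass: float, tau: int) -> None:
        if mass < 0:
            raise ValueError("vintage mass must be non-negative")
        if mass == 0:
            return
        if tau == 10:
            self.vintages_10.append(WoodProductVintage(year, mass, mass))
        elif tau == 100:
            self.vintages_100.append(WoodProductVintage(year, mass, mass))
        else:
            raise ValueError("tau must be 10 or 100")

    def pool_mass(self, tau: int) -> float:
        vs = self.vintages_10 if tau == 10 else self.vintages_100
        return sum(v.remaining for v in vs)

    def total(self) -> float:
        return self.pool_mass(10) + self.pool_mass(100)

    def step(self) -> float:
        """Advance one year; return the emitted mass (Pg C)."""
        emitted = 0.0
        for tau, vs in ((10, self.vintages_10), (100, self.vintages_100)):
            for v in vs:
                if v.remaining <= 0:
                    continue
                if self.decay_mode == "exponential":
                    e = v.remaining * (1.0 - math.exp(-1.0 / tau))
                    v.remaining -= e
                else:
                    v.steps += 1
                    # remaining computed from the step count so the vintage is
                    # exhausted after exactly tau years with no float residue
                    new_remaining = v.initial * max(0.0, 1.0 - v.steps / tau)
                    e = v.remaining - new_remaining
                    v.remaining = new_remaining
                emitted += e
        self.vintages_10 = [v for v in self.vintages_10 if v.remaining > 0]
        self.vintages_100 = [v for v in self.vintages_100 if v.remaining > 0]
        return emitted
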
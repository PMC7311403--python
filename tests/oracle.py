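"""Independent per-event response-curve oracle for the bookkeeping limit.

With all climate sensitivities zero the simulator is a pure bookkeeping
model: every land-use event generates a fixed response curve in time (fire
spike, geometric litter/legacy-soil tails, wood-product release, regrowth
curve, soil relaxation), and annual fluxes are the superposition of the
per-event curves.  This module computes that superposition directly from the
event list and closed forms, without touching the cohort state machinery, so
it can serve as an independent cross-check of the simulator.

Assumptions (arranged by the test schedules): clearing and harvest always
draw from intact forest at its initial densities; grass conversions draw
intact grassland; abandonment draws equilibrated permanent agriculture.
"""

from __future__ import annotations

import math

import numpy as np

MHA_MG_TO_PG = 1.0e-3


def b_pot(age, b_max, k, theta):
    return b_max * (1.0 - math.exp(-k * age)) ** theta if age > 0 else 0.0


def promotion_age(b_max, k, theta, threshold=0.9):
    a = 1
    while b_pot(a, b_max, k, theta) < threshold * b_max:
        a += 1
    return a


def _geometric(out, start_idx, pool0, rate, n_years, stop_after=None):
    """Add k*P0*(1-k)^n terms to out[start_idx + n]; optionally truncate."""
    n_max = n_years - start_idx if stop_after is None else min(stop_after, n_years - start_idx)
    for n in range(n_max):
        out[start_idx + n] += rate * pool0 * (1.0 - rate) ** n


def convolve_events(events, years, p, wood_decay="uniform"):
    """Sum analytic per-event responses.

    ``events`` is a list of dicts with keys ``year``, ``kind`` in
    {clear, grass_to_agri, abandon_to_grass, abandon_to_forest, fuel,
    industrial} and ``amount`` (Mha for areas, Pg C for harvest masses).
    ``p`` is the RegionParams-like namespace of the simulated region.
    Returns dict of numpy arrays e_fire, e_wood, e_legacy, s_recov.
    """
    n = len(years)
    y0 = years[0]
    e_fire = np.zeros(n)
    e_wood = np.zeros(n)
    e_legacy = np.zeros(n)
    s_recov = np.zeros(n)

    forest_agb = p.b_max
    forest_bgb = p.b_max * p.root_shoot
    forest_litter = p.litter_eq_forest
    grass_agb = p.grass_b_max
    grass_bgb = p.grass_b_max * p.root_shoot

    a_star_forest = promotion_age(p.b_max, p.growth_k, p.growth_theta)
    a_star_grass = promotion_age(p.grass_b_max, p.grass_k, p.growth_theta)

    for ev in events:
        i = ev["year"] - y0
        kind = ev["kind"]
        amt = ev["amount"]
        if kind == "clear":
            e_fire[i] += amt * forest_agb * p.f_burn * MHA_MG_TO_PG
            litter0 = (
                amt
                * (forest_agb * (1.0 - p.f_burn) + forest_bgb + forest_litter)
                * MHA_MG_TO_PG
            )
            _geometric(e_legacy, i, litter0, p.k_litter, n)
            legacy0 = amt * max(0.0, p.soil_eq_forest - p.soil_eq_agri) * MHA_MG_TO_PG
            _geometric(e_legacy, i, legacy0, p.k_soil_legacy, n)
        elif kind == "grass_to_agri":
            litter0 = amt * (grass_agb + grass_bgb) * MHA_MG_TO_PG
            _geometric(e_legacy, i, litter0, p.k_litter, n)
            legacy0 = amt * max(0.0, p.soil_eq_grass - p.soil_eq_agri) * MHA_MG_TO_PG
            _geometric(e_legacy, i, legacy0, p.k_soil_legacy, n)
        elif kind in ("abandon_to_grass", "abandon_to_forest"):
            forest = kind == "abandon_to_forest"
            b_max = p.b_max if forest else p.grass_b_max
            k = p.growth_k if forest else p.grass_k
            soil_eq = p.soil_eq_forest if forest else p.soil_eq_grass
            a_star = a_star_forest if forest else a_star_grass
            for m in range(min(a_star, n - i)):
                inc = b_pot(m + 1, b_max, k, p.growth_theta) - b_pot(m, b_max, k, p.growth_theta)
                s_recov[i + m] += amt * inc * (1.0 + p.root_shoot) * MHA_MG_TO_PG
            deficit0 = amt * max(0.0, soil_eq - p.soil_eq_agri) * MHA_MG_TO_PG
            _geometric(s_recov, i, deficit0, p.k_soil_legacy, n, stop_after=a_star)
        elif kind in ("fuel", "industrial"):
            area = amt / (p.wood_frac * forest_agb * MHA_MG_TO_PG)
            if kind == "fuel":
                e_fire[i] += amt
            else:
                for tau, frac in ((10, p.product_split_10), (100, 1.0 - p.product_split_10)):
                    mass = amt * frac
                    if wood_decay == "uniform":
                        for m in range(min(tau, n - i)):
                            e_wood[i + m] += mass / tau
                    else:
                        r = 1.0 - math.exp(-1.0 / tau)
                        for m in range(n - i):
                            e_wood[i + m] += mass * math.exp(-m / tau) * r
            litter0 = (
                area
                * (forest_agb * (1.0 - p.wood_frac) + forest_bgb + forest_litter)
                * MHA_MG_TO_PG
            )
            # slash decay counts against the recovery sink of the new stand
            _geometric(s_recov, i, -litter0, p.k_litter, n, stop_after=a_star_forest)
            for m in range(min(a_star_forest, n - i)):
                inc = b_pot(m + 1, p.b_max, p.growth_k, p.growth_theta) - b_pot(
                    m, p.b_max, p.growth_k, p.growth_theta
                )
                s_recov[i + m] += area * inc * (1.0 + p.root_shoot) * MHA_MG_TO_PG
        else:
            raise ValueError(f"unknown event kind {kind!r}")
    return {"e_fire": e_fire, "e_wood": e_wood, "e_legacy": e_legacy, "s_recov": s_recov}
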
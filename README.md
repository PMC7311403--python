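# luciav

**Land use and the interannual variability of the net land carbon sink.**

The year-to-year variability (IAV) of the net land–atmosphere carbon balance
S_net dominates the fluctuations of the atmospheric CO₂ growth rate, and its
temperature sensitivity γ is a key constraint on climate–carbon-cycle
feedbacks. Global carbon-budget accounting has traditionally split the land
balance as

```
S_net = S_Intact − E_LUC,          E_LUC = E_fire + E_wood + E_legacy − S_recov
```

where E_LUC (net land-use-change emissions) is computed with a *bookkeeping*
model — fixed carbon densities and static post-transition response curves —
and S_Intact (the sink of land never appreciably used by humans) falls out as
the budget residual `S_Intact = S_net + E_LUC`. Because bookkeeping response
curves ignore climate variability, essentially all of the IAV of S_net is
then attributed to intact ecosystems. But croplands, pastures and young
secondary forests respond *more* strongly to hot–dry (El Niño) and cool–wet
(La Niña) anomalies than intact forest does, so a climate-responsive
accounting of managed land shifts a substantial fraction of the IAV — and of
γ — from intact to managed land.

`luciav` is a reduced-complexity, climate-responsive cohort bookkeeping
simulator plus the attribution pipeline needed to quantify that shift, built
to run entirely offline on synthetic forcing:

- **`luciav.forcing`** — seeded generators for ENSO-like bivariate AR(1)
  climate anomalies (T′, W′), multi-decadal land-use transition schedules
  with FAO-style 5-year block smoothing, and global budgets
  (E_FUEL, S_AIR, S_OCEAN) whose residual land sink is prescribed exactly.
- **`luciav.cohorts`** — sub-grid land state: age cohorts per land class
  (intact/secondary forest and grassland, cropland, pasture, permanent
  agriculture, fallow), clearing with intact-first priority and a burned
  fraction, grass↔agriculture transitions without fire, wood harvest,
  Chapman–Richards regrowth `B_pot(a) = b_max (1 − e^{−k a})^θ`, promotion
  back to intact at 90% of maximum wood mass, and an optional 20-year
  shifting-cultivation fallow rotation. Area and carbon are conserved
  exactly by every operation.
- **`luciav.fluxes`** — annual component fluxes (fire, wood-product release
  from 10/100-year pools with uniform or exponential decay, legacy
  slash/soil emissions over agriculture, recovery sink, background intact
  sink), each scaled by linear, zero-clipped climate multipliers; the
  year-by-year simulator. With all sensitivities zero it degenerates to a
  classical bookkeeping model.
- **`luciav.budget`** — the exact budget identities (net land sink, residual
  intact sink).
- **`luciav.attribution`** — linear detrending, the exact variance
  decomposition `Var(S_net) = Var(E_LUC) + Var(S_Intact) − 2 Cov`, covariance
  allocation (raw or half-to-each), OLS temperature sensitivities γ with
  standard errors and two-sided p-values, and Pearson comparisons with a
  volcanic-window exclusion.

## Worked example

The default experiment builds a single tropical macro-region (1850–2015),
runs the climate-responsive baseline, the bookkeeping limit and the
shifting-cultivation sensitivity run on identical forcing, and attributes
Var(S_net) over 1959–2015 (n = 57):

```python
import luciav

summary = luciav.attribution_summary(seed=1)
dyn, book, sc = summary["dynamic"], summary["bookkeeping_residual"], summary["sc"]
print(f"raw E_LUC share            {dyn.frac_eluc_raw:5.2f}")
print(f"managed share, half-cov    {dyn.frac_managed_halfcov:5.2f}")
print(f"  ... bookkeeping E_LUC    {book.frac_eluc_raw:5.2f}")
print(f"  ... shifting cultivation {sc.frac_managed_halfcov:5.2f}")
for k in ("gamma_land", "gamma_intact", "gamma_eluc"):
    r = summary["gammas"][k]
    print(f"{k:12s}  {r.gamma:6.2f} +/- {r.stderr:4.2f} Pg C yr-1 K-1")
```

prints

```
raw E_LUC share             0.15
managed share, half-cov     0.38
  ... bookkeeping E_LUC     0.02
  ... shifting cultivation  0.47
gamma_land     -5.19 +/- 0.39 Pg C yr-1 K-1
gamma_intact   -3.22 +/- 0.26 Pg C yr-1 K-1
gamma_eluc      1.97 +/- 0.16 Pg C yr-1 K-1
```

Reading: when E_LUC comes from the bookkeeping limit and S_Intact from the
budget residual, managed land explains ~2% of Var(S_net); the
climate-responsive run attributes 15% to E_LUC outright and 38% once half of
the (negative) E_LUC–S_Intact covariance is ascribed to managed land, rising
to 47% with the shifting-cultivation rotation. The γ decomposition satisfies
γ_LAND = γ_Intact − γ_ELUC exactly: a sizeable part of the land carbon
cycle's temperature sensitivity lives on managed land, which the residual
bookkeeping picture misattributes to intact ecosystems.

The same pipeline is scriptable from the shell:

```sh
luciav generate-forcing --n-years 166 --seed 1 --out-dir forcing/
luciav simulate --schedule forcing/schedule.csv --climate forcing/climate.csv --out fluxes.csv
luciav attribute --fluxes fluxes.csv --climate forcing/climate.csv \
    --window 1959:2015 --exclude 1991:1993 --cov-alloc half --out report.json
```

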
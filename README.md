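# censoc

A CENTURY-style soil organic carbon (SOC) simulator for long-term
wheat–corn fertilization trials, built for agroecosystem modellers who
want a small, fully tested, reproducible implementation of multi-pool
first-order carbon turnover with management scenarios, grid-search
calibration and the standard model-evaluation statistics.

## The model

Soil carbon is split into five conceptual pools — structural and metabolic
litter (each with a surface and a soil compartment), plus active, slow and
passive soil organic matter with turnover times of roughly 3, 0.5, 1.5, 25
and 1000 years.  Each pool decays first order,

```
dC_i/dt = -k_i · DEFAC · M_i · C_i
```

where `DEFAC` is the monthly abiotic factor (the product of a
soil-temperature scalar and a moisture scalar driven by precipitation and
stored soil water) and `M_i` collects texture and tillage modifiers.  A
fixed fraction of each outflow is respired as CO₂; the rest is routed to
receiving pools (litter → active, active → slow/passive, with
stabilization into the slow pool rising with silt+clay and the active-pool
rate rising with sand).  The slow pool's maximum rate `dec4` (per month,
default 0.0023) is the single calibrated parameter; it is fitted by a
multiplicative grid search that raises the rate 10% per step and scores
RMSE against a measured SOC series.

Crop growth is a genetic maximum `PRDX` cut down multiplicatively by 0–1
scalars for temperature, moisture, nutrient sufficiency, seedling
establishment and soil pH:

```
f_pH = clamp((pH - β) / (δ - β), 0, 1),   β = 4.0,  δ = 5.5
```

so growth is unimpaired above pH 5.5 and stops below pH 4.0.  Aboveground
biomass is removed at harvest; carbon reaches the soil via roots, manure
and returned straw.  Model fit is judged with R², RMSE, normalized RMSE
(`n-RMSE = 100/M̄ · √(Σ(Sᵢ-Mᵢ)²/n)`) and Willmott's index of agreement
`d = 1 - Σ(Mᵢ-Sᵢ)²/Σ(|Sᵢ-M̄|+|Mᵢ-M̄|)²`, with acceptance at
`n-RMSE < 15%` and `d > 0.5`.

Three bundled site fixtures (Changping, Yangling, Qiyang) encode the
published soil properties, climate normals and the seven fertilization
treatments (control, N, NP, NPK, NPKM, hNPKM = 1.5×NPKM manure, NPKS with
returned straw) of the corresponding long-term trials, simulated from a
4000-year native-grassland spin-up through 1901–2050.

## Worked example

Simulate the Yangling high-manure treatment to 2050:

```
$ censoc run --site yangling --treatment hNPKM --seed 1 --end-year 2050 --out yl_hnpkm.csv
yangling/hNPKM: SOC in 2050 = 103.1 Mg/ha -> yl_hnpkm.csv
```

The output table holds one 0–20 cm SOC stock per year (Mg/ha), sampled at
the post-corn-harvest month; for this run the stock rises from 44.3 Mg/ha
in 1990 to 103.1 Mg/ha in 2050, i.e. heavy manure roughly doubles the
stock over 60 years, while the control declines.  Absolute stocks depend
on the spin-up initial condition and run higher than the trials' measured
values; treatment contrasts, pool proportions and calibration behaviour
are the quantities the package is designed to reproduce (see
`docs/methods.md`).

Calibrate `dec4` against a (here: synthetic, noiseless) measured series:

```
$ censoc synth --site qiyang --seed 1 --soc-noise-sd 0 --out-dir fixtures
$ censoc calibrate --site qiyang --measured fixtures/qiyang_measured_soc.csv --seed 1 --out grid.csv
best dec4 = 0.004482 (step 7) -> grid.csv
```

The grid table lists each tested rate and its RMSE; the Qiyang fixture
(whose default rate is 0.0045/month) is recovered from the 0.0023 start in
seven 10% steps.

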
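# Methods

## Pool structure and kinetics

Seven carbon stores are tracked (kg C/ha, 0–20 cm): structural and
metabolic litter on the surface and in the soil, plus active, slow and
passive soil organic matter.  The monthly step removes the fraction
`1 − exp(−k·(DEFAC/DEFAC_ref)·m/12)` from each pool, where `k` is the
pool's maximum annual rate, `m` collects modifiers (tillage, and for the
active pool a texture multiplier), and `DEFAC` is the abiotic factor of
that month.  The exponential form is exact for constant rates and cannot
overshoot.  Because every flow is proportional to donor mass, the whole
system is linear in carbon: the simulator exposes the monthly transition
matrix, the spin-up composes twelve of them into an annual affine map and
iterates it, and tests verify superposition and the closed-form fixed
point.

Routing and respiration fractions (all configurable in `DecompParams`):
litter pools send their non-respired outflow to the active pool, except a
structural lignin share (default 0.25) that goes directly to slow; CO₂
fractions are 0.30/0.55 for surface/soil structural, 0.55 for metabolic,
0.45 for slow and 0.55 for passive; the active pool respires
`0.85 − 0.68·(silt+clay)` (≈0.55 on a sandy loam), routes
`0.003 + 0.032·clay` to passive and the remainder to slow, so
stabilization rises with fine texture.  The active-pool rate is scaled by
`(0.25 + 0.75·sand)` normalized to 1 at a reference loam (sand 0.4, silt
0.4, clay 0.2), making the multiplier directly interpretable.

### Turnover times and the reference DEFAC

The nominal turnover times (structural 3 yr, metabolic 0.5 yr, active
1.5 yr, slow 25 yr, passive 1000 yr) are *effective* e-folding times under
typical field conditions, not decay times at maximal abiotic drive.  The
parameterization makes this explicit through `defac_reference` (default
0.2): rates scale as `DEFAC/DEFAC_ref`, so a pool run at `DEFAC = 0.2` —
close to the simulated annual mean at the three sites (~0.23) — exhibits
exactly its configured turnover.  Setting `defac_reference = 1` gives the
nominal interpretation (turnover realized at DEFAC = 1), which is what the
isolated-pool decay analyses use.  Without this scaling the system is
~5× too sluggish and equilibrates at several hundred Mg/ha.

The slow pool is parameterized by `dec4`, its maximum rate per month
(default 0.0023; `DecompParams.from_turnover(25)` expresses it as a
25-year turnover instead).  `dec4` is the single calibrated parameter.

## Abiotic drivers

The temperature scalar is a generalized-Poisson curve with optimum 30 °C,
cutoff 45 °C and shape/decline exponents 1.5/2.5; it is ≈0 below −5 °C and
1 at the optimum.  Soil surface temperature is approximated by
`(tmax+tmin)/2`.  The moisture scalar ramps linearly from a floor of 0.1
at zero water supply to 1 when supply (precipitation + irrigation + stored
soil water) meets demand; demand is Thornthwaite monthly PET computed from
the per-calendar-month temperature climatology.  A single bucket bounded
by field capacity × depth carries water between months (inflow precip +
irrigation, outflow min(PET, supply)); there is no snow, runoff or
layering.  `DEFAC = temperature scalar × moisture scalar`, so only monthly
water totals matter — per-event irrigation splits are irrelevant by
construction.  The printed irrigation amounts (4–5 mm per application) are
small for the region but are used verbatim; they are ordinary schedule
entries and can be rescaled in the site configuration.

## Crop growth and carbon inputs

Monthly shoot growth is `PRDX × Π(scalars)` with scalars for temperature
(crop-specific optimum: wheat 18 °C, corn 30 °C), moisture (shared with
the decomposition model), nutrient sufficiency, seedling establishment
(0.5 in the sowing month, else 1), and soil pH (linear ramp between 4.0
and 5.5).  Roots grow in fixed proportion (wheat 0.40, corn 0.35).  At
harvest, grain (harvest index × shoot) and the remaining aboveground
residue leave the field; all root carbon enters the soil litter through
the lignin:N partition `Fm = 0.85 − 0.018·(L/N)` clamped to [0.2, 0.85].
`PRDX` values (wheat 900, corn 1800, grassland 300 kg C/ha/month) are
fixture calibration constants chosen once for realistic grain yields
(~0.5–1.2 Mg C/ha) and steppe-like spin-up NPP (~2 Mg C/ha/yr); they are
not published values.

Nutrient sufficiency is a configured per-treatment scalar (control 0.4,
N 0.6, NP 0.8, balanced treatments 1.0) standing in for full nutrient
cycling, which is out of scope.  Mineral-fertilizer events carry no
carbon.  On the acid Qiyang soil, treatments receiving mineral N without
manure acidify linearly (default 0.04 pH/yr) over 1990–2010 and hold
constant afterwards; the rate is an assumption (only the endpoints of the
pH–growth response are published) and is configurable per site.

## Management history

Five blocks: native grassland to 1900 (the spin-up), corn monoculture with
a low-yield cultivar 1901–1960, wheat–corn rotation 1961–1988, uniform
tillage with no crop in 1989, and the experiment 1990–2050 with its
1990–2010 management tiled forward.  Pre-1990 manure is 500 kg C/ha/yr at
every site; experiment rates are the published per-site annual totals
(e.g. Changping NPKM 3150, hNPKM = 1.5× = 4725, NPKS straw 1000).  The
pre-1961 "low-yield cultivar" is a 0.5 multiplier on PRDX (no published
value).  Manure is applied once before wheat sowing except at Qiyang
(30% pre-wheat, 70% pre-corn); Qiyang's inter-cropped rotation is
serialized (wheat harvested April, corn sown May).  Ploughing occurs twice
per cropping year and applies a 1.6× decomposition multiplier for that
month.  Manure quality differs by source — farmyard (Changping) lignin
0.08, cattle (Yangling) 0.12, pig (Qiyang) 0.10 — the ordering (farmyard
lowest) is the documented assumption; the numbers are defaults, not data.

## Spin-up and initialization

4000 years of grassland under the site's 12-month climatology bring the
pools to equilibrium; the annual affine map is iterated, which is exactly
the monthly simulation evaluated efficiently.  The passive pool
(effective residence ~900 yr) still drifts ~2×10⁻⁴ per century at year
4000; the spin-up warns when drift exceeds 10⁻⁴ rather than silently
accepting it.  Because initialization is by spin-up rather than by
prescribing measured 1990 stocks, absolute simulated stocks run higher
than the trials' measurements (e.g. ~44 vs 16.4 Mg/ha at Yangling in
1990).  Treatment contrasts, pool proportions, trajectory shapes and
calibration behaviour — the quantities the test suite pins — are
insensitive to this offset; users wanting measured initial stocks can
rescale the spin-up state.

## Synthetic data

Weather: monthly mean temperature is a sinusoid around the site's annual
mean (amplitude 15 °C at the two northern sites, 10 °C at Qiyang; July
peak) with 1 °C Gaussian jitter and a 10 °C diurnal range; precipitation
is the annual normal × a monthly weight profile (summer-peaked monsoon in
the north, spring-shifted subtropical at Qiyang) × a mean-one lognormal
multiplier (σ=0.3).  Generated series reproduce the printed normals
(13.1/14.9/18.1 °C; 515/525/1445 mm) within the tested tolerances and are
bit-stable per seed.  The generator does not model autocorrelation,
extremes or trends, so passing tests say nothing about model behaviour
under real interannual persistence or climate change.  "Measured" SOC
series are simulator output at the post-corn-harvest month plus Gaussian
observation noise (sd as a fraction of the series mean), standing in for
the unpublished per-year field measurements.

## Calibration and evaluation

`calibrate_dec4` re-runs the complete scenario (spin-up included, since
equilibrium depends on dec4) for each candidate on a geometric grid
(ratio 1.1 from 0.0023/month), scores plain RMSE of total SOC stock
against the measured series (monotone-equivalent to n-RMSE for a fixed
series), and stops after the RMSE worsens on two consecutive steps.  On
noiseless self-generated data the generating value is identified exactly
(grid point 0.0023×1.1⁷ = 0.00448 ≈ 0.0045); with 2% observation noise
recovery stays within one grid step.  Calibration uses the control
treatment by default (the calibrated treatment is not published).
Evaluation implements the standard published forms of n-RMSE and
Willmott's d, locked by hand-computed oracles, with the acceptance rule
n-RMSE < 15% and d > 0.5.

## Numerical choices and limitations

Months are indexed 1–12; intervals are closed on both ends.  Reported SOC
includes the soil litter pools (whole-soil measurement convention; a
toggle excludes them).  Bulk density is held at its 1989 value.  Decay
fractions are guarded against grossly mis-scaled rates (k > 2/month
raises).  The isolated-pool decay analysis discards transfers rather than
recycling them, so log-linear fits recover each pool's own e-folding time;
in the coupled system, return flows (slow→active→slow) lengthen apparent
turnover.  Problem sizes used by the test suite and acceptance script —
full 4000-yr spin-ups, 1901–2050 monthly scenarios, ~10-candidate
calibration grids — run in seconds thanks to the linear-map spin-up.
Known limitations: no nitrogen/phosphorus/sulfur cycling (the nutrient
scalar is configured, not emergent), no multi-layer hydrology or erosion,
no phenology or radiation driver, single 0–20 cm slab, and the synthetic
weather realism noted above.
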
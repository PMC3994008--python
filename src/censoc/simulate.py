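"""Scenario engine: spin-up, historical run and projection for one site x treatment.

The timeline follows the five management blocks: a 4000-year native
grassland spin-up brings the pools to equilibrium under the site's
climatology; the schedule then drives 1901-2050 month by month.  Weather
for the 1990-2010 observation window is synthetic but site-faithful
(seeded); all other years run on the 12-month climatology of that window,
which is also how the projection years 2011-2050 are driven.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import crops as crops_mod
from .drivers import defac_series, future_climatology, temperature_factor
from .management import ManagementEvent, SiteConfig, TreatmentSpec, build_schedule, treatment_spec
from .pools import POOLS, DecompParams, PoolState, partition_litter, decompose_month, spinup
from .sites import SITE_NAMES, Site, get_site
from .synthetic import generate_weather

log = logging.getLogger(__name__)

__all__ = ["ScenarioResult", "run_scenario", "build_weather", "spinup_state"]

#: nutrient sufficiency assumed for the uniformly managed 1901-1989 history
HISTORICAL_NUTRIENT_SCALAR = 0.7
#: shoot-growth scalar in the sowing month (seedling establishment)
SEEDLING_SCALAR = 0.5

_IDX = {p: i for i, p in enumerate(POOLS)}


@dataclass
class ScenarioResult:
    """Monthly pool trajectories plus harvest records for one scenario."""

    site: str
    treatment: str
    monthly: pd.DataFrame  # year, month, one column per pool, total_soc (kg C/ha)
    yields: pd.DataFrame  # year, crop, grain_kg_C_ha
    initial_state: PoolState
    params: DecompParams
    sampling_month: int

    def annual_soc(self, include_soil_litter: bool = True) -> pd.DataFrame:
        """Annual SOC stock (Mg/ha) sampled at the post-corn-harvest month."""
        m = self.monthly
        rows = m[m["month"] == self.sampling_month]
        cols = ["active", "slow", "passive"]
        if include_soil_litter:
            cols += ["structural_soil", "metabolic_soil"]
        stock = rows[cols].sum(axis=1) / 1000.0  # kg -> Mg
        return pd.DataFrame({"year": rows["year"].to_numpy(), "stock_Mg_ha": stock.to_numpy()})

    def pools_at(self, year: int) -> dict:
        rows = self.monthly[
            (self.monthly["year"] == year) & (self.monthly["month"] == self.sampling_month)
        ]
        if rows.empty:
            raise ValueError(f"no sampled month for year {year}")
        r = rows.iloc[0]
        return {p: float(r[p]) for p in POOLS}


def build_weather(site: Site, seed: int, start_year: int = 1901, end_year: int = 2050) -> pd.DataFrame:
    """Full monthly weather 1901-2050 for one site.

    The 1990-2010 window is generated from the site normals with the given
    seed; every other year repeats the 12-month climatology of that window,
    including the projection period 2011-2050.
    """
    observed = generate_weather(site.normals, 1990, 21, seed)
    clim = future_climatology(observed)
    frames = []
    for year in range(start_year, end_year + 1):
        if 1990 <= year <= 2010:
            frames.append(observed[observed["year"] == year])
        else:
            block = clim.copy()
            block.insert(0, "year", year)
            frames.append(block[["year", "month", "tmax", "tmin", "precip", "irrigation"]])
    return pd.concat(frames, ignore_index=True)


def _apply_irrigation(weather: pd.DataFrame, events: list[ManagementEvent]) -> pd.DataFrame:
    w = weather.copy()
    irr = {}
    for e in events:
        if e.kind == "irrigate":
            irr[(e.year, e.month)] = irr.get((e.year, e.month), 0.0) + e.amount
    if irr:
        key = list(zip(w["year"], w["month"]))
        w["irrigation"] = w["irrigation"].to_numpy() + np.array([irr.get(k, 0.0) for k in key])
    return w


def _grass_monthly_inputs(
    site: Site, clim_defac: pd.DataFrame, params: DecompParams
) -> list:
    """12 monthly (defac, tillage, pool-input vector) tuples for the spin-up.

    Native grassland grows year-round; monthly shoot production enters
    surface litter and root production enters soil litter (equivalent, at
    cyclic steady state, to live pools with finite residence).
    """
    grass = site.config.grass
    drivers = []
    for _, row in clim_defac.iterrows():
        tf = temperature_factor(row["tmean"], grass.temp_response())
        shoot, root = crops_mod.monthly_production(grass, tf, row["moist_factor"], 1.0, 1.0, 1.0)
        inputs = np.zeros(len(POOLS))
        met_s, str_s = partition_litter(shoot, grass.residue_lignin, grass.residue_n, params)
        met_b, str_b = partition_litter(root, grass.residue_lignin, grass.residue_n, params)
        inputs[_IDX["metabolic_surface"]] += met_s
        inputs[_IDX["structural_surface"]] += str_s
        inputs[_IDX["metabolic_soil"]] += met_b
        inputs[_IDX["structural_soil"]] += str_b
        drivers.append((float(row["defac"]), 1.0, inputs))
    return drivers


def climatology_defac(site: Site, weather: pd.DataFrame, settle_years: int = 5) -> pd.DataFrame:
    """Steady 12-month DEFAC cycle under the site climatology.

    Tiles the climatology for a few years so the water bucket settles, then
    returns the final year's 12 monthly rows.
    """
    clim = future_climatology(weather[(weather["year"] >= 1990) & (weather["year"] <= 2010)])
    frames = []
    for y in range(settle_years):
        block = clim.copy()
        block.insert(0, "year", 1800 + y)
        frames.append(block[["year", "month", "tmax", "tmin", "precip", "irrigation"]])
    tiled = pd.concat(frames, ignore_index=True)
    series = defac_series(tiled, site.config.profile)
    return series.tail(12).reset_index(drop=True)


def spinup_state(
    site: Site,
    params: DecompParams,
    weather: pd.DataFrame,
    years: int = 4000,
) -> PoolState:
    """Equilibrium pools after the native-grassland spin-up."""
    clim_defac = climatology_defac(site, weather)
    drivers = _grass_monthly_inputs(site, clim_defac, params)
    return spinup(drivers, params, site.config.profile, years=years)


def _treatment_ph(site: SiteConfig, spec: TreatmentSpec, year: int) -> float:
    """Soil pH seen by the crop: mineral-only N treatments acidify 1990-2010.

    Manure buffers acidity, so the decline applies only where N comes
    without organic amendment; after 2010 pH is held constant.
    """
    ph = site.profile.ph
    if site.ph_decline_per_year > 0 and spec.mineral_n and spec.manure_c == 0:
        elapsed = min(max(year - 1990, 0), 2010 - 1990)
        ph = max(ph - site.ph_decline_per_year * elapsed, 3.5)
    return ph


def run_scenario(
    site: str | Site,
    treatment: str,
    seed: int = 0,
    start_year: int = 1901,
    end_year: int = 2050,
    dec4: float | None = None,
    params: DecompParams | None = None,
    spinup_years: int = 4000,
    weather: pd.DataFrame | None = None,
) -> ScenarioResult:
    """Simulate one site x treatment from grassland equilibrium to ``end_year``."""
    if isinstance(site, str):
        site = get_site(site)
    cfg = site.config
    if params is None:
        params = DecompParams(dec4=dec4 if dec4 is not None else cfg.dec4_default)
    elif dec4 is not None:
        params = params.with_dec4(dec4)
    spec = treatment_spec(cfg, treatment)
    if weather is None:
        site_seed = int(seed) + 101 * SITE_NAMES.index(cfg.name)
        weather = build_weather(site, site_seed, start_year, end_year)
    events = build_schedule(cfg, treatment, start=start_year, end=end_year)
    weather = _apply_irrigation(weather, events)
    drivers = defac_series(weather, cfg.profile)

    state = spinup_state(site, params, weather, years=spinup_years)
    equilibrium = state
    by_month: dict[tuple[int, int], list[ManagementEvent]] = {}
    for e in events:
        by_month.setdefault((e.year, e.month), []).append(e)

    crop_state = {"wheat": None, "corn": None}  # None = not planted
    records = []
    yield_rows = []
    driver_rows = drivers.itertuples(index=False)
    wx_rows = weather.itertuples(index=False)
    for drv, wx in zip(driver_rows, wx_rows):
        year, month = int(drv.year), int(drv.month)
        till = 1.0
        inputs = np.zeros(len(POOLS))
        prdx_mult = cfg.pre1961_prdx_multiplier if year <= 1988 else 1.0
        nutrient = HISTORICAL_NUTRIENT_SCALAR if year < 1990 else spec.nutrient_scalar
        for e in by_month.get((year, month), []):
            if e.kind == "harvest":
                crop = getattr(cfg, e.crop)
                plant = crop_state[e.crop]
                if plant is None:
                    continue
                plant, res = crops_mod.harvest(plant, crop, straw_return=0.0, decomp_params=params)
                crop_state[e.crop] = None
                met, struc = res.root_to_soil_litter
                inputs[_IDX["metabolic_soil"]] += met
                inputs[_IDX["structural_soil"]] += struc
                yield_rows.append((year, e.crop, res.grain_removed))
            elif e.kind == "plough":
                till = max(till, e.amount)
            elif e.kind in ("manure", "straw"):
                # incorporated organic inputs enter the soil litter pools
                met, struc = partition_litter(e.amount, e.lignin, e.n, params, when=f"{year}-{month:02d}")
                inputs[_IDX["metabolic_soil"]] += met
                inputs[_IDX["structural_soil"]] += struc
            elif e.kind == "plant":
                crop_state[e.crop] = crops_mod.PlantState()
            # fertilize/irrigate events carry no direct carbon

        # crop growth for every live crop whose season includes this month
        ph = _treatment_ph(cfg, spec, year)
        for name, plant in crop_state.items():
            if plant is None:
                continue
            crop = getattr(cfg, name)
            if month not in crop.growing_months():
                continue
            tf = temperature_factor(drv.tmean, crop.temp_response())
            seedling = SEEDLING_SCALAR if month == crop.sowing_month else 1.0
            fph = crops_mod.ph_factor(ph, crop.ph_delta, crop.ph_beta)
            eff_crop = replace(crop, prdx=crop.prdx * prdx_mult)
            shoot, root = crops_mod.monthly_production(
                eff_crop, tf, drv.moist_factor, nutrient, seedling, fph
            )
            crop_state[name] = crops_mod.PlantState(
                shoot=plant.shoot + shoot, root=plant.root + root, standing_dead=plant.standing_dead
            )

        arr = state.as_array() + inputs
        state = PoolState.from_array(arr, cumulative_co2=state.cumulative_co2)
        state, _ = decompose_month(state, float(drv.defac), params, cfg.profile, till)
        records.append((year, month, *state.as_array(), state.total_soc()))

    monthly = pd.DataFrame(records, columns=["year", "month", *POOLS, "total_soc"])
    yields = pd.DataFrame(yield_rows, columns=["year", "crop", "grain_kg_C_ha"])
    return ScenarioResult(
        site=cfg.name,
        treatment=treatment,
        monthly=monthly,
        yields=yields,
        initial_state=equilibrium,
        params=params,
        sampling_month=cfg.corn.harvest_month,
    )
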
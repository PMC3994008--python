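"""Monthly abiotic decomposition factor (DEFAC).

DEFAC is the product of a soil-temperature scalar and a soil-moisture
scalar, both in [0, 1], computed per calendar month.  Temperature follows a
generalized-Poisson response peaking at a configurable optimum; moisture is
a ramp in the ratio of water supply (precipitation + irrigation + stored
soil water) to a Thornthwaite-style evaporative demand, backed by a
single-bucket store bounded by field capacity over the 0-20 cm slab.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pools import SiteProfile

log = logging.getLogger(__name__)

__all__ = [
    "MonthlyWeather",
    "WaterState",
    "TempResponse",
    "MoistureResponse",
    "temperature_factor",
    "moisture_factor",
    "defac",
    "defac_series",
    "thornthwaite_pet",
    "future_climatology",
]

WEATHER_COLUMNS = ["year", "month", "tmax", "tmin", "precip", "irrigation"]


@dataclass
class MonthlyWeather:
    """One month of weather: temperatures in deg C, water in mm."""

    year: int
    month: int
    tmax: float
    tmin: float
    precip: float
    irrigation: float = 0.0

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise ValueError(f"{self.year}-{self.month:02d}: tmax {self.tmax} < tmin {self.tmin}")
        if self.precip < 0 or self.irrigation < 0:
            raise ValueError(f"{self.year}-{self.month:02d}: negative water input")

    @property
    def tmean(self) -> float:
        return 0.5 * (self.tmax + self.tmin)


@dataclass
class WaterState:
    """Single-bucket soil water store (mm) bounded by field capacity."""

    stored: float
    capacity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.stored <= self.capacity:
            raise ValueError(f"stored water {self.stored} outside [0, {self.capacity}]")

    @classmethod
    def for_site(cls, site: SiteProfile, fill: float = 0.5) -> "WaterState":
        cap = site.field_capacity * site.depth_cm * 10.0  # cm * fraction -> mm
        return cls(stored=fill * cap, capacity=cap)


@dataclass
class TempResponse:
    """Generalized-Poisson temperature curve: 1 at the optimum, 0 above t_max.

    f(T) = r**shape * exp((shape/decline) * (1 - r**decline)),
    r = (t_max - T) / (t_max - t_opt); f = 0 for T >= t_max.
    """

    t_opt: float = 30.0
    t_max: float = 45.0
    shape: float = 1.5
    decline: float = 2.5


@dataclass
class MoistureResponse:
    """Linear ramp from ``floor`` at zero supply to 1 at supply >= demand."""

    floor: float = 0.1


def temperature_factor(tmean: float, response: TempResponse | None = None) -> float:
    """Soil-temperature scalar in [0, 1] for monthly mean surface temperature."""
    r = response or TempResponse()
    if not math.isfinite(tmean):
        raise ValueError("temperature must be finite")
    if tmean >= r.t_max:
        return 0.0
    ratio = (r.t_max - tmean) / (r.t_max - r.t_opt)
    val = ratio**r.shape * math.exp((r.shape / r.decline) * (1.0 - ratio**r.decline))
    return min(max(val, 0.0), 1.0)


def moisture_factor(
    supply: float,
    demand: float,
    response: MoistureResponse | None = None,
) -> float:
    """Soil-moisture scalar: ramps with supply/demand, saturating at 1."""
    r = response or MoistureResponse()
    if supply < 0 or demand < 0:
        raise ValueError("water supply and demand must be non-negative")
    if demand == 0:
        log.debug("zero evaporative demand: moisture factor set to 1 (no limitation)")
        return 1.0
    ratio = min(supply / demand, 1.0)
    return r.floor + (1.0 - r.floor) * ratio


def defac(temp_factor: float, moist_factor: float) -> float:
    """Abiotic decomposition factor: product of the two scalars."""
    for name, v in (("temperature", temp_factor), ("moisture", moist_factor)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} factor {v} outside [0, 1]")
    return temp_factor * moist_factor


_DAYS = np.array([31, 28.25, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


def thornthwaite_pet(tmean_months: np.ndarray) -> np.ndarray:
    """Thornthwaite potential evapotranspiration (mm/month) from 12 monthly means.

    Uses the standard annual heat index I = sum((T/5)**1.514) over months
    with T > 0 and PET = 16 * (10 T / I)**a scaled by month length; a crude
    but adequate monthly demand proxy.
    """
    t = np.asarray(tmean_months, dtype=float)
    if t.shape != (12,):
        raise ValueError("expected 12 monthly mean temperatures")
    tp = np.clip(t, 0.0, None)
    heat = float(np.sum((tp / 5.0) ** 1.514))
    if heat <= 0:
        return np.zeros(12)
    a = 6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239
    pet = 16.0 * (10.0 * tp / heat) ** a
    return pet * (_DAYS / 30.0)


def defac_series(
    weather: pd.DataFrame,
    site: SiteProfile,
    temp_response: TempResponse | None = None,
    moist_response: MoistureResponse | None = None,
    initial_fill: float = 0.5,
) -> pd.DataFrame:
    """Compute monthly DEFAC over a weather series with the water bucket.

    ``weather`` must have columns year, month, tmax, tmin, precip and
    optionally irrigation; months must be contiguous.  Returns a frame with
    columns year, month, tmean, pet, temp_factor, moist_factor, defac.
    """
    w = weather.copy()
    if "irrigation" not in w.columns:
        w["irrigation"] = 0.0
    _check_contiguous(w)
    # PET demand from the per-calendar-month mean temperature climatology
    tmean = 0.5 * (w["tmax"].to_numpy() + w["tmin"].to_numpy())
    w = w.assign(tmean=tmean)
    clim = w.groupby("month")["tmean"].mean().reindex(range(1, 13)).to_numpy()
    pet12 = thornthwaite_pet(np.nan_to_num(clim))
    water = WaterState.for_site(site, fill=initial_fill)
    rows = []
    for rec in w.itertuples(index=False):
        pet = float(pet12[rec.month - 1])
        inflow = rec.precip + rec.irrigation
        supply = inflow + water.stored
        tf = temperature_factor(rec.tmean, temp_response)
        mf = moisture_factor(supply, pet, moist_response)
        d = defac(tf, mf)
        # bucket update: add inflow, evaporate up to PET, spill above capacity
        stored = min(max(water.stored + inflow - pet, 0.0), water.capacity)
        water = WaterState(stored=stored, capacity=water.capacity)
        rows.append((rec.year, rec.month, rec.tmean, pet, tf, mf, d))
    return pd.DataFrame(
        rows, columns=["year", "month", "tmean", "pet", "temp_factor", "moist_factor", "defac"]
    )


def future_climatology(weather: pd.DataFrame) -> pd.DataFrame:
    """Mean 12-month driver cycle from a multi-year weather record.

    For each calendar month, averages tmax, tmin, precip and irrigation
    across all years present; the returned 12-row cycle is what drives the
    projection years beyond the observed record.
    """
    _check_contiguous(weather)
    w = weather.copy()
    if "irrigation" not in w.columns:
        w["irrigation"] = 0.0
    if w["year"].nunique() < 2:
        raise ValueError("need at least 2 complete years for a climatology")
    counts = w.groupby("month").size()
    missing = [m for m in range(1, 13) if m not in counts.index]
    if missing:
        raise ValueError(f"missing calendar months in weather record: {missing}")
    out = (
        w.groupby("month")[["tmax", "tmin", "precip", "irrigation"]]
        .mean()
        .reindex(range(1, 13))
        .reset_index()
    )
    return out


def _check_contiguous(weather: pd.DataFrame) -> None:
    for col in ("year", "month", "tmax", "tmin", "precip"):
        if col not in weather.columns:
            raise ValueError(f"weather table missing column {col!r}")
    seq = weather["year"].to_numpy() * 12 + (weather["month"].to_numpy() - 1)
    if len(seq) > 1 and not np.all(np.diff(seq) == 1):
        gaps = np.nonzero(np.diff(seq) != 1)[0]
        first = weather.iloc[int(gaps[0])]
        raise ValueError(
            f"weather months not contiguous after {int(first.year)}-{int(first.month):02d}"
        )
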
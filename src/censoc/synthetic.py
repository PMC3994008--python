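"""Synthetic inputs: site-faithful monthly weather and noisy "measured" SOC.

The weather generator reproduces each site's printed climate normals —
annual mean temperature 13.1 / 14.9 / 18.1 deg C and annual precipitation
515 / 525 / 1445 mm for Changping / Yangling / Qiyang — with a sinusoidal
seasonal temperature cycle plus Gaussian jitter and a summer-peaked
(monsoon) monthly precipitation profile with lognormal variability.  The
"measured" SOC generator runs the simulator and adds observation noise,
standing in for field sampling error.  Everything is driven by explicit
seeds and is bit-stable per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ClimateNormals", "NoiseModel", "generate_weather", "generate_measured_soc"]

#: monsoon-type monthly precipitation weights (Jun-Sep heavy), summing to 1
MONSOON_WEIGHTS = np.array(
    [0.01, 0.015, 0.025, 0.04, 0.07, 0.14, 0.22, 0.20, 0.13, 0.08, 0.04, 0.03]
)
#: wetter-winter subtropical profile used for the humid southern site
SUBTROPICAL_WEIGHTS = np.array(
    [0.05, 0.07, 0.10, 0.12, 0.14, 0.14, 0.10, 0.09, 0.07, 0.06, 0.04, 0.02]
)


@dataclass
class ClimateNormals:
    """Per-site climate description anchoring the weather generator."""

    annual_mean_t: float  # deg C
    annual_precip: float  # mm
    seasonal_amplitude: float = 15.0  # half peak-to-trough of monthly means, deg C
    diurnal_range: float = 10.0  # tmax - tmin, deg C
    precip_weights: np.ndarray = field(default_factory=lambda: MONSOON_WEIGHTS.copy())
    temp_jitter_sd: float = 1.0  # deg C, monthly
    precip_lognorm_sd: float = 0.3  # sd of log multiplier (mean-1 lognormal)

    def __post_init__(self) -> None:
        self.precip_weights = np.asarray(self.precip_weights, dtype=float)
        if abs(self.precip_weights.sum() - 1.0) > 1e-9:
            raise ValueError("precipitation weights must sum to 1")
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal amplitude must be >= 0")


@dataclass
class NoiseModel:
    """Observation noise on measured SOC: sd as a fraction of the series mean."""

    sd: float = 0.02

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")


def generate_weather(
    normals: ClimateNormals, start_year: int, n_years: int, seed: int
) -> pd.DataFrame:
    """Seeded monthly weather series matching the site's climate normals.

    Monthly mean temperature = annual mean - amplitude * cos(2 pi (m-1)/12)
    (northern-hemisphere July peak) plus Gaussian jitter; tmax/tmin bracket
    it by half the diurnal range.  Monthly precipitation = annual total x
    month weight x a mean-one lognormal multiplier.
    """
    if n_years < 1:
        raise ValueError("need at least one year")
    rng = np.random.default_rng(seed)
    rows = []
    for year in range(start_year, start_year + n_years):
        for m in range(1, 13):
            t = normals.annual_mean_t - normals.seasonal_amplitude * np.cos(
                2.0 * np.pi * (m - 1) / 12.0
            )
            t += rng.normal(0.0, normals.temp_jitter_sd)
            sd = normals.precip_lognorm_sd
            mult = float(np.exp(rng.normal(-0.5 * sd**2, sd)))
            precip = normals.annual_precip * normals.precip_weights[m - 1] * mult
            rows.append(
                (
                    year,
                    m,
                    t + 0.5 * normals.diurnal_range,
                    t - 0.5 * normals.diurnal_range,
                    precip,
                    0.0,
                )
            )
    return pd.DataFrame(rows, columns=["year", "month", "tmax", "tmin", "precip", "irrigation"])


def generate_measured_soc(
    site_name: str,
    treatment: str,
    noise: NoiseModel,
    seed: int,
    start_year: int = 1990,
    end_year: int = 2008,
    dec4: float | None = None,
    spinup_years: int = 4000,
) -> pd.DataFrame:
    """Synthetic annual "measured" SOC series (Mg/ha) for a site x treatment.

    Runs the full scenario, samples the total SOC stock at the
    post-corn-harvest month of each year, and adds seeded Gaussian noise
    with sd = ``noise.sd`` x series mean.  With ``noise.sd == 0`` the
    series equals the simulated stocks exactly.
    """
    from .simulate import run_scenario  # runtime import: simulator sits above this module

    result = run_scenario(
        site_name,
        treatment,
        seed=seed,
        end_year=end_year,
        dec4=dec4,
        spinup_years=spinup_years,
    )
    annual = result.annual_soc()
    annual = annual[(annual["year"] >= start_year) & (annual["year"] <= end_year)].copy()
    rng = np.random.default_rng(seed + 7919)  # distinct stream from the weather seed
    noise_draw = rng.normal(0.0, noise.sd * annual["stock_Mg_ha"].mean(), size=len(annual))
    annual["stock_Mg_ha"] = annual["stock_Mg_ha"] + noise_draw
    return annual.reset_index(drop=True)
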
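"""Monthly crop production, allocation and harvest.

Potential aboveground production is a genetic maximum (PRDX, kg C/ha/month)
cut down multiplicatively by 0-1 scalars for temperature, moisture,
nutrient sufficiency, shading and seedling establishment, plus a soil-pH
scalar: growth is unaffected above pH 5.5 and stops entirely below pH 4.0,
with a linear ramp between.  Shoots and roots grow in fixed proportion;
at harvest the grain (harvest index x shoot) and the remaining aboveground
residue leave the field, while all root carbon enters the soil litter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .drivers import TempResponse, temperature_factor
from .pools import DecompParams, partition_litter

__all__ = ["CropParams", "PlantState", "HarvestResult", "ph_factor", "monthly_production", "harvest"]


@dataclass
class CropParams:
    """Per-crop production and residue-quality parameters."""

    name: str
    prdx: float  # genetic max aboveground production, kg C/ha/month
    sowing_month: int
    harvest_month: int
    root_shoot_ratio: float = 0.5
    harvest_index: float = 0.45
    residue_lignin: float = 0.10
    residue_n: float = 0.008
    t_opt: float = 25.0
    t_max: float = 40.0
    ph_delta: float = 5.5  # growth unimpaired at or above this pH
    ph_beta: float = 4.0  # growth stops at or below this pH

    def __post_init__(self) -> None:
        if not 0.0 < self.harvest_index < 1.0:
            raise ValueError("harvest index must be in (0, 1)")
        if self.root_shoot_ratio <= 0:
            raise ValueError("root:shoot ratio must be positive")
        if self.ph_beta >= self.ph_delta:
            raise ValueError("pH beta (growth stop) must be below delta (no impact)")

    def temp_response(self) -> TempResponse:
        return TempResponse(t_opt=self.t_opt, t_max=self.t_max)

    def growing_months(self) -> list[int]:
        """Calendar months from sowing to harvest inclusive, wrapping year end."""
        m = self.sowing_month
        months = [m]
        while m != self.harvest_month:
            m = m % 12 + 1
            months.append(m)
        return months


@dataclass
class PlantState:
    """Live and standing-dead plant carbon, kg C/ha."""

    shoot: float = 0.0
    root: float = 0.0
    standing_dead: float = 0.0

    def __post_init__(self) -> None:
        if min(self.shoot, self.root, self.standing_dead) < 0:
            raise ValueError("plant pools cannot be negative")


@dataclass
class HarvestResult:
    """Carbon bookkeeping of one harvest event, kg C/ha."""

    grain_removed: float
    residue_removed: float
    residue_to_surface_litter: tuple[float, float]  # (metabolic, structural)
    root_to_soil_litter: tuple[float, float]


def ph_factor(ph: float, delta: float = 5.5, beta: float = 4.0) -> float:
    """Soil-pH growth scalar: 0 at/below ``beta``, 1 at/above ``delta``.

    Rendered as the linear ramp (pH - beta) / (delta - beta) clamped to
    [0, 1] — the simplest form meeting both printed boundary conditions.
    """
    if beta >= delta:
        raise ValueError("beta must be below delta")
    return min(max((ph - beta) / (delta - beta), 0.0), 1.0)


def monthly_production(
    crop: CropParams,
    temp_scalar: float,
    moisture_scalar: float,
    nutrient_scalar: float,
    shading_scalar: float = 1.0,
    ph_scalar: float = 1.0,
) -> tuple[float, float]:
    """Shoot and root growth (kg C/ha) for one in-season month.

    shoot = PRDX x product of all limitation scalars; root = shoot x
    root:shoot ratio.  Any scalar at 0 shuts production off entirely.
    """
    scalars = {
        "temperature": temp_scalar,
        "moisture": moisture_scalar,
        "nutrient": nutrient_scalar,
        "shading": shading_scalar,
        "pH": ph_scalar,
    }
    for name, v in scalars.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} scalar {v} outside [0, 1]")
    shoot = crop.prdx
    for v in scalars.values():
        shoot *= v
    return shoot, shoot * crop.root_shoot_ratio


def harvest(
    plant: PlantState,
    crop: CropParams,
    straw_return: float = 0.0,
    external_straw: float = 0.0,
    decomp_params: DecompParams | None = None,
) -> tuple[PlantState, HarvestResult]:
    """Harvest the crop: remove grain and residue, return roots to the soil.

    Grain = harvest index x live shoot.  Aboveground residue is removed
    from the field except ``straw_return`` kg C/ha, which enters surface
    litter via the lignin:N partition.  ``external_straw`` declares straw
    imported from outside the plot (the straw-return treatments), which may
    be returned on top of what grew in place.  All root carbon joins the
    soil litter; plant pools reset to zero.
    """
    if straw_return < 0:
        raise ValueError("straw return cannot be negative")
    grain = crop.harvest_index * plant.shoot
    residue = plant.shoot - grain + plant.standing_dead
    if straw_return > residue + external_straw + 1e-9:
        raise ValueError(
            f"straw return {straw_return:.1f} kg C/ha exceeds available residue "
            f"{residue:.1f} plus declared external straw {external_straw:.1f}"
        )
    surface = partition_litter(
        straw_return, crop.residue_lignin, crop.residue_n, decomp_params
    )
    roots = partition_litter(plant.root, crop.residue_lignin, crop.residue_n, decomp_params)
    # only return drawn from in-place residue reduces what is carted away
    in_place_return = min(max(straw_return - external_straw, 0.0), residue)
    removed = residue - in_place_return
    result = HarvestResult(
        grain_removed=grain,
        residue_removed=removed,
        residue_to_surface_litter=surface,
        root_to_soil_litter=roots,
    )
    return PlantState(), result
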
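"""SOC stock accounting, pool proportions and scenario summaries.

The field convention converts a 0-20 cm SOC concentration (g/kg) to an
areal stock (Mg/ha) by stock = concentration x bulk density x depth x 0.1;
the sequestration potential of a treatment is the simulated stock
increment between 1990 and the 2050 end of simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .simulate import ScenarioResult

__all__ = [
    "soc_stock",
    "stock_to_concentration",
    "sequestration_potential",
    "pool_breakdown",
    "scenario_report",
]

MINERAL_POOLS = ("active", "slow", "passive")


def soc_stock(concentration_g_kg: float, bulk_density: float, depth_cm: float = 20.0) -> float:
    """SOC stock in Mg/ha from concentration (g/kg), bulk density (g/cm3), depth (cm)."""
    if concentration_g_kg <= 0 or bulk_density <= 0 or depth_cm <= 0:
        raise ValueError("concentration, bulk density and depth must all be positive")
    return concentration_g_kg * bulk_density * depth_cm * 0.1


def stock_to_concentration(stock_Mg_ha: float, bulk_density: float, depth_cm: float = 20.0) -> float:
    """Inverse of :func:`soc_stock`."""
    if stock_Mg_ha <= 0 or bulk_density <= 0 or depth_cm <= 0:
        raise ValueError("stock, bulk density and depth must all be positive")
    return stock_Mg_ha / (bulk_density * depth_cm * 0.1)


def sequestration_potential(soc_start: float, soc_end: float) -> float:
    """Stock increment (Mg/ha) over the simulation; negative if SOC declined."""
    if soc_start < 0 or soc_end < 0:
        raise ValueError("stocks cannot be negative")
    return soc_end - soc_start


def pool_breakdown(result: ScenarioResult, years: list[int] | None = None) -> pd.DataFrame:
    """Active/slow/passive masses (Mg/ha) and fractions of their total, per year."""
    annual = result.monthly[result.monthly["month"] == result.sampling_month]
    if years is not None:
        annual = annual[annual["year"].isin(years)]
    rows = []
    for rec in annual.itertuples(index=False):
        masses = {p: getattr(rec, p) / 1000.0 for p in MINERAL_POOLS}
        total = sum(masses.values())
        row = {"year": int(rec.year)}
        for p in MINERAL_POOLS:
            row[p] = masses[p]
            row[f"{p}_fraction"] = masses[p] / total if total > 0 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def scenario_report(results: list[ScenarioResult], start_year: int = 1990, end_year: int = 2050) -> pd.DataFrame:
    """Summary table: one row per treatment with endpoint stocks and potential."""
    rows = []
    for res in results:
        annual = res.annual_soc()
        start = float(annual.loc[annual["year"] == start_year, "stock_Mg_ha"].iloc[0])
        end = float(annual.loc[annual["year"] == end_year, "stock_Mg_ha"].iloc[0])
        rows.append(
            {
                "site": res.site,
                "treatment": res.treatment,
                f"soc_{start_year}": round(start, 1),
                f"soc_{end_year}": round(end, 1),
                "potential": round(sequestration_potential(start, end), 1),
            }
        )
    return pd.DataFrame(rows)
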
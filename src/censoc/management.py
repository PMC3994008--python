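"""Management periods, fertilization treatments and dated event schedules.

The simulated history runs 1900-2050 in five blocks: a native-grassland
spin-up (handled by the simulator, not the schedule), corn with a
low-yielding cultivar 1901-1960, a wheat-corn rotation 1961-1988, a
uniform-tillage year 1989 with no crop, and the long-term fertilization
experiment 1990-2050 in which the observed 1990-2010 management pattern is
tiled forward.  Seven treatments are encoded: control, N, NP, NPK, NPKM,
hNPKM (1.5x the NPKM manure rate) and NPKS (mineral NPK plus returned
straw).  Manure and straw carbon rates are per-site annual totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .crops import CropParams
from .pools import SiteProfile

__all__ = [
    "TREATMENTS",
    "PeriodSpec",
    "TreatmentSpec",
    "ManagementEvent",
    "SiteConfig",
    "PERIODS",
    "treatment_spec",
    "build_schedule",
    "annual_external_c_input",
    "manure_timing",
    "schedule_to_table",
]

TREATMENTS = ("control", "N", "NP", "NPK", "NPKM", "hNPKM", "NPKS")

#: treatment nutrient-sufficiency scalars (full N-P-K balance -> 1.0);
#: control lowest, reflecting chronic nutrient deficiency
NUTRIENT_SCALARS = {
    "control": 0.4,
    "N": 0.6,
    "NP": 0.8,
    "NPK": 1.0,
    "NPKM": 1.0,
    "hNPKM": 1.0,
    "NPKS": 1.0,
}

EVENT_KINDS = ("plant", "harvest", "plough", "manure", "straw", "irrigate", "fertilize")


@dataclass(frozen=True)
class PeriodSpec:
    """One management block of the 1900-2050 history."""

    label: str
    start: int
    end: int
    sequence_years: int
    land_use: str


PERIODS = (
    PeriodSpec("native grassland", 1900, 1900, 1, "grassland"),
    PeriodSpec("corn, low-yield cultivar", 1901, 1960, 1, "corn"),
    PeriodSpec("wheat-corn rotation, low-yield cultivar", 1961, 1988, 2, "wheat-corn"),
    PeriodSpec("uniform tillage, no crop", 1989, 1989, 1, "fallow"),
    PeriodSpec("long-term fertilization experiment", 1990, 2050, 2, "wheat-corn"),
)


@dataclass(frozen=True)
class ManagementEvent:
    """One dated management action.

    ``amount`` is kg C/ha for manure/straw, mm for irrigation, and the
    decomposition multiplier for plough events; quality fractions apply to
    organic inputs only.
    """

    year: int
    month: int
    kind: str
    amount: float = 0.0
    lignin: float = 0.0
    n: float = 0.0
    crop: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}; expected one of {EVENT_KINDS}")
        if not 1 <= self.month <= 12:
            raise ValueError(f"month {self.month} out of range")


@dataclass
class SiteConfig:
    """Everything site-specific the simulator needs besides weather."""

    name: str
    profile: SiteProfile
    wheat: CropParams
    corn: CropParams
    grass: CropParams
    plough_months: tuple[int, int]
    manure_wheat_month: int
    manure_corn_month: int
    manure_split_wheat: float  # fraction of annual manure applied pre-wheat
    straw_months: tuple[tuple[int, float], ...]  # (month, fraction of annual straw C)
    irrigation_mm: tuple[tuple[int, float], ...]  # (month, mm)
    npkm_rate: float  # Table-2 annual manure C, NPKM treatment
    npks_rate: float  # Table-2 annual straw C, NPKS treatment
    manure_lignin: float = 0.10
    manure_n: float = 0.02
    pre1990_manure: float = 500.0
    pre1961_prdx_multiplier: float = 0.5
    hnpkm_factor: float = 1.5
    #: annual pH decline 1990-2010 under acidifying mineral-N treatments
    ph_decline_per_year: float = 0.0
    initial_soc_g_kg: float = 0.0
    dec4_default: float = 0.0023


@dataclass(frozen=True)
class TreatmentSpec:
    """Resolved per-site treatment: organic input rates and nutrient status."""

    code: str
    manure_c: float  # kg C/ha/yr
    straw_c: float  # kg C/ha/yr
    nutrient_scalar: float
    manure_lignin: float
    manure_n: float
    mineral_n: bool  # receives mineral N fertilizer (drives acidification)

    def __post_init__(self) -> None:
        if self.code == "control" and (self.manure_c or self.straw_c):
            raise ValueError("control treatment cannot have organic inputs")


def treatment_spec(site: SiteConfig, code: str) -> TreatmentSpec:
    """Resolve a treatment code to its per-site input rates."""
    if code not in TREATMENTS:
        raise ValueError(f"unknown treatment {code!r}; valid codes: {', '.join(TREATMENTS)}")
    manure = 0.0
    straw = 0.0
    if code == "NPKM":
        manure = site.npkm_rate
    elif code == "hNPKM":
        manure = site.hnpkm_factor * site.npkm_rate
    elif code == "NPKS":
        straw = site.npks_rate
    return TreatmentSpec(
        code=code,
        manure_c=manure,
        straw_c=straw,
        nutrient_scalar=NUTRIENT_SCALARS[code],
        manure_lignin=site.manure_lignin,
        manure_n=site.manure_n,
        mineral_n=code != "control",
    )


def annual_external_c_input(site: SiteConfig, code: str, period: str = "experiment") -> float:
    """Annual manure+straw carbon input (kg C/ha/yr) for a site x treatment.

    ``period`` is "experiment" (1990-2050) or one of "1901-1960",
    "1961-1988", "1989" (treatment-independent historical blocks).
    """
    if period == "1989":
        return 0.0
    if period in ("1901-1960", "1961-1988"):
        return site.pre1990_manure
    if period != "experiment":
        raise ValueError(f"unknown period {period!r}")
    spec = treatment_spec(site, code)
    return spec.manure_c + spec.straw_c


def manure_timing(site: SiteConfig) -> list[tuple[str, float]]:
    """Within-year manure split: [(label, fraction)], fractions summing to 1."""
    if site.manure_split_wheat >= 1.0:
        return [("pre-wheat", 1.0)]
    return [
        ("pre-wheat", site.manure_split_wheat),
        ("pre-corn", 1.0 - site.manure_split_wheat),
    ]


def _manure_events(site: SiteConfig, year: int, annual_c: float, lignin: float, n: float):
    events = []
    for label, frac in manure_timing(site):
        month = site.manure_wheat_month if label == "pre-wheat" else site.manure_corn_month
        events.append(
            ManagementEvent(year, month, "manure", amount=annual_c * frac, lignin=lignin, n=n)
        )
    return events


def _crop_events(site: SiteConfig, year: int, crops: tuple[str, ...]):
    events = []
    for name in crops:
        crop = getattr(site, name)
        events.append(ManagementEvent(year, crop.sowing_month, "plant", crop=name))
        events.append(ManagementEvent(year, crop.harvest_month, "harvest", crop=name))
    return events


def build_schedule(site: SiteConfig, code: str, start: int = 1901, end: int = 2050):
    """Ordered management events for one site x treatment, 1901-2050.

    Pre-1990 blocks are identical across treatments (500 kg C/ha/yr of
    manure during cropping years); treatment-specific inputs begin with the
    experiment in 1990.  Ploughing occurs twice per cropping year.
    """
    spec = treatment_spec(site, code)
    events: list[ManagementEvent] = []
    till = 1.6  # decomposition multiplier carried on plough events
    for year in range(start, end + 1):
        if year <= 1960:  # corn monoculture, low-yield cultivar
            events += _crop_events(site, year, ("corn",))
            events += [
                ManagementEvent(year, m, "plough", amount=till) for m in site.plough_months
            ]
            events += _manure_events(site, year, site.pre1990_manure, site.manure_lignin, site.manure_n)
        elif year <= 1988:  # wheat-corn rotation, chemical fertilizer + manure
            events += _crop_events(site, year, ("wheat", "corn"))
            events += [
                ManagementEvent(year, m, "plough", amount=till) for m in site.plough_months
            ]
            events += _manure_events(site, year, site.pre1990_manure, site.manure_lignin, site.manure_n)
            events.append(ManagementEvent(year, site.manure_wheat_month, "fertilize"))
        elif year == 1989:  # uniform tillage, no crop
            events += [
                ManagementEvent(year, m, "plough", amount=till) for m in site.plough_months
            ]
        else:  # long-term experiment, 1990-2010 pattern tiled to 2050
            events += _crop_events(site, year, ("wheat", "corn"))
            events += [
                ManagementEvent(year, m, "plough", amount=till) for m in site.plough_months
            ]
            if spec.manure_c > 0:
                events += _manure_events(site, year, spec.manure_c, spec.manure_lignin, spec.manure_n)
            if spec.straw_c > 0:
                for month, frac in site.straw_months:
                    events.append(
                        ManagementEvent(
                            year,
                            month,
                            "straw",
                            amount=spec.straw_c * frac,
                            lignin=site.wheat.residue_lignin,
                            n=site.wheat.residue_n,
                        )
                    )
            if spec.code != "control":
                events.append(ManagementEvent(year, site.manure_wheat_month, "fertilize"))
            for month, mm in site.irrigation_mm:
                events.append(ManagementEvent(year, month, "irrigate", amount=mm))
    events.sort(key=lambda e: (e.year, e.month, _WITHIN_MONTH_ORDER[e.kind]))
    return events


#: within-month processing order: harvest the standing crop, plough, apply
#: organic/mineral inputs and water, then sow the next crop
_WITHIN_MONTH_ORDER = {
    "harvest": 0,
    "plough": 1,
    "manure": 2,
    "straw": 3,
    "fertilize": 4,
    "irrigate": 5,
    "plant": 6,
}


def schedule_to_table(events):
    """Serialize a schedule to a tidy table for audit."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "year": e.year,
                "month": e.month,
                "kind": e.kind,
                "amount": e.amount,
                "lignin": e.lignin,
                "n": e.n,
                "crop": e.crop,
            }
            for e in events
        ]
    )
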
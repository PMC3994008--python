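"""Bundled configurations for the three long-term trial sites.

Changping (semi-humid, silt loam, pH 8.7), Yangling (warm-temperate, silt
loam, pH 8.6) and Qiyang (humid subtropical, red clay, pH 5.7) run a
winter-wheat / summer-corn double crop.  Soil physical properties, climate
normals and annual organic-carbon input rates are the published site
values; crop PRDX values and manure quality fractions are fixture
calibration constants, not published numbers.

Note the printed Changping texture separates total 98.4%; the residual is
folded into silt so fractions close to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

from .crops import CropParams
from .management import SiteConfig
from .pools import SiteProfile
from .synthetic import MONSOON_WEIGHTS, SUBTROPICAL_WEIGHTS, ClimateNormals

__all__ = ["Site", "SITE_NAMES", "get_site"]

SITE_NAMES = ("changping", "yangling", "qiyang")


@dataclass
class Site:
    config: SiteConfig
    normals: ClimateNormals


def _wheat(sowing: int, harvest: int, prdx: float = 900.0) -> CropParams:
    return CropParams(
        name="wheat",
        prdx=prdx,
        sowing_month=sowing,
        harvest_month=harvest,
        root_shoot_ratio=0.40,
        harvest_index=0.42,
        residue_lignin=0.09,
        residue_n=0.006,
        t_opt=18.0,
        t_max=35.0,
    )


def _corn(sowing: int, harvest: int, prdx: float = 1800.0) -> CropParams:
    return CropParams(
        name="corn",
        prdx=prdx,
        sowing_month=sowing,
        harvest_month=harvest,
        root_shoot_ratio=0.35,
        harvest_index=0.48,
        residue_lignin=0.11,
        residue_n=0.007,
        t_opt=30.0,
        t_max=45.0,
    )


def _grass() -> CropParams:
    # native grassland for the spin-up: grows year-round, never harvested;
    # PRDX set for steppe-like NPP of ~2 Mg C/ha/yr (shoot + root)
    return CropParams(
        name="grassland",
        prdx=300.0,
        sowing_month=1,
        harvest_month=12,
        root_shoot_ratio=1.5,
        harvest_index=0.5,  # unused for grassland
        residue_lignin=0.15,
        residue_n=0.010,
        t_opt=25.0,
        t_max=42.0,
    )


def _build_changping() -> Site:
    profile = SiteProfile(
        sand=0.162,
        silt=0.736,  # printed 0.720; closure residual folded in
        clay=0.102,
        ph=8.7,
        bulk_density=1.58,
        depth_cm=20.0,
        field_capacity=0.248,
        parent_material="diluvial alluvium",
    )
    config = SiteConfig(
        name="changping",
        profile=profile,
        wheat=_wheat(10, 6),
        corn=_corn(6, 10),
        grass=_grass(),
        plough_months=(6, 10),
        manure_wheat_month=10,
        manure_corn_month=6,
        manure_split_wheat=1.0,
        straw_months=((10, 1.0),),  # corn straw incorporated after corn harvest
        irrigation_mm=((10, 5.0), (1, 4.0), (3, 5.0), (6, 5.0)),
        npkm_rate=3150.0,
        npks_rate=1000.0,
        manure_lignin=0.08,  # farmyard manure (mixed with soil/residue): lowest lignin
        manure_n=0.022,
        initial_soc_g_kg=7.1,
        dec4_default=0.0023,
    )
    normals = ClimateNormals(
        annual_mean_t=13.1,
        annual_precip=515.0,
        seasonal_amplitude=15.0,
        precip_weights=MONSOON_WEIGHTS.copy(),
    )
    return Site(config, normals)


def _build_yangling() -> Site:
    profile = SiteProfile(
        sand=0.316,
        silt=0.516,
        clay=0.168,
        ph=8.6,
        bulk_density=1.30,
        depth_cm=20.0,
        field_capacity=0.212,
        parent_material="loess",
    )
    config = SiteConfig(
        name="yangling",
        profile=profile,
        wheat=_wheat(10, 6),
        corn=_corn(6, 10),
        grass=_grass(),
        plough_months=(6, 10),
        manure_wheat_month=10,
        manure_corn_month=6,
        manure_split_wheat=1.0,
        straw_months=((10, 1.0),),
        irrigation_mm=((10, 5.0), (1, 4.0), (3, 5.0), (6, 5.0)),
        npkm_rate=3327.0,
        npks_rate=1998.0,
        manure_lignin=0.12,  # cattle manure
        manure_n=0.018,
        initial_soc_g_kg=6.3,
        dec4_default=0.0023,
    )
    normals = ClimateNormals(
        annual_mean_t=14.9,
        annual_precip=525.0,
        seasonal_amplitude=15.0,
        precip_weights=MONSOON_WEIGHTS.copy(),
    )
    return Site(config, normals)


def _build_qiyang() -> Site:
    profile = SiteProfile(
        sand=0.314,
        silt=0.277,
        clay=0.409,
        ph=5.7,
        bulk_density=1.19,
        depth_cm=20.0,
        field_capacity=0.237,
        parent_material="quaternary red clay",
    )
    config = SiteConfig(
        name="qiyang",
        profile=profile,
        # the inter-cropped rotation is serialized: wheat harvested in April,
        # corn sown in May
        wheat=_wheat(11, 4),
        corn=_corn(5, 10),
        grass=_grass(),
        plough_months=(4, 10),
        manure_wheat_month=10,
        manure_corn_month=4,
        manure_split_wheat=0.30,  # 30% pre-wheat, 70% pre-corn
        straw_months=((4, 0.5), (10, 0.5)),  # half wheat straw, half corn straw
        irrigation_mm=(),  # no irrigation: growing-season rainfall suffices
        npkm_rate=5838.0,
        npks_rate=1052.0,
        manure_lignin=0.10,  # pig manure
        manure_n=0.025,
        initial_soc_g_kg=8.6,
        ph_decline_per_year=0.04,
        dec4_default=0.0045,
    )
    normals = ClimateNormals(
        annual_mean_t=18.1,
        annual_precip=1445.0,
        seasonal_amplitude=10.0,
        precip_weights=SUBTROPICAL_WEIGHTS.copy(),
    )
    return Site(config, normals)


_BUILDERS = {
    "changping": _build_changping,
    "yangling": _build_yangling,
    "qiyang": _build_qiyang,
}


def get_site(name: str) -> Site:
    """Return the bundled configuration for one of the three trial sites."""
    key = name.lower()
    if key not in _BUILDERS:
        raise ValueError(f"unknown site {name!r}; expected one of {SITE_NAMES}")
    return _BUILDERS[key]()
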
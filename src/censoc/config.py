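"""Run configuration: a YAML overlay on the bundled site fixtures.

A config file names one of the bundled sites and may override any scalar
of the decomposition parameters, the site's climate normals, or the crop
and treatment settings.  Unknown keys are rejected with the offending path
so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .management import NUTRIENT_SCALARS, TREATMENTS
from .pools import DecompParams
from .sites import SITE_NAMES, Site, get_site

__all__ = ["RunConfig", "load_config"]

_TOP_KEYS = {"site", "treatment", "seed", "end_year", "spinup_years", "decomposition",
             "normals", "profile", "crops", "nutrient_scalars", "out_dir"}


@dataclass
class RunConfig:
    """Validated, fully resolved configuration for one scenario run."""

    site: Site
    treatment: str = "control"
    seed: int = 0
    end_year: int = 2050
    spinup_years: int = 4000
    params: DecompParams = dataclasses.field(default_factory=DecompParams)
    out_dir: Path = Path(".")

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}; valid: {TREATMENTS}")
        if not 1901 <= self.end_year <= 2050:
            raise ValueError("end_year must lie in [1901, 2050]")


def _apply_overrides(obj, overrides: dict, path: str):
    """Replace dataclass fields from a dict, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(obj)}
    unknown = set(overrides) - names
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} under {path!r}; "
                         f"valid keys: {sorted(names)}")
    return dataclasses.replace(obj, **overrides)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown top-level key(s) {sorted(unknown)}; "
                         f"valid keys: {sorted(_TOP_KEYS)}")
    site_name = raw.get("site", "changping")
    if site_name not in SITE_NAMES:
        raise ValueError(f"{path}: unknown site {site_name!r}; valid: {SITE_NAMES}")
    site = get_site(site_name)
    if "profile" in raw:
        site.config.profile = _apply_overrides(site.config.profile, raw["profile"], "profile")
    if "normals" in raw:
        site.normals = _apply_overrides(site.normals, raw["normals"], "normals")
    if "crops" in raw:
        for crop_name, overrides in raw["crops"].items():
            if crop_name not in ("wheat", "corn", "grass"):
                raise ValueError(f"{path}: unknown crop {crop_name!r} under 'crops'")
            setattr(site.config, crop_name,
                    _apply_overrides(getattr(site.config, crop_name), overrides,
                                     f"crops.{crop_name}"))
    if "nutrient_scalars" in raw:
        for code, value in raw["nutrient_scalars"].items():
            if code not in TREATMENTS:
                raise ValueError(f"{path}: unknown treatment {code!r} under 'nutrient_scalars'")
            NUTRIENT_SCALARS[code] = float(value)
    params = DecompParams(dec4=site.config.dec4_default)
    if "decomposition" in raw:
        params = _apply_overrides(params, raw["decomposition"], "decomposition")
    return RunConfig(
        site=site,
        treatment=raw.get("treatment", "control"),
        seed=int(raw.get("seed", 0)),
        end_year=int(raw.get("end_year", 2050)),
        spinup_years=int(raw.get("spinup_years", 4000)),
        params=params,
        out_dir=Path(raw.get("out_dir", ".")),
    )
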
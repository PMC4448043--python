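"""Run configuration: structured YAML in, validated model out.

Every physical constant that is not a law of nature lives in a config file
(the shipped defaults are in ``optomc/data/``): media optical properties,
layer thicknesses, source dimensions, photon count, seed, termination
policy, grid binning and analysis thresholds.  Validation is collected —
a malformed file reports *all* offending fields at once, with their paths.
"""

from __future__ import annotations

import hashlib
import json
import math
from importlib import resources
from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

from .geometry import LayeredGeometry, Region
from .optics import OpticalMedium
from .scoring import FluenceGrid
from .sources import FiberSource, LambertianDiscSource
from .transport import TransportParams


class ConfigError(ValueError):
    """Raised when a config file fails validation; message lists every fault."""


class MediumSpec(BaseModel, extra="forbid"):
    refractive_index: float = Field(ge=1.0)
    mu_a: float = Field(default=0.0, ge=0.0)
    mu_s: float = Field(default=0.0, ge=0.0)
    g: float = Field(default=0.0, gt=-1.0, lt=1.0)


class RegionSpec(BaseModel, extra="forbid"):
    medium: str
    z_lo: float
    z_hi: float
    r_lo: float = Field(default=0.0, ge=0.0)
    r_hi: float = Field(default=math.inf, gt=0.0)

    @model_validator(mode="after")
    def _ordered(self):
        if not self.z_lo < self.z_hi:
            raise ValueError("region needs z_lo < z_hi")
        if not self.r_lo < self.r_hi:
            raise ValueError("region needs r_lo < r_hi")
        return self


class GeometrySpec(BaseModel, extra="forbid"):
    regions: list[RegionSpec] = Field(min_length=1)
    domain_radius: float = Field(default=5.0, gt=0.0)
    z_min: float = -0.1
    z_max: float = 5.0
    back_plane_radius: float = Field(default=0.075, ge=0.0)
    back_plane_policy: Literal["absorb", "mirror"] = "absorb"
    back_plane_reflectivity: float = Field(default=1.0, ge=0.0, le=1.0)


class DiscSourceSpec(BaseModel, extra="forbid"):
    type: Literal["uled_disc"] = "uled_disc"
    diameter: float = Field(default=0.030, gt=0.0)
    center: tuple[float, float, float] = (0.0, 0.0, -0.1)
    medium: str = "sapphire"
    collimated: bool = False
    power: float = Field(default=1.0, gt=0.0)  # mW; rescalable post hoc


class FiberSourceSpec(BaseModel, extra="forbid"):
    type: Literal["fiber"] = "fiber"
    core_diameter: float = Field(default=0.105, gt=0.0)
    numerical_aperture: float = Field(default=0.22, gt=0.0, lt=1.0)
    gaussian_sigma: Optional[float] = Field(default=None, gt=0.0)
    tip: tuple[float, float, float] = (0.0, 0.0, -0.3)
    medium: str = "saline"
    na_reference: Literal["medium", "air"] = "medium"
    power: float = Field(default=1.1, gt=0.0)  # mW at the tip


class GridSpec(BaseModel, extra="forbid"):
    dr: float = Field(default=0.01, gt=0.0)
    dz: float = Field(default=0.01, gt=0.0)
    r_max: float = Field(default=1.5, gt=0.0)
    z_lo: float = -0.4
    z_hi: float = 2.0

    @model_validator(mode="after")
    def _ordered(self):
        if not self.z_lo < self.z_hi:
            raise ValueError("grid needs z_lo < z_hi")
        return self


class TransportSpec(BaseModel, extra="forbid"):
    roulette_threshold: float = Field(default=1.0e-4, gt=0.0)
    roulette_survival: float = Field(default=0.1, gt=0.0, lt=1.0)
    step_cap: int = Field(default=100_000, ge=1)
    termination: Literal["roulette", "threshold"] = "roulette"


class RunConfig(BaseModel, extra="forbid"):
    """Complete, validated description of one simulation run."""

    media: dict[str, MediumSpec]
    geometry: GeometrySpec
    source: Union[DiscSourceSpec, FiberSourceSpec] = Field(discriminator="type")
    n_photons: int = Field(ge=0)
    seed: int = Field(ge=0)
    transport: TransportSpec = TransportSpec()
    grid: GridSpec = GridSpec()
    analysis_thresholds: list[float] = Field(default_factory=lambda: [1.0])

    @field_validator("analysis_thresholds")
    @classmethod
    def _positive_thresholds(cls, v):
        if any(t <= 0.0 for t in v):
            raise ValueError("analysis thresholds must be > 0 mW/mm^2")
        return v

    @model_validator(mode="after")
    def _referenced_media_exist(self):
        missing = {r.medium for r in self.geometry.regions if r.medium not in self.media}
        if self.source.medium not in self.media:
            missing.add(self.source.medium)
        if missing:
            raise ValueError(f"regions/source reference unknown media: {sorted(missing)}")
        return self

    # -- builders --------------------------------------------------------

    def build_geometry(self) -> LayeredGeometry:
        media = {
            name: OpticalMedium(name, m.refractive_index, m.mu_a, m.mu_s, m.g)
            for name, m in self.media.items()
        }
        regions = [
            Region(r.medium, r.z_lo, r.z_hi, r.r_lo, r.r_hi) for r in self.geometry.regions
        ]
        return LayeredGeometry(
            media=media,
            regions=regions,
            domain_radius=self.geometry.domain_radius,
            z_min=self.geometry.z_min,
            z_max=self.geometry.z_max,
            back_plane_radius=self.geometry.back_plane_radius,
            back_plane_policy=self.geometry.back_plane_policy,
            back_plane_reflectivity=self.geometry.back_plane_reflectivity,
        )

    def build_source(self):
        s = self.source
        if isinstance(s, DiscSourceSpec):
            return LambertianDiscSource(
                diameter=s.diameter,
                center=tuple(s.center),
                launch_medium_id=s.medium,
                collimated=s.collimated,
            )
        return FiberSource(
            core_diameter=s.core_diameter,
            numerical_aperture=s.numerical_aperture,
            gaussian_sigma=s.gaussian_sigma,
            tip_position=tuple(s.tip),
            output_power=s.power,
            launch_medium_id=s.medium,
            na_reference=s.na_reference,
        )

    def build_grid(self) -> FluenceGrid:
        g = self.grid
        return FluenceGrid.uniform(
            dr=g.dr, dz=g.dz, r_max=g.r_max, z_lo=g.z_lo, z_hi=g.z_hi,
            source_power=self.source.power,
        )

    def transport_params(self) -> TransportParams:
        t = self.transport
        return TransportParams(
            roulette_threshold=t.roulette_threshold,
            roulette_survival=t.roulette_survival,
            step_cap=t.step_cap,
            strict_terminate=(t.termination == "threshold"),
        )

    # -- identity --------------------------------------------------------

    def canonical_json(self) -> str:
        """Whitespace-insensitive canonical serialisation of the semantics."""
        return json.dumps(self.model_dump(mode="json"), sort_keys=True, separators=(",", ":"))

    def config_hash(self) -> str:
        """sha256 of the canonical form; changes iff a semantic field changes."""
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


def _format_validation_error(err: ValidationError) -> str:
    lines = [f"invalid run config ({err.error_count()} problem(s)):"]
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"]) or "<root>"
        lines.append(f"  - {loc}: {e['msg']}")
    return "\n".join(lines)


def config_from_dict(data: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(data)
    except ValidationError as err:
        raise ConfigError(_format_validation_error(err)) from err


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run config; reports all violations at once."""
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as err:
            raise ConfigError(f"malformed YAML in {path}: {err}") from err
    if not isinstance(data, dict):
        raise ConfigError(f"config root in {path} must be a mapping")
    return config_from_dict(data)


def load_defaults() -> dict:
    """The shipped defaults table (media constants, probe/fiber dimensions...)."""
    text = resources.files("optomc.data").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)
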
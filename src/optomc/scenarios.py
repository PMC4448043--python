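"""Builders for the study scenarios, parameterised from the shipped defaults.

Coordinates: z along the emission axis, z = 0 at the probe/tissue (or
saline/tissue) interface, tissue at z > 0, all lengths mm.

* ``uled_config`` — the 30 um Lambertian uLED pixel emitting through a
  100 um sapphire substrate (laterally bounded at the 150 um probe width,
  embedded in tissue) into semi-infinite cortex.  With ``insertion_depth``
  set, tissue also extends above the pixel plane and the shank above the
  pixel is modelled as an opaque probe body, so depth-selectivity of the
  illumination can be assessed.
* ``fiber_config`` — the 105 um, NA 0.22 optical fiber standing 300 um
  above the cortical surface in saline.
* ``surface_disc_config`` — control: the bare disc emitting directly in
  tissue with no substrate (the no-spread limit of the interface profile).
* ``homogeneous_config`` — a single-medium block for the analytic oracles.
"""

from __future__ import annotations

import math

from .config import RunConfig, config_from_dict, load_defaults


def _base(defaults: dict | None) -> dict:
    return load_defaults() if defaults is None else defaults


def uled_config(
    n_photons: int,
    seed: int,
    insertion_depth: float = 0.0,
    grid: dict | None = None,
    defaults: dict | None = None,
) -> RunConfig:
    """uLED probe scenario.

    ``insertion_depth`` > 0 places the pixel that far below the cortical
    surface: tissue then fills the volume above the probe tip and the shank
    is an absorbing probe-body region, so light reaching shallow cortex must
    scatter through tissue.
    """
    d = _base(defaults)
    half_w = d["probe"]["half_width"]
    thick = d["probe"]["sapphire_thickness"]
    dom = d["domain"]
    z_back = -thick
    regions = [
        dict(medium="sapphire", z_lo=z_back, z_hi=0.0, r_lo=0.0, r_hi=half_w),
        dict(medium="tissue", z_lo=z_back, z_hi=0.0, r_lo=half_w, r_hi=math.inf),
        dict(medium="tissue", z_lo=0.0, z_hi=dom["z_max"], r_lo=0.0, r_hi=math.inf),
    ]
    z_min = z_back
    if insertion_depth > 0.0:
        if insertion_depth <= thick:
            raise ValueError("insertion_depth must exceed the sapphire thickness")
        z_min = -insertion_depth
        regions += [
            dict(medium="probe", z_lo=z_min, z_hi=z_back, r_lo=0.0, r_hi=half_w),
            dict(medium="tissue", z_lo=z_min, z_hi=z_back, r_lo=half_w, r_hi=math.inf),
        ]
    cfg = dict(
        media=d["media"],
        geometry=dict(
            regions=regions,
            domain_radius=dom["radius"],
            z_min=z_min,
            z_max=dom["z_max"],
            back_plane_radius=half_w,
        ),
        source=dict(
            type="uled_disc",
            diameter=d["probe"]["uled_diameter"],
            center=(0.0, 0.0, z_back),
            medium="sapphire",
        ),
        n_photons=n_photons,
        seed=seed,
        transport=d["transport"],
        grid=grid if grid is not None else d["grid"],
    )
    return config_from_dict(cfg)


def fiber_config(
    n_photons: int,
    seed: int,
    grid: dict | None = None,
    defaults: dict | None = None,
) -> RunConfig:
    """Optical-fiber scenario: tip in saline, 300 um above the tissue."""
    d = _base(defaults)
    f = d["fiber"]
    dom = d["domain"]
    standoff = f["saline_standoff"]
    cfg = dict(
        media={k: v for k, v in d["media"].items() if k in ("saline", "tissue")},
        geometry=dict(
            regions=[
                dict(medium="saline", z_lo=-standoff, z_hi=0.0),
                dict(medium="tissue", z_lo=0.0, z_hi=dom["z_max"]),
            ],
            domain_radius=dom["radius"],
            z_min=-standoff,
            z_max=dom["z_max"],
            back_plane_radius=0.5 * f["core_diameter"],
        ),
        source=dict(
            type="fiber",
            core_diameter=f["core_diameter"],
            numerical_aperture=f["numerical_aperture"],
            tip=(0.0, 0.0, -standoff),
            medium="saline",
            na_reference=f["na_reference"],
            power=f["output_power"],
        ),
        n_photons=n_photons,
        seed=seed,
        transport=d["transport"],
        grid=grid if grid is not None else d["grid"],
    )
    return config_from_dict(cfg)


def surface_disc_config(
    n_photons: int,
    seed: int,
    grid: dict | None = None,
    defaults: dict | None = None,
) -> RunConfig:
    """Control: the uLED disc emitting directly into tissue (no substrate)."""
    d = _base(defaults)
    dom = d["domain"]
    cfg = dict(
        media={"tissue": d["media"]["tissue"]},
        geometry=dict(
            regions=[dict(medium="tissue", z_lo=0.0, z_hi=dom["z_max"])],
            domain_radius=dom["radius"],
            z_min=0.0,
            z_max=dom["z_max"],
            back_plane_radius=d["probe"]["half_width"],
        ),
        source=dict(
            type="uled_disc",
            diameter=d["probe"]["uled_diameter"],
            center=(0.0, 0.0, 0.0),
            medium="tissue",
        ),
        n_photons=n_photons,
        seed=seed,
        transport=d["transport"],
        grid=grid if grid is not None else d["grid"],
    )
    return config_from_dict(cfg)


def homogeneous_config(
    n_photons: int,
    seed: int,
    medium: dict,
    z_max: float = 5.0,
    domain_radius: float = 5.0,
    collimated: bool = False,
    diameter: float = 0.005,
    grid: dict | None = None,
) -> RunConfig:
    """Single-medium block with the disc source at z = 0 (oracle scenarios)."""
    cfg = dict(
        media={"medium": medium},
        geometry=dict(
            regions=[dict(medium="medium", z_lo=0.0, z_hi=z_max)],
            domain_radius=domain_radius,
            z_min=0.0,
            z_max=z_max,
            back_plane_radius=0.0,
        ),
        source=dict(
            type="uled_disc",
            diameter=diameter,
            center=(0.0, 0.0, 0.0),
            medium="medium",
            collimated=collimated,
        ),
        n_photons=n_photons,
        seed=seed,
        grid=grid if grid is not None else dict(dr=0.01, dz=0.01, r_max=0.1, z_lo=0.0, z_hi=z_max),
    )
    return config_from_dict(cfg)
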
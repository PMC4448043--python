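"""Photon launch distributions for the two simulated light sources.

* a micro-LED modelled as a uniformly emitting disc (default 30 um diameter)
  whose radiance follows Lambert's cosine law, launching into the sapphire
  substrate it is grown on;
* a multimode optical fiber tip (default 105 um core, NA 0.22) whose
  near-field is approximated by a centred 2-D Gaussian truncated at the core
  rim, and whose far-field is uniform in solid angle inside the acceptance
  cone ``theta_max = arcsin(NA / n_launch)`` evaluated in the launch medium
  (saline by default; configurable to the in-air convention).

Every photon starts with statistical weight 1; total launched weight equals
the photon count exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .optics import cos_sin_azimuth, rotate_direction
from .rng import PhotonRNG

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class LambertianDiscSource:
    """Disc emitter with cosine-weighted (Lambertian) directions.

    ``center`` is the disc centre in mm; ``emission_axis`` points into the
    medium the light enters (the sapphire substrate for the uLED probe).
    """

    diameter: float = 0.030
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    emission_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    launch_medium_id: str = "sapphire"
    collimated: bool = False  # pencil-beam variant used by the analytic oracles

    def __post_init__(self):
        if self.diameter <= 0.0:
            raise ValueError("disc diameter must be > 0")
        ax = self.emission_axis
        if abs(ax[0] ** 2 + ax[1] ** 2 + ax[2] ** 2 - 1.0) > 1.0e-9:
            raise ValueError("emission_axis must be a unit vector")

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter


@dataclass(frozen=True)
class FiberSource:
    """Optical-fiber tip: truncated-Gaussian near field, NA-bounded far field.

    ``gaussian_sigma`` is the radial standard deviation of the launch-position
    weighting; ``None`` selects the default of half the core radius (which
    puts ~86% of the untruncated mass inside the core, a typical multimode
    near-field).  ``na_reference`` selects whether the cone half-angle is
    ``arcsin(NA / n_launch)`` ("medium", physical divergence in saline) or
    ``arcsin(NA)`` ("air").
    """

    core_diameter: float = 0.105
    numerical_aperture: float = 0.22
    gaussian_sigma: float | None = None
    tip_position: tuple[float, float, float] = (0.0, 0.0, -0.3)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    output_power: float = 1.1
    launch_medium_id: str = "saline"
    na_reference: str = "medium"

    def __post_init__(self):
        if self.core_diameter <= 0.0:
            raise ValueError("core_diameter must be > 0")
        if not (0.0 < self.numerical_aperture < 1.0):
            raise ValueError("numerical_aperture must lie in (0, 1)")
        if self.gaussian_sigma is not None and self.gaussian_sigma <= 0.0:
            raise ValueError("gaussian_sigma must be > 0")
        if self.na_reference not in ("medium", "air"):
            raise ValueError("na_reference must be 'medium' or 'air'")

    @property
    def core_radius(self) -> float:
        return 0.5 * self.core_diameter

    @property
    def sigma(self) -> float:
        return self.gaussian_sigma if self.gaussian_sigma is not None else 0.5 * self.core_radius

    def cone_cos_max(self, n_launch: float) -> float:
        """cos(theta_max) of the emission cone for launch-medium index ``n_launch``."""
        na = self.numerical_aperture
        s = na if self.na_reference == "air" else na / n_launch
        if s >= 1.0:
            raise ValueError("numerical aperture exceeds the launch-medium index")
        return math.sqrt(1.0 - s * s)


def sample_disc_position(diameter: float, u1: float, u2: float) -> tuple[float, float]:
    """Uniform areal sample on a disc: r = R*sqrt(u1), azimuth 2*pi*u2."""
    if diameter <= 0.0:
        raise ValueError("diameter must be > 0")
    r = 0.5 * diameter * math.sqrt(u1)
    phi = TWO_PI * u2
    c, s = cos_sin_azimuth(phi)
    return (r * c, r * s)


def sample_lambertian_direction(
    axis: tuple[float, float, float], u1: float, u2: float
) -> tuple[float, float, float]:
    """Cosine-weighted hemisphere direction about ``axis``.

    cos(theta) = sqrt(1 - u1) makes the density proportional to cos(theta);
    the first moment of cos(theta) is 2/3.
    """
    cos_t = math.sqrt(1.0 - u1)
    phi = TWO_PI * u2
    return rotate_direction(axis, cos_t, phi)


def sample_cone_direction(
    axis: tuple[float, float, float], cos_max: float, u1: float, u2: float
) -> tuple[float, float, float]:
    """Direction uniform in solid angle within a cone of cos half-angle ``cos_max``."""
    cos_t = 1.0 - u1 * (1.0 - cos_max)
    phi = TWO_PI * u2
    return rotate_direction(axis, cos_t, phi)


def sample_disc_launch(
    spec: LambertianDiscSource, rng: PhotonRNG
) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Draw one (position, direction) pair for the uLED disc source.

    Consumes exactly four deviates, in the order position(2), direction(2);
    the compiled kernel reproduces the same order.
    """
    u1 = rng.next_float()
    u2 = rng.next_float()
    px, py = sample_disc_position(spec.diameter, u1, u2)
    cx, cy, cz = spec.center
    if spec.collimated:
        d = spec.emission_axis
    else:
        d = sample_lambertian_direction(spec.emission_axis, rng.next_float(), rng.next_float())
    return ((cx + px, cy + py, cz), d)


def sample_fiber_launch(
    spec: FiberSource, rng: PhotonRNG, n_launch: float = 1.34
) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Draw one (position, direction) pair for the fiber source.

    Launch position: centred 2-D Gaussian of std ``spec.sigma`` sampled by
    Box-Muller, rejection-truncated at the core radius.  Direction: uniform
    in solid angle within the NA cone for launch-medium index ``n_launch``.
    """
    sigma = spec.sigma
    rcore = spec.core_radius
    while True:
        u1 = rng.next_open01()
        u2 = rng.next_float()
        amp = sigma * math.sqrt(-2.0 * math.log(u1))
        c, s = cos_sin_azimuth(TWO_PI * u2)
        gx = amp * c
        gy = amp * s
        if gx * gx + gy * gy <= rcore * rcore:
            break
    tx, ty, tz = spec.tip_position
    cos_max = spec.cone_cos_max(n_launch)
    d = sample_cone_direction(spec.axis, cos_max, rng.next_float(), rng.next_float())
    return ((tx + gx, ty + gy, tz), d)
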
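"""Stateless optical primitives for photon transport in turbid media.

All lengths are millimetres; interaction coefficients are mm^-1.  These are
the textbook building blocks of weighted Monte-Carlo transport: exponential
free-path sampling via the Beer-Lambert law, fractional weight absorption at
collision sites, Henyey-Greenstein phase-function sampling, rotation of the
propagation direction by a sampled deflection, and unpolarized Fresnel /
Snell boundary optics.

The compiled transport kernel re-implements the same arithmetic inline (see
``optomc._kernel``); the functions here are the validated public surface and
the ones the pure-Python reference engine calls.  Keeping the floating-point
expressions textually identical in both places is what makes the
kernel-vs-reference equivalence test exact rather than approximate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


def cos_sin_azimuth(phi: float) -> tuple[float, float]:
    """(cos, sin) of an azimuth in [0, 2*pi), with sin derived from cos.

    Deriving sin as ``+/-sqrt(1 - cos^2)`` keeps the compiled kernel and the
    pure-Python engines bit-identical: computing ``cos(phi)`` and
    ``sin(phi)`` side by side lets the compiler fuse them into a ``sincos``
    call whose sin can differ from libm's by 1 ulp.  For a uniform azimuth
    the substitution is statistically exact.
    """
    c = math.cos(phi)
    s = math.sqrt(max(0.0, 1.0 - c * c))
    if phi > math.pi:
        s = -s
    return c, s


@dataclass(frozen=True)
class OpticalMedium:
    """A homogeneous optical medium.

    Parameters
    ----------
    name : str
        Label used in configs and tallies (e.g. ``"tissue"``).
    refractive_index : float
        Real refractive index, >= 1.
    mu_a : float
        Absorption coefficient, mm^-1, >= 0.
    mu_s : float
        Scattering coefficient, mm^-1, >= 0.
    g : float
        Scattering anisotropy (mean cosine of the single-scattering
        deflection), in (-1, 1).  Ignored when ``mu_s == 0``.
    """

    name: str
    refractive_index: float
    mu_a: float = 0.0
    mu_s: float = 0.0
    g: float = 0.0

    def __post_init__(self):
        if self.refractive_index < 1.0:
            raise ValueError(f"refractive_index must be >= 1, got {self.refractive_index}")
        if self.mu_a < 0.0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s < 0.0:
            raise ValueError(f"mu_s must be >= 0, got {self.mu_s}")
        if not (-1.0 < self.g < 1.0):
            raise ValueError(f"anisotropy g must lie in (-1, 1), got {self.g}")

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s, mm^-1."""
        return self.mu_a + self.mu_s

    @property
    def albedo(self) -> float:
        """Single-scattering albedo mu_s / mu_t; NaN for a transparent medium."""
        mu_t = self.mu_t
        return self.mu_s / mu_t if mu_t > 0.0 else math.nan

    @property
    def transparent(self) -> bool:
        return self.mu_t == 0.0


@dataclass
class PhotonState:
    """Position (mm), unit direction, statistical weight and bookkeeping tags."""

    position: tuple[float, float, float]
    direction: tuple[float, float, float]
    weight: float = 1.0
    medium_id: str = ""
    alive: bool = True
    region: int = -1
    steps: int = field(default=0, compare=False)


def sample_free_path(mu_t: float, u: float) -> float:
    """Sample a free path length (mm) between interaction sites.

    Inverse-CDF sampling of the Beer-Lambert exponential:
    ``s = -ln(u) / mu_t`` for ``u`` uniform in (0, 1].  A transparent medium
    (``mu_t == 0``) returns ``inf``: the photon reaches the next boundary
    without interacting.
    """
    if not (0.0 < u <= 1.0):
        raise ValueError(f"deviate u must lie in (0, 1], got {u}")
    if mu_t < 0.0:
        raise ValueError(f"mu_t must be >= 0, got {mu_t}")
    if mu_t == 0.0:
        return math.inf
    return -math.log(u) / mu_t


def attenuate(weight: float, medium: OpticalMedium) -> tuple[float, float]:
    """Split a photon weight at a collision into (surviving, absorbed).

    The absorbed fraction is ``mu_a / mu_t``; the remainder continues and is
    scattered.  Conservation is exact: ``surviving + absorbed == weight``.
    """
    mu_t = medium.mu_t
    if mu_t <= 0.0:
        raise ValueError("attenuate called in a transparent medium (mu_t == 0)")
    absorbed = weight * (medium.mu_a / mu_t)
    return weight - absorbed, absorbed


def sample_hg_cos(g: float, u: float) -> float:
    """Sample cos(theta) of a Henyey-Greenstein deflection.

    Standard inverse-CDF form; ``g == 0`` reduces to an isotropic
    ``2u - 1``.  The first moment of the distribution equals ``g``.
    """
    if not (-1.0 < g < 1.0):
        raise ValueError(f"anisotropy g must lie in (-1, 1), got {g}")
    if not (0.0 <= u <= 1.0):
        raise ValueError(f"deviate u must lie in [0, 1], got {u}")
    if g == 0.0:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    cos_t = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    # clamp roundoff at the CDF endpoints
    if cos_t > 1.0:
        cos_t = 1.0
    elif cos_t < -1.0:
        cos_t = -1.0
    return cos_t


def rotate_direction(
    direction: tuple[float, float, float], cos_theta: float, phi: float
) -> tuple[float, float, float]:
    """Rotate a unit vector by polar angle ``acos(cos_theta)`` and azimuth ``phi``.

    The local frame convention is the usual one from layered-media Monte
    Carlo codes: for a direction along +z and ``phi = 0`` the deflection tips
    the vector toward +x.  The generic local frame is evaluated without
    cancellation, so it stays accurate arbitrarily close to the poles; a
    dedicated branch handles the exactly-polar case.
    """
    ux, uy, uz = direction
    if abs(cos_theta) > 1.0:
        raise ValueError(f"cos_theta must lie in [-1, 1], got {cos_theta}")
    sin_theta = math.sqrt(max(0.0, 1.0 - cos_theta * cos_theta))
    cos_phi, sin_phi = cos_sin_azimuth(phi)
    # (1-uz)(1+uz) avoids the cancellation in 1-uz^2, so the generic frame
    # stays accurate arbitrarily close to the poles; the special branch is
    # needed only when the transverse component underflows entirely.
    tmp = (1.0 - uz) * (1.0 + uz)
    if tmp <= 0.0:
        sign = 1.0 if uz >= 0.0 else -1.0
        nx = sin_theta * cos_phi
        ny = sign * sin_theta * sin_phi
        nz = sign * cos_theta
    else:
        denom = math.sqrt(tmp)
        nx = sin_theta * (ux * uz * cos_phi - uy * sin_phi) / denom + ux * cos_theta
        ny = sin_theta * (uy * uz * cos_phi + ux * sin_phi) / denom + uy * cos_theta
        nz = -sin_theta * cos_phi * denom + uz * cos_theta
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return (nx / norm, ny / norm, nz / norm)


def fresnel_unpolarized(n1: float, n2: float, cos_incident: float) -> float:
    """Unpolarized Fresnel reflectance at a planar interface.

    Average of the s- and p-polarized power reflectances; returns exactly 1
    beyond the critical angle (total internal reflection when going from the
    denser into the rarer medium).
    """
    if cos_incident <= 0.0 or cos_incident > 1.0:
        raise ValueError(f"cos_incident must lie in (0, 1], got {cos_incident}")
    if n1 < 1.0 or n2 < 1.0:
        raise ValueError("refractive indices must be >= 1")
    if n1 == n2:
        return 0.0
    sin_i = math.sqrt(max(0.0, 1.0 - cos_incident * cos_incident))
    sin_t = n1 * sin_i / n2
    if sin_t >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    rs = (n1 * cos_incident - n2 * cos_t) / (n1 * cos_incident + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_incident) / (n1 * cos_t + n2 * cos_incident)
    return 0.5 * (rs * rs + rp * rp)


def refract(
    direction: tuple[float, float, float],
    normal: tuple[float, float, float],
    n1: float,
    n2: float,
) -> tuple[float, float, float] | None:
    """Bend a ray across an interface by Snell's law.

    ``normal`` is the outward unit normal of the surface being crossed
    (``dot(direction, normal) < 0``).  Returns the transmitted unit vector,
    or ``None`` when the incidence angle exceeds the critical angle (total
    internal reflection).
    """
    dx, dy, dz = direction
    nx, ny, nz = normal
    for v, label in ((direction, "direction"), (normal, "normal")):
        if abs(v[0] * v[0] + v[1] * v[1] + v[2] * v[2] - 1.0) > 1.0e-9:
            raise ValueError(f"{label} must be a unit vector")
    cos_i = -(dx * nx + dy * ny + dz * nz)
    if cos_i <= 0.0:
        raise ValueError("direction must point into the surface (dot(d, n) < 0)")
    eta = n1 / n2
    sin2_t = eta * eta * (1.0 - cos_i * cos_i)
    if sin2_t > 1.0:
        return None
    cos_t = math.sqrt(1.0 - sin2_t)
    tx = eta * dx + (eta * cos_i - cos_t) * nx
    ty = eta * dy + (eta * cos_i - cos_t) * ny
    tz = eta * dz + (eta * cos_i - cos_t) * nz
    norm = math.sqrt(tx * tx + ty * ty + tz * tz)
    return (tx / norm, ty / norm, tz / norm)


def critical_angle(n1: float, n2: float) -> float:
    """Critical angle (radians) for total internal reflection, n1 -> n2."""
    if n2 >= n1:
        return math.pi / 2.0
    return math.asin(n2 / n1)
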
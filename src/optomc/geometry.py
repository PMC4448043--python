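"""Axisymmetric layered geometry for the probe-in-tissue scenarios.

The simulated volume is a cylinder of radius ``domain_radius`` spanning
``z_min <= z <= z_max`` (z along the emission axis, z = 0 at the
probe/tissue or saline/tissue interface, tissue at z > 0; all lengths mm).
It is tiled without gaps or overlap by axisymmetric *regions*, each an
annular slab ``[z_lo, z_hi) x [r_lo, r_hi)`` filled with one medium.  This
is enough to express every scenario simulated here: a laterally bounded
sapphire slab embedded in tissue, a saline standoff layer, or homogeneous
tissue for the analytic oracles.

Interfaces between regions of different refractive index are resolved with
unpolarized Fresnel optics (probabilistically: one deviate against the
reflectance); index-matched interfaces are transparent.  Photons leaving the
domain are tallied by face:

* outer radius or deep face (``z_max``)  -> escaped;
* back face (``z_min``) within ``back_plane_radius`` -> back-plane loss
  (the reflecting p-contact behind the uLED is modelled as an absorber by
  default, optionally as a specular mirror with given reflectivity);
* back face outside ``back_plane_radius`` -> edge loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .optics import OpticalMedium

#: surface codes returned by distance_to_boundary
SURF_Z_HI = 0
SURF_Z_LO = 1
SURF_R_HI = 2
SURF_R_LO = 3

BACK_ABSORB = 0
BACK_MIRROR = 1


@dataclass(frozen=True)
class Region:
    """Annular slab ``[z_lo, z_hi) x [r_lo, r_hi)`` of one medium."""

    medium_id: str
    z_lo: float
    z_hi: float
    r_lo: float = 0.0
    r_hi: float = math.inf

    def __post_init__(self):
        if not self.z_lo < self.z_hi:
            raise ValueError(f"region needs z_lo < z_hi, got [{self.z_lo}, {self.z_hi}]")
        if not 0.0 <= self.r_lo < self.r_hi:
            raise ValueError(f"region needs 0 <= r_lo < r_hi, got [{self.r_lo}, {self.r_hi}]")

    def contains(self, x: float, y: float, z: float) -> bool:
        if not (self.z_lo <= z < self.z_hi):
            return False
        r2 = x * x + y * y
        return self.r_lo * self.r_lo <= r2 < self.r_hi * self.r_hi


@dataclass
class LayeredGeometry:
    """Tiled axisymmetric geometry plus domain bounds and back-plane policy."""

    media: dict[str, OpticalMedium]
    regions: list[Region]
    domain_radius: float = 5.0
    z_min: float = -0.1
    z_max: float = 5.0
    back_plane_radius: float = 0.075
    back_plane_policy: str = "absorb"  # or "mirror"
    back_plane_reflectivity: float = 1.0
    _medium_order: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self):
        if self.domain_radius <= 0.0:
            raise ValueError("domain_radius must be > 0")
        if not self.z_min < self.z_max:
            raise ValueError("need z_min < z_max")
        if self.back_plane_policy not in ("absorb", "mirror"):
            raise ValueError("back_plane_policy must be 'absorb' or 'mirror'")
        for reg in self.regions:
            if reg.medium_id not in self.media:
                raise ValueError(f"region references unknown medium '{reg.medium_id}'")
        self._medium_order = sorted(self.media)
        self._check_tiling()

    # -- queries ---------------------------------------------------------

    def medium_index(self, medium_id: str) -> int:
        return self._medium_order.index(medium_id)

    @property
    def medium_ids(self) -> list[str]:
        return list(self._medium_order)

    def locate(self, x: float, y: float, z: float) -> int:
        """Index of the region containing the point, or -1 if outside.

        Points beyond the domain cylinder (outer radius, z_min, z_max) are
        outside by definition even where a semi-infinite region would
        formally contain them.
        """
        if (
            x * x + y * y >= self.domain_radius * self.domain_radius
            or z < self.z_min
            or z >= self.z_max
        ):
            return -1
        for k, reg in enumerate(self.regions):
            if reg.contains(x, y, z):
                return k
        return -1

    def medium_at(self, x: float, y: float, z: float) -> OpticalMedium | None:
        k = self.locate(x, y, z)
        return None if k < 0 else self.media[self.regions[k].medium_id]

    def _check_tiling(self, n_probe: int = 64) -> None:
        """Probe a deterministic lattice of interior points for gaps/overlaps."""
        zs = np.linspace(self.z_min, self.z_max, n_probe, endpoint=False) + (
            (self.z_max - self.z_min) / (2.0 * n_probe)
        )
        rs = np.linspace(0.0, self.domain_radius, n_probe, endpoint=False) + (
            self.domain_radius / (2.0 * n_probe)
        )
        for z in zs:
            for r in rs:
                hits = sum(reg.contains(r, 0.0, z) for reg in self.regions)
                if hits == 0:
                    raise ValueError(f"geometry gap at r={r:.4f}, z={z:.4f} mm")
                if hits > 1:
                    raise ValueError(f"overlapping regions at r={r:.4f}, z={z:.4f} mm")

    # -- ray tracing -----------------------------------------------------

    def distance_to_boundary(
        self,
        position: tuple[float, float, float],
        direction: tuple[float, float, float],
        region_index: int | None = None,
    ) -> tuple[float, int]:
        """Smallest positive ray parameter to a bounding surface of the region.

        Returns ``(distance_mm, surface_code)`` with codes ``SURF_Z_HI``,
        ``SURF_Z_LO``, ``SURF_R_HI``, ``SURF_R_LO``.  Planes are exact; the
        cylindrical faces are solved from the ray/cylinder quadratic.
        """
        x, y, z = position
        dx, dy, dz = direction
        if region_index is None:
            region_index = self.locate(x, y, z)
        if region_index < 0:
            raise ValueError(f"position {position} lies outside every region")
        reg = self.regions[region_index]
        r_hi = min(reg.r_hi, self.domain_radius)
        return _ray_region_exit(
            x, y, z, dx, dy, dz, reg.z_lo, reg.z_hi, reg.r_lo, r_hi
        )

    # -- compiled-kernel export -----------------------------------------

    def as_arrays(self) -> dict:
        """Flat numpy representation consumed by the compiled kernel."""
        n_med = len(self._medium_order)
        med_n = np.empty(n_med)
        med_mua = np.empty(n_med)
        med_mus = np.empty(n_med)
        med_g = np.empty(n_med)
        for i, mid in enumerate(self._medium_order):
            m = self.media[mid]
            med_n[i] = m.refractive_index
            med_mua[i] = m.mu_a
            med_mus[i] = m.mu_s
            med_g[i] = m.g
        nreg = len(self.regions)
        reg_z_lo = np.empty(nreg)
        reg_z_hi = np.empty(nreg)
        reg_r_lo = np.empty(nreg)
        reg_r_hi = np.empty(nreg)
        reg_med = np.empty(nreg, dtype=np.int64)
        for k, reg in enumerate(self.regions):
            reg_z_lo[k] = reg.z_lo
            reg_z_hi[k] = reg.z_hi
            reg_r_lo[k] = reg.r_lo
            reg_r_hi[k] = min(reg.r_hi, self.domain_radius)
            reg_med[k] = self.medium_index(reg.medium_id)
        return {
            "med_n": med_n,
            "med_mua": med_mua,
            "med_mus": med_mus,
            "med_g": med_g,
            "reg_z_lo": reg_z_lo,
            "reg_z_hi": reg_z_hi,
            "reg_r_lo": reg_r_lo,
            "reg_r_hi": reg_r_hi,
            "reg_med": reg_med,
            "domain_radius": float(self.domain_radius),
            "z_min": float(self.z_min),
            "z_max": float(self.z_max),
            "back_r": float(self.back_plane_radius),
            "back_policy": BACK_ABSORB if self.back_plane_policy == "absorb" else BACK_MIRROR,
            "back_refl": float(self.back_plane_reflectivity),
        }


def _ray_region_exit(
    x: float,
    y: float,
    z: float,
    dx: float,
    dy: float,
    dz: float,
    z_lo: float,
    z_hi: float,
    r_lo: float,
    r_hi: float,
) -> tuple[float, int]:
    """Exit distance and surface of a ray from inside an annular slab.

    Mirrored verbatim inside the compiled kernel; keep the arithmetic
    identical (the engine-equivalence test depends on it).
    """
    best = math.inf
    surf = SURF_Z_HI
    if dz > 0.0:
        t = (z_hi - z) / dz
        if t < best:
            best = t
            surf = SURF_Z_HI
    elif dz < 0.0:
        t = (z_lo - z) / dz
        if t < best:
            best = t
            surf = SURF_Z_LO
    a = dx * dx + dy * dy
    if a > 0.0:
        b = 2.0 * (x * dx + y * dy)
        c = x * x + y * y
        if math.isfinite(r_hi):
            disc = b * b - 4.0 * a * (c - r_hi * r_hi)
            if disc > 0.0:
                t = (-b + math.sqrt(disc)) / (2.0 * a)
                if 0.0 < t < best:
                    best = t
                    surf = SURF_R_HI
        if r_lo > 0.0 and b < 0.0:
            disc = b * b - 4.0 * a * (c - r_lo * r_lo)
            if disc > 0.0:
                t = (-b - math.sqrt(disc)) / (2.0 * a)
                if 0.0 < t < best:
                    best = t
                    surf = SURF_R_LO
    if best < 0.0:
        best = 0.0
    return best, surf


def surface_normal(
    surface: int, x: float, y: float
) -> tuple[float, float, float]:
    """Outward unit normal of a region surface at the exit point."""
    if surface == SURF_Z_HI:
        return (0.0, 0.0, 1.0)
    if surface == SURF_Z_LO:
        return (0.0, 0.0, -1.0)
    r = math.sqrt(x * x + y * y)
    if r == 0.0:
        raise ValueError("radial surface normal undefined on the axis")
    if surface == SURF_R_HI:
        return (x / r, y / r, 0.0)
    return (-x / r, -y / r, 0.0)
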
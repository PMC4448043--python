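"""Track-length fluence tallies on a cylindrical (r, z) grid and the derived
stimulation metrics: fluence-rate maps, opsin-activation volume, penetration
depth and the interface irradiance profile.

The estimator credits every voxel a photon segment traverses with
``weight x path-length-in-voxel`` (mm).  Dividing the accumulated tally by
``voxel volume x photons launched`` gives fluence per unit source power;
scaling by the source power gives fluence rate in mW/mm^2.  Track-length
scoring stays well-behaved in voxels with little absorption, which is most
of them at these tissue constants.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import LayeredGeometry

NO_DEPTH = -math.inf  # sentinel: no voxel reaches the threshold


@dataclass
class FluenceGrid:
    """Cylindrical tally grid.

    ``values[iz, ir]`` is the accumulated track length x weight (mm) in the
    voxel ``r in [r_edges[ir], r_edges[ir+1]) x z in [z_edges[iz],
    z_edges[iz+1])``.  Bins are half-open.  ``source_power`` is the total
    emitted optical power in mW used for normalisation.
    """

    r_edges: np.ndarray
    z_edges: np.ndarray
    values: np.ndarray = None
    n_photons: int = 0
    seed: int = 0
    source_power: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.r_edges = np.asarray(self.r_edges, dtype=np.float64)
        self.z_edges = np.asarray(self.z_edges, dtype=np.float64)
        if self.r_edges[0] != 0.0 or np.any(np.diff(self.r_edges) <= 0.0):
            raise ValueError("r_edges must increase strictly from 0")
        if np.any(np.diff(self.z_edges) <= 0.0):
            raise ValueError("z_edges must be strictly increasing")
        shape = (len(self.z_edges) - 1, len(self.r_edges) - 1)
        if self.values is None:
            self.values = np.zeros(shape)
        else:
            self.values = np.asarray(self.values, dtype=np.float64)
            if self.values.shape != shape:
                raise ValueError(f"values shape {self.values.shape} != {shape}")

    @classmethod
    def uniform(
        cls,
        dr: float = 0.01,
        dz: float = 0.01,
        r_max: float = 1.5,
        z_lo: float = -0.4,
        z_hi: float = 2.0,
        **kw,
    ) -> "FluenceGrid":
        """Regular grid; the defaults resolve a 30 um source with 3 radial bins."""
        nr = int(round(r_max / dr))
        nz = int(round((z_hi - z_lo) / dz))
        return cls(
            r_edges=np.linspace(0.0, nr * dr, nr + 1),
            z_edges=z_lo + np.linspace(0.0, nz * dz, nz + 1),
            **kw,
        )

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    @property
    def voxel_volumes(self) -> np.ndarray:
        """Annular voxel volumes, mm^3, shape (nz, nr)."""
        ring = math.pi * (self.r_edges[1:] ** 2 - self.r_edges[:-1] ** 2)
        dz = np.diff(self.z_edges)
        return dz[:, None] * ring[None, :]


def deposit_track(
    grid: FluenceGrid,
    start: tuple[float, float, float],
    end: tuple[float, float, float],
    weight: float,
) -> float:
    """Score one straight photon segment into the grid.

    The segment is split exactly at every voxel boundary it crosses (planes
    in z, cylinders in r) and each voxel receives ``weight x sub-length``.
    Portions outside the gridded domain are clipped; the clipped
    ``weight x length`` is returned so the caller can tally it.
    """
    x0, y0, z0 = start
    x1, y1, z1 = end
    dx, dy, dz = x1 - x0, y1 - y0, z1 - z0
    length = math.sqrt(dx * dx + dy * dy + dz * dz)
    if length == 0.0 or weight == 0.0:
        return 0.0

    cuts = [0.0, 1.0]
    # z-plane crossings (t parametrises [0, 1] along the segment)
    if dz != 0.0:
        zs = grid.z_edges
        for ze in zs[(zs > min(z0, z1)) & (zs < max(z0, z1))]:
            cuts.append((ze - z0) / dz)
    # r-cylinder crossings: |p_xy + t d_xy|^2 = a t^2 + b t + c
    a = dx * dx + dy * dy
    if a > 0.0:
        b = 2.0 * (x0 * dx + y0 * dy)
        c = x0 * x0 + y0 * y0
        for re in grid.r_edges[1:]:
            disc = b * b - 4.0 * a * (c - re * re)
            if disc > 0.0:
                sq = math.sqrt(disc)
                for t in ((-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)):
                    if 0.0 < t < 1.0:
                        cuts.append(t)
    ts = np.sort(np.asarray(cuts))

    r_edges = grid.r_edges
    z_edges = grid.z_edges
    clipped = 0.0
    for t_lo, t_hi in zip(ts[:-1], ts[1:]):
        if t_hi <= t_lo:
            continue
        tm = 0.5 * (t_lo + t_hi)
        xm = x0 + tm * dx
        ym = y0 + tm * dy
        zm = z0 + tm * dz
        sub = (t_hi - t_lo) * length
        rm = math.sqrt(xm * xm + ym * ym)
        ir = np.searchsorted(r_edges, rm, side="right") - 1
        iz = np.searchsorted(z_edges, zm, side="right") - 1
        if 0 <= ir < len(r_edges) - 1 and 0 <= iz < len(z_edges) - 1:
            grid.values[iz, ir] += weight * sub
        else:
            clipped += weight * sub
    return clipped


def _deposit_uniform(
    values: np.ndarray,
    dr: float,
    nr: int,
    z0: float,
    dz: float,
    nz: int,
    x0: float,
    y0: float,
    zz0: float,
    x1: float,
    y1: float,
    zz1: float,
    w: float,
) -> float:
    """Exact segment splitting on a *uniform* (r, z) grid — scalar-engine path.

    Mirrored verbatim by the compiled kernel (``optomc._kernel._deposit``);
    keep the arithmetic identical.  Returns the clipped (out-of-grid)
    weight x length.
    """
    dx = x1 - x0
    dy = y1 - y0
    dzz = zz1 - zz0
    length = math.sqrt(dx * dx + dy * dy + dzz * dzz)
    if length == 0.0 or w == 0.0:
        return 0.0
    cuts = [0.0, 1.0]
    if dzz != 0.0:
        zmin = zz0 if zz0 < zz1 else zz1
        zmax = zz0 if zz0 > zz1 else zz1
        k_lo = int(math.floor((zmin - z0) / dz)) + 1
        k_hi = int(math.floor((zmax - z0) / dz))
        if k_lo < 0:
            k_lo = 0
        if k_hi > nz:
            k_hi = nz
        for k in range(k_lo, k_hi + 1):
            t = (z0 + k * dz - zz0) / dzz
            if 0.0 < t < 1.0:
                cuts.append(t)
    a = dx * dx + dy * dy
    if a > 0.0:
        b = 2.0 * (x0 * dx + y0 * dy)
        c = x0 * x0 + y0 * y0
        r0sq = c
        r1sq = c + b + a
        rmaxsq = r0sq if r0sq > r1sq else r1sq
        tstar = -b / (2.0 * a)
        if 0.0 < tstar < 1.0:
            rminsq = c - (b * b) / (4.0 * a)
            if rminsq < 0.0:
                rminsq = 0.0
        else:
            rminsq = r0sq if r0sq < r1sq else r1sq
        j_lo = int(math.floor(math.sqrt(rminsq) / dr)) + 1
        j_hi = int(math.floor(math.sqrt(rmaxsq) / dr))
        if j_lo < 1:
            j_lo = 1
        if j_hi > nr:
            j_hi = nr
        for j in range(j_lo, j_hi + 1):
            re = j * dr
            disc = b * b - 4.0 * a * (c - re * re)
            if disc > 0.0:
                sq = math.sqrt(disc)
                t1 = (-b - sq) / (2.0 * a)
                t2 = (-b + sq) / (2.0 * a)
                if 0.0 < t1 < 1.0:
                    cuts.append(t1)
                if 0.0 < t2 < 1.0:
                    cuts.append(t2)
    cuts.sort()
    clipped = 0.0
    for i in range(len(cuts) - 1):
        t_lo = cuts[i]
        t_hi = cuts[i + 1]
        if t_hi <= t_lo:
            continue
        tm = 0.5 * (t_lo + t_hi)
        xm = x0 + tm * dx
        ym = y0 + tm * dy
        zm = zz0 + tm * dzz
        sub = (t_hi - t_lo) * length
        rm = math.sqrt(xm * xm + ym * ym)
        ir = int(math.floor(rm / dr))
        iz = int(math.floor((zm - z0) / dz))
        if 0 <= ir < nr and 0 <= iz < nz:
            values[iz, ir] += w * sub
        else:
            clipped += w * sub
    return clipped


def fluence_map(grid: FluenceGrid) -> np.ndarray:
    """Per-voxel fluence rate, mW/mm^2, shape (nz, nr)."""
    if grid.n_photons <= 0:
        raise ValueError("fluence_map needs n_photons > 0")
    return grid.values * (grid.source_power / grid.n_photons) / grid.voxel_volumes


def tissue_mask(grid: FluenceGrid, geometry: LayeredGeometry, tissue_id: str = "tissue") -> np.ndarray:
    """Boolean (nz, nr) mask of voxels whose *centre* lies in the tissue medium."""
    mask = np.zeros((len(grid.z_centers), len(grid.r_centers)), dtype=bool)
    for iz, zc in enumerate(grid.z_centers):
        for ir, rc in enumerate(grid.r_centers):
            k = geometry.locate(rc, 0.0, zc)
            if k >= 0 and geometry.regions[k].medium_id == tissue_id:
                mask[iz, ir] = True
    return mask


@dataclass
class ActivationReport:
    """Above-threshold illumination summary at one fluence-rate threshold."""

    threshold: float  # mW/mm^2
    volume_above: float  # mm^3
    max_depth: float  # mm; -inf when nothing reaches threshold
    above_voxel_count: int

    def to_dict(self) -> dict:
        d = dict(
            threshold_mW_mm2=self.threshold,
            volume_above_mm3=self.volume_above,
            max_depth_mm=None if self.max_depth == NO_DEPTH else self.max_depth,
            above_voxel_count=self.above_voxel_count,
        )
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def activation_volume(
    fluence: np.ndarray,
    grid: FluenceGrid,
    threshold: float,
    tissue: np.ndarray | None = None,
) -> float:
    """Total volume (mm^3) of tissue voxels whose fluence rate >= threshold."""
    if threshold <= 0.0:
        raise ValueError("threshold must be > 0")
    above = fluence >= threshold
    if tissue is not None:
        above = above & tissue
    return float(np.sum(grid.voxel_volumes[above]))


def penetration_depth(
    fluence: np.ndarray,
    grid: FluenceGrid,
    threshold: float,
    tissue: np.ndarray | None = None,
) -> float:
    """Largest z-bin centre (mm) with any tissue voxel at/above threshold.

    Returns ``NO_DEPTH`` (-inf) when no voxel qualifies.
    """
    if threshold <= 0.0:
        raise ValueError("threshold must be > 0")
    above = fluence >= threshold
    if tissue is not None:
        above = above & tissue
    rows = np.nonzero(above.any(axis=1))[0]
    if len(rows) == 0:
        return NO_DEPTH
    return float(grid.z_centers[rows[-1]])


def activation_report(
    fluence: np.ndarray,
    grid: FluenceGrid,
    threshold: float,
    tissue: np.ndarray | None = None,
) -> ActivationReport:
    above = fluence >= threshold
    if tissue is not None:
        above = above & tissue
    return ActivationReport(
        threshold=threshold,
        volume_above=activation_volume(fluence, grid, threshold, tissue),
        max_depth=penetration_depth(fluence, grid, threshold, tissue),
        above_voxel_count=int(np.sum(above)),
    )


def interface_profile(
    fluence: np.ndarray, grid: FluenceGrid, tissue_z0: float = 0.0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Radial irradiance profile in the first tissue layer.

    Returns ``(r_centers, profile, half_max_diameter)``.  The half-max
    diameter is the standard FWHM: twice the radius of the first crossing
    below half the peak when scanning outward from the peak bin, linearly
    interpolated between bin centres (the full grid width if the profile
    never falls below half).  For the uLED this diameter exceeds the
    physical 30 um emitter because light spreads in the sapphire substrate.
    """
    iz = int(np.searchsorted(grid.z_centers, tissue_z0, side="right"))
    if iz >= fluence.shape[0]:
        raise ValueError("grid has no z-bins beyond the tissue interface")
    profile = fluence[iz, :]
    peak = profile.max()
    if peak <= 0.0:
        return grid.r_centers, profile, 0.0
    half = 0.5 * peak
    r = grid.r_centers
    ipk = int(np.argmax(profile))
    diameter = 2.0 * float(r[-1])
    for j in range(ipk + 1, len(profile)):
        if profile[j] < half:
            frac = (profile[j - 1] - half) / (profile[j - 1] - profile[j])
            diameter = 2.0 * float(r[j - 1] + frac * (r[j] - r[j - 1]))
            break
    return grid.r_centers, profile, diameter
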
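"""The Monte-Carlo transport engine.

Two implementations share one contract:

* a scalar, step-level pure-Python walk (``step_photon`` /
  ``propagate_photon``) — readable, debuggable, and the one the naive
  reference runner (:mod:`optomc.reference`) uses;
* the compiled production kernel (:mod:`optomc._kernel`) driven by
  :func:`run_simulation` — same arithmetic, same per-photon deviate
  streams, orders of magnitude faster.

Each photon owns an independent counter-based random substream derived from
``(seed, photon index)``, so results are reproducible and invariant to
execution order.  Photons terminate by Russian roulette (unbiased,
default), by leaving the domain, by hitting the back plane behind the
source, or — in the strict plain-threshold mode — the moment their weight
drops below the threshold, with the discarded weight tallied so the energy
balance still closes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .geometry import (
    SURF_R_HI,
    SURF_Z_HI,
    SURF_Z_LO,
    LayeredGeometry,
    _ray_region_exit,
)
from .optics import PhotonState, attenuate, fresnel_unpolarized, rotate_direction, sample_hg_cos
from .rng import PhotonRNG
from .scoring import FluenceGrid, _deposit_uniform
from .sources import FiberSource, LambertianDiscSource, sample_disc_launch, sample_fiber_launch

TWO_PI = 2.0 * math.pi

# terminal fates
FATE_ROULETTE = 0
FATE_ESCAPED = 1
FATE_BACK_PLANE = 2
FATE_EDGE = 3
FATE_CAPPED = 4
FATE_ABSORBED = 5

FATE_NAMES = {
    FATE_ROULETTE: "roulette",
    FATE_ESCAPED: "escaped",
    FATE_BACK_PLANE: "back_plane",
    FATE_EDGE: "edge",
    FATE_CAPPED: "capped",
    FATE_ABSORBED: "absorbed",
}


@dataclass
class Tallies:
    """Weight bookkeeping for a run, in units of launched photons."""

    launched: float = 0.0
    absorbed_by_medium: dict = field(default_factory=dict)
    escaped_domain: float = 0.0
    back_plane_loss: float = 0.0
    edge_loss: float = 0.0
    roulette_net: float = 0.0  # net weight destroyed by roulette / termination
    capped_weight: float = 0.0
    capped_count: int = 0
    clipped_track: float = 0.0  # weight x length scored outside the grid
    total_steps: int = 0

    @property
    def absorbed_total(self) -> float:
        return sum(self.absorbed_by_medium.values())

    @property
    def energy_balance_residual(self) -> float:
        """launched - (all sinks) - roulette_net; ~0 for a correct run."""
        sinks = (
            self.absorbed_total
            + self.escaped_domain
            + self.back_plane_loss
            + self.edge_loss
            + self.capped_weight
        )
        return self.launched - sinks - self.roulette_net

    def to_dict(self) -> dict:
        return dict(
            launched=self.launched,
            absorbed_by_medium=dict(self.absorbed_by_medium),
            escaped_domain=self.escaped_domain,
            back_plane_loss=self.back_plane_loss,
            edge_loss=self.edge_loss,
            roulette_net=self.roulette_net,
            capped_weight=self.capped_weight,
            capped_count=self.capped_count,
            clipped_track=self.clipped_track,
            total_steps=self.total_steps,
            energy_balance_residual=self.energy_balance_residual,
        )


@dataclass(frozen=True)
class TransportParams:
    """Termination controls; defaults are the package's standard settings."""

    roulette_threshold: float = 1.0e-4
    roulette_survival: float = 0.1
    step_cap: int = 100_000
    strict_terminate: bool = False

    def __post_init__(self):
        if not (0.0 < self.roulette_survival < 1.0):
            raise ValueError("roulette_survival must lie in (0, 1)")
        if self.roulette_threshold <= 0.0:
            raise ValueError("roulette_threshold must be > 0")
        if self.step_cap < 1:
            raise ValueError("step_cap must be >= 1")


def roulette(weight: float, threshold: float, survival_p: float, u: float) -> float:
    """Russian-roulette a photon weight; unbiased in expectation.

    Weights at or above ``threshold`` pass through unchanged; below it the
    photon survives with probability ``survival_p`` (weight boosted by
    ``1/survival_p``) or is terminated (returns 0).
    """
    if not (0.0 < survival_p < 1.0):
        raise ValueError("survival_p must lie in (0, 1)")
    if weight >= threshold:
        return weight
    if u < survival_p:
        return weight / survival_p
    return 0.0


def step_photon(
    photon: PhotonState,
    geometry: LayeredGeometry,
    grid: FluenceGrid,
    tallies: Tallies,
    rng: PhotonRNG,
    params: TransportParams = TransportParams(),
) -> int | None:
    """Advance one photon by one step (to its next interaction or boundary).

    Mutates ``photon`` in place, deposits the traversed segment into
    ``grid`` and updates ``tallies``.  Returns a terminal fate code when the
    step killed the photon, else ``None``.  The arithmetic here is the
    contract the compiled kernel reproduces bit-for-bit.
    """
    if not photon.alive:
        raise ValueError("step_photon called on a dead photon")
    x, y, z = photon.position
    ux, uy, uz = photon.direction
    region = photon.region
    if region < 0:
        region = geometry.locate(x, y, z)
        if region < 0:
            raise ValueError(f"photon position {photon.position} outside the geometry")
    w = photon.weight
    dr = float(grid.r_edges[1] - grid.r_edges[0])
    dzg = float(grid.z_edges[1] - grid.z_edges[0])
    nr = len(grid.r_edges) - 1
    nz = len(grid.z_edges) - 1
    gz0 = float(grid.z_edges[0])
    reg = geometry.regions[region]
    med = geometry.media[reg.medium_id]
    photon.steps += 1
    fate: int | None = None

    mu_t = med.mu_a + med.mu_s
    if mu_t > 0.0:
        s = -math.log(rng.next_open01()) / mu_t
    else:
        s = math.inf
    r_hi = reg.r_hi if reg.r_hi < geometry.domain_radius else geometry.domain_radius
    db, surf = _ray_region_exit(x, y, z, ux, uy, uz, reg.z_lo, reg.z_hi, reg.r_lo, r_hi)

    if s < db:
        # collision inside the region
        nxp, nyp, nzp = x + s * ux, y + s * uy, z + s * uz
        tallies.clipped_track += _deposit_uniform(
            grid.values, dr, nr, gz0, dzg, nz, x, y, z, nxp, nyp, nzp, w
        )
        x, y, z = nxp, nyp, nzp
        w, absorbed = attenuate(w, med)
        tallies.absorbed_by_medium[reg.medium_id] = (
            tallies.absorbed_by_medium.get(reg.medium_id, 0.0) + absorbed
        )
        if med.mu_s > 0.0:
            cos_t = sample_hg_cos(med.g, rng.next_float())
            phi = TWO_PI * rng.next_float()
            ux, uy, uz = rotate_direction((ux, uy, uz), cos_t, phi)
        if w <= 0.0:
            fate = FATE_ABSORBED
        elif w < params.roulette_threshold:
            if params.strict_terminate:
                tallies.roulette_net += w
                fate = FATE_ROULETTE
            else:
                w_before = w
                if rng.next_float() < params.roulette_survival:
                    w = w / params.roulette_survival
                    tallies.roulette_net += w_before - w
                else:
                    tallies.roulette_net += w_before
                    fate = FATE_ROULETTE
    else:
        # advance to the boundary and resolve the interface
        nxp, nyp, nzp = x + db * ux, y + db * uy, z + db * uz
        tallies.clipped_track += _deposit_uniform(
            grid.values, dr, nr, gz0, dzg, nz, x, y, z, nxp, nyp, nzp, w
        )
        x, y, z = nxp, nyp, nzp
        if surf == SURF_Z_HI:
            nx_, ny_, nz_ = 0.0, 0.0, 1.0
        elif surf == SURF_Z_LO:
            nx_, ny_, nz_ = 0.0, 0.0, -1.0
        else:
            rr = math.sqrt(x * x + y * y)
            if surf == SURF_R_HI:
                nx_, ny_, nz_ = x / rr, y / rr, 0.0
            else:
                nx_, ny_, nz_ = -x / rr, -y / rr, 0.0
        eps = 1.0e-7
        neighbor = geometry.locate(x + eps * nx_, y + eps * ny_, z + eps * nz_)
        if neighbor >= 0:
            n1 = med.refractive_index
            n2 = geometry.media[geometry.regions[neighbor].medium_id].refractive_index
            if n1 == n2:
                region = neighbor
            else:
                cos_i = ux * nx_ + uy * ny_ + uz * nz_
                refl = 1.0 if cos_i <= 0.0 else fresnel_unpolarized(n1, n2, cos_i)
                if rng.next_float() < refl:
                    ux = ux - 2.0 * cos_i * nx_
                    uy = uy - 2.0 * cos_i * ny_
                    uz = uz - 2.0 * cos_i * nz_
                else:
                    eta = n1 / n2
                    sin2_t = eta * eta * (1.0 - cos_i * cos_i)
                    cos_t = math.sqrt(1.0 - sin2_t)
                    tx = eta * ux + (cos_t - eta * cos_i) * nx_
                    ty = eta * uy + (cos_t - eta * cos_i) * ny_
                    tz = eta * uz + (cos_t - eta * cos_i) * nz_
                    norm = math.sqrt(tx * tx + ty * ty + tz * tz)
                    ux, uy, uz = tx / norm, ty / norm, tz / norm
                    region = neighbor
        else:
            # left the modelled volume: classify by face
            rr2 = x * x + y * y
            rd = geometry.domain_radius - 1.0e-9
            if surf == SURF_Z_LO and z <= geometry.z_min + 1.0e-9:
                if rr2 <= geometry.back_plane_radius * geometry.back_plane_radius:
                    reflected = False
                    if geometry.back_plane_policy == "mirror":
                        if rng.next_float() < geometry.back_plane_reflectivity:
                            uz = -uz
                            reflected = True
                    if not reflected:
                        tallies.back_plane_loss += w
                        fate = FATE_BACK_PLANE
                else:
                    tallies.escaped_domain += w
                    fate = FATE_ESCAPED
            elif (surf == SURF_Z_HI and z >= geometry.z_max - 1.0e-9) or (
                surf == SURF_R_HI and rr2 >= rd * rd
            ):
                tallies.escaped_domain += w
                fate = FATE_ESCAPED
            else:
                # un-modelled volume (geometry gap): conservative absorber
                tallies.edge_loss += w
                fate = FATE_EDGE

    photon.position = (x, y, z)
    photon.direction = (ux, uy, uz)
    photon.weight = w
    photon.region = region
    photon.medium_id = geometry.regions[region].medium_id
    if fate is not None:
        photon.alive = False
    return fate


def propagate_photon(
    photon: PhotonState,
    geometry: LayeredGeometry,
    grid: FluenceGrid,
    tallies: Tallies,
    rng: PhotonRNG,
    params: TransportParams = TransportParams(),
) -> int:
    """Walk a freshly launched photon to termination; returns its fate code."""
    while True:
        if photon.steps >= params.step_cap:
            tallies.capped_weight += photon.weight
            tallies.capped_count += 1
            photon.alive = False
            fate = FATE_CAPPED
            break
        fate = step_photon(photon, geometry, grid, tallies, rng, params)
        if fate is not None:
            break
    tallies.total_steps += photon.steps
    return fate


def launch_photon(source, rng: PhotonRNG, geometry: LayeredGeometry) -> PhotonState:
    """Sample one launch from the source and wrap it as a live PhotonState."""
    if isinstance(source, LambertianDiscSource):
        pos, d = sample_disc_launch(source, rng)
        medium_id = source.launch_medium_id
    elif isinstance(source, FiberSource):
        n_launch = geometry.media[source.launch_medium_id].refractive_index
        pos, d = sample_fiber_launch(source, rng, n_launch)
        medium_id = source.launch_medium_id
    else:
        raise TypeError(f"unsupported source type {type(source)!r}")
    region = geometry.locate(*pos)
    if region < 0:
        raise ValueError(f"launch position {pos} outside the geometry")
    return PhotonState(position=pos, direction=d, weight=1.0, medium_id=medium_id, region=region)


def _encode_source(source, geometry: LayeredGeometry):
    if isinstance(source, LambertianDiscSource):
        if source.emission_axis != (0.0, 0.0, 1.0):
            raise ValueError("the compiled kernel supports emission along +z only")
        cx, cy, cz = source.center
        return _kernel.SRC_DISC, np.array(
            [source.diameter, cx, cy, cz, 1.0 if source.collimated else 0.0]
        )
    if isinstance(source, FiberSource):
        if source.axis != (0.0, 0.0, 1.0):
            raise ValueError("the compiled kernel supports emission along +z only")
        n_launch = geometry.media[source.launch_medium_id].refractive_index
        tx, ty, tz = source.tip_position
        return _kernel.SRC_FIBER, np.array(
            [source.core_radius, source.sigma, tx, ty, tz, source.cone_cos_max(n_launch)]
        )
    raise TypeError(f"unsupported source type {type(source)!r}")


def run_transport(
    source,
    geometry: LayeredGeometry,
    grid: FluenceGrid,
    n_photons: int,
    seed: int,
    params: TransportParams = TransportParams(),
    source_power: float | None = None,
) -> tuple[FluenceGrid, Tallies, np.ndarray]:
    """Run the compiled engine; returns ``(grid, tallies, per-photon fates)``.

    ``grid.values`` is accumulated in place; metadata (photon count, seed,
    power) is filled in so :func:`optomc.scoring.fluence_map` can normalise.
    """
    if n_photons < 0:
        raise ValueError("n_photons must be >= 0")
    arr = geometry.as_arrays()
    dr = float(grid.r_edges[1] - grid.r_edges[0])
    dzg = float(grid.z_edges[1] - grid.z_edges[0])
    if not (
        np.allclose(np.diff(grid.r_edges), dr) and np.allclose(np.diff(grid.z_edges), dzg)
    ):
        raise ValueError("the compiled engine requires a uniformly spaced grid")
    nr = len(grid.r_edges) - 1
    nz = len(grid.z_edges) - 1
    src_type, src_params = _encode_source(source, geometry)
    tally = np.zeros(_kernel.N_TALLY)
    absorbed = np.zeros(len(arr["med_n"]))
    fates = np.full(n_photons, -1, dtype=np.int64)
    steps = np.zeros(n_photons, dtype=np.int64)
    if n_photons > 0:
        _kernel.run_kernel(
            n_photons,
            seed,
            src_type,
            src_params,
            arr["med_n"],
            arr["med_mua"],
            arr["med_mus"],
            arr["med_g"],
            arr["reg_z_lo"],
            arr["reg_z_hi"],
            arr["reg_r_lo"],
            arr["reg_r_hi"],
            arr["reg_med"],
            arr["domain_radius"],
            arr["z_min"],
            arr["z_max"],
            arr["back_r"],
            arr["back_policy"],
            arr["back_refl"],
            grid.values,
            dr,
            nr,
            float(grid.z_edges[0]),
            dzg,
            nz,
            params.roulette_threshold,
            params.roulette_survival,
            params.step_cap,
            params.strict_terminate,
            tally,
            absorbed,
            fates,
            steps,
        )
    tallies = Tallies(
        launched=float(n_photons),
        absorbed_by_medium={
            mid: float(absorbed[i]) for i, mid in enumerate(geometry.medium_ids) if absorbed[i] != 0.0
        },
        escaped_domain=float(tally[_kernel.T_ESCAPED]),
        back_plane_loss=float(tally[_kernel.T_BACK]),
        edge_loss=float(tally[_kernel.T_EDGE]),
        roulette_net=float(tally[_kernel.T_ROULETTE]),
        capped_weight=float(tally[_kernel.T_CAPPED_W]),
        capped_count=int(tally[_kernel.T_CAPPED_N]),
        clipped_track=float(tally[_kernel.T_CLIPPED]),
        total_steps=int(steps.sum()),
    )
    grid.n_photons = n_photons
    grid.seed = seed
    if source_power is not None:
        grid.source_power = source_power
    elif isinstance(source, FiberSource):
        grid.source_power = source.output_power
    return grid, tallies, fates
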
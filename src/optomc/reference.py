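"""Naive scalar reference engine.

Runs the photon walk entirely through the step-level pure-Python API in
:mod:`optomc.transport` — one photon at a time, one step at a time, no
compilation.  Because it consumes exactly the same per-photon deviate
streams and performs the same floating-point operations as the compiled
production kernel, the two engines must agree *bit for bit* on tallies,
fates, step counts and the deposited grid for any scenario; the
engine-equivalence oracle in :mod:`optomc.validation` asserts exactly that.
Use it for small photon counts only (it is ~1000x slower than the kernel).
"""

from __future__ import annotations

import numpy as np

from .geometry import LayeredGeometry
from .rng import PhotonRNG
from .scoring import FluenceGrid
from .transport import Tallies, TransportParams, launch_photon, propagate_photon


def run_transport_reference(
    source,
    geometry: LayeredGeometry,
    grid: FluenceGrid,
    n_photons: int,
    seed: int,
    params: TransportParams = TransportParams(),
    source_power: float | None = None,
) -> tuple[FluenceGrid, Tallies, np.ndarray]:
    """Pure-Python counterpart of :func:`optomc.transport.run_transport`."""
    tallies = Tallies(launched=float(n_photons))
    fates = np.full(n_photons, -1, dtype=np.int64)
    for i in range(n_photons):
        rng = PhotonRNG(seed, i)
        photon = launch_photon(source, rng, geometry)
        fates[i] = propagate_photon(photon, geometry, grid, tallies, rng, params)
    grid.n_photons = n_photons
    grid.seed = seed
    if source_power is not None:
        grid.source_power = source_power
    elif hasattr(source, "output_power"):
        grid.source_power = source.output_power
    return grid, tallies, fates
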
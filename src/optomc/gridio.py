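"""Grid and report file I/O.

Grids are stored as self-describing HDF5 containers holding the bin-edge
arrays, the raw track-length values and a metadata block (photon count,
seed, source power, media table, config hash).  Files are written with
HDF5 object timestamps disabled, so identical config + seed produces a
byte-identical file — the regression surface the tests rely on.  A plain
delimited-text export (r, z, fluence) is provided for interoperability.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .scoring import FluenceGrid

_FORMAT_VERSION = 1


def write_grid(grid: FluenceGrid, path) -> None:
    """Write a FluenceGrid to an HDF5 container (deterministic bytes)."""
    with h5py.File(path, "w", track_order=False, libver="earliest") as fh:
        for name, data in (
            ("r_edges", grid.r_edges),
            ("z_edges", grid.z_edges),
            ("values", grid.values),
        ):
            fh.create_dataset(name, data=data, track_times=False)
        meta = dict(
            format_version=_FORMAT_VERSION,
            n_photons=int(grid.n_photons),
            seed=int(grid.seed),
            source_power=float(grid.source_power),
            metadata=grid.metadata,
        )
        fh.create_dataset(
            "meta_json", data=np.bytes_(json.dumps(meta, sort_keys=True)), track_times=False
        )


def read_grid(path) -> FluenceGrid:
    """Read a grid container; round-trips :func:`write_grid` bit-exactly."""
    with h5py.File(path, "r") as fh:
        meta = json.loads(bytes(fh["meta_json"][()]).decode())
        if meta.get("format_version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported grid file version in {path}")
        return FluenceGrid(
            r_edges=fh["r_edges"][()],
            z_edges=fh["z_edges"][()],
            values=fh["values"][()],
            n_photons=meta["n_photons"],
            seed=meta["seed"],
            source_power=meta["source_power"],
            metadata=meta["metadata"],
        )


def export_fluence_csv(grid: FluenceGrid, fluence: np.ndarray, path) -> None:
    """Plain-text (r_mm, z_mm, fluence_mW_mm2) export, one voxel per row."""
    r = grid.r_centers
    z = grid.z_centers
    with open(path, "w") as fh:
        fh.write("r_mm\tz_mm\tfluence_mW_mm2\n")
        for iz in range(len(z)):
            for ir in range(len(r)):
                fh.write(f"{r[ir]:.6g}\t{z[iz]:.6g}\t{fluence[iz, ir]:.8g}\n")


def write_report(report: dict, path) -> None:
    """JSON report writer (activation reports, tallies, oracle results)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
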
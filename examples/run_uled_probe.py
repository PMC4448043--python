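"""Simulate the uLED probe and report its activation volume vs drive current.

The 30 um GaN pixel emits a Lambertian beam through its 100 um sapphire
substrate (n = 1.77, laterally bounded at the 150 um probe width) into
cortical tissue (n = 1.36, mu_s = 11.7 mm^-1, mu_a = 0.07 mm^-1, g = 0.88).
One simulation is run per unit power; the map is then rescaled so the peak
irradiance in the first tissue layer matches the bench-calibrated value for
each drive current (0.1 mA -> 0.5, 4 mA -> 40, 6 mA -> 52 mW/mm^2).
"""

from optomc import (
    activation_report,
    fluence_map,
    interface_profile,
    run_simulation,
    scale_power_to_current,
    tissue_mask,
    uled_config,
)

N_PHOTONS = 200_000  # raise to 1e6 for publication-quality statistics

cfg = uled_config(N_PHOTONS, seed=1)
grid, tallies = run_simulation(cfg)
mask = tissue_mask(grid, cfg.build_geometry())
print(f"{N_PHOTONS} photons; energy-balance residual "
      f"{tallies.energy_balance_residual / tallies.launched:.1e}")

for current in (0.25, 1.0, 4.0):
    grid.source_power = scale_power_to_current(grid, current)
    fl = fluence_map(grid)
    rep = activation_report(fl, grid, threshold=1.0, tissue=mask)
    print(
        f"{current:5.2f} mA ({grid.source_power:6.3f} mW): "
        f"volume >= 1 mW/mm^2: {rep.volume_above:6.4f} mm^3, "
        f"max depth {rep.max_depth:5.3f} mm"
    )

_, _, diameter = interface_profile(fl, grid)
print(f"interface spot half-max diameter: {diameter * 1000:.0f} um "
      f"(pixel is 30 um; sapphire spreads the beam)")
# Expected: the activation volume grows from ~0.001 mm^3 at 0.25 mA to
# ~0.25 mm^3 at 4 mA — low currents give local stimulation, high currents
# broad-area stimulation, always confined near the pixel depth.
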
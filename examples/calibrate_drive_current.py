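"""Drive-current calibration: from mA to interface irradiance to source power.

The probe's bench characterisation anchors the map from drive current to
irradiance at the probe/tissue interface; simulations are rescaled to match
it (transport is linear in power, so no re-simulation is needed).
"""

from optomc import CalibrationTable, current_to_interface_irradiance

table = CalibrationTable.default()
print("anchors (mA -> mW/mm^2):", table.anchors)
for current in (0.1, 0.25, 1.0, 4.0, 5.0, 6.0):
    irr = current_to_interface_irradiance(current, table)
    print(f"{current:5.2f} mA -> {irr:6.2f} mW/mm^2 at the interface")

try:
    current_to_interface_irradiance(10.0, table)
except ValueError as err:
    print("extrapolation refused:", err)
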
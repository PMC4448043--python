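"""Drive-current to irradiance calibration for the uLED probe.

The probe is driven by a current source; bench characterisation gives the
irradiance delivered at the probe/tissue interface at a handful of drive
currents.  Simulated fluence maps are computed per unit source power and
rescaled so that the peak first-tissue-bin irradiance matches the
calibrated interface value for the requested current.

The table stores interface irradiance *directly* and never derives it from
surface (on-die) irradiance: the measured surface-to-interface attenuation
is strongly current-dependent (the emission pattern changes with drive),
so a single attenuation factor would be wrong at one end or the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class CalibrationTable:
    """Piecewise-linear map from drive current (mA) to irradiance (mW/mm^2)."""

    anchors: tuple[tuple[float, float], ...]
    surface_anchors: tuple[tuple[float, float], ...] = field(default=())

    def __post_init__(self):
        if len(self.anchors) < 2:
            raise ValueError("calibration needs at least two anchor points")
        currents = [a[0] for a in self.anchors]
        irradiances = [a[1] for a in self.anchors]
        if any(b <= a for a, b in zip(currents, currents[1:])):
            raise ValueError("anchor currents must be strictly increasing")
        if any(b <= a for a, b in zip(irradiances, irradiances[1:])):
            raise ValueError("anchor irradiances must be strictly increasing")

    @classmethod
    def default(cls) -> "CalibrationTable":
        """The probe's bench anchors: 0.1 mA -> 0.5, 4 mA -> 40, 6 mA -> 52 mW/mm^2."""
        return cls(anchors=((0.1, 0.5), (4.0, 40.0), (6.0, 52.0)))

    @property
    def current_range(self) -> tuple[float, float]:
        return self.anchors[0][0], self.anchors[-1][0]


def current_to_interface_irradiance(current: float, table: CalibrationTable) -> float:
    """Interface irradiance (mW/mm^2) at a drive current (mA).

    Piecewise-linear interpolation through the anchors, exact at anchors;
    refuses to extrapolate outside the calibrated current range.
    """
    lo, hi = table.current_range
    if not (lo <= current <= hi):
        raise ValueError(
            f"current {current} mA outside the calibrated range [{lo}, {hi}] mA"
        )
    currents = np.array([a[0] for a in table.anchors])
    irr = np.array([a[1] for a in table.anchors])
    return float(np.interp(current, currents, irr))
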
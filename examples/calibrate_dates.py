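"""Calibrate a single radiocarbon date and inspect its calendar density.

Builds the bundled smooth synthetic calibration curve (drop in a real
IntCal20 ``.14c`` file via ``paleodem.read_curve`` to use the real one),
calibrates a measurement of 4,000 ± 30 ¹⁴C BP, and prints where the
calendar-age probability ends up.
"""

import numpy as np

from paleodem import calibrate, synthetic_calibration_curve

curve = synthetic_calibration_curve()
density = calibrate((4000, 30), curve, normalize=True)

order = np.argsort(density.density)[::-1]
cum = np.cumsum(density.density[order])
hpd = density.grid[order[: int(np.searchsorted(cum, 0.954)) + 1]]

print(f"curve: {curve.name}, span {curve.cal_min:.0f}-{curve.cal_max:.0f} cal BP")
print(f"date 4000 +/- 30 14C BP -> support {density.grid[0]:.0f}-{density.grid[-1]:.0f} cal BP")
print(f"posterior mode: {density.mode:.0f} cal BP; total mass {density.mass:.6f}")
print(f"95.4% highest-density years: {hpd.max():.0f}-{hpd.min():.0f} cal BP")
print()
print("The mode is the single most probable calendar year; the 95.4% range")
print("is the set of most probable years holding ~2 sigma of the calendar-age")
print("probability after pushing the lab measurement through the curve.")
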
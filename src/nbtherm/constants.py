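"""Physical constants and unit conventions.

Temperatures are carried in kelvin everywhere inside the package; energies
are carried in cal·mol⁻¹ internally and reported in kcal·mol⁻¹, matching the
convention of equilibrium-unfolding work where the gas constant is quoted in
cal·mol⁻¹·K⁻¹.
"""

from __future__ import annotations

import numpy as np

#: Ideal gas constant, cal·mol⁻¹·K⁻¹ (the value conventional in protein
#: calorimetry; kept at this precision so ΔG values reproduce published tables).
R_CAL: float = 1.987

#: Offset between the Celsius and Kelvin scales.
CELSIUS_OFFSET: float = 273.15

#: kcal → cal conversion.
KCAL_TO_CAL: float = 1000.0


def celsius_to_kelvin(t_celsius):
    """Convert °C to K (array-safe)."""
    return np.asarray(t_celsius, dtype=float) + CELSIUS_OFFSET


def kelvin_to_celsius(t_kelvin):
    """Convert K to °C (array-safe)."""
    return np.asarray(t_kelvin, dtype=float) - CELSIUS_OFFSET
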
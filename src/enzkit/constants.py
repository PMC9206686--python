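"""Physical constants and temperature conversion used across the thermodynamic modules."""

from __future__ import annotations

#: Gas constant, J mol^-1 K^-1
R = 8.314

#: Boltzmann constant, J K^-1 (CODATA exact)
KB = 1.380649e-23

#: Planck constant, J s (CODATA exact)
H = 6.62607015e-34

#: Avogadro constant, mol^-1 (declared for completeness; no equation here uses it)
N_AVOGADRO = 6.02214076e23

#: Offset between Celsius and Kelvin scales
CELSIUS_OFFSET = 273.15


def celsius_to_kelvin(temp_c: float) -> float:
    """Convert a temperature from degrees Celsius to Kelvin."""
    return temp_c + CELSIUS_OFFSET


def kelvin_to_celsius(temp_k: float) -> float:
    """Convert a temperature from Kelvin to degrees Celsius."""
    return temp_k - CELSIUS_OFFSET
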
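"""Shared physical constants (SI units)."""

import math

#: Permeability of free space (H/m).
MU_0 = 4.0e-7 * math.pi

#: Boltzmann constant (J/K). The value used throughout the heating chain.
K_B = 1.38e-23

#: Universal gas constant (J/mol/K).
R_GAS = 8.3144598

#: Body / arterial blood temperature (K).
T_BODY = 310.15


def celsius_to_kelvin(t_c):
    return t_c + 273.15


def kelvin_to_celsius(t_k):
    return t_k - 273.15
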
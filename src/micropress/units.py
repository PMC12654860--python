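"""Unit conventions and physical constants.

All public interfaces use: force in nN, length in µm, stress/modulus in kPa,
time in s, angles in degrees. The identity 1 nN/µm² = 1 kPa is exact and is
relied on throughout: stress is computed as force[nN] / area[µm²] with no
conversion factor.
"""

import numpy as np

#: standard gravity, m/s^2
STANDARD_GRAVITY = 9.80665

#: nN per (gram-mass under 1 m/s^2): 1 g * 1 m/s^2 = 1e-3 N = 1e6 nN
_NN_PER_GRAM_MPS2 = 1.0e6


def weight_nN(mass_g: float, gravity: float = STANDARD_GRAVITY) -> float:
    """Gravitational force on a mass given in grams, returned in nN."""
    return mass_g * gravity * _NN_PER_GRAM_MPS2


def deg2rad(angle_deg):
    return np.deg2rad(angle_deg)


def rad2deg(angle_rad):
    return np.rad2deg(angle_rad)
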
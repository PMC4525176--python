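"""Physical constants and unit-conversion factors used throughout the package.

All internal angular quantities are radians; user-facing rotational diffusion
coefficients are deg^2 s^-1 (the convention of the chiral-rotor literature).
"""

import math

#: Boltzmann constant, J K^-1 (2019 SI exact value).
K_B = 1.380649e-23

#: One Debye in C m.
DEBYE = 3.33564e-30

#: Multiply a deg^2 s^-1 rotational diffusion coefficient by this to get rad^2 s^-1.
DEG2_TO_RAD2 = (math.pi / 180.0) ** 2

#: Ångström in metres.
ANGSTROM = 1.0e-10

#: cm^2 in Å^2 (for translational diffusion unit conversion).
CM2_TO_A2 = 1.0e16
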
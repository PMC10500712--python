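"""Physical constants (CODATA 2018), frozen so results are bit-stable.

All values are SI.  scipy.constants tracks CODATA releases and could drift
between environments, so the handful of constants used throughout the
package is pinned here.
"""

# vacuum magnetic permeability, N A^-2
MU0 = 1.25663706212e-6
# Boltzmann constant, J K^-1
KB = 1.380649e-23
# Bohr magneton, J T^-1
MUB = 9.2740100783e-24
# reduced Planck constant, J s
HBAR = 1.054571817e-34
# free-electron g factor (magnitude)
GE = 2.00231930436256

# display-unit conversion factors
ANGSTROM = 1e-10          # m per Angstrom
CHI_UNIT = 1e-32          # m^3 per display unit of susceptibility
PPM = 1e-6                # fractional shielding per ppm
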
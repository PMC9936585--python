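"""Physical constants shared across the package.

Units: lengths in Å, energies in kcal/mol, charges in elementary charges,
temperatures in K, pH/pKa in pH units.
"""

#: Coulomb constant k_C = 1/(4 pi eps0) in kcal·Å/(mol·e²)
COULOMB_KCAL = 332.0636

#: Boltzmann constant in kcal/(mol·K)
KB_KCAL = 0.0019872041

#: Default temperature (K)
T_DEFAULT = 298.15

#: Aqueous reference pKa of the cytosine N3 site
CYTOSINE_PKA_WATER = 4.4

import math


def kt(temperature: float = T_DEFAULT) -> float:
    """Thermal energy k_B·T in kcal/mol."""
    return KB_KCAL * temperature


def ln10_kt(temperature: float = T_DEFAULT) -> float:
    """ln(10)·k_B·T in kcal/mol — the free energy of one pH unit."""
    return math.log(10.0) * kt(temperature)
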
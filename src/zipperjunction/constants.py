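"""Physical constants and unit conversions used throughout the package.

Internal unit conventions:

* conductance is stored in units of the conductance quantum G0 = 2e^2/h;
  user-facing plateau values are quoted in mG0 (1e-3 G0)
* displacement in nm, force in pN, energy in pN*nm (per molecule) unless a
  function says kcal/mol explicitly
* tunnelling decay constants beta are defined through G ~ exp(-beta * z)
  with z in Angstrom (natural log); 1 A^-1 == 10 nm^-1
"""

import math

#: Conductance quantum 2e^2/h in siemens.
G0_SIEMENS = 77.480917e-6

#: Boltzmann constant in pN nm / K.
KB_PN_NM = 1.380649e-2

#: Elementary charge (C) and Planck constant (J s), for the single-level I-V model.
E_CHARGE = 1.602176634e-19
H_PLANCK = 6.62607015e-34

#: 1 kcal/mol expressed as pN nm per molecule.
KCAL_PER_MOL_TO_PN_NM = 6.947695

#: Conversion between the two beta conventions: 1 A^-1 = 10 nm^-1.
A_INV_PER_NM_INV = 0.1

LN10 = math.log(10.0)

#: Displacement-origin convention: first sample below this conductance (G0 units)
#: defines z = 0.
ORIGIN_CONDUCTANCE_G0 = 50e-3


def beta_a_inv_to_nm_inv(beta_a: float) -> float:
    """Convert a decay constant from A^-1 to nm^-1 (natural-log convention)."""
    return beta_a / A_INV_PER_NM_INV


def beta_nm_inv_to_a_inv(beta_nm: float) -> float:
    """Convert a decay constant from nm^-1 to A^-1 (natural-log convention)."""
    return beta_nm * A_INV_PER_NM_INV


def kt_pn_nm(temperature_k: float) -> float:
    """Thermal energy kT in pN nm at the given temperature (K)."""
    return KB_PN_NM * temperature_k
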
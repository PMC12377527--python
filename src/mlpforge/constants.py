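"""Project-wide physical constants and unit conventions.

Units are fixed across the whole package: energies in kcal/mol, lengths in
Angstrom, time in femtoseconds, temperature in Kelvin, forces in
kcal/mol/A.  Anything arriving in other units is converted here, once.
"""

from __future__ import annotations

# Boltzmann constant, kcal/mol/K
KB = 0.0019872041

# Unit conversions
KCAL_PER_KJ = 1.0 / 4.184
KJ_PER_KCAL = 4.184

#: Default cap on the adaptive dihedral bias potential, kcal/mol.
#: 70 kJ/mol expressed in the project's energy unit.
DEFAULT_BIAS_CAP_KCAL = 70.0 * KCAL_PER_KJ  # 16.73 kcal/mol

# Velocity unit bookkeeping for the integrator: with E in kcal/mol, m in amu,
# x in A and t in fs, accelerations a = F/m must be scaled by this factor so
# that (a * dt^2) is in A.  1 kcal/mol = 4.184e26 amu A^2 / s^2
#                         = 4.184e-4 amu A^2 / fs^2.
KCAL_MOL_TO_AMU_A2_PER_FS2 = 4.184e-4

#: Atomic masses (amu) for the supported element alphabet.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "S": 32.06,
    "Cl": 35.45,
    "P": 30.974,
}

#: The element alphabet the workflow supports, in a fixed canonical order.
ELEMENTS = ("H", "C", "N", "O", "F", "S", "Cl", "P")
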
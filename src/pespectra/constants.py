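"""Physical constants (CODATA 2018) and unit-conversion factors.

Every conversion factor used anywhere in the package is derived here, at
import time, from the CODATA 2018 values below.  Nothing downstream hard-codes
a composite factor: if two numbers must be consistent (say, the wavenumber
chain used for frequencies and the one used for Raman cross sections) they are
consistent because they come from the same table.

Internal unit policy: Hartree atomic units everywhere in memory; conversions
happen only at I/O boundaries and when spectra are expressed in reporting
units.
"""

from __future__ import annotations

import math

# --- CODATA 2018 (SI) -------------------------------------------------------
SPEED_OF_LIGHT = 299_792_458.0  # m s^-1 (exact)
PLANCK = 6.626_070_15e-34  # J s (exact)
ELEMENTARY_CHARGE = 1.602_176_634e-19  # C (exact)
AVOGADRO = 6.022_140_76e23  # mol^-1 (exact)
BOLTZMANN = 1.380_649e-23  # J K^-1 (exact)
VACUUM_PERMITTIVITY = 8.854_187_8128e-12  # F m^-1
ELECTRON_MASS = 9.109_383_7015e-31  # kg
ATOMIC_MASS = 1.660_539_066_60e-27  # kg (unified atomic mass unit)
BOHR_RADIUS = 5.291_772_109_03e-11  # m
HARTREE = 4.359_744_722_2071e-18  # J

HBAR = PLANCK / (2.0 * math.pi)

# --- length -----------------------------------------------------------------
BOHR_TO_METER = BOHR_RADIUS
BOHR_TO_ANGSTROM = BOHR_RADIUS * 1e10
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

# --- dipole -----------------------------------------------------------------
# 1 debye = 1e-21 / c  C m  (historical definition via statC cm)
DEBYE_TO_CM = 1e-21 / SPEED_OF_LIGHT  # C m
AU_DIPOLE_TO_CM = ELEMENTARY_CHARGE * BOHR_RADIUS
AU_DIPOLE_TO_DEBYE = AU_DIPOLE_TO_CM / DEBYE_TO_CM

# --- energy -----------------------------------------------------------------
HARTREE_TO_JOULE = HARTREE
KJMOL_TO_HARTREE = 1e3 / AVOGADRO / HARTREE
KCALMOL_TO_HARTREE = 4.184e3 / AVOGADRO / HARTREE

# --- polarizability ---------------------------------------------------------
# a.u. of dipole-dipole polarizability: e^2 a0^2 / Eh  ->  C^2 m^2 J^-1
AU_POLARIZABILITY_TO_SI = (
    ELEMENTARY_CHARGE**2 * BOHR_RADIUS**2 / HARTREE
)

# --- vibrational frequency chain --------------------------------------------
# Mass-weighted Hessian eigenvalue in hartree bohr^-2 amu^-1  ->  angular
# frequency squared in s^-2, then to wavenumber in cm^-1.
_EIGVAL_AU_TO_SI = HARTREE / (BOHR_RADIUS**2 * ATOMIC_MASS)  # s^-2
WAVENUMBER_FROM_EIGVAL = math.sqrt(_EIGVAL_AU_TO_SI) / (
    2.0 * math.pi * SPEED_OF_LIGHT
) / 100.0  # multiply by sqrt(|eigval in a.u./amu|) to get cm^-1

CM_TO_PER_METER = 100.0  # 1 cm^-1 = 100 m^-1

COULOMB_CONSTANT = 1.0 / (4.0 * math.pi * VACUUM_PERMITTIVITY)  # J m C^-2

# Minimal element tables for the point-charge proxy cores and environment
# sites the package manipulates (extend as needed).
ATOMIC_NUMBER: dict[str, int] = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "P": 15, "S": 16, "Cl": 17,
    "Ar": 18, "K": 19, "Ca": 20, "Br": 35, "I": 53,
}

ATOMIC_MASS_AMU: dict[str, float] = {
    "H": 1.00782503207, "He": 4.002602, "Li": 7.016004, "Be": 9.012182,
    "B": 11.009305, "C": 12.0, "N": 14.0030740048, "O": 15.9949146196,
    "F": 18.99840322, "Ne": 19.9924401754, "Na": 22.9897692809,
    "Mg": 23.98504170, "P": 30.97376163, "S": 31.97207100,
    "Cl": 34.96885268, "Ar": 39.9623831225, "K": 38.96370668,
    "Ca": 39.96259098, "Br": 78.9183371, "I": 126.904473,
}
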
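"""Physical constants and the pinned isotope-mass table.

Every unit conversion in the package routes through this module so that
comparisons at the 0.1 kcal/mol and 0.0001 Da level are reproducible and
cannot drift with third-party dependency updates.

Sources: CODATA 2018 for the fundamental constants; AME2020 rounded to
8 decimal places for the monoisotopic (most-abundant-isotope) masses.
"""

from __future__ import annotations

# --- CODATA 2018 fundamental constants (SI) ---
PLANCK_J_S = 6.62607015e-34          # h, J s (exact)
SPEED_OF_LIGHT_CM_S = 2.99792458e10  # c, cm/s (exact)
BOLTZMANN_J_K = 1.380649e-23         # k_B, J/K (exact)
AVOGADRO = 6.02214076e23             # N_A, 1/mol (exact)
HARTREE_J = 4.3597447222071e-18      # E_h, J
AMU_KG = 1.66053906660e-27           # u, kg
ELECTRON_MASS_DA = 5.48579909065e-4  # m_e, Da

# --- Derived / pinned conversions ---
# 1 hartree expressed in cm^-1:  E_h / (h c)
HARTREE_IN_INV_CM = HARTREE_J / (PLANCK_J_S * SPEED_OF_LIGHT_CM_S)  # ~219474.63
# Pinned at the conventional 4-decimal value used throughout reports.
HARTREE_IN_KCAL_MOL = 627.5095
# Gas constant in the units of the Boltzmann exponent (kcal mol^-1 K^-1).
R_KCAL_MOL_K = 1.987204e-3
# k_B in hartree/K, for thermal corrections carried in hartree.
KB_HARTREE_K = BOLTZMANN_J_K / HARTREE_J
# k_B/(h c) in cm^-1/K: converts wavenumbers to reduced temperatures.
KB_INV_CM_K = BOLTZMANN_J_K / (PLANCK_J_S * SPEED_OF_LIGHT_CM_S)
# Standard-state pressure for the translational partition function, Pa.
STANDARD_PRESSURE_PA = 1.0e5  # 1 bar

# --- Pinned monoisotopic masses, Da (most abundant isotope) ---
MONOISOTOPIC_MASS = {
    "H": 1.00782503,
    "C": 12.0,
    "N": 14.00307401,
    "O": 15.99491462,
    "F": 18.99840316,
    "Na": 22.98976928,
    "Si": 27.97692654,
    "P": 30.97376200,
    "S": 31.97207117,
    "Cl": 34.96885268,
    "K": 38.96370649,
    "Br": 78.91833760,
    "I": 126.90447300,
}

# --- Integer mass numbers of the most abundant isotopes ---
NOMINAL_MASS = {
    "H": 1, "C": 12, "N": 14, "O": 16, "F": 19, "Na": 23, "Si": 28,
    "P": 31, "S": 32, "Cl": 35, "K": 39, "Br": 79, "I": 127,
}

# --- Atomic numbers, for the QC-output geometry blocks ---
ATOMIC_NUMBER = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "Na": 11, "Si": 14,
    "P": 15, "S": 16, "Cl": 17, "K": 19, "Br": 35, "I": 53,
}
ELEMENT_OF_Z = {z: el for el, z in ATOMIC_NUMBER.items()}
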
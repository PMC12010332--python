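"""Unit conventions and physical constants.

Internal units are fixed across the package: lengths in nm, times in ps,
masses in amu (g/mol), energies in kJ/mol, temperatures in K.  File readers
convert at the boundary (PDB/XYZ Angstrom -> nm).  All constants come from
scipy's CODATA tables.
"""

import numpy as np
from scipy import constants as _c

# Fundamental constants (SI)
KB_SI = _c.k                # J/K
HBAR_SI = _c.hbar           # J s
H_SI = _c.h                 # J s
C_SI = _c.c                 # m/s
N_A = _c.N_A                # 1/mol
AMU_KG = _c.atomic_mass     # kg

# Boltzmann constant in package energy units
KB_KJ_PER_MOL_K = KB_SI * N_A / 1000.0   # kJ/(mol K)

# One kJ/mol expressed per molecule, in joules
KJ_PER_MOL_TO_J = 1000.0 / N_A

# amu nm^2 -> kg m^2 (mass-weighted positional covariance eigenvalues)
AMU_NM2_TO_KG_M2 = AMU_KG * 1e-18

# (kJ/mol/nm^2)/amu -> s^-2 (mass-weighted Hessian eigenvalues to omega^2)
HESSIAN_EIG_TO_OMEGA2_SI = KJ_PER_MOL_TO_J / (AMU_KG * 1e-18)

# Standard pressure for translational entropy (1 bar)
P_STANDARD_PA = 1.0e5


def kbt_kj_per_mol(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol."""
    return KB_KJ_PER_MOL_K * temperature


def omega_si_to_wavenumber(omega: np.ndarray | float) -> np.ndarray | float:
    """Angular frequency (rad/s) -> wavenumber (cm^-1)."""
    return omega / (2.0 * np.pi * C_SI * 100.0)


def wavenumber_to_omega_si(nu_cm: np.ndarray | float) -> np.ndarray | float:
    """Wavenumber (cm^-1) -> angular frequency (rad/s)."""
    return nu_cm * 2.0 * np.pi * C_SI * 100.0
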
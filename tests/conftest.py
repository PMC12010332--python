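"""Shared fixtures and independently coded oracles.

The oracles below deliberately avoid the package's units module and
constants: they hand-type the CODATA values and evaluate the closed forms
along a different code path (log-determinants instead of per-mode sums,
thermal wavelengths instead of partition-function prefactors), so agreement
with the implementation is a genuine cross-check rather than a tautology.
"""

import math

import numpy as np
import pytest
from hypothesis import settings

from linkerthermo.trajectory import Topology, TrajectoryFrames

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")

# hand-typed CODATA constants (SI)
KB = 1.380649e-23
HBAR = 1.0545718176461565e-34
H = 6.62607015e-34
NA = 6.02214076e23
AMU = 1.66053906892e-27


def oracle_schlitter_minus_ts(cov_mw_amu_nm2, temperature):
    """-T*S' (kJ/mol) via log-determinant of the full matrix in SI."""
    c_si = np.asarray(cov_mw_amu_nm2, float) * AMU * 1e-18
    arg = np.eye(c_si.shape[0]) + (KB * temperature * math.e ** 2 / HBAR ** 2) * c_si
    sign, logdet = np.linalg.slogdet(arg)
    assert sign > 0
    s = 0.5 * KB * logdet * NA / 1000.0  # kJ/(mol K)
    return -temperature * s


def oracle_sackur_tetrode(mass_amu, temperature, pressure_pa=1.0e5):
    """Molar translational entropy (kJ/(mol K)) via the thermal wavelength."""
    m = mass_amu * AMU
    lam = H / math.sqrt(2.0 * math.pi * m * KB * temperature)
    v_per_particle = KB * temperature / pressure_pa
    s = KB * (math.log(v_per_particle / lam ** 3) + 2.5)
    return s * NA / 1000.0


def oracle_ho_entropy(omega_si, temperature):
    """Quantum harmonic-oscillator molar entropy (kJ/(mol K)), one mode."""
    x = HBAR * omega_si / (KB * temperature)
    s = KB * (x / (math.exp(x) - 1.0) - math.log(1.0 - math.exp(-x)))
    return s * NA / 1000.0


def oracle_hessian_eig_to_omega_si(eig_kj_mol_nm2_amu):
    """Convert a mass-weighted Hessian eigenvalue to omega (rad/s)."""
    return math.sqrt(eig_kj_mol_nm2_amu * (1000.0 / NA) / (AMU * 1e-18))


def rotation_matrix(axis, angle):
    """Rodrigues rotation matrix (right-multiplication convention)."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * K @ K


@pytest.fixture
def capped_topology():
    """A tiny capped-peptide-like topology: cap / 2 linker residues / cap."""
    names = ["C1", "N", "CA", "C", "N", "CA", "C", "C2"]
    resids = np.array([0, 1, 1, 1, 2, 2, 2, 3])
    resnames = ["ACE", "GLY", "GLY", "GLY", "SER", "SER", "SER", "NME"]
    masses = np.array([12.011, 14.007, 12.011, 12.011, 14.007, 12.011,
                       12.011, 12.011])
    groups = ["cap_N", "linker", "linker", "linker", "linker", "linker",
              "linker", "cap_C"]
    return Topology(names=names, residue_indices=resids, residue_names=resnames,
                    masses=masses, groups=groups)


@pytest.fixture
def small_trajectory(capped_topology):
    """A 12-frame jittered trajectory of the capped fixture."""
    rng = np.random.default_rng(42)
    base = rng.uniform(0.0, 1.0, size=(8, 3))
    coords = base[None] + 0.01 * rng.standard_normal((12, 8, 3))
    return TrajectoryFrames(coordinates=coords,
                            times=np.arange(12, dtype=float),
                            topology=capped_topology)
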
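"""Normal-mode analysis and rigid-rotor harmonic-oscillator thermochemistry.

A dense Hessian at a potential-energy minimum is mass-weighted and
diagonalized; the six (three for a point, five for a linear geometry)
rigid-body modes are identified and removed, and the remaining frequencies
feed the RRHO partition functions:

* vibrational: quantum harmonic oscillator per mode,
  S_i = k_B [ x/(e^x - 1) - ln(1 - e^-x) ],  x = beta hbar omega_i,
  ZPVE = sum_i hbar omega_i / 2;
* rotational: rigid rotor from the principal moments of inertia (symmetry
  number 1, the convention for peptides), with the linear-rotor formula when
  the smallest moment vanishes;
* translational: Sackur-Tetrode for an ideal gas at 1 bar.

Entropies are reported as -T*S in kJ/mol so they add directly onto the
free-energy ledger; ZPVE is kJ/mol.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import units
from .errors import NotAMinimumError, SaddlePointError, StructuralError, TrajectoryFormatError
from .trajectory import Topology

__all__ = [
    "HessianModel",
    "NormalModes",
    "NormalModeResult",
    "mass_weight_and_diagonalize",
    "rrho_thermochemistry",
    "finite_difference_hessian",
    "read_hessian",
    "write_hessian",
    "vibrational_entropy",
    "zero_point_energy",
    "translational_entropy",
    "rotational_entropy",
]

# Modes with |wavenumber| below this are near-zero (rigid-body candidates);
# anything more negative than -ZERO_WAVENUMBER_CM is an imaginary mode.
ZERO_WAVENUMBER_CM = 1.0


@dataclass
class HessianModel:
    """Dense 3N x 3N second-derivative matrix (kJ/mol/nm^2) at a reference
    geometry, with the topology providing the masses for mass-weighting."""

    matrix: np.ndarray
    reference_coordinates: np.ndarray
    topology: Topology

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)
        self.reference_coordinates = np.asarray(self.reference_coordinates, float)
        n = self.topology.n_atoms
        if self.matrix.shape != (3 * n, 3 * n):
            raise StructuralError(
                f"Hessian shape {self.matrix.shape} inconsistent with {n} atoms")
        if self.reference_coordinates.shape != (n, 3):
            raise StructuralError("reference coordinates must be (N, 3)")
        scale = max(np.abs(self.matrix).max(), 1e-300)
        if np.abs(self.matrix - self.matrix.T).max() > 1e-8 * scale:
            raise StructuralError("Hessian is not symmetric")
        self.matrix = 0.5 * (self.matrix + self.matrix.T)


@dataclass
class NormalModes:
    """Retained vibrational modes of a mass-weighted Hessian.

    ``frequencies_cm`` ascending, rigid modes removed; ``eigenvectors`` are
    the corresponding columns in mass-weighted coordinates; ``rigid_overlap``
    is, for each removed mode, its squared projection onto the exact
    translation/rotation generator subspace (1 = purely rigid).
    """

    frequencies_cm: np.ndarray
    eigenvectors: np.ndarray
    n_rigid_removed: int
    rigid_overlap: np.ndarray


def mass_weight_and_diagonalize(h: HessianModel) -> NormalModes:
    """Eigen-decompose M^{-1/2} H M^{-1/2} and strip rigid-body modes.

    Near-zero modes (|wavenumber| < 1 cm^-1) are identified and checked by
    projection onto translation/rotation generators at the reference
    geometry; more than six of them, or any strongly negative eigenvalue,
    raises :class:`SaddlePointError` reporting the imaginary count.
    """
    from .schlitter import rigid_body_generators

    masses = h.topology.masses
    inv_sqrt = 1.0 / np.sqrt(np.repeat(masses, 3))
    hm = h.matrix * np.outer(inv_sqrt, inv_sqrt)
    lam, vecs = np.linalg.eigh(hm)  # kJ/mol/nm^2/amu, ascending
    omega2 = lam * units.HESSIAN_EIG_TO_OMEGA2_SI
    nu = np.sign(omega2) * units.omega_si_to_wavenumber(np.sqrt(np.abs(omega2)))
    imaginary = nu < -ZERO_WAVENUMBER_CM
    n_imag = int(imaginary.sum())
    if n_imag:
        raise SaddlePointError(
            f"{n_imag} imaginary mode(s) (most negative {nu.min():.1f} cm^-1): "
            "not a minimum", n_imaginary=n_imag)
    near_zero = np.abs(nu) < ZERO_WAVENUMBER_CM
    n_zero = int(near_zero.sum())
    if n_zero > 6:
        raise SaddlePointError(
            f"{n_zero} near-zero modes (> 6): degenerate or ill-conditioned "
            "Hessian", n_imaginary=0)
    gens = rigid_body_generators(masses, h.reference_coordinates)
    overlap = np.array([float(((gens @ vecs[:, i]) ** 2).sum())
                        for i in np.nonzero(near_zero)[0]])
    if overlap.size and overlap.min() < 0.5:
        warnings.warn(
            "a near-zero mode has < 50% rigid-body character; the Hessian may "
            "contain an unphysical soft mode", stacklevel=2)
    keep = ~near_zero
    if not keep.any():
        raise SaddlePointError("no positive vibrational modes: degenerate Hessian",
                               n_imaginary=0)
    return NormalModes(frequencies_cm=nu[keep], eigenvectors=vecs[:, keep],
                       n_rigid_removed=n_zero, rigid_overlap=overlap)


@dataclass
class NormalModeResult:
    """RRHO thermochemistry summary (kJ/mol, -TS convention)."""

    frequencies: np.ndarray
    zpve: float
    minus_TS_vib: float
    minus_TS_rot: float
    minus_TS_trans: float
    minus_TS_total_rrho: float
    temperature: float
    n_imaginary: int = 0

    def __post_init__(self):
        total = self.minus_TS_vib + self.minus_TS_rot + self.minus_TS_trans
        if not math.isclose(self.minus_TS_total_rrho, total, rel_tol=0, abs_tol=1e-12):
            raise StructuralError("RRHO total must equal the sum of its components")
        if self.zpve < 0:
            raise StructuralError("ZPVE cannot be negative")
        if np.any(np.asarray(self.frequencies) <= 0):
            raise StructuralError("retained frequencies must be positive")

    def as_dict(self) -> dict:
        return {
            "zpve_kJ_mol": self.zpve,
            "minus_TS_vib_kJ_mol": self.minus_TS_vib,
            "minus_TS_rot_kJ_mol": self.minus_TS_rot,
            "minus_TS_trans_kJ_mol": self.minus_TS_trans,
            "minus_TS_total_rrho_kJ_mol": self.minus_TS_total_rrho,
            "temperature_K": self.temperature,
            "n_modes": int(np.asarray(self.frequencies).size),
            "n_imaginary": self.n_imaginary,
        }


# ---------------------------------------------------------------------------
# partition-function pieces (molar entropies in kJ/(mol K))
# ---------------------------------------------------------------------------

def zero_point_energy(frequencies_cm: np.ndarray) -> float:
    """ZPVE = sum hbar omega / 2, in kJ/mol."""
    omega = units.wavenumber_to_omega_si(np.asarray(frequencies_cm, float))
    return float((units.HBAR_SI * omega / 2.0).sum() * units.N_A / 1000.0)


def vibrational_entropy(frequencies_cm: np.ndarray, temperature: float) -> float:
    """Quantum harmonic-oscillator entropy summed over modes, kJ/(mol K)."""
    omega = units.wavenumber_to_omega_si(np.asarray(frequencies_cm, float))
    x = units.HBAR_SI * omega / (units.KB_SI * temperature)
    s = x / np.expm1(x) - np.log(-np.expm1(-x))
    return float(s.sum() * units.KB_KJ_PER_MOL_K)


def translational_entropy(total_mass_amu: float, temperature: float,
                          pressure_pa: float = units.P_STANDARD_PA) -> float:
    """Sackur-Tetrode entropy of an ideal gas, kJ/(mol K)."""
    m = total_mass_amu * units.AMU_KG
    kt = units.KB_SI * temperature
    q = (2.0 * math.pi * m * kt / units.H_SI ** 2) ** 1.5 * kt / pressure_pa
    return units.KB_KJ_PER_MOL_K * (math.log(q) + 2.5)


def principal_moments(masses: np.ndarray, coordinates: np.ndarray) -> np.ndarray:
    """Principal moments of inertia (amu nm^2), ascending."""
    coordinates = np.asarray(coordinates, float).reshape(-1, 3)
    com = (masses[:, None] * coordinates).sum(axis=0) / masses.sum()
    r = coordinates - com
    r2 = (r ** 2).sum(axis=1)
    inertia = np.einsum("i,ab->ab", masses * r2, np.eye(3)) \
        - np.einsum("i,ia,ib->ab", masses, r, r)
    return np.linalg.eigvalsh(inertia)


def rotational_entropy(masses: np.ndarray, coordinates: np.ndarray,
                       temperature: float, symmetry_number: int = 1,
                       linear_tol: float = 1e-6) -> float:
    """Rigid-rotor entropy, kJ/(mol K).

    Switches to the linear-rotor formula (with a notice) when the smallest
    principal moment is below ``linear_tol`` relative to the largest; returns
    0 for a single atom.
    """
    if masses.size == 1:
        return 0.0
    I = principal_moments(masses, coordinates) * units.AMU_NM2_TO_KG_M2
    kt = units.KB_SI * temperature
    if I[-1] <= 0:
        return 0.0
    if I[0] < linear_tol * I[-1]:
        warnings.warn("near-linear geometry: using the linear-rotor formula",
                      stacklevel=2)
        q = 8.0 * math.pi ** 2 * I[-1] * kt / (units.H_SI ** 2 * symmetry_number)
        return units.KB_KJ_PER_MOL_K * (math.log(q) + 1.0)
    q = (math.sqrt(math.pi) / symmetry_number
         * (8.0 * math.pi ** 2 * kt / units.H_SI ** 2) ** 1.5
         * math.sqrt(I[0] * I[1] * I[2]))
    return units.KB_KJ_PER_MOL_K * (math.log(q) + 1.5)


def rrho_thermochemistry(modes, topology: Topology,
                         reference_coordinates: np.ndarray,
                         temperature: float = 300.0,
                         pressure_pa: float = units.P_STANDARD_PA,
                         symmetry_number: int = 1) -> NormalModeResult:
    """Assemble ZPVE and -TS terms from retained mode frequencies.

    ``modes`` may be a :class:`NormalModes` or a plain array of positive
    wavenumbers (cm^-1).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    freqs = modes.frequencies_cm if isinstance(modes, NormalModes) else np.asarray(modes, float)
    if np.any(freqs <= 0):
        raise ValueError("all retained frequencies must be positive")
    t = temperature
    mts_vib = -t * vibrational_entropy(freqs, t)
    mts_rot = -t * rotational_entropy(topology.masses, reference_coordinates, t,
                                      symmetry_number)
    mts_trans = -t * translational_entropy(topology.total_mass(), t, pressure_pa)
    return NormalModeResult(
        frequencies=np.sort(freqs), zpve=zero_point_energy(freqs),
        minus_TS_vib=mts_vib, minus_TS_rot=mts_rot, minus_TS_trans=mts_trans,
        minus_TS_total_rrho=mts_vib + mts_rot + mts_trans, temperature=t)


# ---------------------------------------------------------------------------
# finite-difference Hessian (for engine-free testing of potentials)
# ---------------------------------------------------------------------------

def finite_difference_hessian(potential, coordinates: np.ndarray,
                              topology: Topology, step: float = 1e-4,
                              gradient_tol: float = 1e-3) -> HessianModel:
    """Central-difference Hessian of ``potential`` (a callable mapping (N, 3)
    nm -> kJ/mol) at ``coordinates``, symmetrized as (H + H^T)/2.

    The point must be a minimum: a central-difference gradient component
    exceeding ``gradient_tol`` (kJ/mol/nm) raises :class:`NotAMinimumError`.
    """
    x0 = np.asarray(coordinates, float).copy()
    n3 = x0.size
    flat = x0.ravel()

    def energy(v):
        return float(potential(v.reshape(x0.shape)))

    grad = np.empty(n3)
    for i in range(n3):
        vp, vm = flat.copy(), flat.copy()
        vp[i] += step
        vm[i] -= step
        grad[i] = (energy(vp) - energy(vm)) / (2 * step)
    gmax = np.abs(grad).max()
    if gmax > gradient_tol:
        raise NotAMinimumError(
            f"max gradient component {gmax:.3g} kJ/mol/nm exceeds tolerance "
            f"{gradient_tol:g}: not at a minimum")
    H = np.empty((n3, n3))
    e0 = energy(flat)
    for i in range(n3):
        vp, vm = flat.copy(), flat.copy()
        vp[i] += step
        vm[i] -= step
        H[i, i] = (energy(vp) - 2 * e0 + energy(vm)) / step ** 2
        for j in range(i + 1, n3):
            vpp, vpm, vmp, vmm = flat.copy(), flat.copy(), flat.copy(), flat.copy()
            vpp[[i, j]] += step
            vmm[[i, j]] -= step
            vpm[i] += step
            vpm[j] -= step
            vmp[i] -= step
            vmp[j] += step
            H[i, j] = H[j, i] = (energy(vpp) - energy(vpm) - energy(vmp)
                                 + energy(vmm)) / (4 * step ** 2)
    H = 0.5 * (H + H.T)
    return HessianModel(matrix=H, reference_coordinates=x0, topology=topology)


# ---------------------------------------------------------------------------
# dense-text Hessian I/O
# ---------------------------------------------------------------------------

def write_hessian(h: HessianModel, path) -> None:
    """Write the dense-text dialect: ``natoms N`` header then 3N x 3N rows."""
    n = h.topology.n_atoms
    with open(path, "w") as fh:
        fh.write(f"natoms {n}\n")
        for row in h.matrix:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_hessian(path, topology: Topology,
                 reference_coordinates: np.ndarray) -> HessianModel:
    """Read the dense-text dialect written by :func:`write_hessian`."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2 or header[0] != "natoms":
            raise TrajectoryFormatError(f"{path}: expected 'natoms N' header")
        try:
            n = int(header[1])
        except ValueError as exc:
            raise TrajectoryFormatError(f"{path}: bad atom count {header[1]!r}") from exc
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            vals = line.split()
            if len(vals) != 3 * n:
                raise TrajectoryFormatError(
                    f"{path}: row {lineno} has {len(vals)} columns, expected {3 * n}")
            rows.append([float(v) for v in vals])
    if len(rows) != 3 * n:
        raise TrajectoryFormatError(
            f"{path}: found {len(rows)} rows, expected {3 * n}")
    return HessianModel(matrix=np.array(rows), reference_coordinates=reference_coordinates,
                        topology=topology)
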
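"""Schlitter upper-bound configurational entropy from positional fluctuations.

The estimator builds the mass-weighted covariance matrix of atomic positions
C = M^{1/2} <dx dx^T> M^{1/2} over a (superposed) trajectory and evaluates

    S' = (k_B / 2) * ln det[ 1 + (k_B T e^2 / hbar^2) C ]

with e Euler's number.  S' is an upper bound to the absolute entropy of the
sampled ensemble; for a harmonic mode it reduces to the classical oscillator
entropy in the high-temperature limit.  Rigid-body (translation/rotation)
content is excluded before the determinant, mirroring the usual practice of
discarding the first six eigenvectors; the default policy projects out exact
translation/rotation generators, which is equivalent when the fit removed
rigid motion and more robust when it did not.

Reported quantities are -T*S' in kJ/mol at the stated temperature, so entropy
appears on the free-energy scale used throughout the package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import units
from .errors import NumericalError, StructuralError
from .trajectory import TrajectoryFrames

__all__ = [
    "CovarianceModel",
    "EntropyReport",
    "ReplicateSummary",
    "build_covariance",
    "schlitter_entropy",
    "entropy_from_eigenvalues",
    "split_conformational",
    "replicate_summary",
    "rigid_body_generators",
]

# Mass-weighted covariance eigenvalues below this (amu nm^2) are treated as
# null modes and contribute ln 1 = 0 instead of erroring (short trajectories
# are rank-deficient by construction).
EIGENVALUE_FLOOR = 1e-14


@dataclass
class CovarianceModel:
    """Mass-weighted positional covariance C_ij = sqrt(m_i m_j) <dx_i dx_j>.

    ``matrix`` is 3N x 3N in amu nm^2; ``mean_coordinates`` (N, 3) is the
    time-mean structure the deviations were taken from, needed to build
    rotation generators for rigid-mode removal.
    """

    matrix: np.ndarray
    masses: np.ndarray
    mean_coordinates: np.ndarray
    n_frames_used: int
    temperature: float | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)
        self.masses = np.asarray(self.masses, float)
        self.mean_coordinates = np.asarray(self.mean_coordinates, float)
        n3 = self.matrix.shape[0]
        if self.matrix.shape != (n3, n3) or n3 != 3 * self.n_atoms:
            raise StructuralError("covariance must be 3N x 3N")
        scale = max(np.abs(self.matrix).max(), 1e-300)
        if np.abs(self.matrix - self.matrix.T).max() > 1e-10 * scale:
            raise NumericalError("covariance matrix is not symmetric")
        self.matrix = 0.5 * (self.matrix + self.matrix.T)

    @property
    def n_atoms(self) -> int:
        return self.masses.size

    def eigenvalues(self) -> np.ndarray:
        """Ascending eigenvalues (amu nm^2); strongly negative ones error."""
        lam = np.linalg.eigvalsh(self.matrix)
        floor = -1e-12 * max(lam.max(), 1.0)
        if lam.min() < floor:
            raise NumericalError(
                f"covariance eigenvalue {lam.min():.3e} below numerical floor")
        return lam


@dataclass
class EntropyReport:
    """-TS components (kJ/mol) at a stated temperature.

    ``minus_TS_schlitter`` is always <= 0 (S' >= 0 for any ensemble); the
    conformational term is defined as Schlitter minus vibrational and may
    take either sign.
    """

    minus_TS_schlitter: float
    temperature: float
    modes_removed: int = 0
    minus_TS_vibrational: float | None = None
    minus_TS_conformational: float | None = None
    provenance: str = ""

    def __post_init__(self):
        if self.minus_TS_schlitter > 1e-9:
            raise NumericalError("-T*S' must be non-positive (S' is an upper bound >= 0)")
        if (self.minus_TS_vibrational is not None
                and self.minus_TS_conformational is not None):
            expect = self.minus_TS_schlitter - self.minus_TS_vibrational
            if not math.isclose(self.minus_TS_conformational, expect,
                                rel_tol=0, abs_tol=1e-9):
                raise NumericalError("conformational term must equal Schlitter - vibrational")

    def as_dict(self) -> dict:
        return {
            "minus_TS_schlitter_kJ_mol": self.minus_TS_schlitter,
            "minus_TS_vibrational_kJ_mol": self.minus_TS_vibrational,
            "minus_TS_conformational_kJ_mol": self.minus_TS_conformational,
            "temperature_K": self.temperature,
            "modes_removed": self.modes_removed,
            "provenance": self.provenance,
        }


@dataclass
class ReplicateSummary:
    """Per-field mean and sample standard deviation over replica reports."""

    mean: EntropyReport
    sd: dict = field(default_factory=dict)
    n: int = 1


# ---------------------------------------------------------------------------
# covariance construction
# ---------------------------------------------------------------------------

def build_covariance(traj: TrajectoryFrames, selection: np.ndarray | None = None,
                     start_time_ps: float = 5000.0, stride: int = 1,
                     check_drift: bool = True,
                     drift_tol_nm: float = 0.1) -> CovarianceModel:
    """Mass-weighted covariance of atomic positions over time.

    Frames before ``start_time_ps`` (default 5 ns, the usual equilibration
    discard) are dropped, then every ``stride``-th frame is used.  Deviations
    are taken from the time-mean structure.  The trajectory is expected to be
    superposed already; a drift of the mass-weighted centroid between the two
    halves of the series beyond ``drift_tol_nm`` raises, since residual
    rigid-body motion would inflate the entropy.
    """
    if selection is None:
        selection = traj.topology.atom_ids()
    selection = np.asarray(selection, int)
    keep = traj.times >= start_time_ps
    X = traj.coordinates[keep][::stride][:, selection, :]
    n_frames = X.shape[0]
    if n_frames < 2:
        raise StructuralError(
            f"need >= 2 frames after start/stride filtering, got {n_frames}")
    masses = traj.topology.masses[selection]
    if check_drift and n_frames >= 4:
        com = (X * masses[None, :, None]).sum(axis=1) / masses.sum()
        drift = np.linalg.norm(com[: n_frames // 2].mean(axis=0)
                               - com[n_frames // 2:].mean(axis=0))
        if drift > drift_tol_nm:
            raise NumericalError(
                f"net centroid drift {drift:.3g} nm suggests an unsuperposed "
                "trajectory; fit frames before building the covariance")
    n = selection.size
    if n_frames < 3 * n:
        warnings.warn(
            f"{n_frames} frames for {3 * n} coordinates: covariance is "
            "rank-deficient; null modes contribute zero entropy", stacklevel=2)
    flat = X.reshape(n_frames, 3 * n)
    dx = flat - flat.mean(axis=0)
    cov = dx.T @ dx / n_frames
    w = np.sqrt(np.repeat(masses, 3))
    cov *= np.outer(w, w)
    return CovarianceModel(matrix=cov, masses=masses,
                           mean_coordinates=flat.mean(axis=0).reshape(n, 3),
                           n_frames_used=n_frames)


# ---------------------------------------------------------------------------
# rigid-body generators and the entropy formula
# ---------------------------------------------------------------------------

def rigid_body_generators(masses: np.ndarray, coordinates: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted translation/rotation generators.

    Returns an (m, 3N) array, m <= 6 (5 for linear geometries, 3 for a single
    point): three translations sqrt(m_i) e_a and up to three rotations
    sqrt(m_i) e_a x (r_i - r_cm), orthonormalized; directions of negligible
    norm are dropped.
    """
    masses = np.asarray(masses, float)
    coordinates = np.asarray(coordinates, float).reshape(-1, 3)
    n = masses.size
    sq = np.sqrt(masses)
    com = (masses[:, None] * coordinates).sum(axis=0) / masses.sum()
    rel = coordinates - com
    gens = []
    for a in range(3):
        g = np.zeros((n, 3))
        g[:, a] = sq
        gens.append(g.ravel())
    for a in range(3):
        axis = np.zeros(3)
        axis[a] = 1.0
        g = sq[:, None] * np.cross(np.broadcast_to(axis, rel.shape), rel)
        gens.append(g.ravel())
    G = np.array(gens)
    # Gram-Schmidt with drop of degenerate directions
    ortho: list[np.ndarray] = []
    ref_norm = np.linalg.norm(G[0])
    for g in G:
        for o in ortho:
            g = g - (g @ o) * o
        nrm = np.linalg.norm(g)
        if nrm > 1e-10 * ref_norm:
            ortho.append(g / nrm)
    return np.array(ortho)


def entropy_from_eigenvalues(eigenvalues: np.ndarray, temperature: float) -> float:
    """S' in kJ/(mol K) from mass-weighted covariance eigenvalues (amu nm^2).

    Per-mode contribution (k_B/2) ln(1 + k_B T e^2 lambda / hbar^2) with all
    bookkeeping for the logarithm's argument done in SI; eigenvalues below
    the rank floor contribute zero.
    """
    lam = np.asarray(eigenvalues, float)
    lam = np.where(lam < EIGENVALUE_FLOOR, 0.0, lam)
    alpha = (units.KB_SI * temperature * math.e ** 2 / units.HBAR_SI ** 2
             * units.AMU_NM2_TO_KG_M2)
    s_per_molecule = 0.5 * units.KB_SI * np.log1p(alpha * lam).sum()  # J/K
    return s_per_molecule * units.N_A / 1000.0  # kJ/(mol K)


def schlitter_entropy(cov: CovarianceModel, temperature: float = 300.0,
                      remove_rigid_modes: int = 6,
                      policy: str = "project") -> EntropyReport:
    """Evaluate -T*S' (kJ/mol) for a covariance model.

    ``policy='project'`` (default) projects exact translation/rotation
    generators out of the covariance before diagonalization, removing at most
    ``remove_rigid_modes`` rigid directions.  ``policy='largest'`` reproduces
    the naive recipe of simply discarding the ``remove_rigid_modes`` largest
    eigenvalues.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    n3 = cov.matrix.shape[0]
    if remove_rigid_modes < 0 or remove_rigid_modes > n3:
        raise ValueError(f"remove_rigid_modes must be in [0, {n3}]")
    removed = 0
    if remove_rigid_modes == 0:
        lam = cov.eigenvalues()
    elif policy == "project":
        gens = rigid_body_generators(cov.masses, cov.mean_coordinates)
        gens = gens[:remove_rigid_modes]
        P = np.eye(n3) - gens.T @ gens
        projected = CovarianceModel(matrix=P @ cov.matrix @ P, masses=cov.masses,
                                    mean_coordinates=cov.mean_coordinates,
                                    n_frames_used=cov.n_frames_used)
        lam = projected.eigenvalues()
        removed = gens.shape[0]
    elif policy == "largest":
        lam = cov.eigenvalues()[:-remove_rigid_modes] if remove_rigid_modes else cov.eigenvalues()
        removed = remove_rigid_modes
    else:
        raise ValueError(f"unknown rigid-mode policy {policy!r}")
    s = entropy_from_eigenvalues(lam, temperature)
    return EntropyReport(minus_TS_schlitter=-temperature * s,
                         temperature=temperature, modes_removed=removed,
                         provenance=f"schlitter policy={policy} "
                                    f"n_frames={cov.n_frames_used}")


def split_conformational(minus_TS_schlitter: float, minus_TS_vibrational: float,
                         temperature: float = 300.0) -> EntropyReport:
    """Conformational term as Schlitter minus vibrational (-TS, kJ/mol).

    The Schlitter bound with rigid modes removed contains vibrational plus
    conformational entropy; subtracting an RRHO vibrational term leaves an
    upper-bound approximation to the conformational entropy.  No sign
    constraint is imposed: the difference can be positive.
    """
    if not (math.isfinite(minus_TS_schlitter) and math.isfinite(minus_TS_vibrational)):
        raise ValueError("entropy components must be finite")
    return EntropyReport(
        minus_TS_schlitter=minus_TS_schlitter,
        minus_TS_vibrational=minus_TS_vibrational,
        minus_TS_conformational=minus_TS_schlitter - minus_TS_vibrational,
        temperature=temperature, provenance="conformational split")


def replicate_summary(reports: list[EntropyReport]) -> ReplicateSummary:
    """Mean and sample standard deviation (n-1 denominator) over replicas."""
    if not reports:
        raise ValueError("need at least one report")
    temps = {r.temperature for r in reports}
    if len(temps) > 1:
        raise ValueError(f"mixed temperatures in replicas: {sorted(temps)}")
    n = len(reports)

    def _stat(values):
        vals = [v for v in values if v is not None]
        if len(vals) != len(values) or not vals:
            return None, None
        arr = np.asarray(vals, float)
        return float(arr.mean()), float(arr.std(ddof=1)) if n > 1 else 0.0

    m_s, s_s = _stat([r.minus_TS_schlitter for r in reports])
    m_v, s_v = _stat([r.minus_TS_vibrational for r in reports])
    m_c, s_c = _stat([r.minus_TS_conformational for r in reports])
    mean = EntropyReport(minus_TS_schlitter=m_s, temperature=reports[0].temperature,
                         modes_removed=reports[0].modes_removed,
                         minus_TS_vibrational=m_v, minus_TS_conformational=m_c,
                         provenance=f"mean of {n} replicas")
    sd = {"minus_TS_schlitter": s_s, "minus_TS_vibrational": s_v,
          "minus_TS_conformational": s_c}
    return ReplicateSummary(mean=mean, sd=sd, n=n)
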
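"""Synthetic inputs with closed-form ground truth for every pipeline stage.

Each generator stands in, at desk scale, for data that would otherwise come
from microsecond MD: multivariate-Gaussian atomic fluctuations with a chosen
covariance (Schlitter), Boltzmann-sampled harmonic chains with an assembled
Hessian (normal modes and the classical-limit cross-check), freely rotating
chains (persistence length), overdamped Langevin traces in known potentials
(PMF and autocorrelation), and exact harmonic alchemical datasets (MBAR/TI).
Every generator is deterministic under a fixed seed and attaches a ``truth``
dict of closed-form reference values; outputs use the same containers as
real data so downstream analyses cannot special-case synthetic input.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np

from . import units
from .errors import NumericalError, StructuralError
from .alchemy import AlchemicalDataset
from .metrics import CVSeries
from .nma import HessianModel
from .schlitter import entropy_from_eigenvalues
from .trajectory import Topology, TrajectoryFrames

__all__ = [
    "GaussianEnsemble",
    "HarmonicChain",
    "FRCChains",
    "LangevinTrace",
    "HarmonicAlchemy",
    "gaussian_ensemble",
    "harmonic_chain",
    "frc_chain",
    "langevin_cv",
    "harmonic_alchemy",
]


def _generic_topology(n_atoms: int, masses) -> Topology:
    """Generic single-residue topology; beads are written as carbons so a
    file round-trip can re-infer a mass."""
    masses = np.broadcast_to(np.asarray(masses, float), (n_atoms,)).copy()
    return Topology(names=["C"] * n_atoms,
                    residue_indices=np.zeros(n_atoms, int),
                    residue_names=["SYN"] * n_atoms,
                    masses=masses, groups=["linker"] * n_atoms)


class GaussianEnsemble(NamedTuple):
    frames: TrajectoryFrames
    truth: dict


def gaussian_ensemble(covariance: np.ndarray, masses, n_frames: int, seed: int,
                      reference: np.ndarray | None = None,
                      temperature: float = 300.0,
                      dt_ps: float = 1.0) -> GaussianEnsemble:
    """Frames drawn iid from N(reference, covariance) in plain coordinates.

    ``covariance`` is 3N x 3N in nm^2 (positive semidefinite).  The truth
    entry ``minus_TS_schlitter`` is the closed-form Schlitter value of the
    mass-weighted target covariance with no mode removal (the ensemble has
    no rigid-body motion beyond what the covariance encodes).
    """
    cov = np.asarray(covariance, float)
    n3 = cov.shape[0]
    if cov.shape != (n3, n3) or n3 % 3:
        raise StructuralError("covariance must be 3N x 3N")
    n = n3 // 3
    masses = np.broadcast_to(np.asarray(masses, float), (n,)).copy()
    lam, vecs = np.linalg.eigh(0.5 * (cov + cov.T))
    if lam.min() < -1e-10 * max(lam.max(), 1.0):
        raise NumericalError(f"covariance not PSD (min eigenvalue {lam.min():.3e})")
    lam = np.clip(lam, 0.0, None)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_frames, n3))
    dx = z * np.sqrt(lam) @ vecs.T
    ref = np.zeros((n, 3)) if reference is None else np.asarray(reference, float)
    coords = ref.reshape(1, n, 3) + dx.reshape(n_frames, n, 3)
    topo = _generic_topology(n, masses)
    frames = TrajectoryFrames(coordinates=coords,
                              times=np.arange(n_frames, dtype=float) * dt_ps,
                              topology=topo)
    w = np.sqrt(np.repeat(masses, 3))
    mw_eigs = np.linalg.eigvalsh(cov * np.outer(w, w))
    s = entropy_from_eigenvalues(np.clip(mw_eigs, 0.0, None), temperature)
    truth = {"minus_TS_schlitter": -temperature * s,
             "temperature": temperature,
             "mw_eigenvalues_amu_nm2": mw_eigs}
    return GaussianEnsemble(frames=frames, truth=truth)


class HarmonicChain(NamedTuple):
    hessian: HessianModel
    frames: TrajectoryFrames
    truth: dict


def harmonic_chain(n_beads: int, force_constant: float, mass: float,
                   temperature: float, n_frames: int, seed: int,
                   bond_length: float = 0.38) -> HarmonicChain:
    """Nearest-neighbor harmonic chain with exact Boltzmann normal-mode
    sampling.

    The potential is (k/2) sum_i |d_i - d_i^0|^2 over bond vectors, giving a
    block-tridiagonal Hessian with three translational null modes (bond-
    vector springs are not rotation-invariant, so there are no rotational
    null modes).  Sampling places independent Gaussian amplitudes of
    variance k_B T / omega_j^2 on each finite mode; null modes get zero
    variance.  Truth includes the analytic 1D chain frequencies
    omega_j^2 = (2k/m)(1 - cos(j pi / n)), each threefold degenerate, and
    the classical and quantum vibrational entropies of the spectrum.
    """
    if n_beads < 2:
        raise StructuralError("need at least 2 beads")
    n = n_beads
    k = float(force_constant)
    topo = _generic_topology(n, mass)
    ref = np.zeros((n, 3))
    ref[:, 0] = bond_length * np.arange(n)
    H = np.zeros((3 * n, 3 * n))
    eye3 = np.eye(3)
    for i in range(n - 1):
        a, b = 3 * i, 3 * (i + 1)
        H[a:a + 3, a:a + 3] += k * eye3
        H[b:b + 3, b:b + 3] += k * eye3
        H[a:a + 3, b:b + 3] -= k * eye3
        H[b:b + 3, a:a + 3] -= k * eye3
    hess = HessianModel(matrix=H, reference_coordinates=ref, topology=topo)

    # mass-weighted spectrum (amu-consistent units): sample finite modes
    lam, vecs = np.linalg.eigh(H / mass)
    kbt = units.kbt_kj_per_mol(temperature)
    finite = lam > 1e-9 * lam.max()
    rng = np.random.default_rng(seed)
    amps = rng.standard_normal((n_frames, int(finite.sum())))
    q = amps * np.sqrt(kbt / lam[finite])          # sqrt(amu) nm
    dx_mw = q @ vecs[:, finite].T                  # mass-weighted displacements
    dx = dx_mw / math.sqrt(mass)
    coords = ref.reshape(1, n, 3) + dx.reshape(n_frames, n, 3)
    frames = TrajectoryFrames(coordinates=coords,
                              times=np.arange(n_frames, dtype=float),
                              topology=topo)

    j = np.arange(1, n)
    omega2_1d = (2.0 * k / mass) * (1.0 - np.cos(j * np.pi / n))
    omega2 = np.sort(np.repeat(omega2_1d, 3))      # threefold degenerate
    omega_si = np.sqrt(omega2 * units.HESSIAN_EIG_TO_OMEGA2_SI)
    freqs_cm = units.omega_si_to_wavenumber(omega_si)
    x = units.HBAR_SI * omega_si / (units.KB_SI * temperature)
    s_quantum = units.KB_KJ_PER_MOL_K * float((x / np.expm1(x)
                                               - np.log(-np.expm1(-x))).sum())
    s_classical = units.KB_KJ_PER_MOL_K * float((1.0 - np.log(x)).sum())
    truth = {
        "frequencies_cm": freqs_cm,
        "max_beta_hbar_omega": float(x.max()),
        "minus_TS_vib_quantum": -temperature * s_quantum,
        "minus_TS_vib_classical": -temperature * s_classical,
        "mode_variance_amu_nm2": kbt / lam[finite],
        "temperature": temperature,
    }
    return HarmonicChain(hessian=hess, frames=frames, truth=truth)


class FRCChains(NamedTuple):
    frames: TrajectoryFrames
    truth: dict


def frc_chain(n_bonds: int, bond_length: float, cos_theta: float,
              n_chains: int, seed: int) -> FRCChains:
    """Freely rotating chains: fixed bond angle, uniform azimuth.

    Each chain is one frame of an (n_bonds + 1)-bead molecule.  The bond
    correlation decays exactly as C(n) = cos^n(theta), so the persistence
    length truth is l_p = -l_b / ln(cos theta) for cos theta > 0; for
    cos theta <= 0 the chain has no directional memory and the truth is
    flagged undefined.
    """
    if not abs(cos_theta) < 1.0:
        raise StructuralError("|cos_theta| must be < 1")
    rng = np.random.default_rng(seed)
    sin_theta = math.sqrt(1.0 - cos_theta ** 2)
    u = rng.standard_normal((n_chains, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    bonds = np.empty((n_chains, n_bonds, 3))
    bonds[:, 0] = u
    for i in range(1, n_bonds):
        # orthonormal frame transverse to the current direction
        helper = np.zeros_like(u)
        smallest = np.argmin(np.abs(u), axis=1)
        helper[np.arange(n_chains), smallest] = 1.0
        e1 = np.cross(u, helper)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(u, e1)
        phi = rng.uniform(0.0, 2.0 * np.pi, n_chains)
        u = (cos_theta * u
             + sin_theta * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        bonds[:, i] = u
    coords = np.zeros((n_chains, n_bonds + 1, 3))
    coords[:, 1:] = np.cumsum(bond_length * bonds, axis=1)
    topo = _generic_topology(n_bonds + 1, 1.0)
    frames = TrajectoryFrames(coordinates=coords,
                              times=np.arange(n_chains, dtype=float),
                              topology=topo)
    if cos_theta > 0:
        truth = {"l_p": -bond_length / math.log(cos_theta), "defined": True}
    else:
        truth = {"l_p": None, "defined": False}
    truth["bond_length"] = bond_length
    truth["cos_theta"] = cos_theta
    return FRCChains(frames=frames, truth=truth)


class LangevinTrace(NamedTuple):
    cv: CVSeries
    truth: dict


def _potential_funcs(potential: str, parameters: dict):
    if potential == "harmonic":
        k = float(parameters["k"])
        x0 = float(parameters.get("x0", 0.0))
        return (lambda x: 0.5 * k * (x - x0) ** 2,
                lambda x: k * (x - x0), k)
    if potential == "double_well":
        h = float(parameters["barrier"])
        a = float(parameters["half_width"])
        return (lambda x: h * (x ** 2 / a ** 2 - 1.0) ** 2,
                lambda x: 4.0 * h * x * (x ** 2 - a ** 2) / a ** 4,
                8.0 * h / a ** 2)
    raise StructuralError(f"unknown potential {potential!r}")


def langevin_cv(potential: str, parameters: dict, n_steps: int, dt: float,
                friction: float, temperature: float, seed: int,
                n_walkers: int = 1, burn_in_fraction: float = 0.1,
                metropolis: bool = True) -> LangevinTrace:
    """Overdamped Langevin trace of a 1D coordinate in a known potential.

    Euler-Maruyama proposal x' = x - dt V'(x)/gamma + sqrt(2 k_B T dt/gamma)
    xi with gamma in kJ/mol ps/nm^2; by default a Metropolis accept/reject
    step (MALA) removes the time-discretization bias so the stationary
    density is exactly Boltzmann — set ``metropolis=False`` for the plain
    integrator.  ``n_steps`` is the total retained sample count, split over
    ``n_walkers`` independent walkers (for the double well the walkers start
    alternately in either minimum); the leading ``burn_in_fraction`` of each
    walker is discarded.  The truth is the Boltzmann density of the
    potential; for the harmonic case the variance k_B T / k and the OU decay
    rate k/gamma are attached.
    """
    vfun, grad, curv_max = _potential_funcs(potential, parameters)
    kbt = units.kbt_kj_per_mol(temperature)
    if dt * curv_max / friction > 0.25:
        raise NumericalError(
            f"unstable integration: dt * max|V''| / gamma = "
            f"{dt * curv_max / friction:.2f} > 0.25")
    rng = np.random.default_rng(seed)
    per_walker = int(math.ceil(n_steps / n_walkers))
    burn = int(burn_in_fraction * per_walker)
    total = per_walker + burn
    if potential == "double_well":
        a = float(parameters["half_width"])
        x = np.where(np.arange(n_walkers) % 2 == 0, a, -a).astype(float)
    else:
        x = np.zeros(n_walkers)
    diff = kbt * dt / friction          # D dt
    noise_scale = math.sqrt(2.0 * diff)
    out = np.empty((total, n_walkers))
    for t in range(total):
        drift = -dt * grad(x) / friction
        prop = x + drift + noise_scale * rng.standard_normal(n_walkers)
        if metropolis:
            drift_back = -dt * grad(prop) / friction
            log_q_fwd = -((prop - x - drift) ** 2) / (4.0 * diff)
            log_q_back = -((x - prop - drift_back) ** 2) / (4.0 * diff)
            log_alpha = (vfun(x) - vfun(prop)) / kbt + log_q_back - log_q_fwd
            accept = np.log(rng.random(n_walkers)) < log_alpha
            x = np.where(accept, prop, x)
        else:
            x = prop
        out[t] = x
    kept = out[burn:].T.reshape(-1)[:n_steps]
    cv = CVSeries(values=kept, times=np.arange(kept.size, dtype=float) * dt,
                  label=f"langevin_{potential}")
    truth: dict = {"potential": potential, "parameters": dict(parameters),
                   "kbt": kbt, "boltzmann_log_density": lambda xx: -vfun(xx) / kbt}
    if potential == "harmonic":
        truth["variance"] = kbt / parameters["k"]
        truth["acf_rate_per_ps"] = parameters["k"] / friction
    else:
        truth["barrier"] = float(parameters["barrier"])
        truth["minima"] = (-float(parameters["half_width"]),
                           float(parameters["half_width"]))
    return LangevinTrace(cv=cv, truth=truth)


class HarmonicAlchemy(NamedTuple):
    dataset: AlchemicalDataset
    truth: dict


def harmonic_alchemy(k_start: float, k_end: float, n_states: int,
                     samples_per_state: int, temperature: float,
                     seed: int) -> HarmonicAlchemy:
    """Exact Boltzmann samples from harmonic lambda-states.

    States interpolate the force constant geometrically,
    k(lambda) = k_start^(1-lambda) k_end^lambda, so <dH/dlambda> is constant
    and trapezoid TI is exact.  Both the reduced-potential matrix u_kn and
    per-sample dH/dlambda are emitted.  Truth:
    dA = (k_B T / 2) ln(k_end / k_start), independent of the path.
    """
    if k_start <= 0 or k_end <= 0:
        raise StructuralError("force constants must be positive")
    if n_states < 2:
        raise StructuralError("need at least 2 lambda states")
    lam = np.linspace(0.0, 1.0, n_states)
    ks = k_start ** (1.0 - lam) * k_end ** lam
    log_ratio = math.log(k_end / k_start)
    kbt = units.kbt_kj_per_mol(temperature)
    rng = np.random.default_rng(seed)
    xs = []
    origin = []
    for i, k in enumerate(ks):
        xs.append(rng.normal(0.0, math.sqrt(kbt / k), samples_per_state))
        origin.append(np.full(samples_per_state, i, dtype=int))
    x = np.concatenate(xs)
    origin = np.concatenate(origin)
    u = 0.5 * ks[None, :] * x[:, None] ** 2 / kbt
    dkdl = ks[origin] * log_ratio
    dhdl = 0.5 * dkdl * x ** 2
    dataset = AlchemicalDataset(lambda_states=lam, temperature=temperature,
                                reduced_potentials=u, origin_state=origin,
                                dhdl=dhdl)
    truth = {"delta_A": 0.5 * kbt * log_ratio, "kbt": kbt,
             "beta_delta_A": 0.5 * log_ratio}
    return HarmonicAlchemy(dataset=dataset, truth=truth)
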
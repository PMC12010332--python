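"""Alchemical free-energy estimators over lambda-states.

Two estimators of the free-energy difference between the endpoints of a
lambda path are provided and cross-checked:

* TI  - trapezoid integration of per-state <dH/dlambda> means, with
  autocorrelation-corrected standard errors;
* MBAR - the multistate Bennett acceptance ratio, solved self-consistently
  (with a quasi-Newton warm start) from the reduced-potential matrix u_kn,
  with the asymptotic covariance of the state free energies.

A solvation free energy follows from the standard thermodynamic cycle as
the difference of the solvent-leg and vacuum-leg decoupling free energies,
dA_solv = dA_1 - dA_2.  A Wang-Landau weight updater for expanded-ensemble
sampling is included together with a Metropolized-Gibbs toy sampler: the
converged weights reproduce the dimensionless state free energies, which is
how the schedule (initial increment 1.0, scaled by 0.7 at 20% histogram
flatness, converged below 0.001) is exercised at desk scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from . import units
from .errors import CapabilityError, ConvergenceError, StructuralError

__all__ = [
    "AlchemicalDataset",
    "FreeEnergyResult",
    "SoftCoreSpec",
    "WangLandauState",
    "ConsistencyReport",
    "ti_integrate",
    "mbar_solve",
    "solvation_cycle",
    "wang_landau_update",
    "wang_landau_toy",
    "consistency_check",
    "read_alchemical_dataset",
    "write_alchemical_dataset",
]


@dataclass
class SoftCoreSpec:
    """Beutler soft-core protocol metadata carried with datasets.

    No soft-core sampling happens in this package; the spec exists so that
    datasets produced elsewhere keep their protocol description attached.
    """

    sc_alpha: float = 0.5
    sd_power: int = 1
    sc_sigma: float = 0.3
    scheme: str = "beutler"


@dataclass
class AlchemicalDataset:
    """Per-lambda-state samples for free-energy estimation.

    ``reduced_potentials`` is (n_samples, K): sample n evaluated at every
    state k, dimensionless (beta-scaled); ``origin_state`` labels the state
    each sample was drawn from.  ``dhdl`` (kJ/mol), aligned with the samples,
    enables TI.  ``times_ps`` (optional) allows the equilibration discard.
    """

    lambda_states: np.ndarray
    temperature: float
    reduced_potentials: np.ndarray | None = None
    origin_state: np.ndarray | None = None
    dhdl: np.ndarray | None = None
    times_ps: np.ndarray | None = None
    softcore: SoftCoreSpec | None = None

    def __post_init__(self):
        self.lambda_states = np.asarray(self.lambda_states, float)
        lam = self.lambda_states
        if lam.size < 2 or np.any(np.diff(lam) <= 0):
            raise StructuralError("lambda states must be strictly increasing, >= 2")
        if not (abs(lam[0]) < 1e-12 and abs(lam[-1] - 1.0) < 1e-12):
            raise StructuralError("lambda endpoints 0 and 1 must be present")
        if self.reduced_potentials is not None:
            self.reduced_potentials = np.asarray(self.reduced_potentials, float)
            if self.origin_state is None:
                raise StructuralError("reduced potentials require origin-state labels")
            self.origin_state = np.asarray(self.origin_state, int)
            u = self.reduced_potentials
            if u.ndim != 2 or u.shape[1] != lam.size:
                raise StructuralError("reduced potentials must be (n_samples, K)")
            if u.shape[0] != self.origin_state.size:
                raise StructuralError("one origin label per sample required")
            if not np.all(np.isfinite(u)):
                raise StructuralError("non-finite reduced potentials")
        if self.dhdl is not None:
            self.dhdl = np.asarray(self.dhdl, float)
            if self.origin_state is None or self.dhdl.shape != self.origin_state.shape:
                raise StructuralError("dhdl must align with origin-state labels")

    @property
    def n_states(self) -> int:
        return self.lambda_states.size

    def counts(self) -> np.ndarray:
        return np.bincount(self.origin_state, minlength=self.n_states)

    def discard_equilibration(self, t0_ps: float = 100.0) -> "AlchemicalDataset":
        """Drop samples before ``t0_ps`` (default 100 ps); no-op without times."""
        if self.times_ps is None:
            return self
        keep = np.asarray(self.times_ps, float) >= t0_ps
        return AlchemicalDataset(
            lambda_states=self.lambda_states, temperature=self.temperature,
            reduced_potentials=None if self.reduced_potentials is None
            else self.reduced_potentials[keep],
            origin_state=None if self.origin_state is None else self.origin_state[keep],
            dhdl=None if self.dhdl is None else self.dhdl[keep],
            times_ps=np.asarray(self.times_ps, float)[keep], softcore=self.softcore)


@dataclass
class FreeEnergyResult:
    """A free-energy difference between lambda endpoints (kJ/mol)."""

    delta_A: float
    uncertainty: float
    method: str
    per_interval: np.ndarray = field(default_factory=lambda: np.array([]))
    temperature: float = 300.0

    def __post_init__(self):
        if self.uncertainty < 0:
            raise StructuralError("uncertainty must be non-negative")
        pi = np.asarray(self.per_interval, float)
        if pi.size and abs(pi.sum() - self.delta_A) > 1e-10 * max(1.0, abs(self.delta_A)):
            raise StructuralError("per-interval contributions must sum to delta_A")


# ---------------------------------------------------------------------------
# thermodynamic integration
# ---------------------------------------------------------------------------

def _effective_sample_size(x: np.ndarray) -> float:
    from .metrics import autocorrelation
    n = x.size
    if n < 8 or np.ptp(x) == 0:
        return float(n)
    tau = autocorrelation(x, max_lag=min(n - 1, 1000)).tau_int
    return n / max(tau, 1.0)


def ti_integrate(dataset: AlchemicalDataset) -> FreeEnergyResult:
    """Trapezoid thermodynamic integration of per-state <dH/dlambda>.

    Uncertainty propagates the per-state standard errors of the mean (with
    an autocorrelation-corrected effective sample size) through the
    trapezoid weights.
    """
    if dataset.dhdl is None:
        raise CapabilityError("dataset carries no dH/dlambda samples; use MBAR")
    lam = dataset.lambda_states
    K = dataset.n_states
    means = np.empty(K)
    se2 = np.empty(K)
    for k in range(K):
        xk = dataset.dhdl[dataset.origin_state == k]
        if xk.size == 0:
            raise CapabilityError(f"no dH/dlambda samples at state {k}")
        means[k] = xk.mean()
        ess = _effective_sample_size(xk)
        se2[k] = xk.var(ddof=1) / ess if xk.size > 1 else 0.0
    dlam = np.diff(lam)
    per_interval = 0.5 * dlam * (means[:-1] + means[1:])
    w = np.zeros(K)
    w[:-1] += 0.5 * dlam
    w[1:] += 0.5 * dlam
    var = float((w ** 2 * se2).sum())
    return FreeEnergyResult(delta_A=float(per_interval.sum()),
                            uncertainty=math.sqrt(var), method="TI",
                            per_interval=per_interval,
                            temperature=dataset.temperature)


# ---------------------------------------------------------------------------
# MBAR
# ---------------------------------------------------------------------------

def _mbar_objective(f: np.ndarray, u: np.ndarray, N: np.ndarray):
    """Convex MBAR objective and gradient; f are dimensionless free energies."""
    logN = np.log(N)
    a = logN[None, :] + f[None, :] - u  # (n, K)
    lse = logsumexp(a, axis=1)
    obj = lse.sum() - float(N @ f)
    WN = np.exp(a - lse[:, None])  # (n, K), rows sum to 1
    grad = WN.sum(axis=0) - N
    W = WN / N[None, :]            # column-normalized MBAR weights
    return obj, grad, W


def mbar_solve(dataset: AlchemicalDataset, tol: float = 1e-10,
               max_iter: int = 100_000,
               overlap_warn: float = 0.03) -> FreeEnergyResult:
    """Self-consistent MBAR free energies, anchored at state 0 = 0.

    A quasi-Newton minimization of the convex MBAR objective provides the
    warm start; plain self-consistent iteration then polishes to ``tol``
    (max change in any dimensionless free energy).  Returns the endpoint
    difference in kJ/mol with the asymptotic-covariance uncertainty, and
    warns when the estimated overlap between adjacent states drops below
    ``overlap_warn``.
    """
    if dataset.reduced_potentials is None:
        raise CapabilityError("dataset carries no reduced potentials; use TI")
    u = dataset.reduced_potentials
    N = dataset.counts().astype(float)
    if np.any(N == 0):
        raise StructuralError("every lambda state needs at least one sample for MBAR")
    K = dataset.n_states
    f = np.zeros(K)

    def fun(fr):
        full = np.concatenate([[0.0], fr])
        obj, grad, _ = _mbar_objective(full, u, N)
        return obj, grad[1:]

    res = minimize(fun, f[1:], jac=True, method="L-BFGS-B",
                   options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-9})
    f = np.concatenate([[0.0], res.x])
    logN = np.log(N)
    residual = np.inf
    for _ in range(max_iter):
        lse_n = logsumexp(logN[None, :] + f[None, :] - u, axis=1)  # (n,)
        f_new = -logsumexp(-u - lse_n[:, None], axis=0)
        f_new = f_new - f_new[0]
        residual = float(np.abs(f_new - f).max())
        f = f_new
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"MBAR self-consistent iteration did not reach {tol:g} in "
            f"{max_iter} iterations", residual=residual)
    _, _, W = _mbar_objective(f, u, N)
    # overlap between adjacent states: O = (N W)^T W
    O = (W * N[None, :] / 1.0).T @ W  # K x K; O[i, j] ~ overlap of i with j
    adj = np.array([min(O[k, k + 1], O[k + 1, k]) for k in range(K - 1)])
    if adj.size and adj.min() < overlap_warn:
        warnings.warn(
            f"low adjacent-state overlap (min {adj.min():.3g}); MBAR estimates "
            "may be unreliable", stacklevel=2)
    theta = _mbar_covariance(W, N)
    kbt = units.kbt_kj_per_mol(dataset.temperature)
    var = theta[0, 0] + theta[-1, -1] - 2.0 * theta[0, -1]
    per_interval = np.diff(f) * kbt
    return FreeEnergyResult(delta_A=float((f[-1] - f[0]) * kbt),
                            uncertainty=kbt * math.sqrt(max(var, 0.0)),
                            method="MBAR", per_interval=per_interval,
                            temperature=dataset.temperature)


def _mbar_covariance(W: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Asymptotic covariance of the dimensionless free energies.

    Theta = V S (I - S V^T diag(N) V S)^+ S V^T with W = U S V^T, the
    standard estimator from the MBAR normal equations.
    """
    _, s, Vt = np.linalg.svd(W, full_matrices=False)
    V = Vt.T
    S = np.diag(s)
    inner = np.eye(len(s)) - S @ V.T @ (N[:, None] * V) @ S
    inner = 0.5 * (inner + inner.T)
    # one exact null direction (weight normalization); invert the rest
    ev, evec = np.linalg.eigh(inner)
    inv = np.zeros_like(inner)
    for lam, v in zip(ev, evec.T):
        if lam > 1e-10 * max(abs(ev).max(), 1.0):
            inv += np.outer(v, v) / lam
    theta = V @ S @ inv @ S @ V.T
    return theta


def solvation_cycle(delta_A_solvent_leg: FreeEnergyResult,
                    delta_A_vacuum_leg: FreeEnergyResult) -> FreeEnergyResult:
    """dA_solv = dA_1(solvent decoupling) - dA_2(vacuum decoupling), with
    uncertainties combined in quadrature."""
    a, b = delta_A_solvent_leg, delta_A_vacuum_leg
    if abs(a.temperature - b.temperature) > 1e-9:
        raise StructuralError("cycle legs must share a temperature")
    method = a.method if a.method == b.method else f"{a.method}/{b.method}"
    return FreeEnergyResult(
        delta_A=a.delta_A - b.delta_A,
        uncertainty=math.hypot(a.uncertainty, b.uncertainty),
        method=f"cycle({method})", temperature=a.temperature)


@dataclass
class ConsistencyReport:
    passed: bool
    discrepancy: float
    threshold: float
    conclusive: str | None


def consistency_check(ti: FreeEnergyResult, mbar: FreeEnergyResult,
                      tolerance_kT: float = 1.0) -> ConsistencyReport:
    """Compare TI and MBAR on the same dataset.

    The discrepancy is tested against max(tolerance_kT * k_B T, combined
    quadrature uncertainty); on a pass MBAR is designated the conclusive
    estimate, following the usual convention.
    """
    disc = abs(ti.delta_A - mbar.delta_A)
    kbt = units.kbt_kj_per_mol(mbar.temperature)
    thr = max(tolerance_kT * kbt, math.hypot(ti.uncertainty, mbar.uncertainty))
    ok = disc <= thr
    return ConsistencyReport(passed=ok, discrepancy=disc, threshold=thr,
                             conclusive="MBAR" if ok else None)


# ---------------------------------------------------------------------------
# Wang-Landau expanded-ensemble machinery
# ---------------------------------------------------------------------------

@dataclass
class WangLandauState:
    """Adaptive expanded-ensemble weights over lambda states.

    ``log_weights`` g_k bias the state marginal p_k ~ exp(g_k - f_k); when
    the visit histogram is flat (max relative deviation from its mean below
    ``flatness_threshold``) the histogram resets and the increment scales by
    ``scale_factor``.  A flatness check only fires once every state holds at
    least ``min_samples_per_state`` visits, so a stage cannot end on a
    trivially small histogram.  Convergence: increment below ``stop_delta``.
    At the flat-histogram fixed point g_k - g_0 = f_k - f_0 = beta dA_k.
    """

    log_weights: np.ndarray
    histogram: np.ndarray
    wl_delta: float = 1.0
    flatness_threshold: float = 0.20
    scale_factor: float = 0.7
    stop_delta: float = 0.001
    min_samples_per_state: int = 20
    n_scalings: int = 0

    def __post_init__(self):
        self.log_weights = np.asarray(self.log_weights, float)
        self.histogram = np.asarray(self.histogram, float)
        if self.log_weights.shape != self.histogram.shape:
            raise StructuralError("weights and histogram sizes differ")
        if self.wl_delta <= 0 and not self.converged:
            raise StructuralError("wl_delta must stay positive until converged")
        if not np.all(np.isfinite(self.log_weights)):
            raise StructuralError("non-finite Wang-Landau weights")

    @property
    def converged(self) -> bool:
        return self.wl_delta < self.stop_delta

    @classmethod
    def initial(cls, n_states: int, **kwargs) -> "WangLandauState":
        return cls(log_weights=np.zeros(n_states), histogram=np.zeros(n_states),
                   **kwargs)


def wang_landau_update(state: WangLandauState, visited_state: int) -> WangLandauState:
    """One Wang-Landau step: penalize the visited state and test flatness.

    The visited state's log-weight decreases by the current increment and its
    histogram count increments; when every state holds enough visits and the
    maximum relative deviation of the histogram from its mean falls below the
    flatness threshold, the histogram resets and the increment is scaled
    down.  The state is updated in place and returned.
    """
    k = int(visited_state)
    if not 0 <= k < state.log_weights.size:
        raise IndexError(f"state index {k} out of range")
    if state.converged:
        return state
    state.log_weights[k] -= state.wl_delta
    state.histogram[k] += 1
    h = state.histogram
    if h.min() >= state.min_samples_per_state:
        mean = h.mean()
        if np.abs(h - mean).max() / mean < state.flatness_threshold:
            state.histogram = np.zeros_like(h)
            state.wl_delta *= state.scale_factor
            state.n_scalings += 1
    return state


def _metropolized_gibbs_move(p: np.ndarray, current: int, rng) -> int:
    """One Metropolized-Gibbs jump for target state probabilities p:
    propose j != i with prob p_j / (1 - p_i), accept with
    min(1, (1 - p_i) / (1 - p_j))."""
    q = p.copy()
    q[current] = 0.0
    qs = q.sum()
    if qs <= 0:
        return current
    j = rng.choice(p.size, p=q / qs)
    if rng.random() < min(1.0, (1.0 - p[current]) / (1.0 - p[j])):
        return j
    return current


def wang_landau_toy(beta_free_energies: np.ndarray, seed: int,
                    max_steps: int = 2_000_000, polish_steps: int = 30_000,
                    wl: WangLandauState | None = None) -> WangLandauState:
    """Metropolized-Gibbs expanded-ensemble toy over discrete states.

    States k carry dimensionless free energies f_k; the sampler jumps with
    Metropolized-Gibbs transition probabilities for p_k ~ exp(g_k - f_k)
    (an exact marginal move, as if the configurational coordinate were
    resampled from its conditional at every step) while Wang-Landau adapts
    the weights g.  Runs until convergence or ``max_steps``.

    After convergence the raw weights still carry the random-walk noise of
    the finite schedule (~sqrt(delta) per stage); ``polish_steps`` of
    fixed-weight sampling refine them through the stationary visit histogram
    (g_k <- g_k - ln h_k up to a constant), the usual post-equilibration
    weight estimate in expanded-ensemble practice.  Set ``polish_steps=0``
    for the raw converged weights.
    """
    f = np.asarray(beta_free_energies, float)
    K = f.size
    rng = np.random.default_rng(seed)
    state = wl if wl is not None else WangLandauState.initial(K)
    current = 0
    for _ in range(max_steps):
        logp = state.log_weights - f
        p = np.exp(logp - logsumexp(logp))
        current = _metropolized_gibbs_move(p, current, rng)
        state = wang_landau_update(state, current)
        if state.converged:
            break
    else:
        raise ConvergenceError("Wang-Landau toy did not converge within step budget")
    if polish_steps:
        h = np.zeros(K)
        logp = state.log_weights - f
        p = np.exp(logp - logsumexp(logp))
        for _ in range(polish_steps):
            current = _metropolized_gibbs_move(p, current, rng)
            h[current] += 1
        if h.min() > 0:
            corr = np.log(h)
            state.log_weights = state.log_weights - (corr - corr.mean())
    return state


# ---------------------------------------------------------------------------
# delimited-text dataset I/O
# ---------------------------------------------------------------------------

def write_alchemical_dataset(dataset: AlchemicalDataset, path) -> None:
    """Write the delimited-text dialect (u_kn or dhdl flavor).

    Header comments carry the temperature and the lambda values; the column
    header distinguishes the two flavors.
    """
    lam = ",".join(f"{v:.17g}" for v in dataset.lambda_states)
    with open(path, "w") as fh:
        fh.write(f"# temperature_K = {dataset.temperature:.10g}\n")
        fh.write(f"# lambda_states = {lam}\n")
        if dataset.softcore is not None:
            sc = dataset.softcore
            fh.write(f"# softcore = sc_alpha={sc.sc_alpha},sd_power={sc.sd_power},"
                     f"sc_sigma={sc.sc_sigma},scheme={sc.scheme}\n")
        if dataset.reduced_potentials is not None:
            cols = ",".join(f"u_at_state_{k}" for k in range(dataset.n_states))
            fh.write(f"origin_state,{cols}\n")
            for k, row in zip(dataset.origin_state, dataset.reduced_potentials):
                fh.write(f"{k}," + ",".join(f"{v:.17g}" for v in row) + "\n")
        elif dataset.dhdl is not None:
            fh.write("state,dhdl_kJ_per_mol\n")
            for k, v in zip(dataset.origin_state, dataset.dhdl):
                fh.write(f"{k},{v:.17g}\n")
        else:
            raise StructuralError("dataset has neither reduced potentials nor dhdl")


def read_alchemical_dataset(path) -> AlchemicalDataset:
    """Read the dialect written by :func:`write_alchemical_dataset`."""
    temperature = None
    lam = None
    header = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("temperature_K"):
                    temperature = float(body.split("=", 1)[1])
                elif body.startswith("lambda_states"):
                    lam = np.array([float(v) for v in body.split("=", 1)[1].split(",")])
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
                continue
            rows.append([float(v) for v in line.split(",")])
    if temperature is None or lam is None or header is None:
        raise StructuralError(f"{path}: missing temperature/lambda header or data")
    data = np.asarray(rows, float)
    origin = data[:, 0].astype(int)
    if header[0] == "origin_state" and header[1].startswith("u_at_state_"):
        return AlchemicalDataset(lambda_states=lam, temperature=temperature,
                                 reduced_potentials=data[:, 1:], origin_state=origin)
    if header[0] == "state" and header[1].startswith("dhdl"):
        return AlchemicalDataset(lambda_states=lam, temperature=temperature,
                                 origin_state=origin, dhdl=data[:, 1])
    raise StructuralError(f"{path}: unrecognized column header {header}")
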
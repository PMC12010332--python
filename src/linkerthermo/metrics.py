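"""Collective-variable extraction, free-energy surfaces, persistence length
and autocorrelation diagnostics.

The canonical collective variable for a linker is the distance between the
mass-weighted centers of its two terminal capping groups; its histogram is
Boltzmann-inverted into a potential of mean force F(d) = -k_B T ln p(d),
min-shifted to zero.  Chain stiffness is summarized by the persistence
length l_p obtained from the exponential decay of bond-direction
correlations, C(n) = <u_i . u_{i+n}> ~ exp(-n <l_b> / l_p).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import units
from .errors import FitError, NumericalError, StructuralError
from .trajectory import TrajectoryFrames

__all__ = [
    "CVSeries",
    "FreeEnergySurface",
    "PersistenceFit",
    "ACFResult",
    "end_to_end_series",
    "fes_from_cv",
    "persistence_length",
    "bond_correlation",
    "autocorrelation",
]


@dataclass
class CVSeries:
    """A scalar collective-variable trace: one value (nm) per frame."""

    values: np.ndarray
    times: np.ndarray
    label: str = "cv"
    is_distance: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.times = np.asarray(self.times, float)
        if self.values.shape != self.times.shape:
            raise StructuralError("values and times lengths differ")
        if not np.all(np.isfinite(self.values)):
            raise StructuralError("non-finite CV values")
        if self.is_distance and np.any(self.values < 0):
            raise StructuralError("distance CV cannot be negative")


@dataclass
class FreeEnergySurface:
    """Binned PMF: free energy per bin (kJ/mol), min-shifted so the lowest
    occupied bin is exactly 0.  Unoccupied bins carry NaN, not 0."""

    bin_edges: np.ndarray
    free_energy: np.ndarray
    counts: np.ndarray
    temperature: float

    def __post_init__(self):
        occ = self.counts > 0
        if occ.any():
            fmin = np.nanmin(self.free_energy[occ])
            if abs(fmin) > 1e-12:
                raise NumericalError("occupied-bin minimum must be shifted to 0")
        if np.any(np.isfinite(self.free_energy[~occ])):
            raise NumericalError("unoccupied bins must be marked NaN")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def write(self, path) -> None:
        """Three-column text: bin center (nm), F (kJ/mol), count."""
        with open(path, "w") as fh:
            fh.write("# bin_center_nm free_energy_kJ_mol count\n")
            for c, f, n in zip(self.bin_centers, self.free_energy, self.counts):
                fh.write(f"{c:.6f} {f if np.isfinite(f) else 'nan'} {int(n)}\n")


@dataclass
class PersistenceFit:
    """Exponential bond-correlation fit.  ``flag`` marks degenerate regimes
    (near-rigid chains get a capped estimate)."""

    l_p: float
    mean_bond_length: float
    fit_range: tuple[int, int]
    r_squared: float
    flag: str | None = None

    def __post_init__(self):
        if not (self.l_p > 0):
            raise FitError("persistence length must be positive")
        if not (np.isnan(self.r_squared) or 0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise FitError("r_squared outside [0, 1]")


@dataclass
class ACFResult:
    """Normalized autocorrelation function and its integrated time."""

    acf: np.ndarray
    tau_int: float
    first_nonpositive_lag: int | None


# ---------------------------------------------------------------------------

def end_to_end_series(traj: TrajectoryFrames, group_a, group_b) -> CVSeries:
    """Per-frame distance between mass-weighted centers of two atom groups."""
    a = np.asarray(group_a, int)
    b = np.asarray(group_b, int)
    if a.size == 0 or b.size == 0:
        raise StructuralError("both groups must be non-empty")
    if np.intersect1d(a, b).size:
        warnings.warn("end-to-end groups overlap", stacklevel=2)
    m = traj.topology.masses
    ca = (traj.coordinates[:, a] * m[a, None]).sum(axis=1) / m[a].sum()
    cb = (traj.coordinates[:, b] * m[b, None]).sum(axis=1) / m[b].sum()
    d = np.linalg.norm(ca - cb, axis=1)
    return CVSeries(values=d, times=traj.times.copy(), label="end_to_end_nm",
                    is_distance=True)


def fes_from_cv(cv: CVSeries, bin_width: float = 0.05, temperature: float = 300.0,
                weights: np.ndarray | None = None) -> FreeEnergySurface:
    """Boltzmann inversion of a (optionally weighted) CV histogram.

    F(bin) = -k_B T ln p(bin), shifted so the minimum over occupied bins is
    exactly zero; by default no reweighting is applied.  Bin edges are
    aligned to integer multiples of ``bin_width``.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    v = cv.values
    if v.size == 0:
        raise StructuralError("empty CV series")
    lo = np.floor(v.min() / bin_width) * bin_width
    hi = np.ceil(v.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    nbins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(nbins + 1)
    counts, _ = np.histogram(v, bins=edges)
    wsum, _ = np.histogram(v, bins=edges, weights=weights) if weights is not None \
        else (counts.astype(float), None)
    kbt = units.kbt_kj_per_mol(temperature)
    free = np.full(nbins, np.nan)
    occ = counts > 0
    with np.errstate(divide="ignore"):
        free[occ] = -kbt * np.log(wsum[occ] / wsum.sum())
    free[occ] -= free[occ].min()
    return FreeEnergySurface(bin_edges=edges, free_energy=free,
                             counts=counts, temperature=temperature)


def _parabolic_extremum(fes: FreeEnergySurface, m: int, maximum: bool) -> float:
    """Refine the extremum at bin ``m`` with a parabola through its three
    bins, removing most of the bin-averaging bias; falls back to the bin
    value at edges or when the curvature has the wrong sign."""
    F = fes.free_energy
    if 0 < m < F.size - 1 and fes.counts[m - 1] > 0 and fes.counts[m + 1] > 0:
        y0, y1, y2 = F[m - 1:m + 2]
        denom = y0 - 2 * y1 + y2
        if (denom < 0) == maximum and denom != 0:
            delta = 0.5 * (y0 - y2) / denom
            if abs(delta) <= 1.0:
                return float(y1 - 0.25 * (y0 - y2) * delta)
    return float(F[m])


def barrier_height(fes: FreeEnergySurface, x_lo: float, x_hi: float) -> float:
    """Barrier height (kJ/mol) of a PMF between two basins.

    Both the occupied-bin maximum of F over centers in (x_lo, x_hi) and the
    global occupied minimum are refined by parabolic interpolation over
    their neighboring bins, so the estimate is nearly free of the
    bin-averaging bias at either extremum.
    """
    c = fes.bin_centers
    occ = fes.counts > 0
    mask = (c > x_lo) & (c < x_hi) & occ
    if not mask.any():
        raise NumericalError("no occupied bins between the given basins")
    idx = np.nonzero(mask)[0]
    top = idx[np.nanargmax(fes.free_energy[idx])]
    bottom = np.nonzero(occ)[0][np.nanargmin(fes.free_energy[occ])]
    return (_parabolic_extremum(fes, top, maximum=True)
            - _parabolic_extremum(fes, bottom, maximum=False))


# ---------------------------------------------------------------------------

def bond_correlation(traj: TrajectoryFrames, backbone) -> tuple[np.ndarray, float]:
    """Ensemble-average bond-direction correlation C(n) and mean bond length.

    Bond vectors follow consecutive ``backbone`` atoms; C(n) averages
    u_i . u_{i+n} over all offsets i and frames, n = 0 .. n_bonds-1.
    """
    bb = np.asarray(backbone, int)
    if bb.size < 3:
        raise StructuralError("need at least 3 backbone atoms")
    xyz = traj.coordinates[:, bb, :]
    bonds = np.diff(xyz, axis=1)
    lengths = np.linalg.norm(bonds, axis=2)
    u = bonds / lengths[:, :, None]
    n_bonds = u.shape[1]
    corr = np.empty(n_bonds)
    for n in range(n_bonds):
        corr[n] = float(np.mean(np.einsum("fik,fik->fi", u[:, : n_bonds - n],
                                          u[:, n:])))
    return corr, float(lengths.mean())


def persistence_length(traj: TrajectoryFrames, backbone,
                       fit_range: tuple[int, int] | None = None) -> PersistenceFit:
    """Persistence length from the exponential decay of C(n).

    ln C(n) is fitted by weighted least squares over lags in ``fit_range``
    (default 1 .. n_bonds // 2) restricted to the initial run of strictly
    positive correlations; l_p = -<l_b> / slope.  Weights are proportional
    to C(n)^2, the delta-method variance of ln C under lag-independent
    correlation noise, so lags where the correlation has decayed into the
    noise floor do not bias the slope.  A chain whose correlation never
    drops below 0.999 is reported as capped (l_p = inf) with a flag;
    nonpositive correlation already at lag 1 is a fit error.
    """
    if traj.n_frames < 10:
        raise StructuralError("need at least 10 frames (chains) for a stable fit")
    corr, l_b = bond_correlation(traj, backbone)
    n_bonds = corr.size
    lo, hi = fit_range if fit_range is not None else (1, max(2, n_bonds // 2))
    hi = min(hi, n_bonds - 1)
    if corr[1] <= 0:
        raise FitError("bond correlation nonpositive already at lag 1")
    if corr[min(hi, n_bonds - 1)] > 0.999:
        return PersistenceFit(l_p=np.inf, mean_bond_length=l_b, fit_range=(lo, hi),
                              r_squared=np.nan, flag="near-rigid chain: estimate capped")
    lags = np.arange(lo, hi + 1)
    pos = corr[lags] > 0
    if not pos.all():
        cut = int(np.argmin(pos))
        lags = lags[:cut]
    if lags.size < 2:
        raise FitError("fewer than 2 usable lags with positive correlation")
    y = np.log(corr[lags])
    w = corr[lags] ** 2
    w = w / w.sum()
    xm = float((w * lags).sum())
    ym = float((w * y).sum())
    sxx = float((w * (lags - xm) ** 2).sum())
    sxy = float((w * (lags - xm) * (y - ym)).sum())
    syy = float((w * (y - ym) ** 2).sum())
    slope = sxy / sxx
    r2 = (sxy ** 2 / (sxx * syy)) if syy > 0 else 1.0
    if slope >= 0:
        return PersistenceFit(l_p=np.inf, mean_bond_length=l_b,
                              fit_range=(int(lags[0]), int(lags[-1])),
                              r_squared=r2,
                              flag="non-decaying correlation: estimate capped")
    return PersistenceFit(l_p=-l_b / slope, mean_bond_length=l_b,
                          fit_range=(int(lags[0]), int(lags[-1])), r_squared=r2)


# ---------------------------------------------------------------------------

def autocorrelation(cv, max_lag: int) -> ACFResult:
    """Normalized autocorrelation of a CV trace with integrated time.

    Mean-removed, biased (1/n) normalization for stability at large lags;
    tau_int = 1 + 2 sum acf(k) over the initial run of positive values
    (initial-positive-sequence rule).  Also reports the first lag with
    acf <= 0, a direct sampling-sufficiency diagnostic.
    """
    v = cv.values if isinstance(cv, CVSeries) else np.asarray(cv, float)
    n = v.size
    if n <= max_lag:
        raise StructuralError(f"series length {n} must exceed max_lag {max_lag}")
    x = v - v.mean()
    var = float(np.mean(x * x))
    if var == 0:
        raise NumericalError("constant series: autocorrelation undefined")
    m = 1
    while m < 2 * n:
        m <<= 1
    fx = np.fft.rfft(x, m)
    acov = np.fft.irfft(fx * np.conj(fx), m)[: max_lag + 1] / n
    acf = acov / acov[0]
    nonpos = np.nonzero(acf[1:] <= 0)[0]
    first_np = int(nonpos[0] + 1) if nonpos.size else None
    upto = first_np if first_np is not None else max_lag + 1
    tau = 1.0 + 2.0 * float(acf[1:upto].sum())
    return ACFResult(acf=acf, tau_int=tau, first_nonpositive_lag=first_np)
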
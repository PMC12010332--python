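# Methods

This note records the models implemented in `linkerthermo`, the numerical
choices behind them, what the synthetic generators do and do not emulate,
and the limitations a user should keep in mind.

## Units and constants

Internal units are nm, ps, amu, kJ/mol and K throughout; file readers
convert at the boundary (PDB/XYZ are Å on disk).  All physical constants
come from `scipy.constants` (CODATA).  Entropies are reported as −T·S in
kJ/mol so they add directly onto free-energy budgets; at 300 K,
k_BT ≈ 2.494 kJ/mol.

## Trajectory model

`Topology` carries per-atom masses (the diagonal of the mass matrix M) and
group tags `{linker, cap_N, cap_C, other}`; the reader tags the first/last
residue as caps when its residue name is one of ACE/NME/NMA/CAP.  Masses are
inferred from the PDB element column, falling back to the first alphabetic
character of the atom name; a user override table wins.  Periodic-boundary
unwrapping is *not* implemented — inputs are assumed whole molecules, and
`detect_broken_molecule` rejects frames with implausibly long assumed bonds.

Superposition is mass-weighted Kabsch (SVD with the determinant correction),
applied per frame against a reference frame over a fit selection; the
rotation is unique only when the reference selection spans a plane, so
collinear or <3-atom selections raise.  Fitting is idempotent to 1e-10 nm
and never increases the mass-weighted RMSD.

## Schlitter entropy

The estimator builds C = M^{1/2}⟨Δx Δxᵀ⟩M^{1/2} (population covariance,
1/N normalization, deviations from the time mean) from frames after a
configurable equilibration discard (default 5 ns, the common practice for
multi-microsecond production runs; synthetic tests pass 0) and evaluates

    S' = (k_B/2) Σ_modes ln(1 + (k_B T e²/ħ²) λ_mode),

with e Euler's number and λ the eigenvalues of C converted to SI inside the
logarithm's argument.  S' bounds the true entropy from above and reduces,
mode by mode, to the classical harmonic-oscillator entropy at high
temperature.

Rigid-body content is excluded before diagonalization.  The default policy
projects out the (up to six) exact translation/rotation generators built at
the mean structure — equivalent to discarding the "first six eigenvectors"
when superposition already removed rigid motion, and robust when it did not.
A `policy="largest"` flag reproduces the naive drop-six-largest recipe.
Eigenvalues below 1e-14 amu·nm² are treated as null modes contributing
ln 1 = 0, so short (rank-deficient) trajectories evaluate cleanly; negative
eigenvalues beyond the floor are an error, as is a trajectory whose centroid
drifts between its halves (evidence of missing superposition).  The default
atom selection is all linker atoms including hydrogens; the selection is
exposed because heavy-atom-only conventions also exist.

The conformational term is defined as the Schlitter bound minus the RRHO
vibrational term, −TS_conf = −TS' − (−TS_vib).  It inherits upper-bound
character and may take either sign.

## Normal modes and RRHO

M^{-1/2} H M^{-1/2} is diagonalized; modes with |ν̃| < 1 cm⁻¹ are treated as
rigid (their projection onto the translation/rotation generators is
reported, and a warning fires when a near-zero mode is less than half
rigid), more than six near-zero modes or any mode below −1 cm⁻¹ raises a
saddle-point error with the imaginary count.  Thermochemistry uses the
quantum harmonic oscillator per retained mode, the rigid rotor on the
principal moments of inertia with symmetry number 1 (the peptide
convention; near-linear geometries switch to the linear-rotor formula with
a notice), and Sackur–Tetrode at 1 bar.  The 1 bar ideal-gas standard state
is a convention, recorded here because absolute −TS_trans/rot values are
only comparable between codes that share it; ZPVE and −TS_vib are
convention-free.

`finite_difference_hessian` (central differences, step 1e-4 nm, symmetrized)
enables Hessians from any Python potential without an MD engine; it insists
the supplied point is a minimum (gradient below 1e-3 kJ/mol/nm).

## Structural metrics

The collective variable is the distance between mass-weighted centers of the
two cap groups.  The PMF is −k_BT ln of the (optionally weighted) histogram
with 0.05 nm default bins aligned to multiples of the bin width, shifted so
the occupied-bin minimum is exactly 0; unoccupied bins are NaN, never 0.
`barrier_height` refines both the barrier-top and reference-minimum bins by
three-point parabolic interpolation, which removes most of the
bin-averaging bias (≈0.2–0.4 kJ/mol at 0.05 nm bins when extrema fall on
bin edges).

Persistence length: C(n) = ⟨û_i·û_{i+n}⟩ averaged over offsets and frames;
ln C(n) is fitted over lags 1..⌊n_bonds/2⌋ restricted to the initial run of
positive values.  The fit is *weighted* least squares with weights ∝ C(n)²
— the delta-method variance of ln C under lag-independent correlation noise
— because uniform weighting lets the noise floor at large lags bias l_p low
by ~10 % at 10⁴ chains.  Near-rigid chains (C > 0.999 at the last fit lag)
return a capped (infinite) estimate with a flag rather than a meaningless
number; backbone atom choice (N, CA, C for peptides) is the caller's.

The ACF uses FFT evaluation with biased 1/n normalization (stable at large
lags); the integrated time is τ = 1 + 2Σ ACF(k) summed over the initial
positive sequence, and the first nonpositive lag is reported as a
sampling-sufficiency diagnostic.

## Alchemical estimators

TI integrates per-state ⟨dH/dλ⟩ with the trapezoid rule; standard errors use
an autocorrelation-corrected effective sample size and propagate through the
trapezoid weights.  MBAR minimizes the convex objective with L-BFGS and
polishes by self-consistent iteration to 1e-10 in the dimensionless free
energies (anchor f₀ = 0); uncertainties come from the asymptotic covariance
Θ = V S (I − S Vᵀ N V S)⁺ S Vᵀ of the column-normalized weight matrix,
inverted by symmetric eigendecomposition with the single normalization null
direction dropped.  The reported σ was checked against the empirical spread
over independent seeds on the harmonic toy (agreement within ~15 %).  An
overlap matrix warns below 0.03 adjacent-state overlap.  λ spacing is data:
it is read from the input file, never rebalanced.  Datasets can carry Beutler
soft-core protocol metadata (α = 0.5, power 1, σ = 0.3 nm) but no soft-core
energies are evaluated here; samples before 100 ps are discarded when the
file carries times.

Wang–Landau: visiting a state lowers its log-weight by the current
increment; when every state holds at least `min_samples_per_state` (default
20) visits and the histogram's maximum relative deviation from its mean is
below 0.20, the histogram resets and the increment scales by 0.7; runs
start at 1.0 and are converged below 0.001 — exactly 20 scalings.  The
minimum-visits guard exists because a per-update flatness test on a
near-empty histogram is trivially satisfiable, collapsing the whole
schedule into a few dozen steps with unadapted weights.  The toy sampler
moves by Metropolized Gibbs over states (the configurational coordinate is
integrated out exactly for harmonic states) and, after convergence,
refines the weights by a fixed-weight visit-histogram correction
(g_k ← g_k − ln h_k up to a constant), the usual post-equilibration weight
estimate; `polish_steps=0` returns the raw converged weights, which carry
the schedule's intrinsic ~√δ random-walk noise (≈0.03–0.09 for 3–5 states).

The solvation cycle is ΔA_solv = ΔA(solvent leg) − ΔA(vacuum leg) with
quadrature uncertainties; the Helmholtz ΔA from an NVT ensemble is used
directly on the Gibbs side of the ledger, the pV term being negligible for
a solvated peptide.  TI/MBAR consistency compares |ΔA_TI − ΔA_MBAR| against
max(1 k_BT, combined uncertainty) and designates MBAR conclusive on a pass.

## Ledger

G = U + ZPVE + A_solv + (−TS_trans) + (−TS_rot) + (−TS_vib) + (−TS_conf),
exactly linear in its components; sds (carried by U and A_solv) combine in
quadrature.  A missing component yields an explicit null total naming it —
never a silent zero.  Residue counting excludes the capping groups (2
residues per dipeptide unit); the policy string travels with the data.
Per-residue decomposition divides every component by the count and is
exactly invertible; slopes versus residue count come from ordinary least
squares and require ≥3 distinct lengths.

The shipped reference tables cover 19 capped AP/GS/GG-repeat linkers in two
force fields.  They print the total RRHO entropy and its vibrational part
but not the translational/rotational split, so the fixture builder
reconstructs it: −TS_trans from Sackur–Tetrode at the linker's molar mass
(computed from residue composition; the caps-plus-termini mass is
approximated as +73.1 g/mol, which only enters a logarithm) and the
rotational term as the remainder.  Only the split is reconstructed — the
trans+rot+vib sum is the tabulated total to 1e-9.

## Synthetic generators

Each generator emits the same containers as real data and attaches a
closed-form `truth`:

* `gaussian_ensemble` — iid frames from N(ref, Σ); truth is the Schlitter
  value of the mass-weighted Σ.  No dynamics: frames are uncorrelated,
  unlike MD.
* `harmonic_chain` — bond-vector springs (k/2)Σ|d_i − d_i⁰|², a
  block-tridiagonal Hessian with exactly 3 translational null modes
  (bond-vector springs are not rotation invariant), exact Boltzmann
  sampling via independent mode amplitudes of variance k_BT/ω²; truth
  includes the analytic 1D-chain spectrum ω_j² = (2k/m)(1 − cos jπ/n)
  (threefold degenerate) and classical/quantum entropies.  The classical
  cross-check runs the Schlitter side with `remove_rigid_modes=0`: the
  ensemble holds zero variance in the null modes (they contribute ln 1 = 0)
  and the chain's rotation-like finite modes are genuine vibrations that
  RRHO keeps, so projecting rotations out would discard variance the other
  route counts.
* `frc_chain` — freely rotating chains (fixed bond angle, uniform azimuth);
  C(n) = cosⁿθ exactly, so l_p = −l_b/ln cos θ for cos θ > 0; for
  cos θ ≤ 0 the truth is flagged undefined.
* `langevin_cv` — overdamped Langevin with a Metropolis accept/reject step
  (MALA) by default, making the stationary density exactly Boltzmann at any
  stable step size; plain Euler–Maruyama (metropolis=False) carries an
  O(dt) density bias that is visible at the 0.5 kJ/mol level for
  dt·V″/γ ≈ 0.1.  The harmonic ACF truth exp(−kt/γ) is the continuous-time
  limit.  Multiple walkers (double-well walkers start alternately in either
  minimum) are concatenated for histogram work; use a single walker for
  autocorrelation analysis.
* `harmonic_alchemy` — exact Boltzmann samples from harmonic λ-states with
  geometric force-constant interpolation, so ⟨dH/dλ⟩ is λ-independent and
  trapezoid TI is discretization-free; truth ΔA = (k_BT/2) ln(k_end/k_start).

All generators are deterministic under a fixed seed with independent
per-generator streams.  What passing these tests shows: the estimators are
correct on ensembles satisfying their assumptions (Gaussian fluctuations,
harmonic modes, ideal chains, exact Boltzmann λ-samples).  What they do not
show: robustness to anharmonicity, conformational multi-modality, sampling
correlation and force-field error present in real MD data — there the
Schlitter value is an upper bound of unquantified looseness and the
conformational split inherits it.

## Problem sizes

The default verification runs use 10⁵ frames (Gaussian ensemble), 2×10⁴
frames of an 8-bead chain (classical-limit check), 10⁴ chains × 50 bonds
(persistence length), 10⁶ samples (Gaussian PMF), 10⁷ Langevin samples over
100 walkers (double well), 5 λ-states × 2000 samples × 5 seeds (alchemy)
and the 19-linker reference tables — sizes at which every tolerance has
severalfold statistical headroom on a single CPU.

## Known limitations

No periodic-boundary unwrapping, no reweighted (biased-sampling) PMFs, no
internal-coordinate or quasi-harmonic anharmonic entropy corrections, no
quantum-chemical Hessians, no soft-core energy evaluation or replica
exchange, and no recomputation of the shipped reference tables from raw
trajectories (they derive from multi-microsecond simulations and enter only
as ledger inputs).  The DCD/XTC adapter requires MDAnalysis and is disabled
without it.
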
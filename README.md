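# linkerthermo

A Python toolkit for the thermodynamic characterization of peptide linkers —
the short, often glycine/serine/proline-rich segments that tether protein
domains.  It implements the full analysis chain used to budget a linker's
free energy from simulation data:

* **Schlitter configurational entropy** — the upper bound
  `S ≤ S' = (k_B/2) ln det[1 + (k_B T e²/ħ²) M^{1/2} σ M^{1/2}]`
  from the mass-weighted covariance `σ` of atomic positions over a
  (superposed) trajectory, with rigid-body modes projected out;
* **RRHO thermochemistry** — normal-mode analysis of a dense Hessian at a
  minimum, giving ZPVE = Σ ħω/2 and the vibrational (quantum harmonic
  oscillator), rotational (rigid rotor, σ = 1) and translational
  (Sackur–Tetrode, 1 bar) entropies;
* **conformational entropy** as the difference of the two:
  `−TS_conf = −TS_Schlitter − (−TS_vib)`, an upper-bound approximation;
* **structural metrics** — end-to-end-distance collective variables,
  Boltzmann-inverted free-energy surfaces `F(d) = −k_B T ln p(d)` (0.05 nm
  bins), persistence lengths from the bond-correlation decay
  `⟨û_i·û_{i+n}⟩ ≈ e^{−n l_b / l_p}`, and autocorrelation diagnostics;
* **alchemical free energies** — thermodynamic integration and MBAR over
  λ-states, the solvation thermodynamic cycle `ΔA_solv = ΔA₁ − ΔA₂`, and a
  Wang–Landau expanded-ensemble weight updater (increment 1.0, scaled by 0.7
  at 20 % histogram flatness, converged below 0.001);
* **a free-energy ledger** — per-linker totals
  `G = U + ZPVE + A_solv − TS_trans − TS_rot − TS_vib − TS_conf` and
  per-residue slope fits, with reference component tables for 19 linkers
  (AP/GS/GG dipeptide repeats, capped termini) in two force fields;
* **synthetic data generators** with closed-form ground truth for every
  stage (Gaussian ensembles, Boltzmann-sampled harmonic chains, freely
  rotating chains, Metropolis-adjusted Langevin traces, harmonic alchemical
  datasets), so every estimator is tested against an exact answer.

The package is aimed at simulators who want desk-scale, fully verifiable
implementations of these estimators — for analyzing their own trajectory,
Hessian or λ-sample files (multi-model PDB, XYZ, dense-text Hessians,
delimited alchemical tables), or as a reference against engine outputs.

## Worked example

The alchemical toy interpolates a harmonic force constant from 1000 to
4000 kJ/mol/nm², so the endpoint free-energy difference is exactly
`(k_B T/2) ln 4`:

```bash
$ python examples/alchemical_free_energy.py
analytic dA = 1.7289 kJ/mol
TI          = 1.7607 +- 0.0264 kJ/mol
MBAR        = 1.7433 +- 0.0225 kJ/mol
TI/MBAR consistency: passed=True (discrepancy 0.0174 kJ/mol); conclusive estimate: MBAR
...
Wang-Landau toy: converged after 20 increment scalings
learned weight gap 0.6921 vs beta*dA = 0.6931
```

Both estimators land within their reported uncertainties of the analytic
value; the Wang–Landau weights converge to the dimensionless free-energy
gap.  The other scripts in `examples/` (one per capability) are equally
short: `schlitter_entropy.py`, `rrho_thermochemistry.py`,
`chain_statistics.py`, `linker_ledger.py`.  The ledger example prints, for
instance,

```
  AP       n_res= 2  G =    789.5 +-  17.9
  ...
  AP: ZPVE  +257.9  U  +171.9  -TS_vib   -39.3  -TS_conf   -33.5
```

— every linker total is positive, ZPVE is the fastest-growing destabilizing
term and vibrational entropy the dominant stabilizing one.

A thin CLI mirrors the library:

```bash
linkerthermo synth harmonic_alchemy --seed 1 --out data/
linkerthermo alchemy estimate --data data/alchemy_u.csv --method mbar
linkerthermo entropy schlitter --traj traj.pdb --select group:linker --temp 300
linkerthermo metrics fes --traj traj.pdb --bin-width 0.05 --out fes.txt
linkerthermo ledger build --force-field charmm36m --fit
linkerthermo pipeline run --seed 1 --out run/
```

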
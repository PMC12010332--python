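"""Assemble the per-linker free-energy ledger from the shipped tables.

Each capped linker peptide's total free energy is the sum of its linker-only
potential energy, ZPVE, solvation free energy, and the -TS entropy terms
(translational, rotational, vibrational, conformational).  Per-residue
slopes quantify how each term grows as the linker lengthens.
"""

from linkerthermo.ledger import (assemble_ledger, fit_slopes, linker_sequence,
                                 reference_components)

comps = reference_components("charmm36m")
print("linker totals (kJ/mol, CHARMM36m):")
for c in comps[:6]:
    e = assemble_ledger(c)
    print(f"  {c.linker_id:8s} n_res={c.n_residues:2d}  "
          f"G = {e.total:8.1f} +- {e.sd:5.1f}")
print("  ... (19 linkers total; every total is positive)")

print("\nper-residue slopes (kJ/mol per added residue):")
for family in ("AP", "GS", "GG"):
    fam = [c for c in comps if linker_sequence(c.linker_id)[:2] == family]
    zpve = fit_slopes(fam, "zpve")
    u = fit_slopes(fam, "potential_energy_U")
    vib = fit_slopes(fam, "minus_TS_vib")
    conf = fit_slopes(fam, "minus_TS_conf")
    print(f"  {family}: ZPVE {zpve.slope:+7.1f}  U {u.slope:+7.1f}  "
          f"-TS_vib {vib.slope:+7.1f}  -TS_conf {conf.slope:+7.1f}")
print("\nZPVE is the fastest-growing destabilizing term in every family,")
print("while the vibrational entropy is the dominant stabilizing one.")
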
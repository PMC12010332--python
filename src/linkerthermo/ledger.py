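"""Per-linker free-energy ledger and per-residue linear decomposition.

The "absolute Gibbs energy" of a capped linker peptide is assembled as

    G = U + ZPVE + A_solv + (-TS_trans) + (-TS_rot) + (-TS_vib) + (-TS_conf)

where U is the linker-only potential energy, A_solv the alchemical solvation
free energy (Helmholtz from NVT, used as the Gibbs-side term with pV
ignored), the trans/rot/vib terms come from RRHO normal-mode analysis and
the conformational term is the Schlitter upper bound minus the vibrational
entropy.  Components carry optional standard deviations which combine in
quadrature; a missing component propagates as an explicit null total, never
as zero.

Reference component tables for three linker families (AP, GS, GG dipeptide
repeats, capped termini) in two force fields ship with the package and feed
the ledger arithmetic; the trans/rot split of the total RRHO entropy is
reconstructed from the Sackur-Tetrode translational entropy at the linker's
molar mass, since published summaries typically print only the total and
vibrational parts.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, StructuralError
from .nma import translational_entropy

__all__ = [
    "ThermoComponents",
    "LedgerEntry",
    "SlopeFit",
    "assemble_ledger",
    "per_residue",
    "fit_slopes",
    "load_table",
    "reference_components",
    "linker_sequence",
    "linker_molar_mass",
    "REFERENCE_TABLES",
]

REFERENCE_TABLES = (
    "potential_energy", "persistence_length", "schlitter_entropy",
    "rrho_entropy", "vibrational_entropy", "solvation_free_energy",
)

# Average residue masses (amu) for the amino acids appearing in the linker
# families, and an approximate combined mass of the two capping groups plus
# chain termini (acetyl + N-methylamide).  The mass only enters through the
# logarithm of the Sackur-Tetrode formula, so ~1 amu accuracy is ample.
RESIDUE_MASSES = {"G": 57.0513, "A": 71.0779, "S": 87.0773, "P": 97.1152}
CAP_MASS = 73.09


@dataclass
class ThermoComponents:
    """Energy components (kJ/mol) of one linker in one force field.

    ``n_residues`` counts amino-acid residues in the repeat (2 per dipeptide
    unit), excluding capping groups — the residue-counting policy is recorded
    so per-residue decompositions remain interpretable.  Optional components
    are ``None`` when unavailable.
    """

    linker_id: str
    n_residues: int
    force_field_label: str
    potential_energy_U: float | None = None
    potential_energy_U_sd: float = 0.0
    zpve: float | None = None
    minus_TS_trans: float | None = None
    minus_TS_rot: float | None = None
    minus_TS_vib: float | None = None
    minus_TS_conf: float | None = None
    a_solv: float | None = None
    a_solv_sd: float = 0.0
    residue_count_policy: str = "repeat_residues_excluding_caps"

    COMPONENT_FIELDS = ("potential_energy_U", "zpve", "minus_TS_trans",
                        "minus_TS_rot", "minus_TS_vib", "minus_TS_conf", "a_solv")

    def __post_init__(self):
        if self.n_residues < 2:
            raise StructuralError("a dipeptide-repeat linker has at least 2 residues")
        for name in self.COMPONENT_FIELDS:
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise StructuralError(f"component {name} is non-finite")

    def missing(self) -> list[str]:
        return [n for n in self.COMPONENT_FIELDS if getattr(self, n) is None]


@dataclass
class LedgerEntry:
    """Assembled total for one linker; ``total`` is None when a component is
    missing, with the reason recorded."""

    linker_id: str
    force_field_label: str
    total: float | None
    sd: float | None
    reason: str | None = None


@dataclass
class SlopeFit:
    """OLS fit of one component against residue count."""

    component: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self):
        if self.n_points < 3:
            raise FitError("a reported slope fit needs at least 3 points")


def assemble_ledger(components: ThermoComponents) -> LedgerEntry:
    """Sum all components into the total free energy, sd in quadrature.

    Missing components yield an explicit null total naming them (the pattern
    used when a solvation leg could not be computed), never a silent zero.
    """
    missing = components.missing()
    if missing:
        return LedgerEntry(linker_id=components.linker_id,
                           force_field_label=components.force_field_label,
                           total=None, sd=None,
                           reason="missing component(s): " + ", ".join(missing))
    total = sum(getattr(components, n) for n in components.COMPONENT_FIELDS)
    sd = math.hypot(components.potential_energy_U_sd, components.a_solv_sd)
    return LedgerEntry(linker_id=components.linker_id,
                       force_field_label=components.force_field_label,
                       total=float(total), sd=sd)


def per_residue(components: ThermoComponents) -> ThermoComponents:
    """Divide every component (and sd) by the residue count; nulls propagate.

    Exactly inverted by multiplying each component back by ``n_residues``.
    """
    n = components.n_residues
    if n <= 0:
        raise StructuralError("residue count must be positive")
    updates = {}
    for name in components.COMPONENT_FIELDS:
        v = getattr(components, name)
        updates[name] = None if v is None else v / n
    updates["potential_energy_U_sd"] = components.potential_energy_U_sd / n
    updates["a_solv_sd"] = components.a_solv_sd / n
    updates["residue_count_policy"] = components.residue_count_policy + ";per_residue"
    return replace(components, **updates)


def fit_slopes(series: list[ThermoComponents], component: str) -> SlopeFit:
    """Ordinary least squares of a component against residue count.

    Entries with a null component are dropped; at least 3 distinct lengths
    are required (a single repeated length is rank-deficient).
    """
    if component not in ThermoComponents.COMPONENT_FIELDS:
        raise StructuralError(f"unknown component {component!r}")
    pts = [(c.n_residues, getattr(c, component)) for c in series
           if getattr(c, component) is not None]
    if len(pts) < 3:
        raise FitError(f"need >= 3 linkers with {component}, got {len(pts)}")
    x = np.array([p[0] for p in pts], float)
    y = np.array([p[1] for p in pts], float)
    if np.unique(x).size < 2:
        raise FitError("all linkers have the same residue count: fit is rank-deficient")
    res = stats.linregress(x, y)
    return SlopeFit(component=component, slope=float(res.slope),
                    intercept=float(res.intercept),
                    r_squared=float(res.rvalue ** 2), n_points=len(pts))


# ---------------------------------------------------------------------------
# reference tables
# ---------------------------------------------------------------------------

def load_table(name: str) -> pd.DataFrame:
    """Load one of the shipped reference tables by short name."""
    if name not in REFERENCE_TABLES:
        raise StructuralError(f"unknown table {name!r}; available: {REFERENCE_TABLES}")
    ref = resources.files("linkerthermo") / "data" / f"{name}.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


def linker_sequence(linker_id: str) -> str:
    """One-letter sequence of a linker id such as 'AP' or '(GS)10'."""
    m = re.fullmatch(r"\((\w+)\)(\d+)", linker_id)
    if m:
        return m.group(1) * int(m.group(2))
    if re.fullmatch(r"[A-Z]+", linker_id):
        return linker_id
    raise StructuralError(f"malformed linker id {linker_id!r}")


def linker_molar_mass(linker_id: str) -> float:
    """Approximate molar mass (amu) of the capped linker from its sequence."""
    seq = linker_sequence(linker_id)
    try:
        return sum(RESIDUE_MASSES[a] for a in seq) + CAP_MASS
    except KeyError as exc:
        raise StructuralError(f"no residue mass for {exc.args[0]!r}") from exc


def reference_components(force_field: str = "charmm36m",
                         temperature: float = 300.0) -> list[ThermoComponents]:
    """Build per-linker components from the shipped tables.

    The conformational term is Schlitter minus vibrational; the trans/rot
    split of the RRHO total is reconstructed by evaluating Sackur-Tetrode at
    the linker molar mass (1 bar) and assigning the remainder to rotation.
    Missing table entries become null components.
    """
    ff = force_field.lower()
    if ff not in ("charmm36m", "ff14sb"):
        raise StructuralError("force_field must be 'charmm36m' or 'ff14sb'")
    u = load_table("potential_energy").set_index("linker")
    sch = load_table("schlitter_entropy").set_index("linker")
    rrho = load_table("rrho_entropy").set_index("linker")
    vib = load_table("vibrational_entropy").set_index("linker")
    solv = load_table("solvation_free_energy").set_index("linker")
    out = []
    for linker in u.index:
        n_res = len(linker_sequence(linker))
        mts_vib = float(vib.loc[linker, f"mts_vib_{ff}"])
        mts_nma = float(rrho.loc[linker, f"mts_nma_{ff}"])
        mts_trans = -temperature * translational_entropy(
            linker_molar_mass(linker), temperature)
        mts_rot = (mts_nma - mts_vib) - mts_trans
        mts_schlitter = float(sch.loc[linker, f"mts_{ff}"])
        a = solv.loc[linker, f"asolv_{ff}"]
        a_sd = solv.loc[linker, f"asolv_{ff}_sd"]
        u_sd_col = f"U_{ff}_sd"
        out.append(ThermoComponents(
            linker_id=linker, n_residues=n_res, force_field_label=force_field,
            potential_energy_U=float(u.loc[linker, f"U_{ff}"]),
            potential_energy_U_sd=float(u.loc[linker, u_sd_col]),
            zpve=float(rrho.loc[linker, f"zpve_{ff}"]),
            minus_TS_trans=mts_trans, minus_TS_rot=mts_rot, minus_TS_vib=mts_vib,
            minus_TS_conf=mts_schlitter - mts_vib,
            a_solv=None if pd.isna(a) else float(a),
            a_solv_sd=0.0 if pd.isna(a_sd) else float(a_sd)))
    return out
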
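"""Core trajectory/topology containers, readers and writers, selection and
rigid-body superposition.

Conventions
-----------
Coordinates are stored in nm, times in ps, masses in amu.  PDB and XYZ files
are Angstrom on disk and converted at the boundary.  Atom indexing is 0-based
internally; file dialects keep their native 1-based serials.

Only whole molecules are expected: periodic-boundary unwrapping is not
performed here, a broken molecule should be rejected upstream (see
:func:`detect_broken_molecule`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FitError, SelectionError, StructuralError, TrajectoryFormatError

__all__ = [
    "Topology",
    "TrajectoryFrames",
    "Superposition",
    "read_trajectory",
    "write_trajectory",
    "superpose",
    "select",
    "kabsch",
    "detect_broken_molecule",
    "ELEMENT_MASSES",
]

# Average atomic masses (amu) for element inference from PDB/XYZ records.
ELEMENT_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06,
    "CL": 35.45, "K": 39.098, "CA": 40.078, "FE": 55.845, "ZN": 65.38,
    "SE": 78.971, "BR": 79.904, "I": 126.904,
}

GROUP_TAGS = ("linker", "cap_N", "cap_C", "other")

# Residue names treated as terminal capping groups when tagging atoms.
CAP_RESIDUE_NAMES = ("ACE", "NME", "NMA", "CAP")


@dataclass
class Topology:
    """Per-atom metadata: names, residues, masses and group tags.

    The ``masses`` array is the diagonal of the mass matrix M used by the
    entropy machinery; the ``groups`` tags distinguish the linker proper from
    its two capping groups so the terminal-distance collective variable and
    linker-only selections can be formed.
    """

    names: list[str]
    residue_indices: np.ndarray
    residue_names: list[str]
    masses: np.ndarray
    groups: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.masses = np.asarray(self.masses, dtype=float)
        n = len(self.names)
        if self.groups is None:
            self.groups = ["linker"] * n
        if not (len(self.residue_names) == len(self.groups) == n
                == self.residue_indices.size == self.masses.size):
            raise StructuralError("topology field lengths disagree")
        if np.any(self.masses <= 0):
            bad = int(np.argmax(self.masses <= 0))
            raise StructuralError(f"non-positive mass for atom {bad} ({self.names[bad]})")
        unknown = set(self.groups) - set(GROUP_TAGS)
        if unknown:
            raise StructuralError(f"unknown group tags: {sorted(unknown)}")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def atom_ids(self) -> np.ndarray:
        """Contiguous 0-based atom indices."""
        return np.arange(self.n_atoms)

    def total_mass(self) -> float:
        return float(self.masses.sum())


@dataclass
class TrajectoryFrames:
    """Time-ordered Cartesian coordinates of one molecule.

    ``coordinates`` has shape (n_frames, n_atoms, 3) in nm; ``times`` are ps,
    strictly increasing and (nominally) equally spaced.
    """

    coordinates: np.ndarray
    times: np.ndarray
    topology: Topology

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise StructuralError(
                f"coordinates must be (n_frames, n_atoms, 3), got {self.coordinates.shape}")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise StructuralError(
                f"{self.coordinates.shape[1]} atoms in coordinates but "
                f"{self.topology.n_atoms} in topology")
        if self.coordinates.shape[0] != self.times.size:
            raise StructuralError("one time per frame required")
        if not np.all(np.isfinite(self.coordinates)):
            raise StructuralError("non-finite coordinates")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise StructuralError("frame times must be strictly increasing")
            spread = (dt.max() - dt.min()) / dt.mean()
            if spread > 1e-6:
                warnings.warn(f"frames not equally spaced (relative spread {spread:.2e})",
                              stacklevel=2)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class Superposition:
    """Rigid-body fit result.  Applied as ``x' = x @ rotation + translation``
    (row-vector convention); ``rmsd`` is the mass-weighted residual in nm."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-10):
            raise FitError("rotation matrix is not orthogonal")
        if np.linalg.det(self.rotation) < 0:
            raise FitError("rotation matrix is an improper rotation (det < 0)")
        if self.rmsd < 0:
            raise FitError("negative rmsd")


# ---------------------------------------------------------------------------
# element / group inference
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str, element_field: str = "") -> str:
    el = element_field.strip().upper()
    if el:
        return el
    for ch in atom_name.strip():
        if ch.isalpha():
            return ch.upper()
    return ""


def _mass_for(atom_name: str, element_field: str, overrides: dict | None,
              where: str) -> float:
    if overrides:
        if atom_name in overrides:
            return float(overrides[atom_name])
        el0 = _infer_element(atom_name, element_field)
        if el0 in overrides:
            return float(overrides[el0])
    el = _infer_element(atom_name, element_field)
    # two-letter elements first (CL before C)
    el2 = element_field.strip().upper() or atom_name.strip().upper()[:2]
    if el2 in ELEMENT_MASSES and element_field.strip():
        return ELEMENT_MASSES[el2]
    if el in ELEMENT_MASSES:
        return ELEMENT_MASSES[el]
    raise StructuralError(f"cannot assign a mass to atom {atom_name!r} ({where}); "
                          "supply a mass override")


def _assign_groups(residue_indices: np.ndarray, residue_names: list[str]) -> list[str]:
    """Tag atoms of capping residues at the chain ends as cap_N / cap_C."""
    if residue_indices.size == 0:
        return []
    first, last = residue_indices.min(), residue_indices.max()
    groups = []
    for ri, rn in zip(residue_indices, residue_names):
        if rn.upper() in CAP_RESIDUE_NAMES:
            if ri == first:
                groups.append("cap_N")
            elif ri == last:
                groups.append("cap_C")
            else:
                groups.append("other")
        else:
            groups.append("linker")
    return groups


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_trajectory(path, format: str = "auto", dt_ps: float = 1.0,
                    mass_overrides: dict | None = None) -> TrajectoryFrames:
    """Read a multi-model PDB or (multi-frame) XYZ file.

    Coordinates are converted Angstrom -> nm.  PDB atom records populate the
    topology (names, residues, element-inferred masses, cap tags); XYZ files
    yield a single generic residue.  Frame times are synthesized as
    ``0, dt_ps, 2*dt_ps, ...`` since neither dialect stores time.
    """
    path = str(path)
    fmt = format
    if fmt == "auto":
        low = path.lower()
        if low.endswith((".pdb", ".ent")):
            fmt = "pdb_multimodel"
        elif low.endswith(".xyz"):
            fmt = "xyz"
        else:
            raise TrajectoryFormatError(f"cannot guess format of {path!r}")
    if fmt == "pdb_multimodel":
        return _read_pdb(path, dt_ps, mass_overrides)
    if fmt == "xyz":
        return _read_xyz(path, dt_ps, mass_overrides)
    raise TrajectoryFormatError(f"unknown trajectory format {fmt!r}")


def _read_pdb(path: str, dt_ps: float, overrides: dict | None) -> TrajectoryFrames:
    frames: list[list[tuple]] = []
    current: list[tuple] | None = None
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                if current:
                    frames.append(current)
                current = []
            elif rec == "ENDMDL":
                if current is not None:
                    frames.append(current)
                    current = None
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    current = []
                try:
                    name = line[12:16].strip()
                    resname = line[17:20].strip()
                    resid = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except (ValueError, IndexError) as exc:
                    raise TrajectoryFormatError(
                        f"{path}: unparseable ATOM record at line {lineno}: {exc}") from exc
                element = line[76:78] if len(line) >= 78 else ""
                current.append((name, resname, resid, x, y, z, element))
    if current:
        frames.append(current)
    if not frames or not frames[0]:
        raise TrajectoryFormatError(f"{path}: no ATOM records found")
    if saw_model and len(frames) >= 1:
        n0 = len(frames[0])
        for i, fr in enumerate(frames):
            if len(fr) != n0:
                raise StructuralError(
                    f"{path}: model {i + 1} has {len(fr)} atoms, expected {n0}")
    first = frames[0]
    names = [a[0] for a in first]
    resnames = [a[1] for a in first]
    resids = np.array([a[2] for a in first])
    masses = np.array([_mass_for(a[0], a[6], overrides, f"{path} atom {i}")
                       for i, a in enumerate(first)])
    topo = Topology(names=names, residue_indices=resids, residue_names=resnames,
                    masses=masses, groups=_assign_groups(resids, resnames))
    coords = np.array([[(a[3], a[4], a[5]) for a in fr] for fr in frames]) / 10.0
    times = np.arange(len(frames), dtype=float) * dt_ps
    return TrajectoryFrames(coordinates=coords, times=times, topology=topo)


def _read_xyz(path: str, dt_ps: float, overrides: dict | None) -> TrajectoryFrames:
    frames = []
    symbols0: list[str] | None = None
    with open(path) as fh:
        lines = fh.readlines()
    i, lineno = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise TrajectoryFormatError(
                f"{path}: expected atom count at line {i + 1}") from exc
        if i + 1 >= len(lines):
            raise TrajectoryFormatError(f"{path}: truncated header at line {i + 1}")
        block = lines[i + 2:i + 2 + natoms]
        if len(block) < natoms:
            raise TrajectoryFormatError(
                f"{path}: truncated frame starting at line {i + 1} "
                f"({len(block)} of {natoms} records)")
        symbols, xyz = [], []
        for j, rec in enumerate(block):
            parts = rec.split()
            if len(parts) < 4:
                raise TrajectoryFormatError(
                    f"{path}: bad XYZ record at line {i + 3 + j}")
            symbols.append(parts[0])
            try:
                xyz.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError as exc:
                raise TrajectoryFormatError(
                    f"{path}: bad coordinate at line {i + 3 + j}") from exc
        if symbols0 is None:
            symbols0 = symbols
        elif symbols != symbols0:
            raise StructuralError(f"{path}: atom records differ between frames")
        frames.append(xyz)
        i += 2 + natoms
    if not frames:
        raise TrajectoryFormatError(f"{path}: empty XYZ file")
    assert symbols0 is not None
    masses = np.array([_mass_for(s, s, overrides, f"{path} atom {i}")
                       for i, s in enumerate(symbols0)])
    n = len(symbols0)
    topo = Topology(names=list(symbols0), residue_indices=np.zeros(n, dtype=int),
                    residue_names=["MOL"] * n, masses=masses, groups=["linker"] * n)
    coords = np.asarray(frames, dtype=float) / 10.0
    times = np.arange(len(frames), dtype=float) * dt_ps
    return TrajectoryFrames(coordinates=coords, times=times, topology=topo)


def write_trajectory(traj: TrajectoryFrames, path, format: str = "auto") -> None:
    """Write frames as multi-model PDB or XYZ (nm -> Angstrom)."""
    path = str(path)
    fmt = format
    if fmt == "auto":
        fmt = "pdb_multimodel" if path.lower().endswith(".pdb") else "xyz"
    topo = traj.topology
    with open(path, "w") as fh:
        if fmt == "pdb_multimodel":
            for m, frame in enumerate(traj.coordinates, start=1):
                fh.write(f"MODEL     {m:4d}\n")
                for i, (x, y, z) in enumerate(frame * 10.0):
                    name = topo.names[i][:4]
                    pad_name = f" {name:<3s}" if len(name) < 4 else name
                    el = _infer_element(topo.names[i])[:2]
                    fh.write(
                        f"ATOM  {i + 1:5d} {pad_name:<4s} {topo.residue_names[i][:3]:<3s} "
                        f"A{topo.residue_indices[i]:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                        f"{el:>2s}\n")
                fh.write("ENDMDL\n")
            fh.write("END\n")
        elif fmt == "xyz":
            for t, frame in zip(traj.times, traj.coordinates):
                fh.write(f"{traj.n_atoms}\n")
                fh.write(f"t = {t} ps\n")
                for i, (x, y, z) in enumerate(frame * 10.0):
                    fh.write(f"{topo.names[i]:<4s} {x:18.10f} {y:18.10f} {z:18.10f}\n")
        else:
            raise TrajectoryFormatError(f"unknown trajectory format {fmt!r}")


def read_trajectory_mdanalysis(topology_path, trajectory_path,
                               dt_ps: float = 1.0) -> TrajectoryFrames:
    """Optional adapter: load DCD/XTC (or anything MDAnalysis reads) into the
    package container.  Disabled (ImportError) when MDAnalysis is absent."""
    import MDAnalysis as mda  # noqa: F401  (optional backend)

    u = mda.Universe(str(topology_path), str(trajectory_path))
    atoms = u.atoms
    resids = atoms.resids.astype(int)
    resnames = [str(r) for r in atoms.resnames]
    topo = Topology(names=[str(n) for n in atoms.names],
                    residue_indices=resids,
                    residue_names=resnames,
                    masses=atoms.masses.astype(float),
                    groups=_assign_groups(resids, resnames))
    coords = np.array([atoms.positions.copy() for _ in u.trajectory]) / 10.0
    times = np.array([ts.time for ts in u.trajectory], dtype=float)
    if times.size > 1 and not np.all(np.diff(times) > 0):
        times = np.arange(len(coords), dtype=float) * dt_ps
    return TrajectoryFrames(coordinates=coords, times=times, topology=topo)


def detect_broken_molecule(traj: TrajectoryFrames,
                           bond_pairs: np.ndarray | None = None,
                           max_bond_nm: float = 0.3) -> bool:
    """Heuristic check for molecules broken across periodic boundaries.

    With no explicit bond list, consecutive atoms of each residue are assumed
    bonded.  Returns True (broken) when any assumed bond exceeds
    ``max_bond_nm`` in any frame.
    """
    if bond_pairs is None:
        ri = traj.topology.residue_indices
        idx = np.arange(traj.n_atoms - 1)
        idx = idx[ri[idx] == ri[idx + 1]]
        bond_pairs = np.column_stack([idx, idx + 1])
    if len(bond_pairs) == 0:
        return False
    d = traj.coordinates[:, bond_pairs[:, 0]] - traj.coordinates[:, bond_pairs[:, 1]]
    return bool((np.linalg.norm(d, axis=-1) > max_bond_nm).any())


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def select(topology: Topology, query) -> np.ndarray:
    """Resolve a selection query to sorted unique atom indices.

    Accepted forms: ``"all"``, ``"group:linker"``, ``"resid:3-8"`` (inclusive,
    also ``"resid:3"``), or an explicit index sequence.  An empty result is
    allowed but flagged with a warning.
    """
    if isinstance(query, (list, tuple, np.ndarray)):
        idx = np.unique(np.asarray(query, dtype=int))
        if idx.size and (idx.min() < 0 or idx.max() >= topology.n_atoms):
            raise SelectionError("selection index out of range")
    elif query == "all":
        idx = topology.atom_ids()
    elif isinstance(query, str) and query.startswith("group:"):
        tag = query.split(":", 1)[1]
        if tag not in GROUP_TAGS:
            raise SelectionError(f"unknown group tag {tag!r}; expected one of {GROUP_TAGS}")
        idx = np.array([i for i, g in enumerate(topology.groups) if g == tag], dtype=int)
    elif isinstance(query, str) and query.startswith("resid:"):
        spec = query.split(":", 1)[1]
        try:
            if "-" in spec:
                lo, hi = (int(s) for s in spec.split("-", 1))
            else:
                lo = hi = int(spec)
        except ValueError as exc:
            raise SelectionError(f"malformed residue range {spec!r}") from exc
        ri = topology.residue_indices
        idx = np.nonzero((ri >= lo) & (ri <= hi))[0]
    else:
        raise SelectionError(f"malformed selection query {query!r}")
    if idx.size == 0:
        warnings.warn(f"selection {query!r} matched no atoms", stacklevel=2)
    return idx


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, reference: np.ndarray,
           weights: np.ndarray | None = None) -> Superposition:
    """Weighted least-squares rigid-body fit of ``mobile`` onto ``reference``.

    Both arrays are (n, 3); ``weights`` default to uniform.  Raises
    :class:`FitError` for degenerate (fewer than 3 atoms or collinear)
    reference geometry, where the rotation is not unique.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    n = mobile.shape[0]
    if n < 3:
        raise FitError(f"need at least 3 fit atoms, got {n}")
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    pc = (w[:, None] * mobile).sum(axis=0)
    qc = (w[:, None] * reference).sum(axis=0)
    P = mobile - pc
    Q = reference - qc
    if np.linalg.matrix_rank(Q, tol=1e-10) < 2:
        raise FitError("degenerate (collinear) fit selection")
    H = P.T @ (w[:, None] * Q)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    fitted = P @ R + qc
    rmsd = float(np.sqrt((w * ((fitted - reference) ** 2).sum(axis=1)).sum()))
    return Superposition(rotation=R, translation=qc - pc @ R, rmsd=rmsd)


def superpose(mobile: TrajectoryFrames, reference_frame: int = 0,
              fit_selection=None) -> tuple[TrajectoryFrames, list[Superposition]]:
    """Least-squares fit every frame onto ``reference_frame`` (mass-weighted
    Kabsch over ``fit_selection``, default all atoms), removing rigid-body
    motion.  The input trajectory is left unmodified."""
    if not 0 <= reference_frame < mobile.n_frames:
        raise FitError(f"reference frame {reference_frame} out of range")
    if fit_selection is None:
        sel = mobile.topology.atom_ids()
    else:
        sel = select(mobile.topology, fit_selection)
    if sel.size == 0:
        raise FitError("empty fit selection")
    weights = mobile.topology.masses[sel]
    ref = mobile.coordinates[reference_frame, sel]
    new_coords = np.empty_like(mobile.coordinates)
    fits = []
    for f in range(mobile.n_frames):
        sp = kabsch(mobile.coordinates[f, sel], ref, weights)
        new_coords[f] = mobile.coordinates[f] @ sp.rotation + sp.translation
        fits.append(sp)
    fitted = replace(mobile, coordinates=new_coords, times=mobile.times.copy())
    return fitted, fits
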
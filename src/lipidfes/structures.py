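"""Molecular structures, trajectories, atom roles and selections.

Reading and writing of standard formats (PDB, GRO, XTC, DCD) is delegated
to MDAnalysis; this module converts everything to the package's internal
conventions at the boundary: lengths in nm, times in ps, 0-based atom
indices, orthorhombic boxes only.

Atom *roles* (hydrophobic carbon, phosphate, tail terminal, backbone CA,
heavy) are assigned deterministically from ``(residue_name, atom_name)``
via a shipped, user-overridable role table keyed to CHARMM36 atom names.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Iterator, Sequence

import numpy as np
import yaml

__all__ = [
    "AtomRecord",
    "MolecularSystem",
    "Frame",
    "Trajectory",
    "SelectionSpec",
    "RoleTable",
    "load_default_role_table",
    "expand_name_range",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "select_atoms",
    "superpose",
    "StructureError",
]

ROLE_NAMES = frozenset(
    {"hydrophobic_carbon", "phosphate", "tail_terminal", "backbone_ca", "heavy"}
)

AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS HSD HSE HSP ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL".split()
)


class StructureError(ValueError):
    """Raised for malformed structure/trajectory input."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: naming, residue membership and derived role flags."""

    index: int
    name: str
    residue_name: str
    residue_id: int
    chain: str = ""
    element: str = ""
    role_flags: frozenset = field(default_factory=frozenset)


@dataclass
class MolecularSystem:
    """Atoms plus one frame of coordinates (nm) and an orthorhombic box (nm)."""

    atoms: list
    coordinates: np.ndarray
    box: np.ndarray

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.shape != (len(self.atoms), 3):
            raise StructureError(
                f"coordinate count {self.coordinates.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise StructureError(f"box must be 3 positive lengths, got {self.box}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def indices_with_role(self, role: str) -> np.ndarray:
        return np.array(
            [a.index for a in self.atoms if role in a.role_flags], dtype=int
        )


@dataclass(frozen=True)
class Frame:
    """One trajectory frame: time (ps), coordinates (nm), box (nm)."""

    time: float
    coordinates: np.ndarray
    box: np.ndarray


class Trajectory:
    """Ordered frames over a fixed topology.

    Frames are either held in memory (fixtures, generators) or streamed
    lazily from an on-disk trajectory through MDAnalysis.  Iteration always
    yields :class:`Frame` objects in nm/ps.
    """

    def __init__(self, topology: MolecularSystem, frames=None, _universe=None):
        self.topology = topology
        self._frames = list(frames) if frames is not None else None
        self._universe = _universe
        if self._frames:
            times = [f.time for f in self._frames]
            if any(t1 < t0 for t0, t1 in zip(times, times[1:])):
                raise StructureError("frame times must be non-decreasing")
            for f in self._frames:
                if f.coordinates.shape[0] != topology.n_atoms:
                    raise StructureError("frame atom count differs from topology")

    @property
    def n_frames(self) -> int:
        if self._frames is not None:
            return len(self._frames)
        return len(self._universe.trajectory)

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[Frame]:
        if self._frames is not None:
            yield from self._frames
            return
        u = self._universe
        n_expected = len(u.trajectory)
        i = -1
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for i, ts in enumerate(u.trajectory):
                    dims = ts.dimensions
                    if dims is None or np.all(dims[:3] == 0):
                        box = self.topology.box
                    else:
                        _check_orthorhombic(dims)
                        box = np.asarray(dims[:3], dtype=float) / 10.0
                    yield Frame(float(ts.time), ts.positions.astype(float) / 10.0, box)
        except (OSError, EOFError, RuntimeError) as exc:  # truncated file
            raise StructureError(
                f"trajectory ended unexpectedly; last complete frame was {i} "
                f"of {n_expected} expected ({exc})"
            ) from exc

    def coordinates_array(self) -> np.ndarray:
        """All frames as a dense (n_frames, n_atoms, 3) array."""
        return np.array([f.coordinates for f in self])

    def times(self) -> np.ndarray:
        return np.array([f.time for f in self])


# ---------------------------------------------------------------------------
# Role table


def _infer_element(name: str) -> str:
    stripped = name.lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0] == "H":
        return "H"
    if len(stripped) >= 2 and stripped[:2].capitalize() in ("Cl", "Na", "Mg", "Ca", "Zn"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def expand_name_range(expr: str) -> list:
    """Expand an atom-name range like ``C23-C216`` or ``C3F-C16F``.

    The two endpoints are split into (longest common prefix, numeric part,
    longest common suffix); the numeric part is swept inclusively.  A name
    without ``-`` is returned as a singleton.
    """
    if "-" not in expr:
        return [expr]
    lo, hi = expr.split("-", 1)
    # longest common prefix
    p = 0
    while p < min(len(lo), len(hi)) and lo[p] == hi[p]:
        p += 1
    # longest common suffix of the remainders
    a, b = lo[p:], hi[p:]
    s = 0
    while s < min(len(a), len(b)) and a[len(a) - 1 - s] == b[len(b) - 1 - s]:
        s += 1
    mid_a = a[: len(a) - s] if s else a
    mid_b = b[: len(b) - s] if s else b
    if not (mid_a.isdigit() and mid_b.isdigit()):
        raise ValueError(f"cannot expand non-numeric range {expr!r}")
    prefix, suffix = lo[:p], a[len(a) - s:] if s else ""
    i0, i1 = int(mid_a), int(mid_b)
    step = 1 if i1 >= i0 else -1
    return [f"{prefix}{k}{suffix}" for k in range(i0, i1 + step, step)]


class RoleTable:
    """Maps (residue_name, atom_name) to role flags and tail definitions."""

    def __init__(self, spec: dict):
        self.spec = spec
        self._residues = {}
        for res, entry in spec.get("residues", {}).items():
            names = {}
            for role in ("phosphate", "hydrophobic_carbon", "tail_terminal"):
                expanded = []
                for expr in entry.get(role, []):
                    expanded.extend(expand_name_range(expr))
                names[role] = set(expanded)
            tails = [
                [n for expr in tail for n in expand_name_range(expr)]
                if isinstance(tail, list)
                else expand_name_range(tail)
                for tail in entry.get("tails", [])
            ]
            # tail terminals default to the last carbon of each tail
            if not names["tail_terminal"]:
                names["tail_terminal"] = {t[-1] for t in tails if t}
            self._residues[res] = {
                "names": names,
                "tails": tails,
                "anchor": entry.get("anchor"),
                "headgroup_backbone": set(
                    n
                    for expr in entry.get("headgroup_backbone", [])
                    for n in expand_name_range(expr)
                ),
            }
        self.hydrophobic_residues = set(spec.get("protein", {}).get(
            "hydrophobic_residues",
            ["ALA", "ILE", "LEU", "MET", "PHE", "TRP", "VAL", "PRO", "CYS"],
        ))

    def residue_entry(self, residue_name: str) -> dict | None:
        return self._residues.get(residue_name)

    def roles_for(self, residue_name: str, atom_name: str, element: str) -> frozenset:
        flags = set()
        if element and element != "H":
            flags.add("heavy")
        entry = self._residues.get(residue_name)
        if entry is not None:
            for role, names in entry["names"].items():
                if atom_name in names:
                    flags.add(role)
        if residue_name in AMINO_ACIDS:
            if atom_name == "CA":
                flags.add("backbone_ca")
            if (
                residue_name in self.hydrophobic_residues
                and element == "C"
                and atom_name not in ("C", "CA")
            ):
                # hydrophobic side-chain carbon
                flags.add("hydrophobic_carbon")
        return frozenset(flags)


def load_default_role_table() -> RoleTable:
    text = resources.files("lipidfes").joinpath("data/roles.yaml").read_text()
    return RoleTable(yaml.safe_load(text))


def load_role_table(path) -> RoleTable:
    with open(path) as fh:
        return RoleTable(yaml.safe_load(fh))


def assign_roles(atoms: Sequence[AtomRecord], table: RoleTable) -> list:
    out = []
    for a in atoms:
        elem = a.element or _infer_element(a.name)
        out.append(
            replace(a, element=elem, role_flags=table.roles_for(a.residue_name, a.name, elem))
        )
    return out


# ---------------------------------------------------------------------------
# Readers / writers (MDAnalysis behind the boundary)


def _check_orthorhombic(dims) -> None:
    angles = np.asarray(dims[3:6], dtype=float)
    if not np.allclose(angles, 90.0, atol=1e-3):
        raise StructureError(f"only orthorhombic boxes supported, angles {angles}")


def _system_from_universe(u, role_table: RoleTable) -> MolecularSystem:
    dims = u.dimensions
    if dims is None or np.all(np.asarray(dims)[:3] == 0):
        raise StructureError("structure file carries no box information")
    _check_orthorhombic(dims)
    box = np.asarray(dims[:3], dtype=float) / 10.0
    atoms = []
    have_chain = hasattr(u.atoms, "chainIDs")
    for i, a in enumerate(u.atoms):
        atoms.append(
            AtomRecord(
                index=i,
                name=str(a.name),
                residue_name=str(a.resname),
                residue_id=int(a.resid),
                chain=str(a.chainID) if have_chain else "",
                element="",
            )
        )
    atoms = assign_roles(atoms, role_table)
    return MolecularSystem(atoms, u.atoms.positions.astype(float) / 10.0, box)


def read_structure(path, format: str | None = None, role_table: RoleTable | None = None) -> MolecularSystem:
    """Read a PDB or GRO file into a :class:`MolecularSystem` (nm)."""
    import MDAnalysis as mda

    role_table = role_table or load_default_role_table()
    kwargs = {}
    if format is not None:
        fmt = format.upper()
        if fmt not in ("PDB", "GRO"):
            raise ValueError(f"unsupported structure format {format!r}")
        kwargs["topology_format"] = fmt
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), **kwargs)
    except (ValueError, OSError) as exc:
        raise StructureError(f"failed to parse {path}: {exc}") from exc
    return _system_from_universe(u, role_table)


def _universe_from_system(system: MolecularSystem):
    import MDAnalysis as mda

    n_res = len({(a.residue_id, a.residue_name) for a in system.atoms})
    resids_seen: dict = {}
    residx = np.empty(system.n_atoms, dtype=int)
    resnames, resids = [], []
    for i, a in enumerate(system.atoms):
        key = (a.residue_id, a.residue_name)
        if key not in resids_seen:
            resids_seen[key] = len(resids_seen)
            resnames.append(a.residue_name)
            resids.append(a.residue_id)
        residx[i] = resids_seen[key]
    u = mda.Universe.empty(
        system.n_atoms,
        n_residues=len(resids),
        atom_resindex=residx,
        residue_segindex=np.zeros(len(resids), dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.name for a in system.atoms])
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", resids)
    u.atoms.positions = system.coordinates * 10.0
    u.dimensions = np.array([*(system.box * 10.0), 90.0, 90.0, 90.0])
    return u


def write_structure(system: MolecularSystem, path) -> None:
    """Write a system to GRO or PDB (by file extension), converting nm→Å."""
    u = _universe_from_system(system)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_trajectory(path, topology: MolecularSystem, format: str | None = None) -> Trajectory:
    """Open a trajectory (XTC/DCD/multi-frame PDB or GRO) over a topology."""
    u = _universe_from_system(topology)
    kwargs = {"format": format.upper()} if format else {}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.load_new(str(path), **kwargs)
    except (ValueError, OSError) as exc:
        raise StructureError(f"failed to open trajectory {path}: {exc}") from exc
    if u.trajectory.n_atoms != topology.n_atoms:
        raise StructureError(
            f"trajectory has {u.trajectory.n_atoms} atoms but topology has "
            f"{topology.n_atoms}"
        )
    return Trajectory(topology, _universe=u)


def write_trajectory(trajectory: Trajectory, path) -> None:
    """Write frames to a multi-frame PDB (or any MDAnalysis-writable format)."""
    import MDAnalysis as mda

    u = _universe_from_system(trajectory.topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), trajectory.topology.n_atoms, multiframe=True) as w:
            for fr in trajectory:
                u.atoms.positions = fr.coordinates * 10.0
                u.dimensions = np.array([*(fr.box * 10.0), 90.0, 90.0, 90.0])
                u.trajectory.ts.time = fr.time
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# Selections


@dataclass(frozen=True)
class SelectionSpec:
    """Declarative atom selection.

    All stated conditions must hold (logical AND); each list is a set of
    alternatives (logical OR).  ``atom_names`` entries may be ranges like
    ``C23-C216`` which expand over the numeric part.
    """

    residue_names: tuple | None = None
    residue_ids: tuple | None = None  # ints and/or (lo, hi) inclusive ranges
    atom_names: tuple | None = None
    role_flags: tuple | None = None
    chains: tuple | None = None

    def __post_init__(self):
        for f in ("residue_names", "residue_ids", "atom_names", "role_flags", "chains"):
            v = getattr(self, f)
            if v is not None and not isinstance(v, tuple):
                object.__setattr__(self, f, tuple(v))
        if self.role_flags:
            unknown = set(self.role_flags) - ROLE_NAMES
            if unknown:
                raise ValueError(f"unknown role flags {sorted(unknown)}")


def _resid_match(rid: int, patterns) -> bool:
    for p in patterns:
        if isinstance(p, (tuple, list)):
            if p[0] <= rid <= p[1]:
                return True
        elif rid == p:
            return True
    return False


def select_atoms(system: MolecularSystem, spec: SelectionSpec) -> np.ndarray:
    """Evaluate a selection to a sorted, unique 0-based index array.

    An empty result is allowed (with a warning) so that absent residue or
    atom names degrade gracefully.
    """
    names = None
    if spec.atom_names is not None:
        names = set()
        for expr in spec.atom_names:
            names.update(expand_name_range(expr))
    out = []
    for a in system.atoms:
        if spec.residue_names is not None and a.residue_name not in spec.residue_names:
            continue
        if spec.residue_ids is not None and not _resid_match(a.residue_id, spec.residue_ids):
            continue
        if names is not None and a.name not in names:
            continue
        if spec.chains is not None and a.chain not in spec.chains:
            continue
        if spec.role_flags is not None and not set(spec.role_flags) <= a.role_flags:
            continue
        out.append(a.index)
    if not out and (spec.residue_names or spec.atom_names):
        warnings.warn(f"selection {spec} matched no atoms", stacklevel=2)
    return np.array(sorted(set(out)), dtype=int)


# ---------------------------------------------------------------------------
# Superposition


def superpose(
    mobile: np.ndarray, reference: np.ndarray, indices: Sequence[int] | None = None
):
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    The rotation/translation is determined over ``indices`` (all atoms if
    None) and applied to every atom of ``mobile``.  Returns
    ``(transformed, rmsd)`` with the RMSD computed post-fit over the fit
    selection.  Proper rotations only (Kabsch with reflection correction).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = np.arange(len(mobile)) if indices is None else np.asarray(indices, dtype=int)
    if len(idx) < 3:
        raise ValueError("need at least 3 atoms to superpose")
    A = mobile[idx]
    B = reference[idx]
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    if np.linalg.matrix_rank(A0, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) fit selection")
    H = A0.T @ B0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    transformed = (mobile - ca) @ R.T + cb
    diff = transformed[idx] - B
    rmsd = float(np.sqrt((diff**2).sum() / len(idx)))
    return transformed, rmsd
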
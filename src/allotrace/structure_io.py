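"""Structures, trajectories and atom selections.

The interchange format is plain fixed-column PDB; a multi-model PDB
(``MODEL``/``ENDMDL`` blocks sharing one topology) carries a trajectory.
Coordinates are Ångström throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "Selection",
    "PDBParseError",
    "SelectionError",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "resolve_selection",
]

#: Atom names making up the peptide backbone in selection expressions.
BACKBONE_NAMES = ("N", "CA", "C", "O")


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input."""


class SelectionError(ValueError):
    """Raised for invalid or empty atom selections."""


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record: identity plus Cartesian coordinates in Å."""

    serial: int
    name: str
    residue_name: str
    residue_id: int
    chain: str
    coordinates: np.ndarray  # shape (3,), Å
    element: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.serial}: coordinates must be a finite 3-vector")
        if not self.name:
            raise ValueError(f"atom {self.serial}: empty atom name")
        object.__setattr__(self, "coordinates", coords)


class Structure:
    """An ordered list of atoms with a derived residue table."""

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms: list[AtomRecord] = list(atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array of positions, Å."""
        return np.array([a.coordinates for a in self.atoms], dtype=float)

    @property
    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, residue_id, residue_name) triples."""
        seen: dict[tuple[str, int], str] = {}
        out: list[tuple[str, int, str]] = []
        for a in self.atoms:
            key = (a.chain, a.residue_id)
            if key not in seen:
                seen[key] = a.residue_name
                out.append((a.chain, a.residue_id, a.residue_name))
        return out

    def with_coordinates(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected coordinates of shape ({self.n_atoms}, 3), got {coords.shape}")
        return Structure(
            [
                AtomRecord(a.serial, a.name, a.residue_name, a.residue_id, a.chain, c, a.element)
                for a, c in zip(self.atoms, coords)
            ]
        )

    def residue_atom_indices(self, residue_id: int, chain: str | None = None) -> list[int]:
        idx = [
            i
            for i, a in enumerate(self.atoms)
            if a.residue_id == residue_id and (chain is None or a.chain == chain)
        ]
        return idx


class Trajectory:
    """Frames sharing one topology.

    ``topology`` holds the atoms of frame 0; ``frames`` is a
    (n_frames, n_atoms, 3) coordinate array in Å.
    """

    def __init__(
        self,
        topology: Structure,
        frames: np.ndarray,
        frame_times: np.ndarray | None = None,
    ):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[1:] != (topology.n_atoms, 3):
            raise ValueError(
                f"frames must have shape (n_frames, {topology.n_atoms}, 3), got {frames.shape}"
            )
        if frames.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        self.topology = topology
        self.frames = frames
        if frame_times is not None:
            frame_times = np.asarray(frame_times, dtype=float)
            if frame_times.shape != (frames.shape[0],):
                raise ValueError("frame_times length must equal n_frames")
        self.frame_times = frame_times

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]

    def slice_frames(self, start: int, stop: int | None = None) -> "Trajectory":
        frames = self.frames[start:stop]
        times = self.frame_times[start:stop] if self.frame_times is not None else None
        return Trajectory(self.topology, frames, times)


@dataclass
class Selection:
    """A resolved atom selection: the expression plus strictly-increasing indices."""

    expression: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1 or (idx.size > 1 and not np.all(np.diff(idx) > 0)):
            raise ValueError("selection indices must be strictly increasing")
        self.indices = idx

    def __len__(self) -> int:
        return int(self.indices.size)


# ---------------------------------------------------------------------------
# PDB reading / writing (fixed columns)
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> AtomRecord | None:
    """Parse one ATOM/HETATM line; return None if the altloc is filtered out."""
    altloc = line[16:17].strip() if len(line) > 16 else ""
    if altloc not in ("", "A"):
        return None
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21:22].strip() or "A"
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from None
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = re.sub(r"[^A-Za-z]", "", name)[:1]
    return AtomRecord(serial, name, resname, resid, chain, np.array([x, y, z]), element)


def _parse_models(text: str) -> list[list[AtomRecord]]:
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    in_model = False
    saw_model_record = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model_record = True
            in_model = True
            current = []
        elif rec == "ENDMDL":
            in_model = False
            models.append(current)
            current = []
        elif rec in ("ATOM", "HETATM"):
            atom = _parse_atom_line(line, lineno)
            if atom is not None:
                current.append(atom)
    if current and (in_model or not saw_model_record):
        models.append(current)
    return [m for m in models if m] if saw_model_record else ([current] if current else [])


def read_pdb(path: str | Path) -> Structure:
    """Read a PDB file; for multi-model files, MODEL 1 only."""
    text = Path(path).read_text()
    models = _parse_models(text)
    if not models:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    return Structure(models[0])


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a multi-model PDB as a trajectory (frames ordered by MODEL block).

    Every model must contain the same number of atoms.
    """
    text = Path(path).read_text()
    models = _parse_models(text)
    if not models:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    n0 = len(models[0])
    for m, atoms in enumerate(models, start=1):
        if len(atoms) != n0:
            raise PDBParseError(f"model {m}: {len(atoms)} atoms, expected {n0}")
    topology = Structure(models[0])
    frames = np.array([[a.coordinates for a in m] for m in models], dtype=float)
    return Trajectory(topology, frames)


def _format_atom(a: AtomRecord, serial: int) -> str:
    # PDB convention: atom names of <4 chars start in column 14
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (
        f"ATOM  {serial:5d} {name:<4s} {a.residue_name:<3s} {a.chain:1s}"
        f"{a.residue_id:4d}    {a.coordinates[0]:8.3f}{a.coordinates[1]:8.3f}"
        f"{a.coordinates[2]:8.3f}{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}"
    )


def write_pdb(structure: Structure, path: str | Path) -> None:
    lines = [_format_atom(a, i + 1) for i, a in enumerate(structure.atoms)]
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    lines: list[str] = []
    for f in range(traj.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        frame = traj.frames[f]
        for i, a in enumerate(traj.topology.atoms):
            moved = AtomRecord(a.serial, a.name, a.residue_name, a.residue_id, a.chain, frame[i], a.element)
            lines.append(_format_atom(moved, i + 1))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Selection language
# ---------------------------------------------------------------------------
#
# Grammar (case-insensitive keywords):
#   expr    := clause ("and" clause)* | clause ("or" clause)*
#   clause  := "backbone" | "calpha" | "all"
#            | "name" NAME[,NAME...]
#            | "resname" NAME[,NAME...]
#            | "chain" CHAR[,CHAR...]
#            | "resid" RANGE[,RANGE...]      RANGE := N | N-M (inclusive)
# Mixing "and" and "or" in one expression is rejected (keeps resolution
# trivially order-independent); parenthesised grammar is a non-goal.

def _clause_mask(tokens: list[str], topology: Structure) -> np.ndarray:
    n = topology.n_atoms
    head = tokens[0].lower()
    if head == "all":
        return np.ones(n, dtype=bool)
    if head == "backbone":
        return np.array([a.name in BACKBONE_NAMES for a in topology.atoms])
    if head == "calpha":
        return np.array([a.name == "CA" for a in topology.atoms])
    if len(tokens) < 2:
        raise SelectionError(f"selection keyword '{tokens[0]}' needs an argument")
    args = [t for tok in tokens[1:] for t in tok.split(",") if t]
    if head == "name":
        names = {a.upper() for a in args}
        return np.array([a.name.upper() in names for a in topology.atoms])
    if head == "resname":
        names = {a.upper() for a in args}
        return np.array([a.residue_name.upper() in names for a in topology.atoms])
    if head == "chain":
        chains = set(args)
        return np.array([a.chain in chains for a in topology.atoms])
    if head == "resid":
        mask = np.zeros(n, dtype=bool)
        resids = np.array([a.residue_id for a in topology.atoms])
        for spec in args:
            m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", spec)
            if not m:
                raise SelectionError(f"bad resid range '{spec}'")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) is not None else lo
            mask |= (resids >= lo) & (resids <= hi)
        return mask
    raise SelectionError(f"unknown selection keyword '{tokens[0]}'")


def resolve_selection(topology: Structure, expression: str) -> Selection:
    """Resolve a selection expression to strictly-increasing atom indices.

    Raises :class:`SelectionError` on unknown tokens or when the selection
    matches no atoms (silent empties would corrupt downstream math).
    """
    words = expression.split()
    if not words:
        raise SelectionError("empty selection expression")
    lowered = [w.lower() for w in words]
    has_and, has_or = "and" in lowered, "or" in lowered
    if has_and and has_or:
        raise SelectionError("mixing 'and' and 'or' in one expression is not supported")
    op = "and" if has_and or not has_or else "or"
    clauses: list[list[str]] = [[]]
    for w in words:
        if w.lower() in ("and", "or"):
            if not clauses[-1]:
                raise SelectionError(f"misplaced '{w}' in selection")
            clauses.append([])
        else:
            clauses[-1].append(w)
    if not clauses[-1]:
        raise SelectionError("selection ends with a dangling operator")
    masks = [_clause_mask(c, topology) for c in clauses]
    mask = masks[0]
    for m in masks[1:]:
        mask = (mask & m) if op == "and" else (mask | m)
    indices = np.flatnonzero(mask)
    if indices.size == 0:
        raise SelectionError(f"selection '{expression}' matches no atoms")
    return Selection(expression, indices)
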
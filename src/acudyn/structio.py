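"""Structure and trajectory I/O with deterministic atom selections.

Coordinates are handled as plain numpy arrays so that the downstream
geometry, landscape and stability stages never touch file formats.  PDB
parsing is delegated to :mod:`gemmi`; a light column check runs first so
that malformed fixed-column records are reported with their line number.

Conventions
-----------
* Residue numbering is 1-based and ranges are inclusive, e.g. the
  N-terminal CBS modules of an AcuB monomer are residues 1-82.
* Alternate locations are collapsed to the highest-occupancy conformer
  (ties resolved to the first record in the file).
* Insertion-coded residues are kept as distinct residues in file order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "Selection",
    "PDBParseError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "select_atoms",
]


class PDBParseError(ValueError):
    """Raised for malformed fixed-column PDB records (reports line number)."""


@dataclass(frozen=True)
class Atom:
    """Metadata for one atom; coordinates live in the parent Structure."""

    chain: str
    resnum: int
    resname: str
    name: str
    element: str
    occupancy: float = 1.0
    b_factor: float = 0.0
    icode: str = ""
    het: bool = False


@dataclass
class Structure:
    """A single model: per-atom metadata plus an (n, 3) coordinate array in A."""

    atoms: list[Atom]
    coords: np.ndarray
    model_id: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("structure contains non-finite coordinates")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(self.atoms, np.array(coords, dtype=float), self.model_id)


@dataclass
class Trajectory:
    """Ordered frames sharing one topology.

    ``frames`` is an (n_frames, n_atoms, 3) array; frame order is the
    storage order and is preserved on round-trip.
    """

    topology: Structure
    frames: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (self.topology.n_atoms, 3):
            raise ValueError(
                f"frames shape {self.frames.shape} incompatible with topology "
                f"of {self.topology.n_atoms} atoms"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")

    def __len__(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_frames(self) -> int:
        return len(self)

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


@dataclass(frozen=True)
class Selection:
    """Declarative atom selection resolved against a Structure.

    All criteria are combined with logical AND; ``None`` means
    "no constraint".  ``residue_range`` is a 1-based inclusive (lo, hi)
    pair, matching the residue-range phrasing used throughout the
    analysis (residues 1-82, 135-214, ...).
    """

    chains: frozenset[str] | None = None
    residue_range: tuple[int, int] | None = None
    atom_names: frozenset[str] | None = None
    resnames: frozenset[str] | None = None
    elements: frozenset[str] | None = None
    exclude_elements: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if lo > hi:
                raise ValueError(f"residue range lo={lo} > hi={hi}")
        # normalise iterables passed as plain sets/lists
        for fname in ("chains", "atom_names", "resnames", "elements", "exclude_elements"):
            v = getattr(self, fname)
            if v is not None and not isinstance(v, frozenset):
                object.__setattr__(self, fname, frozenset(v))

    def matches(self, atom: Atom) -> bool:
        if self.chains is not None and atom.chain not in self.chains:
            return False
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if not (lo <= atom.resnum <= hi):
                return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        if self.resnames is not None and atom.resname not in self.resnames:
            return False
        el = atom.element.upper()
        if self.elements is not None and el not in {e.upper() for e in self.elements}:
            return False
        if self.exclude_elements is not None and el in {
            e.upper() for e in self.exclude_elements
        }:
            return False
        return True


# the "not H" filter used for MD alignment ("non-hydrogen atoms")
NOH = Selection(exclude_elements=frozenset({"H", "D"}))


def _as_text(source: str | Path) -> str:
    if isinstance(source, Path):
        return source.read_text()
    s = str(source)
    if "\n" not in s and (s.endswith(".pdb") or s.endswith(".ent") or Path(s).exists()):
        return Path(s).read_text()
    return s


def _check_fixed_columns(text: str) -> None:
    """Validate coordinate fields of ATOM/HETATM records before parsing."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: coordinate record too short")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fieldtxt = line[lo:hi]
            try:
                float(fieldtxt)
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed {what} coordinate field {fieldtxt!r}"
                ) from None
        try:
            int(line[22:26])
        except ValueError:
            raise PDBParseError(
                f"line {lineno}: malformed residue number {line[22:26]!r}"
            ) from None


def _structure_from_gemmi_model(model: gemmi.Model, model_id: int) -> Structure:
    atoms: list[Atom] = []
    coords: list[tuple[float, float, float]] = []
    for chain in model:
        for residue in chain:
            # collapse altlocs: group by atom name, keep highest occupancy
            # (ties -> first occurrence in file order)
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for at in residue:
                if at.name not in best:
                    best[at.name] = at
                    order.append(at.name)
                elif at.occ > best[at.name].occ:
                    best[at.name] = at
            for name in order:
                at = best[name]
                atoms.append(
                    Atom(
                        chain=chain.name,
                        resnum=residue.seqid.num,
                        resname=residue.name,
                        name=at.name,
                        element=at.element.name,
                        occupancy=float(at.occ),
                        b_factor=float(at.b_iso),
                        icode=residue.seqid.icode.strip(),
                        het=residue.het_flag == "H",
                    )
                )
                coords.append((at.pos.x, at.pos.y, at.pos.z))
    return Structure(atoms, np.array(coords, dtype=float).reshape(-1, 3), model_id)


def _read_gemmi(text: str) -> gemmi.Structure:
    _check_fixed_columns(text)
    st = gemmi.read_pdb_string(text)
    return st


def read_structure(source: str | Path, model: int = 1) -> Structure:
    """Read one model of a PDB file (path or text) into a Structure.

    Parameters
    ----------
    source:
        Path to a PDB file, or PDB-format text.
    model:
        1-based model number (MODEL record value; single-model files are
        model 1).
    """
    st = _read_gemmi(_as_text(source))
    for m in st:
        if m.num == model:
            return _structure_from_gemmi_model(m, model)
    raise KeyError(
        f"model {model} not found; file has models "
        f"{[m.num for m in st]}"
    )


def read_trajectory(
    topology: str | Path | Structure,
    frames: str | Path,
    format: str = "pdb",
) -> Trajectory:
    """Read an ordered multi-frame coordinate file against a topology.

    ``format`` is ``"pdb"`` (multi-model PDB, the interchange default) or
    ``"xyz"``.  Every frame must have exactly the topology's atom count;
    a mismatch is reported with the offending 0-based frame index.
    """
    top = topology if isinstance(topology, Structure) else read_structure(topology)
    fmt = format.lower()
    if fmt in ("pdb", "multi-model-pdb"):
        st = _read_gemmi(_as_text(frames))
        frame_list = []
        for k, m in enumerate(st):
            c = np.array(
                [[a.pos.x, a.pos.y, a.pos.z] for ch in m for r in ch for a in r],
                dtype=float,
            ).reshape(-1, 3)
            if c.shape[0] != top.n_atoms:
                raise ValueError(
                    f"frame {k}: atom count {c.shape[0]} does not match "
                    f"topology ({top.n_atoms})"
                )
            frame_list.append(c)
        if not frame_list:
            raise ValueError("no frames found in trajectory file")
        return Trajectory(top, np.stack(frame_list))
    if fmt == "xyz":
        return Trajectory(top, _read_xyz(_as_text(frames), top.n_atoms))
    raise ValueError(f"unknown trajectory format {format!r}")


def _read_xyz(text: str, n_atoms: int) -> np.ndarray:
    """Minimal XYZ multi-frame reader (count / comment / element x y z)."""
    lines = text.splitlines()
    i = 0
    frames = []
    k = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"frame {k}: bad atom-count line {lines[i]!r}") from exc
        block = lines[i + 2 : i + 2 + count]
        if len(block) < count:
            raise ValueError(f"frame {k}: truncated (expected {count} atom lines)")
        coords = np.array(
            [[float(x) for x in ln.split()[1:4]] for ln in block], dtype=float
        )
        if coords.shape[0] != n_atoms:
            raise ValueError(
                f"frame {k}: atom count {coords.shape[0]} does not match "
                f"topology ({n_atoms})"
            )
        frames.append(coords)
        i += 2 + count
        k += 1
    if not frames:
        raise ValueError("no frames found in XYZ file")
    return np.stack(frames)


def _format_atom_line(serial: int, atom: Atom, xyz: np.ndarray) -> str:
    record = "HETATM" if atom.het else "ATOM  "
    name = atom.name
    # PDB v3.3 alignment: 1-3 char names start in column 14 unless 4 chars
    if len(name) < 4 and len(atom.element) < 2:
        name = f" {name}"
    return (
        f"{record}{serial:>5d} {name:<4s} {atom.resname:<3s} {atom.chain:1s}"
        f"{atom.resnum:>4d}{atom.icode or ' ':1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
        f"          {atom.element:>2s}"
    )


def write_structure(structure: Structure, path: str | Path | None = None) -> str:
    """Serialize a Structure to PDB text (3-decimal coordinate precision)."""
    lines = [
        _format_atom_line(i + 1, a, structure.coords[i])
        for i, a in enumerate(structure.atoms)
    ]
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def write_trajectory(
    traj: Trajectory, path: str | Path | None = None, format: str = "pdb"
) -> str:
    """Serialize a Trajectory to multi-model PDB (default) or XYZ text."""
    fmt = format.lower()
    chunks: list[str] = []
    if fmt in ("pdb", "multi-model-pdb"):
        for k in range(traj.n_frames):
            chunks.append(f"MODEL     {k + 1:>4d}")
            chunks.extend(
                _format_atom_line(i + 1, a, traj.frames[k, i])
                for i, a in enumerate(traj.topology.atoms)
            )
            chunks.append("ENDMDL")
        chunks.append("END")
    elif fmt == "xyz":
        for k in range(traj.n_frames):
            chunks.append(str(traj.topology.n_atoms))
            chunks.append(f"frame {k}")
            chunks.extend(
                f"{a.element or 'X'} {traj.frames[k, i, 0]:.6f} "
                f"{traj.frames[k, i, 1]:.6f} {traj.frames[k, i, 2]:.6f}"
                for i, a in enumerate(traj.topology.atoms)
            )
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    text = "\n".join(chunks) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def select_atoms(structure: Structure, selection: Selection) -> np.ndarray:
    """Resolve a Selection to a deterministic, ordered atom index array.

    Ordering is (chain id, residue number, file order); repeated calls on
    the same structure give identical results.  An empty result is valid.
    """
    hits = [
        (a.chain, a.resnum, i)
        for i, a in enumerate(structure.atoms)
        if selection.matches(a)
    ]
    hits.sort()
    return np.array([i for _, _, i in hits], dtype=int)
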
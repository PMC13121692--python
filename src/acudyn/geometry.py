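"""Superposition, RMSD and distance measurements.

Implements the rigid-body toolbox shared by the MD pipeline (alignment to
a reference frame with non-hydrogen atoms) and by crystal-structure
comparisons (superposition on the Bateman domain, residues 1-132, and
per-residue displacement read-out such as the His31 C-alpha shift).

Superposition uses the Kabsch algorithm: SVD of the covariance matrix of
centered paired coordinates, with the sign of the smallest singular
vector corrected so only proper rotations (det = +1) are returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd

from .structio import Atom, Selection, Structure, select_atoms

logger = logging.getLogger(__name__)

__all__ = [
    "SuperpositionResult",
    "atomic_mass",
    "masses_for",
    "center_of_mass",
    "rmsd",
    "kabsch_superpose",
    "per_residue_displacement",
    "AtomSpec",
    "atom_pair_distance",
    "ligand_b_factor_summary",
    "classify_nucleotide_site",
]


def atomic_mass(element: str) -> float:
    """Standard atomic weight in Da; unknown elements fall back to 1.0."""
    el = gemmi.Element(element.capitalize() if element else "X")
    if el.name != "X" and el.weight > 0:
        return float(el.weight)
    logger.warning("unknown element %r: using unit mass", element)
    return 1.0


def masses_for(structure: Structure, indices: np.ndarray, mass_mode: str = "atomic") -> np.ndarray:
    if mass_mode == "unit":
        return np.ones(len(indices))
    if mass_mode != "atomic":
        raise ValueError(f"mass_mode must be 'atomic' or 'unit', got {mass_mode!r}")
    return np.array([atomic_mass(structure.atoms[i].element) for i in indices])


def center_of_mass(
    coords: np.ndarray,
    indices: np.ndarray | None = None,
    masses: np.ndarray | None = None,
) -> np.ndarray:
    """Mass-weighted mean position of the selected atoms (A).

    ``coords`` may be a frame (n, 3) array; ``indices`` selects atoms
    (all atoms when None); ``masses`` defaults to unit masses.
    """
    coords = np.asarray(coords, dtype=float)
    sub = coords if indices is None else coords[np.asarray(indices, dtype=int)]
    if sub.shape[0] == 0:
        raise ValueError("center of mass of an empty selection is undefined")
    if masses is None:
        return sub.mean(axis=0)
    m = np.asarray(masses, dtype=float)
    if m.shape[0] != sub.shape[0]:
        raise ValueError("masses length does not match selection")
    return (sub * m[:, None]).sum(axis=0) / m.sum()


def rmsd(a: np.ndarray, b: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Plain (optionally weighted) root-mean-square deviation, no fitting."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d2 = ((a - b) ** 2).sum(axis=1)
    if weights is None:
        return float(np.sqrt(d2.mean()))
    w = np.asarray(weights, dtype=float)
    return float(np.sqrt((w * d2).sum() / w.sum()))


@dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares rigid fit: y ~ rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    fitted_rmsd: float
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[SuperpositionResult, np.ndarray]:
    """Optimal proper rotation + translation of ``mobile`` onto ``reference``.

    Returns the fit and the transformed mobile coordinates.  Reflections
    are excluded by flipping the sign of the smallest singular value when
    det(V U^T) < 0.  Requires >= 3 non-collinear atom pairs.
    """
    x = np.asarray(mobile, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    n = x.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 atom pairs, got {n}")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    xc = (w[:, None] * x).sum(axis=0) / wsum
    yc = (w[:, None] * y).sum(axis=0) / wsum
    x0 = x - xc
    y0 = y - yc
    cov = (w[:, None] * x0).T @ y0
    u, s, vt = np.linalg.svd(cov)
    if np.linalg.matrix_rank(cov, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) configuration: rank < 2")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    trans = yc - rot @ xc
    moved = x @ rot.T + trans
    res = SuperpositionResult(rot, trans, rmsd(moved, y, w), n)
    return res, moved


def _matched_pairs(
    a: Structure,
    b: Structure,
    selection: Selection,
    chain_map: dict[str, str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of atoms matched by (mapped chain, resnum, icode, atom name)."""
    chain_map = chain_map or {}
    idx_a = select_atoms(a, selection)
    key_b = {
        (at.chain, at.resnum, at.icode, at.name): j for j, at in enumerate(b.atoms)
    }
    ia, ib = [], []
    for i in idx_a:
        at = a.atoms[i]
        key = (chain_map.get(at.chain, at.chain), at.resnum, at.icode, at.name)
        j = key_b.get(key)
        if j is not None:
            ia.append(i)
            ib.append(j)
    return np.array(ia, dtype=int), np.array(ib, dtype=int)


def per_residue_displacement(
    mobile: Structure,
    reference: Structure,
    fit_selection: Selection,
    report_selection: Selection,
    chain_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Superpose ``mobile`` on ``reference`` over the fit selection, then
    report per-atom displacements |dxyz| for the report selection.

    The fit is computed once on the fit selection (e.g. Bateman-domain
    C-alpha atoms, residues 1-132) and applied rigidly; reported atoms are
    NOT re-fitted, so a moving loop shows its full displacement.
    ``chain_map`` maps mobile chain ids onto reference chain ids (identity
    by default).

    Returns a DataFrame with columns chain, resnum, resname, atom,
    displacement_A.
    """
    fit_m, fit_r = _matched_pairs(mobile, reference, fit_selection, chain_map)
    if len(fit_m) == 0:
        raise ValueError("fit selection matched no atom pairs")
    fit, _ = kabsch_superpose(mobile.coords[fit_m], reference.coords[fit_r])
    moved = fit.apply(mobile.coords)
    rep_m, rep_r = _matched_pairs(mobile, reference, report_selection, chain_map)
    if len(rep_m) == 0:
        raise ValueError("report selection matched no atom pairs")
    disp = np.linalg.norm(moved[rep_m] - reference.coords[rep_r], axis=1)
    rows = [
        {
            "chain": mobile.atoms[i].chain,
            "resnum": mobile.atoms[i].resnum,
            "resname": mobile.atoms[i].resname,
            "atom": mobile.atoms[i].name,
            "displacement_A": d,
        }
        for i, d in zip(rep_m, disp)
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AtomSpec:
    """Unique atom address: chain + residue number (+ name, resname)."""

    chain: str | None = None
    resnum: int | None = None
    name: str | None = None
    resname: str | None = None

    def matches(self, atom: Atom) -> bool:
        return (
            (self.chain is None or atom.chain == self.chain)
            and (self.resnum is None or atom.resnum == self.resnum)
            and (self.name is None or atom.name == self.name)
            and (self.resname is None or atom.resname == self.resname)
        )

    @classmethod
    def parse(cls, text: str) -> "AtomSpec":
        """Parse 'chain/resnum/atom' or 'chain/resname resnum/atom' text."""
        parts = text.split("/")
        if len(parts) != 3:
            raise ValueError(f"atom spec {text!r} is not 'chain/resnum/atom'")
        chain, mid, name = parts
        resname = None
        if " " in mid.strip():
            resname, num = mid.split()
        else:
            num = mid
        return cls(chain or None, int(num), name or None, resname)


def _resolve_unique(structure: Structure, spec: AtomSpec) -> int:
    hits = [i for i, a in enumerate(structure.atoms) if spec.matches(a)]
    if len(hits) == 1:
        return hits[0]
    if not hits:
        raise KeyError(f"no atom matches {spec}")
    cands = ", ".join(
        f"{structure.atoms[i].chain}/{structure.atoms[i].resname} "
        f"{structure.atoms[i].resnum}/{structure.atoms[i].name}"
        for i in hits[:10]
    )
    raise KeyError(f"ambiguous atom spec {spec}: candidates {cands}")


def atom_pair_distance(structure: Structure, spec1: AtomSpec | str, spec2: AtomSpec | str) -> float:
    """Euclidean distance (A) between two uniquely-resolved atoms."""
    s1 = AtomSpec.parse(spec1) if isinstance(spec1, str) else spec1
    s2 = AtomSpec.parse(spec2) if isinstance(spec2, str) else spec2
    i = _resolve_unique(structure, s1)
    j = _resolve_unique(structure, s2)
    return float(np.linalg.norm(structure.coords[i] - structure.coords[j]))


def ligand_b_factor_summary(
    structure: Structure,
    resname: str,
    chain: str | None = None,
    resnum: int | None = None,
) -> pd.DataFrame:
    """Mean/min/max B-factor (A^2) per matching ligand residue.

    Used e.g. for bound AMP/ADP molecules, whose B-factors report how well
    a nucleotide is defined in each binding site.
    """
    groups: dict[tuple[str, int, str], list[float]] = {}
    for a in structure.atoms:
        if a.resname != resname:
            continue
        if chain is not None and a.chain != chain:
            continue
        if resnum is not None and a.resnum != resnum:
            continue
        groups.setdefault((a.chain, a.resnum, a.icode), []).append(a.b_factor)
    if not groups:
        raise KeyError(f"no residue {resname!r} (chain={chain}, resnum={resnum})")
    rows = [
        {
            "chain": c,
            "resnum": r,
            "resname": resname,
            "n_atoms": len(bs),
            "b_mean": float(np.mean(bs)),
            "b_min": float(np.min(bs)),
            "b_max": float(np.max(bs)),
        }
        for (c, r, _), bs in sorted(groups.items())
    ]
    return pd.DataFrame(rows)


#: adenine atoms whose hydrogen-bond partners discriminate the two site types
_ADENINE_PROBE_ATOMS = ("N6", "N1")
#: protein backbone atoms eligible as hydrogen-bond partners
_BACKBONE = {"N", "CA", "C", "O"}


def classify_nucleotide_site(
    structure: Structure,
    ligand_chain: str,
    ligand_resnum: int,
    type1_residues: frozenset[int] = frozenset({13, 35}),
    type2_residues: frozenset[int] = frozenset({106, 84}),
    cutoff: float = 3.6,
) -> str:
    """Classify a bound adenine nucleotide as a type I or type II site.

    The two nucleotide sites of a Bateman domain are distinguished by
    which backbone groups hydrogen-bond the adenine N6/N1 edge: Ile13 and
    His35 backbone for type I, Cys106 and Ile84 backbone for type II
    (GsAcuB numbering; residue sets configurable).  A contact is any
    probe-backbone pair within ``cutoff`` A.

    Returns "I", "II" or "unassigned".
    """
    lig_idx = [
        i
        for i, a in enumerate(structure.atoms)
        if a.chain == ligand_chain and a.resnum == ligand_resnum and a.name in _ADENINE_PROBE_ATOMS
    ]
    if not lig_idx:
        raise KeyError(
            f"ligand {ligand_chain}/{ligand_resnum} has no adenine probe atoms "
            f"{_ADENINE_PROBE_ATOMS}"
        )
    prot_idx = [
        i
        for i, a in enumerate(structure.atoms)
        if not a.het and a.name in _BACKBONE
    ]
    contacts: set[int] = set()
    for i in lig_idx:
        d = np.linalg.norm(structure.coords[prot_idx] - structure.coords[i], axis=1)
        for j, dist in zip(prot_idx, d):
            if dist <= cutoff:
                contacts.add(structure.atoms[j].resnum)
    if contacts & type1_residues:
        return "I"
    if contacts & type2_residues:
        return "II"
    return "unassigned"
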
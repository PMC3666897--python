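"""Coordinate parsing, rigid-body superposition and metal-site geometry.

PDB files are parsed through gemmi (first model only; for alternate
conformations the highest-occupancy location is kept).  Superposition is
the closed-form Kabsch least-squares fit on Cα atoms paired by identical
chain and residue number — appropriate for comparing a mutant structure
with its parent wild-type structure; cross-species comparisons require an
explicit user-supplied residue pairing table.  Metal-coordination
geometry is reported as all non-water, non-metal atoms within a distance
cutoff of each metal (2.6 Å by default; coordination bonds to Zn/Mn/Mg
sit near 2.0–2.1 Å).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from .errors import ValidationError

#: default set of metal elements of interest (the ions assayed biochemically)
DEFAULT_METALS = frozenset({"ZN", "MN", "MG", "NI", "CO", "CU"})

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


@dataclass(frozen=True)
class Atom:
    chain: str
    res_number: int
    res_name: str
    atom_name: str
    xyz: tuple[float, float, float]
    element: str

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.res_number, self.atom_name)


@dataclass(frozen=True)
class CoordSet:
    """A parsed structure: all atoms plus the subset recognized as metals."""

    atoms: tuple[Atom, ...]
    metal_elements: frozenset[str] = DEFAULT_METALS

    def __post_init__(self) -> None:
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (chain, residue, atom) keys")
        for a in self.atoms:
            if not all(np.isfinite(a.xyz)):
                raise ValidationError(f"non-finite coordinates for {a.key}")

    @property
    def metals(self) -> tuple[Atom, ...]:
        return tuple(a for a in self.atoms if a.element.upper() in self.metal_elements)

    @property
    def calpha(self) -> dict[tuple[str, int], Atom]:
        return {
            (a.chain, a.res_number): a
            for a in self.atoms
            if a.atom_name == "CA" and a.element.upper() == "C"
        }


@dataclass(frozen=True)
class SuperpositionResult:
    n_matched: int
    rmsd: float
    rotation: np.ndarray    # 3x3, det +1
    translation: np.ndarray  # applied as x @ R.T + t


def _element_of(atom: gemmi.Atom) -> str:
    el = atom.element.name.upper()
    if el and el != "X":
        return el
    # fall back to the atom name: strip digits, take the leading letters
    name = "".join(ch for ch in atom.name if ch.isalpha())
    if len(name) >= 2 and name[:2].upper() in DEFAULT_METALS:
        return name[:2].upper()
    return name[:1].upper()


def read_pdb(path: str | Path, metal_elements: Iterable[str] = DEFAULT_METALS) -> CoordSet:
    """Parse a PDB file into a CoordSet (first model, best altloc)."""
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValidationError(f"{path}: no models")
    model = st[0]
    best: dict[tuple[str, int, str], tuple[float, Atom]] = {}
    order: list[tuple[str, int, str]] = []
    for chain in model:
        for residue in chain:
            for atom in residue:
                key = (chain.name, residue.seqid.num, atom.name)
                rec = Atom(
                    chain=chain.name,
                    res_number=residue.seqid.num,
                    res_name=residue.name.strip(),
                    atom_name=atom.name,
                    xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                    element=_element_of(atom),
                )
                occ = float(atom.occ)
                if key not in best:
                    best[key] = (occ, rec)
                    order.append(key)
                elif occ > best[key][0]:
                    best[key] = (occ, rec)
    atoms = tuple(best[k][1] for k in order)
    cs = CoordSet(atoms=atoms, metal_elements=frozenset(e.upper() for e in metal_elements))
    if not cs.calpha and not cs.metals:
        raise ValidationError(f"{path}: no Cα atoms parsed")
    return cs


def kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired points p onto q.

    Returns (R, t, rmsd) with a proper rotation (det +1) such that
    p @ R.T + t best matches q.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.shape[0] < 3:
        raise ValidationError("need >= 3 paired points of identical shape")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = qc - pc @ rot.T
    moved = p @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return rot, t, rmsd


def superpose_by_residue(
    a: CoordSet,
    b: CoordSet,
    pairing: Mapping[tuple[str, int], tuple[str, int]] | None = None,
) -> SuperpositionResult:
    """Kabsch superposition of Cα atoms paired by chain + residue number.

    ``pairing`` optionally maps (chain, residue) keys of ``a`` to keys of
    ``b`` for cross-species comparisons; by default identical keys pair.
    """
    ca_a, ca_b = a.calpha, b.calpha
    if pairing is None:
        shared = sorted(set(ca_a) & set(ca_b))
        pairs = [(k, k) for k in shared]
    else:
        pairs = [(ka, kb) for ka, kb in sorted(pairing.items()) if ka in ca_a and kb in ca_b]
    if len(pairs) < 3:
        raise ValidationError(f"only {len(pairs)} paired Cα atoms; need >= 3")
    p = np.array([ca_a[ka].xyz for ka, _ in pairs])
    q = np.array([ca_b[kb].xyz for _, kb in pairs])
    rot, t, rmsd = kabsch(p, q)
    return SuperpositionResult(n_matched=len(pairs), rmsd=rmsd, rotation=rot, translation=t)


def metal_contacts(
    c: CoordSet, max_dist: float = 2.6
) -> list[tuple[Atom, Atom, float]]:
    """All non-water, non-metal atoms within ``max_dist`` Å of each metal.

    The interval is closed (an atom at exactly ``max_dist`` is included);
    contacts are sorted by distance within each metal.
    """
    metals = c.metals
    if not metals:
        return []
    contacts: list[tuple[Atom, Atom, float]] = []
    metal_keys = {m.key for m in metals}
    for m in metals:
        mx = np.asarray(m.xyz)
        found = []
        for a in c.atoms:
            if a.key in metal_keys or a.res_name in WATER_NAMES:
                continue
            dist = float(np.linalg.norm(np.asarray(a.xyz) - mx))
            if dist <= max_dist:
                found.append((m, a, dist))
        contacts.extend(sorted(found, key=lambda t: t[2]))
    return contacts


def read_pairing_table(path: str | Path) -> dict[tuple[str, int], tuple[str, int]]:
    """Tab-delimited residue pairing: chainA, resA, chainB, resB."""
    pairing: dict[tuple[str, int], tuple[str, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValidationError(f"{path}: line {lineno}: expected 4 columns")
            pairing[(parts[0], int(parts[1]))] = (parts[2], int(parts[3]))
    return pairing
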
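"""Coordinate handling, rigid-body geometry and solenoid decomposition.

This module provides the structural primitives used throughout the
package: a light-weight atom-list :class:`Structure`, PDB input/output
(via gemmi), Kabsch least-squares superposition, Cα-geometry helix
assignment, decomposition of an odd-count helix solenoid into
overlapping three-helix UBA units, and scanning of the UBA signature
motif (M/L-G-Y/F, with the KGF variant) in amino-acid sequences.

All coordinates are in Å and residue numbering is 1-based throughout.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import gemmi
import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: residues shorter than this are never reported as helices
MIN_HELIX_LENGTH = 6
#: Cα(i)->Cα(i+3) distance window for helical geometry, Å
HELIX_D3_RANGE = (4.5, 5.6)
#: Cα(i)->Cα(i+4) distance window for helical geometry, Å
HELIX_D4_RANGE = (5.8, 6.8)

#: pattern of the UBA signature motif, including the KGF variant seen in
#: the second UBA of the UBAP1 solenoid
SIGNATURE_MOTIF = re.compile(r"[MLK]G[FY]")

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be interpreted."""


class GeometryError(ValueError):
    """Raised on degenerate geometry (too few or collinear points)."""


class HelixError(ValueError):
    """Raised when helix assignment or decomposition preconditions fail."""


class SequenceError(ValueError):
    """Raised on illegal characters in an amino-acid sequence."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    chain: str
    resnum: int
    resname: str
    name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    bfactor: float = 0.0

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Structure:
    """An ordered list of atoms grouped by chain and residue.

    Residue numbers must be non-decreasing within a chain (strictly
    increasing per residue); every atom must have finite coordinates.
    """

    atoms: List[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        last: Dict[str, int] = {}
        for a in self.atoms:
            if not np.all(np.isfinite([a.x, a.y, a.z])):
                raise ValueError(f"non-finite coordinates for atom {a}")
            prev = last.get(a.chain)
            if prev is not None and a.resnum < prev:
                raise ValueError(
                    f"residue numbers not increasing in chain {a.chain}: "
                    f"{a.resnum} after {prev}"
                )
            last[a.chain] = a.resnum

    # -- accessors ---------------------------------------------------------

    def chains(self) -> List[str]:
        seen: List[str] = []
        for a in self.atoms:
            if a.chain not in seen:
                seen.append(a.chain)
        return seen

    def chain_atoms(self, chain: str) -> List[Atom]:
        return [a for a in self.atoms if a.chain == chain]

    def residue_numbers(self, chain: str) -> List[int]:
        nums: List[int] = []
        for a in self.atoms:
            if a.chain == chain and (not nums or a.resnum != nums[-1]):
                nums.append(a.resnum)
        return nums

    def residue_name(self, chain: str, resnum: int) -> str:
        for a in self.atoms:
            if a.chain == chain and a.resnum == resnum:
                return a.resname
        raise KeyError(f"residue {resnum} not found in chain {chain}")

    def atom(self, chain: str, resnum: int, name: str) -> Atom:
        for a in self.atoms:
            if a.chain == chain and a.resnum == resnum and a.name == name:
                return a
        raise KeyError(f"atom {chain}/{resnum}/{name} not found")

    def has_atom(self, chain: str, resnum: int, name: str) -> bool:
        try:
            self.atom(chain, resnum, name)
            return True
        except KeyError:
            return False

    def sequence(self, chain: str) -> str:
        """One-letter sequence of a chain, 'X' for non-standard residues."""
        out = []
        for r in self.residue_numbers(chain):
            out.append(_THREE_TO_ONE.get(self.residue_name(chain, r), "X"))
        return "".join(out)

    def ca_coords(self, chain: str, resnums: Iterable[int] | None = None) -> np.ndarray:
        nums = list(resnums) if resnums is not None else self.residue_numbers(chain)
        coords = []
        missing = []
        for r in nums:
            try:
                coords.append(self.atom(chain, r, "CA").coords)
            except KeyError:
                missing.append(r)
        if missing:
            raise HelixError(
                f"chain {chain} is missing CA atoms for residues {missing}"
            )
        return np.array(coords, dtype=float)

    def coords_array(self, heavy_only: bool = False) -> np.ndarray:
        atoms = self.atoms
        if heavy_only:
            atoms = [a for a in atoms if a.element != "H"]
        return np.array([[a.x, a.y, a.z] for a in atoms], dtype=float)

    # -- manipulation ------------------------------------------------------

    def transformed(self, t: "Transformation") -> "Structure":
        pts = self.coords_array()
        moved = pts @ t.rotation.T + t.translation
        atoms = [
            Atom(a.chain, a.resnum, a.resname, a.name, a.element,
                 float(p[0]), float(p[1]), float(p[2]), a.occupancy, a.bfactor)
            for a, p in zip(self.atoms, moved)
        ]
        return Structure(atoms)

    def renamed_chain(self, old: str, new: str) -> "Structure":
        atoms = [
            Atom(new if a.chain == old else a.chain, a.resnum, a.resname,
                 a.name, a.element, a.x, a.y, a.z, a.occupancy, a.bfactor)
            for a in self.atoms
        ]
        return Structure(atoms)

    def subset(self, chains: Sequence[str]) -> "Structure":
        return Structure([a for a in self.atoms if a.chain in chains])

    def merged(self, other: "Structure") -> "Structure":
        return Structure(list(self.atoms) + list(other.atoms))

    def with_bfactors(self, per_residue: Dict[Tuple[str, int], float]) -> "Structure":
        """Return a copy with B-factors replaced by per-residue values.

        Useful for exporting per-residue quantities (e.g. chemical shift
        perturbations) for colouring in a molecular viewer.
        """
        atoms = [
            Atom(a.chain, a.resnum, a.resname, a.name, a.element,
                 a.x, a.y, a.z, a.occupancy,
                 per_residue.get((a.chain, a.resnum), 0.0))
            for a in self.atoms
        ]
        return Structure(atoms)


@dataclass(frozen=True)
class Transformation:
    """A proper rigid-body motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if r.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if abs(np.linalg.det(r) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "Transformation":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(coords, dtype=float))
        out = pts @ self.rotation.T + self.translation
        return out[0] if np.asarray(coords).ndim == 1 else out

    def compose(self, other: "Transformation") -> "Transformation":
        """self ∘ other: apply `other` first, then `self`."""
        return Transformation(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "Transformation":
        rt = self.rotation.T
        return Transformation(rt, -rt @ self.translation)


@dataclass(frozen=True)
class HelixSegment:
    """A helical stretch [start, end] (inclusive) of one chain."""

    chain: str
    start: int
    end: int
    axis: np.ndarray

    def __post_init__(self) -> None:
        if self.end - self.start + 1 < MIN_HELIX_LENGTH:
            raise ValueError("helix shorter than the minimum length")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def residues(self) -> List[int]:
        return list(range(self.start, self.end + 1))


@dataclass(frozen=True)
class UBAUnit:
    """One three-helix UBA unit of the solenoid.

    Consecutive units share a helix: the third helix of unit *i* is the
    first helix of unit *i+1*.
    """

    index: int
    helices: Tuple[HelixSegment, HelixSegment, HelixSegment]

    @property
    def span(self) -> Tuple[int, int]:
        return (self.helices[0].start, self.helices[2].end)


# ---------------------------------------------------------------------------
# PDB / FASTA I/O
# ---------------------------------------------------------------------------

def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    return stripped[0] if stripped else "C"


def read_pdb(path: str | Path) -> Structure:
    """Read a single-model PDB file into a :class:`Structure`.

    Malformed ATOM/HETATM records raise :class:`PDBParseError` naming the
    offending line; duplicate atom serial numbers are accepted with a
    logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    serials: set[int] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        try:
            serial = int(line[6:11])
            float(line[30:38]); float(line[38:46]); float(line[46:54])
            int(line[22:26])
        except (ValueError, IndexError) as exc:
            raise PDBParseError(f"{path}: malformed record at line {lineno}: "
                                f"{line!r}") from exc
        if serial in serials:
            logger.warning("%s: duplicate atom serial %d at line %d",
                           path, serial, lineno)
        serials.add(serial)

    st = gemmi.read_pdb(str(path))
    if len(st) == 0 or all(len(model) == 0 for model in st):
        raise PDBParseError(f"{path}: no atoms found")
    if len(st) > 1:
        logger.warning("%s: %d models present, using the first", path, len(st))

    model = st[0]
    atoms: List[Atom] = []
    for chain in model:
        for res in chain:
            for at in res:
                atoms.append(Atom(
                    chain.name, res.seqid.num, res.name, at.name,
                    at.element.name if at.element.name else
                    _element_from_name(at.name),
                    at.pos.x, at.pos.y, at.pos.z, at.occ, at.b_iso,
                ))
    return Structure(atoms)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` as a single-model PDB file."""
    st = gemmi.Structure()
    st.name = "soubakit"
    model = gemmi.Model("1")
    for chain_id in structure.chains():
        chain = gemmi.Chain(chain_id)
        current: gemmi.Residue | None = None
        for a in structure.chain_atoms(chain_id):
            if current is None or current.seqid.num != a.resnum:
                current = gemmi.Residue()
                current.name = a.resname
                current.seqid = gemmi.SeqId(a.resnum, " ")
                chain.add_residue(current)
                current = chain[-1]
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(a.x, a.y, a.z)
            at.occ = a.occupancy
            at.b_iso = a.bfactor
            current.add_atom(at)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    doc_path = Path(path)
    doc_path.parent.mkdir(parents=True, exist_ok=True)
    st.write_pdb(str(doc_path))


def read_fasta(path: str | Path) -> Dict[str, str]:
    """Read a FASTA file into {record id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# rigid-body superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> Tuple[Transformation, float]:
    """Least-squares rigid superposition of paired points (Kabsch).

    Returns the proper rotation + translation mapping ``mobile`` onto
    ``reference`` and the RMSD after applying it. Reflections are
    rejected by flipping the sign of the smallest singular direction.
    """
    p = np.asarray(mobile, dtype=float)
    q = np.asarray(reference, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or p.shape != q.shape:
        raise GeometryError("point sets must be equal-shaped (N, 3) arrays")
    if len(p) < 3:
        raise GeometryError("at least 3 paired points are required")

    pm, qm = p.mean(axis=0), q.mean(axis=0)
    pc, qc = p - pm, q - qm
    if np.linalg.matrix_rank(pc, tol=1e-8) < 2 or \
            np.linalg.matrix_rank(qc, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) point set")

    h = pc.T @ qc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    trans = qm - rot @ pm
    moved = p @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return Transformation(rot, trans), rmsd


# ---------------------------------------------------------------------------
# helix assignment and solenoid decomposition
# ---------------------------------------------------------------------------

def _helix_axis(ca: np.ndarray) -> np.ndarray:
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def assign_helices(structure: Structure, chain: str | None = None) -> List[HelixSegment]:
    """Detect α-helical segments from Cα geometry.

    A residue window is helical when the Cα(i)→Cα(i+3) distance falls in
    ``HELIX_D3_RANGE`` and Cα(i)→Cα(i+4) in ``HELIX_D4_RANGE``; maximal
    runs covering at least ``MIN_HELIX_LENGTH`` residues are reported.
    Runs are broken at gaps in residue numbering. Deterministic; when
    expanded segments would overlap, the N-terminal segment keeps the
    shared residues.
    """
    chains = [chain] if chain is not None else structure.chains()
    segments: List[HelixSegment] = []
    for ch in chains:
        nums = structure.residue_numbers(ch)
        if len(nums) < MIN_HELIX_LENGTH:
            raise HelixError(
                f"chain {ch} has fewer than {MIN_HELIX_LENGTH} residues")
        ca = structure.ca_coords(ch, nums)

        flags = np.zeros(len(nums), dtype=bool)
        for i in range(len(nums) - 4):
            if nums[i + 4] - nums[i] != 4:  # numbering gap breaks the run
                continue
            d3 = np.linalg.norm(ca[i + 3] - ca[i])
            d4 = np.linalg.norm(ca[i + 4] - ca[i])
            flags[i] = (HELIX_D3_RANGE[0] <= d3 <= HELIX_D3_RANGE[1]
                        and HELIX_D4_RANGE[0] <= d4 <= HELIX_D4_RANGE[1])

        chain_segments: List[Tuple[int, int]] = []
        i = 0
        while i < len(flags):
            if not flags[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(flags) and flags[j + 1]:
                j += 1
            first, last = i, j + 4  # indices into nums
            if last - first + 1 >= MIN_HELIX_LENGTH:
                if chain_segments and first <= chain_segments[-1][1]:
                    first = chain_segments[-1][1] + 1  # N-terminal wins ties
                if last - first + 1 >= MIN_HELIX_LENGTH:
                    chain_segments.append((first, last))
            i = j + 1

        for first, last in chain_segments:
            segments.append(HelixSegment(
                ch, nums[first], nums[last],
                _helix_axis(ca[first:last + 1]),
            ))
    return segments


def decompose_overlapping_ubas(helices: Sequence[HelixSegment]) -> List[UBAUnit]:
    """Decompose an odd number of helices into overlapping 3-helix units.

    Unit *i* is built from helices (2i−1, 2i, 2i+1), so the third helix
    of each unit is the first helix of the next — the defining feature
    of a solenoid of overlapping UBAs.
    """
    n = len(helices)
    if n < 3 or n % 2 == 0:
        raise HelixError(
            f"a solenoid of overlapping UBAs requires an odd helix count "
            f">= 3, got {n}"
        )
    units = []
    for i in range((n - 1) // 2):
        trio = (helices[2 * i], helices[2 * i + 1], helices[2 * i + 2])
        units.append(UBAUnit(i + 1, trio))
    return units


# ---------------------------------------------------------------------------
# signature-motif scanning
# ---------------------------------------------------------------------------

def scan_signature_motifs(sequence: str) -> List[Tuple[int, str]]:
    """Find UBA signature motifs ((M/L)-G-(Y/F) and the KGF variant).

    The scan is non-overlapping, left to right; positions are 1-based.
    """
    for pos, letter in enumerate(sequence, start=1):
        if letter not in _STANDARD_AA:
            raise SequenceError(
                f"illegal amino-acid character {letter!r} at position {pos}")
    return [(m.start() + 1, m.group()) for m in SIGNATURE_MOTIF.finditer(sequence)]


def one_to_three(letter: str) -> str:
    """One-letter to PDB three-letter residue name."""
    try:
        return _ONE_TO_THREE[letter]
    except KeyError:
        raise SequenceError(f"unknown residue letter {letter!r}") from None
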
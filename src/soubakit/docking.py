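"""Template-superposition docking of monoubiquitins onto a UBA solenoid.

Each three-helix UBA unit of the receptor is superposed (Kabsch on Cα,
helix-by-helix pairing trimmed from midpoints) onto the UBA of a known
UBA:ubiquitin template complex; the template's ubiquitin is carried
along, giving one placed ubiquitin copy per unit. Steric clashes between
chains and the geometric feasibility of K48/K63 isopeptide linkages
between adjacently placed ubiquitins are assessed on the resulting model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .structlib import (
    HelixSegment,
    Structure,
    Transformation,
    UBAUnit,
    assign_helices,
    kabsch_superpose,
)

logger = logging.getLogger(__name__)

#: heavy-atom distance below which two atoms of different chains clash, Å
DEFAULT_CLASH_CUTOFF = 2.4
#: heavy-atom distance defining the template's UBA/ubiquitin contact footprint, Å
INTERFACE_CONTACT_CUTOFF = 4.5
#: Lys NZ – Gly76 C distance compatible with an isopeptide bond given the
#: flexibility of the ubiquitin C-terminal tail, Å
DEFAULT_LINKAGE_THRESHOLD = 9.0

LINKAGE_RESIDUES = {"K48": 48, "K63": 63}
UB_TAIL_RESIDUE = 76


class DockingError(ValueError):
    """Raised when template pairing or model assembly fails."""


class LinkageError(ValueError):
    """Raised when atoms required for linkage assessment are missing."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TemplateComplex:
    """A UBA:ubiquitin template: two chains plus the UBA's helix annotation."""

    structure: Structure
    uba_chain: str
    ub_chain: str
    uba_helices: List[HelixSegment]

    def __post_init__(self) -> None:
        chains = self.structure.chains()
        if self.uba_chain not in chains or self.ub_chain not in chains:
            raise DockingError(
                f"template must contain chains {self.uba_chain!r} and "
                f"{self.ub_chain!r}; found {chains}")
        if len(self.uba_helices) != 3:
            raise DockingError(
                f"template UBA must have exactly 3 helices, "
                f"found {len(self.uba_helices)}")

    @classmethod
    def from_structure(cls, structure: Structure, uba_chain: str,
                       ub_chain: str) -> "TemplateComplex":
        helices = assign_helices(structure, chain=uba_chain)
        return cls(structure, uba_chain, ub_chain, helices)

    def interface_footprint(
        self, cutoff: float = INTERFACE_CONTACT_CUTOFF
    ) -> FrozenSet[int]:
        """UBA residues with any heavy atom within `cutoff` of the ubiquitin."""
        uba = [a for a in self.structure.chain_atoms(self.uba_chain)
               if a.element != "H"]
        ub = [a for a in self.structure.chain_atoms(self.ub_chain)
              if a.element != "H"]
        tree = cKDTree(np.array([[a.x, a.y, a.z] for a in ub]))
        touching = set()
        for a in uba:
            if tree.query_ball_point([a.x, a.y, a.z], cutoff):
                touching.add(a.resnum)
        return frozenset(touching)


@dataclass
class PlacedUbiquitin:
    unit_index: int
    chain_id: str
    transform: Transformation
    rmsd: float
    #: receptor residues of this copy's own modelled interface (excluded
    #: from clash detection when the exclusion flag is on)
    interface_residues: FrozenSet[Tuple[str, int]] = frozenset()


@dataclass
class DockedModel:
    """Receptor plus template-placed ubiquitin copies (chains U1, U2, ...)."""

    receptor: Structure
    placements: List[PlacedUbiquitin]
    structure: Structure  # receptor + placed copies combined

    def placed_chains(self) -> List[str]:
        return [p.chain_id for p in self.placements]


@dataclass
class ClashReport:
    """Inter-chain heavy-atom contacts below the clash cutoff."""

    cutoff: float
    contacts: List[Tuple[Tuple[str, str], Tuple[str, str], float]]
    counts: Dict[Tuple[str, str], int] = field(default_factory=dict)

    def total(self) -> int:
        return len(self.contacts)


@dataclass
class LinkageAssessment:
    """Minimum Lys NZ – Gly76 C distances between adjacent placed copies."""

    linkage: str
    threshold: float
    entries: List[Tuple[Tuple[str, str], float, bool]]


# ---------------------------------------------------------------------------
# docking
# ---------------------------------------------------------------------------

def _paired_ca(structure: Structure, chain: str, helix: HelixSegment,
               m: int) -> np.ndarray:
    """Cα of `m` residues centred on the helix midpoint."""
    residues = helix.residues()
    start = (len(residues) - m) // 2
    return structure.ca_coords(chain, residues[start:start + m])


def _helix_pairing(receptor: Structure, unit: UBAUnit,
                   template: TemplateComplex) -> Tuple[np.ndarray, np.ndarray,
                                                       Dict[int, Tuple[str, int]]]:
    """Paired Cα coordinates (template, receptor) and the residue map."""
    mob, ref = [], []
    resmap: Dict[int, Tuple[str, int]] = {}
    for k in range(3):
        helix_r = unit.helices[k]
        helix_t = template.uba_helices[k]
        m = min(helix_r.length, helix_t.length)
        if m < 3:
            raise DockingError(
                f"unit {unit.index}: helix {k + 1} leaves fewer than 3 "
                f"paired residues ({helix_r.length} vs {helix_t.length})")
        mob.append(_paired_ca(template.structure, template.uba_chain,
                              helix_t, m))
        ref.append(_paired_ca(receptor, helix_r.chain, helix_r, m))
        r_res = helix_r.residues()
        t_res = helix_t.residues()
        r_start = (len(r_res) - m) // 2
        t_start = (len(t_res) - m) // 2
        for j in range(m):
            resmap[t_res[t_start + j]] = (helix_r.chain, r_res[r_start + j])
    return np.vstack(mob), np.vstack(ref), resmap


def dock_ubiquitins(receptor: Structure, units: Sequence[UBAUnit],
                    template: TemplateComplex) -> DockedModel:
    """Place one template ubiquitin per UBA unit by Cα superposition.

    Helix k of each unit is paired with helix k of the template, Cα
    pairs trimmed symmetrically to the shorter helix; the least-squares
    transform of the template UBA onto the unit is applied to the
    template's ubiquitin, added as chain U<i>.
    """
    if not units:
        raise DockingError("no UBA units to dock onto")
    footprint = template.interface_footprint()
    ub = template.structure.subset([template.ub_chain])

    placements: List[PlacedUbiquitin] = []
    combined = receptor
    for unit in units:
        mob, ref, resmap = _helix_pairing(receptor, unit, template)
        transform, rmsd = kabsch_superpose(mob, ref)
        chain_id = f"U{unit.index}"
        placed = ub.transformed(transform).renamed_chain(
            template.ub_chain, chain_id)
        iface = frozenset(resmap[r] for r in footprint if r in resmap)
        placements.append(PlacedUbiquitin(unit.index, chain_id, transform,
                                          rmsd, iface))
        combined = combined.merged(placed)
        logger.info("unit %d: placed %s with superposition rmsd %.3f Å",
                    unit.index, chain_id, rmsd)
    return DockedModel(receptor, placements, combined)


# ---------------------------------------------------------------------------
# clash detection
# ---------------------------------------------------------------------------

def detect_clashes(model: DockedModel | Structure,
                   cutoff: float = DEFAULT_CLASH_CUTOFF,
                   exclude_interface: bool = True) -> ClashReport:
    """All inter-chain heavy-atom pairs closer than `cutoff`.

    For a :class:`DockedModel` with `exclude_interface`, contacts between
    a placed ubiquitin and the receptor residues of its own
    template-defined interface footprint are skipped — that contact is
    the modelled binding interface, not a clash.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if isinstance(model, DockedModel):
        structure = model.structure
        exclusions = {p.chain_id: p.interface_residues
                      for p in model.placements} if exclude_interface else {}
        receptor_chains = set(model.receptor.chains())
    else:
        structure = model
        exclusions = {}
        receptor_chains = set()

    heavy = [a for a in structure.atoms if a.element != "H"]
    coords = np.array([[a.x, a.y, a.z] for a in heavy])
    tree = cKDTree(coords)
    contacts: List[Tuple[Tuple[str, str], Tuple[str, str], float]] = []
    counts: Dict[Tuple[str, str], int] = {}
    for i, j in sorted(tree.query_pairs(cutoff)):
        a, b = heavy[i], heavy[j]
        if a.chain == b.chain:
            continue
        excluded = False
        for atom_u, atom_o in ((a, b), (b, a)):
            if atom_u.chain in exclusions and atom_o.chain in receptor_chains \
                    and (atom_o.chain, atom_o.resnum) in exclusions[atom_u.chain]:
                excluded = True
        if excluded:
            continue
        pair = tuple(sorted((a.chain, b.chain)))
        first, second = (a, b) if a.chain <= b.chain else (b, a)
        dist = float(np.linalg.norm(first.coords - second.coords))
        contacts.append((
            pair,
            (f"{first.chain}/{first.resnum}/{first.name}",
             f"{second.chain}/{second.resnum}/{second.name}"),
            dist,
        ))
        counts[pair] = counts.get(pair, 0) + 1
    return ClashReport(cutoff, contacts, counts)


# ---------------------------------------------------------------------------
# isopeptide linkage feasibility
# ---------------------------------------------------------------------------

def assess_linkage(model: DockedModel, linkage: str = "K48",
                   threshold: float = DEFAULT_LINKAGE_THRESHOLD
                   ) -> LinkageAssessment:
    """Geometric feasibility of K48/K63 linkages between adjacent copies.

    For each pair of copies on consecutive UBA units, the reported
    distance is the minimum over both directions of Lys-k NZ on one copy
    to Gly76 carbonyl C on the other; the linkage is feasible when that
    distance is <= threshold.
    """
    if linkage not in LINKAGE_RESIDUES:
        raise ValueError(f"linkage must be one of {sorted(LINKAGE_RESIDUES)}")
    if len(model.placements) < 2:
        raise LinkageError("at least 2 placed ubiquitins are required")
    lys = LINKAGE_RESIDUES[linkage]

    def _atom(chain: str, resnum: int, name: str) -> np.ndarray:
        try:
            return model.structure.atom(chain, resnum, name).coords
        except KeyError:
            raise LinkageError(
                f"copy {chain} is missing atom {name} of residue {resnum}"
            ) from None

    ordered = sorted(model.placements, key=lambda p: p.unit_index)
    entries: List[Tuple[Tuple[str, str], float, bool]] = []
    for p1, p2 in zip(ordered, ordered[1:]):
        if p2.unit_index != p1.unit_index + 1:
            continue
        d_fwd = np.linalg.norm(_atom(p1.chain_id, lys, "NZ")
                               - _atom(p2.chain_id, UB_TAIL_RESIDUE, "C"))
        d_rev = np.linalg.norm(_atom(p2.chain_id, lys, "NZ")
                               - _atom(p1.chain_id, UB_TAIL_RESIDUE, "C"))
        dist = float(min(d_fwd, d_rev))
        entries.append(((p1.chain_id, p2.chain_id), dist, dist <= threshold))
    return LinkageAssessment(linkage, threshold, entries)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def write_docking_report(model: DockedModel, clashes: ClashReport,
                         linkages: Sequence[LinkageAssessment],
                         path: str | Path) -> None:
    """TSV report: per-unit rmsd, clash counts, linkage distances."""
    lines = ["# section\tkey\tvalue"]
    for p in model.placements:
        lines.append(f"placement\t{p.chain_id}\trmsd={p.rmsd:.4f}")
    lines.append(f"clashes\ttotal\t{clashes.total()}")
    for pair in sorted(clashes.counts):
        lines.append(f"clashes\t{pair[0]}-{pair[1]}\t{clashes.counts[pair]}")
    for la in linkages:
        for (c1, c2), dist, feasible in la.entries:
            verdict = "feasible" if feasible else "infeasible"
            lines.append(f"linkage_{la.linkage}\t{c1}-{c2}\t"
                         f"{dist:.2f}\t{verdict}")
    Path(path).write_text("\n".join(lines) + "\n")
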
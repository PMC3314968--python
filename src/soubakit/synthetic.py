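"""Synthetic fixtures with the geometric/statistical structure the
analysis assumes.

Generators (all pure functions of an explicit spec + seed):

* :func:`make_solenoid` — an idealised right-handed solenoid of N α
  helices (default 7, giving three overlapping three-helix UBA units)
  built by repeating a two-helix motif under a screw transformation, so
  every UBA unit has identical internal geometry.
* :func:`make_ub_like_domain` — a 76-residue compact helical decoy that
  stands in for monoubiquitin. It is a geometric stand-in, not a fold
  prediction: what matters downstream is that the named atoms exist at
  fixed relative geometry (Ile44/Val70 patch markers on the contact
  face, Lys48/Lys63 NZ, Gly76 C, and spin-label sites at residues 6, 39,
  48, 57 with residues 39/57 on the face opposite the contact patch).
* :func:`make_template_complex` — the decoy posed against the helix-1/
  helix-3 face of a three-helix bundle, playing the role of a known
  UBA:ubiquitin complex used for template docking.
* :func:`simulate_titration` — fast-exchange HSQC titration peak lists.
* :func:`simulate_pre_observed` — noisy spin-label attenuation profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from . import binding, docking, pre as pre_mod
from .csp import PeakList, TitrationSeries
from .docking import DockedModel, TemplateComplex, detect_clashes
from .structlib import Atom, Structure, one_to_three

# -- ideal α-helix parameters (Cα) ------------------------------------------
HELIX_RISE = 1.5          # Å per residue
HELIX_TWIST = 100.0       # degrees per residue
HELIX_RADIUS = 2.3        # Å

# -- solenoid screw geometry -------------------------------------------------
#: rotation (deg) and rise (Å) of the screw relating consecutive UBA repeats;
#: positive rotation with positive rise gives a right-handed superhelix
SCREW_ANGLE_DEG = 45.0
SCREW_RISE = 16.0
#: radial offsets of the outer (odd) and inner (even) helices, Å
OUTER_RADIUS = 13.0
INNER_RADIUS = 5.0
#: axial tilt of helix axes out of the superhelix plane
HELIX_TILT = 0.3

#: positional jitter applied to generated coordinates, Å
COORD_JITTER = 0.02

#: canonical human ubiquitin sequence (76 residues)
UBIQUITIN_SEQUENCE = (
    "MQIFVKTLTGKTITLEVEPSDTIENVKAKIQDKEGIPPDQQRLIFAGKQLEDGRTLSDYNIQKESTLHLVLRLRGG"
)

#: alphabet used for unconstrained solenoid positions — excludes G (so the
#: only signature-motif glycines are the planted ones), P (prolines are
#: planted explicitly) and the motif-prone letters M/K/L/F/Y
_FILLER_ALPHABET = "ADESTNQRHVIW"


class SyntheticError(ValueError):
    """Raised when a generator spec is invalid or produces bad geometry."""


# ---------------------------------------------------------------------------
# specs and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolenoidSpec:
    seed: int
    helix_count: int = 7
    residues_per_helix: int = 11
    loop_length: int = 3
    handedness: str = "right"

    def __post_init__(self) -> None:
        if self.helix_count < 3 or self.helix_count % 2 == 0:
            raise SyntheticError(
                f"a solenoid of overlapping UBAs needs an odd helix count "
                f">= 3, got {self.helix_count}")
        if self.residues_per_helix < 6 or self.loop_length < 1:
            raise SyntheticError("helices must have >= 6 residues and loops >= 1")
        if self.handedness != "right":
            raise SyntheticError("only right-handed solenoids are generated")


@dataclass(frozen=True)
class SolenoidTruth:
    """Construction ground truth returned with a generated solenoid."""

    helix_bounds: Tuple[Tuple[int, int], ...]
    unit_count: int
    sequence: str
    motif_positions: Tuple[int, ...]
    prolines: Tuple[int, ...]


@dataclass(frozen=True)
class TitrationSpec:
    seed: int
    protein_uM: float = 500.0
    equivalents: Tuple[float, ...] = (0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0)
    kd_uM: float = 70.0
    perturbed: Tuple[Tuple[int, float], ...] = (
        (8, 0.4), (9, 0.4), (12, 0.4), (13, 0.4), (14, 0.4), (36, 0.4),
        (40, 0.4), (41, 0.4), (42, 0.4), (64, 0.4), (68, 0.4), (69, 0.4),
    )
    noise_sigma_ppm: float = 0.01
    residues: Tuple[int, ...] = tuple(range(1, 96))
    prolines: Tuple[int, ...] = (26, 54)

    def __post_init__(self) -> None:
        eqs = self.equivalents
        if not eqs or eqs[0] != 0.0 or any(b <= a for a, b in zip(eqs, eqs[1:])):
            raise SyntheticError("equivalents must increase from 0")
        if self.noise_sigma_ppm < 0 or self.protein_uM <= 0 or self.kd_uM <= 0:
            raise SyntheticError("concentrations/Kd must be positive, noise >= 0")


# ---------------------------------------------------------------------------
# low-level builders
# ---------------------------------------------------------------------------

def _rot_z(deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class _HelixPose:
    center: np.ndarray   # midpoint of the helix axis
    axis: np.ndarray     # unit vector, N->C direction
    e1: np.ndarray       # phase reference, unit, perpendicular to axis

    def transformed(self, rot: np.ndarray, shift: np.ndarray) -> "_HelixPose":
        return _HelixPose(rot @ self.center + shift, rot @ self.axis,
                          rot @ self.e1)


def _helix_ca(pose: _HelixPose, n_res: int, phase_deg: float) -> np.ndarray:
    e2 = np.cross(pose.axis, pose.e1)
    half = (n_res - 1) / 2.0
    out = np.empty((n_res, 3))
    for i in range(n_res):
        theta = math.radians(phase_deg + i * HELIX_TWIST)
        out[i] = (pose.center
                  + HELIX_RADIUS * (math.cos(theta) * pose.e1
                                    + math.sin(theta) * e2)
                  + (i - half) * HELIX_RISE * pose.axis)
    return out


def _loop_ca(a: np.ndarray, b: np.ndarray, n_res: int,
             bulge_dir: np.ndarray) -> np.ndarray:
    """CA positions of a loop of n_res residues between anchors a and b."""
    pts = []
    for k in range(1, n_res + 1):
        f = k / (n_res + 1)
        bulge = 1.2 * math.sin(math.pi * f)
        pts.append(a + f * (b - a) + bulge * bulge_dir)
    return np.array(pts)


def _backbone_atoms(chain: str, ca: np.ndarray, sequence: str,
                    rng: np.random.Generator) -> List[Atom]:
    """Approximate backbone (N, CA, C, O, CB[, NZ]) from a CA trace.

    Atom placement is idealised from local chain direction; accuracy at
    the sub-Å level is irrelevant downstream (helix detection uses CA
    only, PRE uses amide positions at >10 Å distances).
    """
    n_res = len(ca)
    assert len(sequence) == n_res
    jitter = rng.normal(0.0, COORD_JITTER, size=(n_res, 8, 3))

    def _unit(v: np.ndarray) -> np.ndarray:
        norm = np.linalg.norm(v)
        return v / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])

    atoms: List[Atom] = []
    for i in range(n_res):
        prev_dir = _unit(ca[i - 1] - ca[i]) if i > 0 else _unit(ca[i] - ca[i + 1])
        next_dir = _unit(ca[i + 1] - ca[i]) if i < n_res - 1 else -prev_dir
        n_pos = ca[i] + 1.45 * prev_dir
        c_pos = ca[i] + 1.52 * next_dir
        normal = np.cross(next_dir, prev_dir)
        if np.linalg.norm(normal) < 1e-6:
            normal = np.cross(next_dir, np.array([0.0, 0.0, 1.0]))
            if np.linalg.norm(normal) < 1e-6:
                normal = np.array([1.0, 0.0, 0.0])
        normal = _unit(normal)
        o_pos = c_pos + 1.23 * _unit(normal + 0.3 * next_dir)

        resname = one_to_three(sequence[i])
        resnum = i + 1
        entries = [("N", "N", n_pos + jitter[i, 0]),
                   ("CA", "C", ca[i] + jitter[i, 1]),
                   ("C", "C", c_pos + jitter[i, 2]),
                   ("O", "O", o_pos + jitter[i, 3])]
        if resname != "GLY":
            b1 = _unit(n_pos - ca[i])
            b2 = _unit(c_pos - ca[i])
            bis = _unit(b1 + b2)
            perp = _unit(np.cross(b1, b2))
            cb = ca[i] + 1.53 * (-0.604 * bis + 0.797 * perp)
            entries.append(("CB", "C", cb + jitter[i, 4]))
            if resname == "LYS":
                nz = cb + 3.3 * _unit(cb - ca[i])
                entries.append(("NZ", "N", nz + jitter[i, 5]))
        for name, elem, pos in entries:
            atoms.append(Atom(chain, resnum, resname, name, elem,
                              round(float(pos[0]), 3), round(float(pos[1]), 3),
                              round(float(pos[2]), 3)))
    return atoms


def _check_self_intersection(ca: np.ndarray, min_dist: float = 3.0) -> None:
    tree = cKDTree(ca)
    for i, j in tree.query_pairs(min_dist):
        if abs(i - j) > 2:
            raise SyntheticError(
                f"generated backbone self-intersects (CA {i + 1}/{j + 1})")


# ---------------------------------------------------------------------------
# solenoid generator
# ---------------------------------------------------------------------------

def _base_poses() -> Tuple[_HelixPose, _HelixPose]:
    """Poses of the first outer and first inner helix of the repeat."""
    tilt = HELIX_TILT
    u1 = np.array([0.0, 1.0, tilt])
    u1 /= np.linalg.norm(u1)
    e1 = np.array([1.0, 0.0, 0.0])
    e1 = e1 - (e1 @ u1) * u1
    e1 /= np.linalg.norm(e1)
    h1 = _HelixPose(np.array([OUTER_RADIUS, 0.0, 0.0]), u1, e1)

    half = _rot_z(SCREW_ANGLE_DEG / 2.0)
    u2 = np.array([0.0, -1.0, tilt])
    u2 /= np.linalg.norm(u2)
    e1b = np.array([1.0, 0.0, 0.0])
    e1b = e1b - (e1b @ u2) * u2
    e1b /= np.linalg.norm(e1b)
    c2 = np.array([INNER_RADIUS, 0.0, SCREW_RISE / 2.0])
    h2 = _HelixPose(half @ c2, half @ u2, half @ e1b)
    return h1, h2


def _helix_poses(count: int) -> List[_HelixPose]:
    h1, h2 = _base_poses()
    screw_rot = _rot_z(SCREW_ANGLE_DEG)
    shift = np.array([0.0, 0.0, SCREW_RISE])
    poses = []
    for k in range(count):
        repeat, parity = divmod(k, 2)
        base = h1 if parity == 0 else h2
        rot = np.linalg.matrix_power(screw_rot, repeat)
        poses.append(base.transformed(rot, repeat * shift))
    return poses


def _solenoid_sequence(spec: SolenoidSpec, rng: np.random.Generator
                       ) -> Tuple[str, List[int], List[int]]:
    """Sequence with signature motifs planted in the loop after the first
    helix of each UBA unit and prolines in the loops after even helices."""
    n_helix, n_loop = spec.residues_per_helix, spec.loop_length
    total = spec.helix_count * n_helix + (spec.helix_count - 1) * n_loop
    letters = list(rng.choice(list(_FILLER_ALPHABET), size=total))

    motif_texts = ["MGF", "KGF", "LGY"]
    motifs: List[int] = []
    prolines: List[int] = []
    for h in range(1, spec.helix_count):  # loop following helix h
        loop_start = h * n_helix + (h - 1) * n_loop + 1  # 1-based
        if h % 2 == 1 and n_loop >= 3:
            text = motif_texts[(h // 2) % len(motif_texts)]
            for off, letter in enumerate(text):
                letters[loop_start - 1 + off] = letter
            motifs.append(loop_start)
        elif h % 2 == 0:
            letters[loop_start - 1] = "P"
            prolines.append(loop_start)
    return "".join(letters), motifs, prolines


def make_solenoid(spec: SolenoidSpec) -> Tuple[Structure, SolenoidTruth]:
    """Generate an idealised solenoid of overlapping three-helix units.

    Returns the structure (chain A) and the construction ground truth:
    helix bounds, expected unit count, sequence, planted motif positions
    and prolines.
    """
    poses = _helix_poses(spec.helix_count)
    n_helix, n_loop = spec.residues_per_helix, spec.loop_length

    helix_cas = [_helix_ca(p, n_helix, 0.0) for p in poses]
    segments: List[np.ndarray] = []
    bounds: List[Tuple[int, int]] = []
    resnum = 1
    for k, hca in enumerate(helix_cas):
        if k > 0:
            a = helix_cas[k - 1][-1]
            b = hca[0]
            mid = (a + b) / 2.0
            radial = mid - np.array([0.0, 0.0, mid[2]])
            norm = np.linalg.norm(radial)
            bulge = radial / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
            segments.append(_loop_ca(a, b, n_loop, bulge))
            resnum += n_loop
        segments.append(hca)
        bounds.append((resnum, resnum + n_helix - 1))
        resnum += n_helix

    ca = np.vstack(segments)
    _check_self_intersection(ca)

    rng = np.random.default_rng(spec.seed)
    sequence, motifs, prolines = _solenoid_sequence(spec, rng)
    atoms = _backbone_atoms("A", ca, sequence, rng)
    truth = SolenoidTruth(tuple(bounds), (spec.helix_count - 1) // 2,
                          sequence, tuple(motifs), tuple(prolines))
    return Structure(atoms), truth


# ---------------------------------------------------------------------------
# ubiquitin-like decoy
# ---------------------------------------------------------------------------

# helix spans (residue ranges) and xy positions of the decoy's four-helix
# bundle; axes along ±z. Residue 6 and the Ile44/Val70 patch markers face
# -y (the contact face); residues 39 and 57 face +y.
_DECOY_HELICES = (
    ((2, 15), (0.0, -5.5), +1, 230.0),
    ((19, 35), (-5.0, 2.5), -1, 0.0),
    ((39, 57), (0.0, 10.5), +1, 90.0),
    ((61, 74), (5.0, 2.5), -1, 90.0),
)


def make_ub_like_domain(seed: int, chain: str = "V") -> Structure:
    """A 76-residue helical decoy standing in for monoubiquitin.

    Carries the canonical ubiquitin sequence so the named atoms required
    downstream exist: K6/D39/K48/S57 spin-label sites (with residues 39
    and 57 on the face opposite the binding patch), the Ile44/Val70
    patch markers on the contact (-y) face, Lys48/Lys63 NZ and Gly76 C.
    """
    z_tops = {}
    ca = np.full((76, 3), np.nan)
    z_cursor = 0.0
    for (start, end), (x, y), direction, phase in _DECOY_HELICES:
        n_res = end - start + 1
        length = (n_res - 1) * HELIX_RISE
        center_z = z_cursor + length / 2.0 if direction > 0 else \
            z_cursor - length / 2.0
        axis = np.array([0.0, 0.0, float(direction)])
        e1 = np.array([1.0, 0.0, 0.0])
        pose = _HelixPose(np.array([x, y, center_z]), axis, e1)
        hca = _helix_ca(pose, n_res, phase)
        ca[start - 1:end] = hca
        z_cursor = center_z + direction * length / 2.0 + 1.5
        z_tops[(start, end)] = z_cursor

    spans = [h[0] for h in _DECOY_HELICES]
    for (s1, e1_), (s2, _) in zip(spans, spans[1:]):
        n_loop = s2 - e1_ - 1
        a, b = ca[e1_ - 1], ca[s2 - 1]
        bulge = np.array([0.0, 0.0, 1.0]) if a[2] > 10 else \
            np.array([0.0, 0.0, -1.0])
        ca[e1_:s2 - 1] = _loop_ca(a, b, n_loop, bulge)

    # N-terminal residue and the C-terminal Leu-Arg-Gly-Gly tail, extended
    first = spans[0][0]
    ca[first - 2] = ca[first - 1] + (ca[first - 1] - ca[first]) \
        / np.linalg.norm(ca[first - 1] - ca[first]) * 3.8
    last = spans[-1][1]
    tail_dir = ca[last - 1] - ca[last - 2]
    tail_dir = tail_dir / np.linalg.norm(tail_dir)
    side = np.array([0.6, -0.8, 0.0])
    for k in range(last, 76):
        step = tail_dir + 0.45 * side * (k - last + 1)
        ca[k] = ca[k - 1] + 3.8 * step / np.linalg.norm(step)

    _check_self_intersection(ca)
    rng = np.random.default_rng(seed)
    atoms = _backbone_atoms(chain, ca, UBIQUITIN_SEQUENCE, rng)
    return Structure(atoms)


# ---------------------------------------------------------------------------
# template complex
# ---------------------------------------------------------------------------

def make_template_complex(seed: int) -> TemplateComplex:
    """A three-helix bundle with the ubiquitin decoy posed on its
    helix-1/helix-3 face, free of inter-chain clashes at 2.4 Å."""
    uba, _ = make_solenoid(SolenoidSpec(seed=seed, helix_count=3))
    uba = uba.renamed_chain("A", "T")
    ub_local = make_ub_like_domain(seed, chain="V")

    helices = [h for h in _helix_poses(3)]
    h13_ca = np.vstack([_helix_ca(helices[0], 11, 0.0),
                        _helix_ca(helices[2], 11, 0.0)])
    h2_ca = _helix_ca(helices[1], 11, 0.0)
    face_center = h13_ca.mean(axis=0)
    f = face_center - h2_ca.mean(axis=0)
    f /= np.linalg.norm(f)

    t = np.array([0.0, 0.0, 1.0]) - (np.array([0.0, 0.0, 1.0]) @ f) * f
    t /= np.linalg.norm(t)
    rot = np.column_stack([np.cross(f, t), f, t])  # local y -> f, z -> t

    local_ca = np.array([[a.x, a.y, a.z] for a in ub_local.atoms
                         if a.name == "CA"])
    local_center = local_ca.mean(axis=0)
    uba_heavy = uba.coords_array(heavy_only=True)
    tree = cKDTree(uba_heavy)

    placed = None
    for d in np.arange(40.0, 8.0, -0.2):
        shift = face_center + d * f - rot @ local_center
        coords = np.array([[a.x, a.y, a.z] for a in ub_local.atoms]) @ rot.T \
            + shift
        min_dist = tree.query(coords)[0].min()
        if min_dist < 3.4:
            break
        placed = coords
    if placed is None:
        raise SyntheticError("could not pose the decoy against the bundle")

    ub_atoms = [Atom(a.chain, a.resnum, a.resname, a.name, a.element,
                     round(float(p[0]), 3), round(float(p[1]), 3),
                     round(float(p[2]), 3), a.occupancy, a.bfactor)
                for a, p in zip(ub_local.atoms, placed)]
    template = TemplateComplex.from_structure(
        uba.merged(Structure(ub_atoms)), uba_chain="T", ub_chain="V")
    report = detect_clashes(template.structure)
    if report.total():
        raise SyntheticError(
            f"generated template pose has {report.total()} clashes")
    return template


def make_docked_model(seed: int,
                      solenoid_spec: SolenoidSpec | None = None) -> DockedModel:
    """Convenience: solenoid + template + docking in one call."""
    from .structlib import assign_helices, decompose_overlapping_ubas

    spec = solenoid_spec or SolenoidSpec(seed=seed)
    receptor, _ = make_solenoid(spec)
    helices = assign_helices(receptor, chain="A")
    units = decompose_overlapping_ubas(helices)
    template = make_template_complex(seed)
    return docking.dock_ubiquitins(receptor, units, template)


# ---------------------------------------------------------------------------
# titration simulation
# ---------------------------------------------------------------------------

def simulate_titration(spec: TitrationSpec) -> TitrationSeries:
    """Fast-exchange titration: peaks move linearly with fraction bound.

    δ(L) = δ_free + f_b(P, L, Kd)·Δδ_max per perturbed residue, with the
    per-residue maximum shift split between ¹H and ¹⁵N components so the
    combined CSP at saturation equals Δδ_max. Gaussian noise is applied
    to ¹H shifts (σ) and ¹⁵N shifts (5σ); prolines are omitted from all
    peak lists.
    """
    rng = np.random.default_rng(spec.seed)
    observable = [r for r in spec.residues if r not in spec.prolines]
    base = {r: (float(rng.uniform(7.0, 9.5)), float(rng.uniform(105.0, 130.0)))
            for r in observable}
    perturbed = dict(spec.perturbed)
    split = {r: float(rng.uniform(0.25, 1.3)) for r in perturbed}  # radians

    points: List[Tuple[float, PeakList]] = []
    for eq in spec.equivalents:
        ligand = eq * spec.protein_uM
        fb = binding.fraction_bound(spec.protein_uM, ligand, spec.kd_uM) \
            if ligand > 0 else 0.0
        shifts: Dict[int, Tuple[float, float]] = {}
        for r in observable:
            dh, dn = base[r]
            if r in perturbed:
                psi = split[r]
                dh += fb * perturbed[r] * math.cos(psi)
                dn += fb * perturbed[r] * 5.0 * math.sin(psi)
            if spec.noise_sigma_ppm > 0:
                dh += float(rng.normal(0.0, spec.noise_sigma_ppm))
                dn += float(rng.normal(0.0, 5.0 * spec.noise_sigma_ppm))
            shifts[r] = (dh, dn)
        label = "apo" if eq == 0 else f"{eq:g} eq"
        points.append((ligand, PeakList(shifts, label=label)))
    return TitrationSeries(spec.protein_uM, points)


# ---------------------------------------------------------------------------
# PRE simulation
# ---------------------------------------------------------------------------

def simulate_pre_observed(model: DockedModel, site: pre_mod.SpinLabelSite,
                          noise_sigma: float, seed: int,
                          params: pre_mod.PREParams | None = None
                          ) -> pre_mod.PREProfile:
    """Predicted attenuation plus Gaussian noise, clipped at zero."""
    if noise_sigma < 0:
        raise SyntheticError("noise sigma must be non-negative")
    prediction = pre_mod.predict_attenuation(model, site, params)
    rng = np.random.default_rng(seed)
    values = {}
    for r in prediction.residues():
        if r in prediction.flagged:
            continue
        noisy = prediction.values[r] + float(rng.normal(0.0, noise_sigma)) \
            if noise_sigma > 0 else prediction.values[r]
        values[r] = max(noisy, 0.0)
    return pre_mod.PREProfile(values, frozenset())


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

#: seed used for the fixtures shipped with the package
BUNDLE_SEED = 20210

#: ITC protocol of the monoubiquitin titration fixture
BUNDLE_ITC_PROTOCOL = dict(cell_uM=150.0, syringe_uM=3000.0,
                           n_injections=38, injection_uL=1.0)
BUNDLE_ITC_TRUTH = dict(n=1.0, kd_uM=70.0, dh_cal_per_mol=-2000.0)


def write_fixture_bundle(outdir: str | Path, seed: int = BUNDLE_SEED) -> None:
    """Write the full synthetic fixture set (PDB/TSV + run config)."""
    from .structlib import write_pdb

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    solenoid, truth = make_solenoid(SolenoidSpec(seed=seed))
    write_pdb(solenoid, outdir / "solenoid.pdb")
    write_pdb(make_ub_like_domain(seed), outdir / "ubiquitin_decoy.pdb")
    template = make_template_complex(seed)
    write_pdb(template.structure, outdir / "template_complex.pdb")

    tdir = outdir / "titration"
    tdir.mkdir(exist_ok=True)
    series = simulate_titration(TitrationSpec(seed=seed))
    manifest = ["# ligand_uM\tpath"]
    for i, (ligand, peaks) in enumerate(series.points):
        name = f"point_{i:02d}.tsv"
        lines = [f"# {peaks.label}: residue\tdH_ppm\tdN_ppm"]
        for r in peaks.residues():
            dh, dn = peaks.shifts[r]
            lines.append(f"{r}\t{dh:.4f}\t{dn:.4f}")
        (tdir / name).write_text("\n".join(lines) + "\n")
        manifest.append(f"{ligand:.1f}\ttitration/{name}")
    (outdir / "titration_manifest.tsv").write_text("\n".join(manifest) + "\n")

    protocol = binding.ITCProtocol.uniform(**BUNDLE_ITC_PROTOCOL)
    itc_truth = binding.SingleSiteFit(**BUNDLE_ITC_TRUTH)
    sigma = binding.peak_noise_sigma(protocol, itc_truth)
    thermo = binding.simulate_itc(protocol, itc_truth, sigma, seed=seed)
    binding.write_thermogram(thermo, outdir / "itc_mono.tsv")

    model = make_docked_model(seed)
    site = pre_mod.attach_spin_label(model, "U1", 6)
    observed = simulate_pre_observed(model, site, noise_sigma=0.05, seed=seed)
    pre_mod.write_pre_profile(observed, outdir / "pre_k6c_observed.tsv")

    cfg = [
        "# soubakit run configuration (paths relative to this file)",
        "solenoid_pdb = solenoid.pdb",
        "template_pdb = template_complex.pdb",
        "template_uba_chain = T",
        "template_ub_chain = V",
        "titration_manifest = titration_manifest.tsv",
        "protein_uM = 500.0",
        "itc_thermogram = itc_mono.tsv",
        f"itc_cell_uM = {BUNDLE_ITC_PROTOCOL['cell_uM']}",
        f"itc_syringe_uM = {BUNDLE_ITC_PROTOCOL['syringe_uM']}",
        f"itc_injections = {BUNDLE_ITC_PROTOCOL['n_injections']}",
        f"itc_injection_uL = {BUNDLE_ITC_PROTOCOL['injection_uL']}",
        "pre_observed = pre_k6c_observed.tsv",
        "pre_sites = U1:6,U1:39,U1:48,U1:57",
        "csp_threshold_ppm = 0.2",
        "clash_cutoff_A = 2.4",
        "linkage_threshold_A = 9.0",
        "pre_ratio_threshold = 0.7",
        f"seed = {seed}",
    ]
    (outdir / "run.cfg").write_text("\n".join(cfg) + "\n")
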
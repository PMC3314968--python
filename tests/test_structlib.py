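import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soubakit import structlib
from soubakit.structlib import (
    Atom,
    GeometryError,
    HelixError,
    PDBParseError,
    SequenceError,
    Structure,
    Transformation,
    assign_helices,
    decompose_overlapping_ubas,
    kabsch_superpose,
    read_pdb,
    scan_signature_motifs,
    write_pdb,
)
from soubakit.synthetic import _helix_ca, _HelixPose

from .oracles import qcp_rmsd


def _rotation(axis, angle):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * k @ k


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

class TestPDBIO:
    def test_single_residue_roundtrip(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   7      11.000  -2.500   3.250"
            "  1.00 12.50           C\nEND\n")
        s = read_pdb(path)
        atom = s.atom("A", 7, "CA")
        assert (atom.x, atom.y, atom.z) == (11.0, -2.5, 3.25)
        assert atom.resname == "ALA" and atom.element == "C"
        assert atom.bfactor == pytest.approx(12.5)

    def test_solenoid_roundtrip_preserves_geometry(self, solenoid, tmp_path):
        structure, _ = solenoid
        path = tmp_path / "solenoid.pdb"
        write_pdb(structure, path)
        back = read_pdb(path)
        assert len(back.atoms) == len(structure.atoms)
        assert [a.name for a in back.atoms] == [a.name for a in structure.atoms]
        assert [a.resnum for a in back.atoms] == [a.resnum for a in structure.atoms]
        np.testing.assert_allclose(back.coords_array(),
                                   structure.coords_array(), atol=1e-3)

    def test_malformed_record_names_line(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1       1.000   2.000   3.000"
            "  1.00  0.00           C\n"
            "ATOM      2  CA  ALA A   2       XXXXX   2.000   3.000"
            "  1.00  0.00           C\n")
        with pytest.raises(PDBParseError, match="line 2"):
            read_pdb(path)

    def test_duplicate_serials_warn_but_parse(self, tmp_path, caplog):
        path = tmp_path / "dup.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1       1.000   2.000   3.000"
            "  1.00  0.00           C\n"
            "ATOM      1  CA  ALA A   2       4.000   5.000   6.000"
            "  1.00  0.00           C\n")
        with caplog.at_level(logging.WARNING):
            s = read_pdb(path)
        assert len(s.atoms) == 2
        assert any("duplicate atom serial" in r.message for r in caplog.records)

    def test_empty_model_is_an_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("HEADER    NOTHING\nEND\n")
        with pytest.raises(PDBParseError):
            read_pdb(path)


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

class TestKabsch:
    def test_identical_sets_give_identity(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        t, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-12)

    def test_recovers_constructed_rigid_motion(self):
        rng = np.random.default_rng(1)
        mobile = rng.normal(size=(12, 3))
        rot = _rotation([0, 0, 1], math.pi / 2)
        shift = np.array([5.0, -3.0, 2.0])
        reference = mobile @ rot.T + shift
        t, rmsd = kabsch_superpose(mobile, reference)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(t.rotation, rot, atol=1e-9)
        np.testing.assert_allclose(t.translation, shift, atol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_noisy_rmsd_matches_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mobile = rng.normal(size=(10, 3)) * 5.0
        rot = _rotation(rng.normal(size=3), rng.uniform(0, math.pi))
        reference = mobile @ rot.T + rng.normal(size=3)
        reference += rng.normal(scale=0.3, size=reference.shape)
        _, rmsd = kabsch_superpose(mobile, reference)
        assert rmsd == pytest.approx(qcp_rmsd(mobile, reference), abs=1e-6)

    def test_mirror_images_still_get_proper_rotation(self):
        pts = np.random.default_rng(3).normal(size=(9, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        t, _ = kabsch_superpose(pts, mirrored)
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(GeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(GeometryError):
            kabsch_superpose(line, line)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_rmsd_invariant_under_joint_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(7, 3)) * 4.0
        b = a + rng.normal(scale=0.5, size=a.shape)
        rot = _rotation(rng.normal(size=3), rng.uniform(0, math.pi))
        shift = rng.normal(size=3) * 10.0
        _, rmsd0 = kabsch_superpose(a, b)
        _, rmsd1 = kabsch_superpose(a @ rot.T + shift, b @ rot.T + shift)
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-9)


# ---------------------------------------------------------------------------
# transformation algebra
# ---------------------------------------------------------------------------

def test_bfactor_annotation_for_visual_export(solenoid):
    """Per-residue values (e.g. CSPs) can be written into the B-factor
    column for colouring in a viewer; unlisted residues get 0."""
    structure, _ = solenoid
    annotated = structure.with_bfactors({("A", 12): 0.41, ("A", 13): 0.28})
    assert annotated.atom("A", 12, "CA").bfactor == pytest.approx(0.41)
    assert annotated.atom("A", 1, "CA").bfactor == 0.0
    assert len(annotated.atoms) == len(structure.atoms)


def test_transformation_invert_roundtrip():
    rot = _rotation([1, 2, 3], 0.7)
    t = Transformation(rot, np.array([1.0, -2.0, 0.5]))
    pts = np.random.default_rng(5).normal(size=(6, 3))
    np.testing.assert_allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)


def test_transformation_rejects_reflection():
    with pytest.raises(ValueError):
        Transformation(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


# ---------------------------------------------------------------------------
# helix assignment
# ---------------------------------------------------------------------------

def _structure_from_ca(coords, chain="A"):
    atoms = [Atom(chain, i + 1, "ALA", "CA", "C", *map(float, p))
             for i, p in enumerate(coords)]
    return Structure(atoms)


class TestAssignHelices:
    def test_ideal_helix_is_one_segment(self):
        pose = _HelixPose(np.zeros(3), np.array([0.0, 0.0, 1.0]),
                          np.array([1.0, 0.0, 0.0]))
        s = _structure_from_ca(_helix_ca(pose, 12, 0.0))
        segments = assign_helices(s)
        assert [(h.start, h.end) for h in segments] == [(1, 12)]
        assert abs(segments[0].axis @ [0, 0, 1]) == pytest.approx(1.0, abs=1e-3)

    def test_extended_chain_has_no_helices(self):
        coords = np.outer(np.arange(15.0), [3.8, 0.0, 0.0])
        assert assign_helices(_structure_from_ca(coords)) == []

    def test_solenoid_boundaries_match_construction(self, solenoid):
        structure, truth = solenoid
        segments = assign_helices(structure, chain="A")
        assert len(segments) == len(truth.helix_bounds)
        for seg, (start, end) in zip(segments, truth.helix_bounds):
            assert abs(seg.start - start) <= 1
            assert abs(seg.end - end) <= 1

    def test_deterministic(self, solenoid):
        structure, _ = solenoid
        a = assign_helices(structure, chain="A")
        b = assign_helices(structure, chain="A")
        assert [(h.start, h.end) for h in a] == [(h.start, h.end) for h in b]

    def test_missing_ca_reported(self):
        atoms = [Atom("A", i + 1, "ALA", "CA", "C", 0.0, 0.0, 1.5 * i)
                 for i in range(8)]
        atoms[3] = Atom("A", 4, "ALA", "N", "N", 0.0, 0.0, 4.5)
        with pytest.raises(HelixError, match=r"\[4\]"):
            assign_helices(Structure(atoms))


# ---------------------------------------------------------------------------
# overlapping-UBA decomposition
# ---------------------------------------------------------------------------

def _fake_helices(n):
    axis = np.array([0.0, 0.0, 1.0])
    return [structlib.HelixSegment("A", 1 + 10 * i, 8 + 10 * i, axis)
            for i in range(n)]


class TestDecomposition:
    @pytest.mark.parametrize("n_helices,n_units", [(3, 1), (5, 2), (7, 3)])
    def test_unit_count(self, n_helices, n_units):
        units = decompose_overlapping_ubas(_fake_helices(n_helices))
        assert len(units) == n_units

    def test_consecutive_units_share_one_helix(self):
        units = decompose_overlapping_ubas(_fake_helices(5))
        assert units[0].helices[2] is units[1].helices[0]

    def test_helix_coverage(self):
        helices = _fake_helices(7)
        units = decompose_overlapping_ubas(helices)
        appearances = {id(h): 0 for h in helices}
        for u in units:
            for h in u.helices:
                appearances[id(h)] += 1
        # shared helices (3rd, 5th) appear twice, all others once
        assert [appearances[id(h)] for h in helices] == [1, 1, 2, 1, 2, 1, 1]

    @pytest.mark.parametrize("n", [0, 1, 2, 4, 6])
    def test_even_or_short_counts_rejected(self, n):
        with pytest.raises(HelixError, match="odd"):
            decompose_overlapping_ubas(_fake_helices(n))


# ---------------------------------------------------------------------------
# signature motifs
# ---------------------------------------------------------------------------

class TestMotifScan:
    @pytest.mark.parametrize("sequence,expected", [
        ("MGF", [(1, "MGF")]),
        ("AAKGFAA", [(3, "KGF")]),
        ("MGFLGYKGF", [(1, "MGF"), (4, "LGY"), (7, "KGF")]),
        ("AAAA", []),
    ])
    def test_examples(self, sequence, expected):
        assert scan_signature_motifs(sequence) == expected

    def test_scanning_a_fasta_record(self, tmp_path):
        fasta = tmp_path / "seqs.fasta"
        fasta.write_text(">domainA\nAAMGFAA\n>domainB\nQQQLGY\n")
        sequences = structlib.read_fasta(fasta)
        assert scan_signature_motifs(sequences["domainA"]) == [(3, "MGF")]
        assert scan_signature_motifs(sequences["domainB"]) == [(4, "LGY")]

    def test_illegal_character_position_reported(self):
        with pytest.raises(SequenceError, match="position 3"):
            scan_signature_motifs("MGX1F")

    def test_solenoid_sequence_has_one_motif_per_uba(self, solenoid):
        _, truth = solenoid
        hits = scan_signature_motifs(truth.sequence)
        assert [pos for pos, _ in hits] == list(truth.motif_positions)
        assert [text for _, text in hits] == ["MGF", "KGF", "LGY"]
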
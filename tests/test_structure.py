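"""Contact shell, interaction geometry, and superposition on constructed
fixtures with hand-computable geometry."""

import numpy as np
import pytest

from porphyfit.structure import (
    Atom,
    StructureModel,
    contact_residues,
    detect_hbonds,
    detect_pi_stacking,
    heme_plane_rotation,
    kabsch,
    parse_structure,
    superpose_ca,
)
from conftest import make_porphyrin, make_protein_scaffold

LIG = "X:HEM:201"

PDB_FIXTURE = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  C   ALA A   1      10.762   5.173  -4.284  1.00 10.00           C
ATOM      4  O   ALA A   1       9.545   5.135  -4.466  1.00 10.00           O
ATOM      5  CB  ALA A   1      11.713   7.470  -4.541  1.00 10.00           C
ATOM      6  N   SER A   2      11.367   4.459  -3.336  1.00 10.00           N
ATOM      7  CA ASER A   2      10.627   3.567  -2.437  0.40 10.00           C
ATOM      8  CA BSER A   2      10.639   3.570  -2.441  0.60 10.00           C
ATOM      9  CB  SER A   2      11.532   2.420  -1.984  1.00 10.00           C
ATOM     10  OG  SER A   2      12.685   2.885  -1.299  1.00 10.00           O
HETATM   11 FE   HEM B 201       2.000   1.000   0.500  1.00 15.00          FE
HETATM   12  NA  HEM B 201       4.010   1.050   0.510  1.00 15.00           N
END
"""


def test_parse_pdb_fixture(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(PDB_FIXTURE)
    model = parse_structure(path)
    # 12 records, but the SER CA altloc pair collapses to the 0.60 conformer
    assert len(model) == 11
    chains = {a.chain for a in model.atoms}
    assert chains == {"A", "B"}
    hetero = [a for a in model.atoms if a.hetero]
    assert {a.resname for a in hetero} == {"HEM"}
    ser_ca = [a for a in model.atoms if a.resname == "SER" and a.name == "CA"]
    assert len(ser_ca) == 1
    assert ser_ca[0].occupancy == pytest.approx(0.60)
    assert ser_ca[0].pos == pytest.approx((10.639, 3.570, -2.441))


def test_parse_empty_file_fails(tmp_path):
    path = tmp_path / "empty.pdb"
    path.write_text("")
    with pytest.raises(ValueError):
        parse_structure(path)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def _residue(chain, resname, resnum, atoms):
    return [Atom(chain, resname, resnum, "", name, el, tuple(pos), False)
            for name, el, pos in atoms]


def test_contact_census_distance_threshold():
    # ligand = single-atom heme stand-in at origin; CB at 3.9 in, CB at 4.1 out
    lig = [Atom("X", "HEM", 201, "", "FE", "Fe", (0.0, 0.0, 0.0), True)]
    near = _residue("A", "LEU", 10, [("CB", "C", np.array([3.9, 0, 0]))])
    far = _residue("A", "VAL", 11, [("CB", "C", np.array([4.1, 0, 0]))])
    model = StructureModel(lig + near + far)
    report = contact_residues(model, LIG, cutoff=4.0)
    assert report.residue_names == ["LEU10"]
    assert report.contacts[0]["min_distance"] == pytest.approx(3.9)
    assert contact_residues(model, LIG, cutoff=0.0).contacts == []


def test_contact_census_separates_waters_and_hydrogens():
    lig = [Atom("X", "HEM", 201, "", "FE", "Fe", (0.0, 0.0, 0.0), True)]
    protein = _residue("A", "TYR", 5, [("OH", "O", np.array([3.0, 0, 0])),
                                       ("HH", "H", np.array([2.0, 0, 0]))])
    water = [Atom("W", "HOH", 301, "", "O", "O", (0.0, 3.2, 0.0), True)]
    # a residue reachable only through its hydrogen must not count
    h_only = _residue("A", "GLY", 6, [("HA", "H", np.array([0, 0, 2.5])),
                                      ("CA", "C", np.array([0, 0, 8.0]))])
    model = StructureModel(lig + protein + water + h_only)
    report = contact_residues(model, LIG, cutoff=4.0)
    assert report.residue_names == ["TYR5"]
    assert [w["resname"] for w in report.waters] == ["HOH"]


def test_contact_report_monotone_in_cutoff(porphyrin_complex):
    lig_atoms = [a for a in porphyrin_complex.atoms if a.resname == "HEM"]
    shell = [Atom("A", "PHE", 50, "", "CZ", "C", (0.0, 3.7, 3.0), False),
             Atom("A", "TRP", 60, "", "CZ2", "C", (3.9, 0.0, 1.5), False)]
    model = StructureModel(porphyrin_complex.atoms + shell)
    tight = {tuple(c.values()) for c in contact_residues(model, LIG, 3.5).contacts}
    loose = {tuple(c.values()) for c in contact_residues(model, LIG, 4.0).contacts}
    tight_keys = {t[:4] for t in tight}
    loose_keys = {t[:4] for t in loose}
    assert tight_keys <= loose_keys


def test_empty_ligand_selection_rejected(porphyrin_complex):
    with pytest.raises(ValueError, match="matched no"):
        contact_residues(porphyrin_complex, "Z:HEM:999", cutoff=4.0)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def _hbond_model(donor_pos, o_pos=(0.0, 0.0, 0.0), ante_pos=(-1.5, 0.0, 0.0)):
    """SER OG donor vs a carboxylate-like ligand oxygen with antecedent."""
    lig = [Atom("X", "HEM", 201, "", "O1A", "O", tuple(o_pos), True),
           Atom("X", "HEM", 201, "", "CGA", "C", tuple(ante_pos), True)]
    ser = _residue("A", "SER", 7, [("OG", "O", np.asarray(donor_pos)),
                                   ("CB", "C", np.asarray(donor_pos) + [0, 1.5, 0])])
    return StructureModel(lig + ser)


def test_hbond_detected_at_ideal_geometry():
    # O...O at 2.8 A, donor opposite the antecedent (angle 180 deg)
    model = _hbond_model((2.8, 0.0, 0.0))
    bonds = detect_hbonds(model, LIG, d_max=3.5, angle_min=90.0)
    assert any(b.acceptor.endswith("O1A") and b.distance == pytest.approx(2.8)
               for b in bonds)


def test_hbond_rejected_far_or_bad_angle():
    assert detect_hbonds(_hbond_model((10.0, 0.0, 0.0)), LIG) == []
    # donor on the antecedent side: D-A-AA angle ~0, sterically impossible
    model = _hbond_model((-2.8, 0.0, 0.0), ante_pos=(-1.5, 0.0, 0.0))
    bonds = detect_hbonds(model, LIG, d_max=3.5, angle_min=90.0)
    assert all(not b.acceptor.endswith("O1A") for b in bonds)


def test_hbond_tyrosine_hydroxyl_to_propionate():
    # TYR OH donor at 2.7 A from a propionate oxygen
    lig = [Atom("X", "HEM", 201, "", "O1D", "O", (0.0, 0.0, 0.0), True),
           Atom("X", "HEM", 201, "", "CGD", "C", (0.0, -1.4, 0.0), True)]
    tyr = _residue("A", "TYR", 137, [("OH", "O", np.array([1.9, 1.9, 0.0])),
                                     ("CZ", "C", np.array([2.9, 2.9, 0.0]))])
    model = StructureModel(lig + tyr)
    bonds = detect_hbonds(model, LIG)
    assert any("TYR137/OH" in b.donor and "O1D" in b.acceptor for b in bonds)


# ---------------------------------------------------------------------------
# pi stacking
# ---------------------------------------------------------------------------

def _phe_ring(center, normal_rot=None, chain="A", resnum=53):
    """Regular hexagon (benzene geometry, r = 1.39 A) in the xy-plane."""
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    atoms = []
    for j, name in enumerate(names):
        phi = np.radians(60.0 * j)
        pos = np.array([1.39 * np.cos(phi), 1.39 * np.sin(phi), 0.0])
        if normal_rot is not None:
            pos = normal_rot @ pos
        atoms.append(Atom(chain, "PHE", resnum, "", name, "C",
                          tuple(pos + np.asarray(center)), False))
    return atoms


def test_parallel_stack_detected(porphyrin_complex):
    # ring I of the porphyrin is centered at (3.2, 0, 0); park a parallel
    # benzene 3.8 A above it
    model = StructureModel(porphyrin_complex.atoms + _phe_ring((3.2, 0.0, 3.8)))
    stacks = detect_pi_stacking(model, LIG)
    hit = [s for s in stacks if s.residue.endswith("PHE53") and s.porphyrin_ring == "I"]
    assert hit
    assert hit[0].centroid_distance == pytest.approx(3.8, abs=0.05)
    assert hit[0].interplanar_angle == pytest.approx(0.0, abs=1.0)


def test_perpendicular_or_distant_rings_not_stacked(porphyrin_complex):
    rx = np.array([[1.0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]])  # 90 deg about x
    perp = _phe_ring((3.2, 0.0, 9.0), normal_rot=rx)
    model = StructureModel(porphyrin_complex.atoms + perp)
    assert detect_pi_stacking(model, LIG) == []
    tilted = _phe_ring((3.2, 0.0, 3.8), normal_rot=rx, resnum=54)
    model2 = StructureModel(porphyrin_complex.atoms + tilted)
    assert all(not s.residue.endswith("PHE54") for s in detect_pi_stacking(model2, LIG))


def test_incomplete_ring_skipped_with_warning(porphyrin_complex):
    broken = _phe_ring((3.2, 0.0, 3.8))[:-2]  # drop two carbons
    model = StructureModel(porphyrin_complex.atoms + broken)
    with pytest.warns(UserWarning, match="atoms missing"):
        stacks = detect_pi_stacking(model, LIG)
    assert all("PHE" not in s.residue for s in stacks)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def _rand_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def test_self_superposition_is_identity(porphyrin_complex):
    res = superpose_ca(porphyrin_complex, porphyrin_complex)
    assert res.rmsd == pytest.approx(0.0, abs=1e-10)
    np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)


def test_known_rigid_transform_recovered(rng):
    rot = _rand_rotation(rng)
    t = np.array([5.0, -3.0, 8.0])
    ref = StructureModel(make_protein_scaffold())
    mob = StructureModel(make_protein_scaffold(transform=rot, translation=t))
    res = superpose_ca(ref, mob)
    assert res.rmsd <= 1e-8
    assert res.n_atoms == 7
    # recovered transform inverts the applied one
    np.testing.assert_allclose(res.rotation @ rot, np.eye(3), atol=1e-8)


def test_rmsd_invariant_under_rigid_pretransform(rng):
    ref = StructureModel(make_protein_scaffold())
    jitter = StructureModel([
        Atom(a.chain, a.resname, a.resnum, a.icode, a.name, a.element,
             tuple(a.xyz + rng.normal(0, 0.5, 3)), a.hetero)
        for a in make_protein_scaffold()
    ])
    base = superpose_ca(ref, jitter).rmsd
    for _ in range(3):
        rot = _rand_rotation(rng)
        t = rng.normal(0, 10, 3)
        moved = jitter.transformed(rot, t)
        assert abs(superpose_ca(ref, moved).rmsd - base) <= 1e-8


def test_rotation_matrix_is_proper_orthonormal(rng):
    ref = StructureModel(make_protein_scaffold())
    mob = StructureModel(make_protein_scaffold(
        transform=_rand_rotation(rng), translation=np.array([1.0, 2.0, 3.0])))
    r = superpose_ca(ref, mob).rotation
    np.testing.assert_allclose(r.T @ r, np.eye(3), atol=1e-10)
    assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-10)


def test_degenerate_and_undersized_inputs_rejected():
    collinear = np.array([[float(i), 0.0, 0.0] for i in range(5)])
    with pytest.raises(ValueError, match="collinear|degenerate"):
        kabsch(collinear, collinear + 1.0)
    with pytest.raises(ValueError, match="at least 3"):
        kabsch(collinear[:2], collinear[:2])


# ---------------------------------------------------------------------------
# heme plane rotation
# ---------------------------------------------------------------------------

def test_identical_complexes_have_zero_rotation(porphyrin_complex):
    res = heme_plane_rotation(porphyrin_complex, porphyrin_complex, LIG, LIG)
    assert res.in_plane_deg == pytest.approx(0.0, abs=1e-6)
    assert res.normal_tilt_deg == pytest.approx(0.0, abs=1e-6)


@pytest.mark.parametrize("angle", [30.0, 90.0, 120.0])
def test_in_plane_rotation_recovered(porphyrin_complex, angle):
    rotated = StructureModel(make_protein_scaffold() + make_porphyrin(rot_deg=angle))
    res = heme_plane_rotation(porphyrin_complex, rotated, LIG, LIG)
    assert res.in_plane_deg == pytest.approx(angle, abs=0.1)
    assert res.normal_tilt_deg == pytest.approx(0.0, abs=0.1)


def test_rotation_detected_through_global_frame_change(porphyrin_complex, rng):
    # rotate the WHOLE complex rigidly and the porphyrin by 90 deg extra:
    # superposition must strip the global motion and report only the 90
    rot = _rand_rotation(rng)
    t = np.array([-4.0, 7.0, 2.0])
    atoms = make_protein_scaffold(transform=rot, translation=t) + make_porphyrin(
        rot_deg=90.0, transform=rot, translation=t)
    res = heme_plane_rotation(porphyrin_complex, StructureModel(atoms), LIG, LIG)
    assert res.in_plane_deg == pytest.approx(90.0, abs=0.1)


def test_mirrored_porphyrin_reports_flipped_plane(porphyrin_complex):
    # reflection reversing the ring sense: the oriented plane normal flips,
    # which must surface as a 180 deg tilt, not a NaN
    mirror = np.diag([-1.0, 1.0, 1.0])
    atoms = make_protein_scaffold() + make_porphyrin(transform=mirror)
    res = heme_plane_rotation(porphyrin_complex, StructureModel(atoms),
                              LIG, LIG, superpose=False)
    assert np.isfinite(res.in_plane_deg) and np.isfinite(res.normal_tilt_deg)
    assert res.normal_tilt_deg == pytest.approx(180.0, abs=1.0)
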
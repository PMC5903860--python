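"""Parsing, unit handling, template annotation and round-trips."""

import numpy as np
import pytest

import memflex as mx
from memflex.traj_io import ParseError, TemplateError

GRO_FIXTURE = """\
one lipid two waters
 7
    1LIP      P    1   1.000   2.000   7.000
    1LIP     C2    2   1.000   2.000   6.750
    1LIP     A1    3   0.920   2.000   6.600
    1LIP     B1    4   1.080   2.000   6.600
    2SOL     OW    5   3.000   3.000   9.500
    2SOL    HW1    6   3.050   3.000   9.550
    3SOL     OW    7   2.000   2.000   0.500
   5.00000   5.00000  10.00000
"""

PDB_FIXTURE = """\
CRYST1   50.000   50.000  100.000  90.00  90.00  90.00 P 1
ATOM      1  P   LIP     1      15.000  20.000  70.000  1.00  0.00           P
ATOM      2  C2  LIP     1      15.000  20.000  67.500  1.00  0.00           C
END
"""

TEMPLATE = mx.LipidTemplate(residue_name="LIP", phosphate_atom="P",
                            glycerol_central_atom="C2",
                            sn1_carbons=("A1",), sn2_carbons=("B1",))


def test_gro_round_trip(tmp_path):
    """Coordinates survive write → read at GRO precision (3 decimals)."""
    p = tmp_path / "in.gro"
    p.write_text(GRO_FIXTURE)
    atoms, frame = mx.read_structure(p)
    assert len(atoms) == 7
    assert len({a.residue_id for a in atoms}) == 3
    assert frame.coords[0, 2] == pytest.approx(7.0)
    assert frame.box.tolist() == [5.0, 5.0, 10.0]
    out = tmp_path / "out.gro"
    mx.write_gro(out, atoms, frame)
    atoms2, frame2 = mx.read_structure(out)
    np.testing.assert_allclose(frame2.coords, frame.coords, atol=5e-4)
    assert [a.atom_name for a in atoms2] == [a.atom_name for a in atoms]


def test_pdb_coordinates_are_converted_to_nm(tmp_path):
    p = tmp_path / "s.pdb"
    p.write_text(PDB_FIXTURE)
    atoms, frame = mx.read_structure(p)
    assert frame.coords[0, 0] == pytest.approx(1.5)
    assert frame.box[2] == pytest.approx(10.0)


def test_truncated_gro_record_reports_line_number(tmp_path):
    bad = GRO_FIXTURE.splitlines()
    bad[4] = bad[4][:30]  # truncate a coordinate field
    p = tmp_path / "bad.gro"
    p.write_text("\n".join(bad))
    with pytest.raises(ParseError, match="line 5"):
        mx.read_structure(p)


def test_pdb_without_box_is_rejected(tmp_path):
    p = tmp_path / "nobox.pdb"
    p.write_text("\n".join(l for l in PDB_FIXTURE.splitlines()
                           if not l.startswith("CRYST1")))
    with pytest.raises(ParseError, match="CRYST1"):
        mx.read_structure(p)


def test_frame_text_round_trip_and_times(tmp_path):
    frames = [mx.Frame(time=10.0 * t, box=np.array([5.0, 5.0, 10.0]),
                       coords=np.random.default_rng(t).uniform(0, 5, (7, 3)))
              for t in range(11)]
    traj = mx.Trajectory(frames)
    p = tmp_path / "t.frames"
    mx.write_frame_text(p, traj)
    back = mx.read_trajectory(p, format="frame-text")
    assert len(back) == 11
    assert back.dt == pytest.approx(10.0)
    assert back.duration == pytest.approx(110.0)
    for a, b in zip(traj.frames, back.frames):
        np.testing.assert_allclose(a.coords, b.coords, atol=1e-6)


def test_trajectory_rejects_mismatched_atom_counts():
    f1 = mx.Frame(0.0, np.ones(3), np.zeros((100, 3)))
    f2 = mx.Frame(10.0, np.ones(3), np.zeros((99, 3)))
    with pytest.raises(ValueError, match="atom count"):
        mx.Trajectory([f1, f2])


def test_trajectory_rejects_non_monotonic_times():
    mk = lambda t: mx.Frame(t, np.ones(3), np.zeros((5, 3)))
    with pytest.raises(ValueError, match="increasing"):
        mx.Trajectory([mk(0.0), mk(20.0), mk(10.0)])


def test_single_frame_trajectory_has_undefined_dt():
    traj = mx.Trajectory([mx.Frame(0.0, np.ones(3), np.zeros((5, 3)))])
    assert traj.dt is None


def _toy_atoms(resname="LIP", with_water=True):
    atoms = [mx.Atom(1, "P", resname, 1, "P"),
             mx.Atom(2, "C2", resname, 1, "C"),
             mx.Atom(3, "A1", resname, 1, "C"),
             mx.Atom(4, "B1", resname, 1, "C")]
    if with_water:
        atoms += [mx.Atom(5, "OW", "SOL", 2, "O"),
                  mx.Atom(6, "HW1", "SOL", 2, "H")]
    return atoms


def test_templates_resolve_roles_and_terminal_carbons():
    long_tmpl = mx.LipidTemplate(
        residue_name="LNG", phosphate_atom="P", glycerol_central_atom="C2",
        sn1_carbons=tuple(f"A{k}" for k in range(1, 19)),
        sn2_carbons=tuple(f"B{k}" for k in range(1, 23)))
    atoms = ([mx.Atom(1, "P", "LNG", 1, "P"), mx.Atom(2, "C2", "LNG", 1, "C")]
             + [mx.Atom(2 + k, f"A{k}", "LNG", 1, "C") for k in range(1, 19)]
             + [mx.Atom(20 + k, f"B{k}", "LNG", 1, "C") for k in range(1, 23)])
    topo = mx.apply_lipid_templates(atoms, [long_tmpl])
    lip = topo.lipids[0]
    assert atoms[lip.sn1_terminal].atom_name == "A18"
    assert atoms[lip.sn2_terminal].atom_name == "B22"
    # carbonyls excluded from the default aliphatic set
    assert lip.sn1[0] not in lip.aliphatic
    assert lip.sn2[0] not in lip.aliphatic
    assert lip.sn1_terminal in lip.aliphatic


def test_ignored_residues_are_excluded():
    atoms = _toy_atoms() + [mx.Atom(7, "O1", "CHOL", 3, "O")]
    topo = mx.apply_lipid_templates(atoms, [TEMPLATE], ignore_residues={"CHOL"})
    assert len(topo.lipids) == 1
    assert topo.n_waters == 1


def test_unmatched_residue_is_named_in_error():
    atoms = _toy_atoms() + [mx.Atom(7, "O1", "CHOL", 3, "O")]
    with pytest.raises(TemplateError, match="CHOL"):
        mx.apply_lipid_templates(atoms, [TEMPLATE])


def test_missing_template_atom_names_residue_and_atom():
    tmpl = mx.LipidTemplate(residue_name="LIP", phosphate_atom="P",
                            glycerol_central_atom="C2",
                            sn1_carbons=("A1", "C218"), sn2_carbons=("B1",))
    with pytest.raises(TemplateError, match="C218"):
        mx.apply_lipid_templates(_toy_atoms(), [tmpl])


def test_template_application_is_idempotent_and_order_independent():
    other = mx.LipidTemplate(residue_name="XXX", phosphate_atom="P",
                             glycerol_central_atom="C2",
                             sn1_carbons=("A1",), sn2_carbons=("B1",))
    atoms = _toy_atoms()
    t1 = mx.apply_lipid_templates(atoms, [TEMPLATE, other])
    t2 = mx.apply_lipid_templates(atoms, [other, TEMPLATE])
    t3 = mx.apply_lipid_templates(atoms, [TEMPLATE, other])
    for a, b in ((t1, t2), (t1, t3)):
        assert [l.phosphate for l in a.lipids] == [l.phosphate for l in b.lipids]
        assert a.water_oxygens == b.water_oxygens


def test_gro_reader_agrees_with_mdanalysis(tmp_path):
    """Independent cross-check of the GRO path against MDAnalysis."""
    mda = pytest.importorskip("MDAnalysis")
    p = tmp_path / "x.gro"
    p.write_text(GRO_FIXTURE)
    atoms, frame = mx.read_structure(p)
    u = mda.Universe(str(p))
    np.testing.assert_allclose(frame.coords, u.atoms.positions / 10.0, atol=1e-4)
    assert [a.atom_name for a in atoms] == list(u.atoms.names)
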
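"""Loading, atom-selection tables and the minimum-distance primitive."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dyncomp.exceptions import FormatError, SelectionError, ValidationError
from dyncomp.exporters import format_pdb_atom_line
from dyncomp.trajectory_io import (
    atom_selection,
    load_trajectory,
    min_distance,
    min_distance_series,
    polar_head_atoms,
    try_atom_selection,
)
from helpers import build_traj


def _write_multimodel_pdb(path, frames, residues):
    """frames: list of per-atom xyz arrays; residues: list of (name, resname, resseq)."""
    lines = []
    for f, coords in enumerate(frames):
        lines.append(f"MODEL     {f + 1:4d}")
        for serial, ((name, resname, resseq), xyz) in enumerate(zip(residues, coords), 1):
            lines.append(format_pdb_atom_line(serial, name, resname, "A", resseq, np.asarray(xyz)))
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


@pytest.fixture()
def three_model_pdb(tmp_path):
    atoms = [("N", "ALA", 1), ("CA", "ALA", 1), ("CB", "ALA", 1),
             ("N", "SER", 2), ("CA", "SER", 2), ("OG", "SER", 2)]
    frames = [np.arange(18).reshape(6, 3) + 10.0 * f for f in range(3)]
    path = tmp_path / "three.pdb"
    _write_multimodel_pdb(path, frames, atoms)
    return path, frames


def test_multi_model_frame_count_and_stride(three_model_pdb):
    path, frames = three_model_pdb
    traj = load_trajectory(str(path))
    assert traj.n_frames == 3
    assert len(traj.residues) == 2
    np.testing.assert_allclose(traj.coords[1], frames[1], atol=5e-4)

    strided = load_trajectory(str(path), stride=2)
    assert strided.n_frames == 2  # ceil(3/2): models 1 and 3
    np.testing.assert_allclose(strided.coords, traj.coords[::2])


def test_atom_count_mismatch_raises_format_error(tmp_path, three_model_pdb):
    topo_path = tmp_path / "topo.pdb"
    atoms = [("N", "ALA", 1), ("CA", "ALA", 1)]  # fewer atoms than the frames
    _write_multimodel_pdb(topo_path, [np.zeros((2, 3))], atoms)
    with pytest.raises(FormatError):
        load_trajectory(str(topo_path), str(three_model_pdb[0]))


def test_single_frame_input_rejected(tmp_path):
    path = tmp_path / "one.pdb"
    _write_multimodel_pdb(path, [np.zeros((1, 3))], [("CA", "ALA", 1)])
    with pytest.raises(ValidationError):
        load_trajectory(str(path))


def test_hetero_residues_skipped(tmp_path):
    path = tmp_path / "het.pdb"
    atoms = [("CA", "ALA", 1), ("CA", "GLY", 2), ("O", "HOH", 3)]
    _write_multimodel_pdb(path, [np.arange(9).reshape(3, 3), np.arange(9).reshape(3, 3) + 1],
                          atoms)
    traj = load_trajectory(str(path))
    assert [r.res_name for r in traj.residues] == ["ALA", "GLY"]
    assert traj.n_atoms == 2


@pytest.mark.parametrize(
    "code,expected",
    [
        ("ARG", {"NE", "CZ", "NH1", "NH2"}),
        ("TRP", {"NE1"}),
        ("HIS", {"CG", "ND1", "CE1", "NE2", "CD2"}),
        ("GLU", {"CD", "OE1", "OE2"}),
        ("THR", {"OG1"}),
        ("ALA", set()),
        ("LEU", set()),
        ("HSD", {"CG", "ND1", "CE1", "NE2", "CD2"}),  # force-field alias
    ],
)
def test_polar_head_group_table(code, expected):
    assert polar_head_atoms(code) == expected


def test_polar_head_unknown_code():
    with pytest.raises(ValidationError):
        polar_head_atoms("XYZ")


def _two_residue_traj(coords_a, coords_b, names_a=None, names_b=None,
                      resnames=("ALA", "ALA"), seq=(1, 5)):
    coords_a, coords_b = np.asarray(coords_a, float), np.asarray(coords_b, float)
    na, nb = coords_a.shape[1], coords_b.shape[1]
    names = list(names_a or [f"C{i}" for i in range(na)]) + \
        list(names_b or [f"C{i}" for i in range(nb)])
    coords = np.concatenate([coords_a, coords_b], axis=1)
    return build_traj(coords, names, [0] * na + [1] * nb, list(resnames), seq_indices=seq)


def test_min_distance_minimal_case():
    a = np.zeros((2, 1, 3))
    b = np.zeros((2, 2, 3))
    b[:, 0] = (3, 0, 0)
    b[:, 1] = (5, 0, 0)
    traj = _two_residue_traj(a, b, names_a=["CB"], names_b=["CB", "CG"])
    sa = atom_selection(traj, 0, "sidechain_nonH")
    sb = atom_selection(traj, 1, "sidechain_nonH")
    assert min_distance(traj, 0, sa, sb) == pytest.approx(3.0)
    assert min_distance(traj, 0, sb, sa) == pytest.approx(3.0)  # symmetric


def test_min_distance_self_pair_rejected():
    traj = _two_residue_traj(np.zeros((2, 1, 3)), np.ones((2, 1, 3)),
                             names_a=["CB"], names_b=["CB"])
    sel = atom_selection(traj, 0, "sidechain_nonH")
    with pytest.raises(SelectionError):
        min_distance(traj, 0, sel, sel)


def test_min_distance_matches_brute_force_and_rigid_invariance():
    rng = np.random.default_rng(42)
    a = rng.normal(size=(3, 5, 3)) * 4
    b = rng.normal(size=(3, 7, 3)) * 4 + 6
    traj = _two_residue_traj(a, b, names_a=[f"C{i}" for i in range(5)],
                             names_b=[f"C{i}" for i in range(7)])
    sa = atom_selection(traj, 0, "sidechain_nonH")
    sb = atom_selection(traj, 1, "sidechain_nonH")
    for f in range(3):
        brute = min(
            np.linalg.norm(a[f, i] - b[f, j]) for i in range(5) for j in range(7)
        )
        assert min_distance(traj, f, sa, sb) == pytest.approx(brute, abs=1e-12)

    # whole-frame rotation + translation leaves every distance unchanged
    rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
    moved = np.einsum("fij,kj->fik", traj.coords, rot) + np.array([10.0, -3.0, 7.0])
    traj2 = _two_residue_traj(moved[:, :5], moved[:, 5:],
                              names_a=[f"C{i}" for i in range(5)],
                              names_b=[f"C{i}" for i in range(7)])
    s2a = atom_selection(traj2, 0, "sidechain_nonH")
    s2b = atom_selection(traj2, 1, "sidechain_nonH")
    np.testing.assert_allclose(
        min_distance_series(traj, sa, sb), min_distance_series(traj2, s2a, s2b),
        atol=1e-9,
    )


def test_selection_modes_exclude_backbone_and_hydrogens():
    names = ["N", "CA", "C", "O", "CB", "OG", "HB1", "1HG", "HA"]
    coords = np.zeros((2, len(names) + 1, 3))
    all_names = names + ["CA"]
    traj = build_traj(coords, all_names, [0] * len(names) + [1], ["SER", "GLY"])

    side = atom_selection(traj, 0, "sidechain_nonH")
    assert side.atom_names == frozenset({"CB", "OG"})
    polar = atom_selection(traj, 0, "polar_head")
    assert polar.atom_names == frozenset({"OG"})
    calpha = atom_selection(traj, 0, "calpha")
    assert calpha.atom_names == frozenset({"CA"})

    # glycine has no side-chain heavy atoms
    assert try_atom_selection(traj, 1, "sidechain_nonH") is None
    with pytest.raises(SelectionError):
        atom_selection(traj, 1, "sidechain_nonH")
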
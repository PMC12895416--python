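"""Featurization: structure parsing, pair accounting, distances, contacts,
dihedrals and rigid-body alignment."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mdcompress.features import (
    Topology,
    align_and_flatten,
    backbone_dihedrals,
    enumerate_pairs,
    exponential_contacts,
    pairwise_distances,
    read_structure,
    superpose,
)
from mdcompress.synthetic import polyalanine_pdb


def random_rigid_motion(frames, rng):
    rot = Rotation.random(random_state=np.random.RandomState(
        rng.integers(2 ** 31))).as_matrix()
    shift = 10.0 * rng.standard_normal(3)
    return frames @ rot.T + shift


# ---------------------------------------------------------------------------
# read_structure
# ---------------------------------------------------------------------------

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
END
"""

HETATM_ONLY = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
END
"""


def test_read_structure_minimal(tmp_path):
    path = tmp_path / "two.pdb"
    path.write_text(MINIMAL_PDB)
    top, coords = read_structure(path)
    assert top.n_atoms == 2
    assert top.n_residues == 1
    assert coords.shape == (2, 3)
    np.testing.assert_allclose(coords[1], [1.458, 0.0, 0.0])
    assert list(top.atom_names) == ["N", "CA"]
    assert top.heavy.all()


def test_read_structure_polyalanine_backbone_count(polyala39_pdb):
    top, coords = read_structure(polyala39_pdb)
    assert top.n_residues == 39
    assert len(top.select("backbone")) == 39 * 3 == 117
    assert coords.shape[0] == top.n_atoms


def test_read_structure_rejects_hetatm_only(tmp_path):
    path = tmp_path / "water.pdb"
    path.write_text(HETATM_ONLY)
    with pytest.raises(ValueError, match="no ATOM records"):
        read_structure(path)


def test_read_structure_rejects_duplicate_serials(tmp_path):
    path = tmp_path / "dup.pdb"
    path.write_text(MINIMAL_PDB.replace("ATOM      2", "ATOM      1"))
    with pytest.raises(ValueError, match="duplicate"):
        read_structure(path)


# ---------------------------------------------------------------------------
# enumerate_pairs
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_residues, selection, expected", [
    (39, "backbone", 6786),   # 117 backbone atoms of a 39-residue chain
    (35, "backbone", 5460),   # 105 backbone atoms of a 35-residue chain
    (35, "calpha", 595),      # 35 C-alpha atoms
])
def test_pair_counts_match_protein_bookkeeping(tmp_path, n_residues,
                                               selection, expected):
    path = tmp_path / "chain.pdb"
    polyalanine_pdb(n_residues, path)
    top, _ = read_structure(path)
    pairs = enumerate_pairs(top, selection, 0)
    assert pairs.shape == (expected, 2)


def test_dipeptide_heavy_pairs(dipeptide_pdb):
    top, _ = read_structure(dipeptide_pdb)
    assert len(top.select("heavy")) == 10
    assert enumerate_pairs(top, "heavy", 0).shape[0] == 45


@pytest.mark.parametrize("k", [2, 5, 17, 88, 200])
def test_pair_count_closed_form(k):
    top = Topology(np.array(["CA"] * k, dtype=object),
                   np.arange(1, k + 1), np.ones(k, dtype=bool))
    pairs = enumerate_pairs(top, "calpha", 0)
    assert pairs.shape[0] == k * (k - 1) // 2
    # lexicographic order, i < j
    assert np.all(pairs[:, 0] < pairs[:, 1])
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    assert np.array_equal(order, np.arange(len(pairs)))


def test_min_residue_separation_filters_pairs():
    top = Topology(np.array(["CA"] * 6, dtype=object),
                   np.arange(1, 7), np.ones(6, dtype=bool))
    pairs = enumerate_pairs(top, "calpha", min_residue_separation=3)
    seps = np.abs(np.diff(pairs, axis=1))
    assert (seps >= 3).all()
    assert pairs.shape[0] == 6  # (1,4),(1,5),(1,6),(2,5),(2,6),(3,6)


def test_empty_selection_is_an_error():
    top = Topology(np.array(["CB", "CB"], dtype=object),
                   np.array([1, 1]), np.ones(2, dtype=bool))
    with pytest.raises(ValueError, match="backbone"):
        enumerate_pairs(top, "backbone", 0)


# ---------------------------------------------------------------------------
# distances and contacts
# ---------------------------------------------------------------------------

def test_pairwise_distance_values():
    frame = np.array([[[0.0, 0, 0], [3.0, 4.0, 0], [0.0, 0, 0]]])
    fm = pairwise_distances(frame, np.array([[0, 1], [0, 2]]))
    np.testing.assert_allclose(fm.values, [[5.0, 0.0]])


def test_pairwise_distances_match_bruteforce(rng):
    frames = rng.standard_normal((4, 5, 3))
    pairs = np.array([[i, j] for i in range(5) for j in range(i + 1, 5)])
    fm = pairwise_distances(frames, pairs)
    for t in range(4):
        for c, (i, j) in enumerate(pairs):
            expected = np.sqrt(((frames[t, i] - frames[t, j]) ** 2).sum())
            assert fm.values[t, c] == pytest.approx(expected, abs=1e-12)


def test_pairwise_distances_index_out_of_range():
    with pytest.raises(IndexError):
        pairwise_distances(np.zeros((1, 2, 3)), np.array([[0, 5]]))


def test_exponential_contacts_definition(rng):
    d = np.abs(rng.standard_normal((10, 4))) * 5
    from mdcompress.containers import FeatureMatrix
    c = exponential_contacts(FeatureMatrix(d), d0=2.0)
    np.testing.assert_allclose(c.values, np.exp(-d / 2.0))
    assert ((c.values > 0) & (c.values <= 1)).all()
    # boundary cases
    fm = FeatureMatrix(np.array([[0.0], [2.0]]))
    c2 = exponential_contacts(fm, d0=2.0)
    assert c2.values[0, 0] == pytest.approx(1.0)
    assert c2.values[1, 0] == pytest.approx(np.exp(-1.0))


def test_exponential_contacts_rejects_bad_d0():
    from mdcompress.containers import FeatureMatrix
    with pytest.raises(ValueError, match="d0"):
        exponential_contacts(FeatureMatrix(np.ones((2, 1))), d0=0.0)


def test_contacts_invariant_under_rigid_motion(rng):
    frames = rng.standard_normal((3, 8, 3)) * 4
    pairs = np.array([[0, 4], [1, 7], [2, 3]])
    moved = random_rigid_motion(frames, rng)
    c1 = exponential_contacts(pairwise_distances(frames, pairs), 1.5)
    c2 = exponential_contacts(pairwise_distances(moved, pairs), 1.5)
    np.testing.assert_allclose(c1.values, c2.values, atol=1e-10)


# ---------------------------------------------------------------------------
# dihedrals
# ---------------------------------------------------------------------------

def _four_atom_topology():
    # two residues, each with N, CA, C
    return Topology(np.array(["N", "CA", "C"] * 2, dtype=object),
                    np.array([1, 1, 1, 2, 2, 2]), np.ones(6, dtype=bool))


def _dihedral_oracle(p0, p1, p2, p3):
    """Independent oracle: project the flanking bonds onto the plane
    orthogonal to the central bond and take the signed angle between them."""
    b0 = p0 - p1
    b1 = (p2 - p1) / np.linalg.norm(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return np.arctan2(np.dot(np.cross(b1, v), w), np.dot(v, w))


def test_dihedral_cis_and_trans_conventions():
    top = _four_atom_topology()
    # psi_1 uses atoms N1, CA1, C1, N2; place them planar
    cis = np.array([[-0.5, 1.0, 0], [0, 0, 0], [1, 0, 0], [1.5, 1.0, 0],
                    [2.5, 1.0, 0], [3.0, 0.0, 0]], dtype=float)
    trans = cis.copy()
    trans[3] = [1.5, -1.0, 0]           # N2 on the opposite side: trans
    fm_cis = backbone_dihedrals(cis, top)
    fm_trans = backbone_dihedrals(trans, top)
    psi_col = fm_cis.labels.index("psi_1")
    assert fm_cis.values[0, psi_col] == pytest.approx(0.0, abs=1e-12)
    # trans sits on the +-pi branch boundary, reported as -pi in [-pi, pi)
    assert fm_trans.values[0, psi_col] == pytest.approx(-np.pi)


def test_dihedrals_match_stepwise_oracle(rng):
    top = _four_atom_topology()
    frames = rng.standard_normal((6, 6, 3)) * 3
    fm = backbone_dihedrals(frames, top)
    quads = {"phi_2": [2, 3, 4, 5], "psi_1": [0, 1, 2, 3]}
    for label, (a, b, c, d) in quads.items():
        col = fm.labels.index(label)
        for t in range(6):
            expected = _dihedral_oracle(frames[t, a], frames[t, b],
                                        frames[t, c], frames[t, d])
            if expected >= np.pi:
                expected -= 2 * np.pi
            assert fm.values[t, col] == pytest.approx(expected, abs=1e-10)


def test_dihedrals_match_mdtraj(rng):
    mdtraj = pytest.importorskip("mdtraj")
    n_res = 5
    top = Topology(np.array(["N", "CA", "C"] * n_res, dtype=object),
                   np.repeat(np.arange(1, n_res + 1), 3),
                   np.ones(3 * n_res, dtype=bool))
    frames = rng.standard_normal((8, 3 * n_res, 3)) * 3

    md_top = mdtraj.Topology()
    chain = md_top.add_chain()
    for r in range(n_res):
        res = md_top.add_residue("ALA", chain)
        for name in ("N", "CA", "C"):
            md_top.add_atom(name, mdtraj.element.get_by_symbol(name[0]), res)
    traj = mdtraj.Trajectory(frames / 10.0, md_top)   # Angstrom -> nm
    _, phi = mdtraj.compute_phi(traj)
    _, psi = mdtraj.compute_psi(traj)

    fm = backbone_dihedrals(frames, top)
    ours_phi = fm.values[:, [fm.labels.index(f"phi_{i}")
                             for i in range(2, n_res + 1)]]
    ours_psi = fm.values[:, [fm.labels.index(f"psi_{i}")
                             for i in range(1, n_res)]]
    # both live on the circle; compare as complex phases
    np.testing.assert_allclose(np.exp(1j * ours_phi), np.exp(1j * phi),
                               atol=1e-6)
    np.testing.assert_allclose(np.exp(1j * ours_psi), np.exp(1j * psi),
                               atol=1e-6)


def test_dihedral_count_for_chain():
    # an R-residue chain has 2*(R-1) phi/psi angles
    n_res = 35
    top = Topology(np.array(["N", "CA", "C"] * n_res, dtype=object),
                   np.repeat(np.arange(1, n_res + 1), 3),
                   np.ones(3 * n_res, dtype=bool))
    frames = np.random.default_rng(0).standard_normal((2, 3 * n_res, 3)) * 3
    fm = backbone_dihedrals(frames, top)
    assert fm.n_features == 2 * (n_res - 1) == 68


def test_dihedrals_invariant_under_rigid_motion(rng):
    top = _four_atom_topology()
    frames = rng.standard_normal((5, 6, 3)) * 3
    moved = random_rigid_motion(frames, rng)
    a = backbone_dihedrals(frames, top).values
    b = backbone_dihedrals(moved, top).values
    np.testing.assert_allclose(np.exp(1j * a), np.exp(1j * b), atol=1e-10)


def test_missing_backbone_atom_is_an_error():
    top = Topology(np.array(["N", "CA", "C", "N", "CA"], dtype=object),
                   np.array([1, 1, 1, 2, 2]), np.ones(5, dtype=bool))
    with pytest.raises(ValueError, match="residue 2.*C"):
        backbone_dihedrals(np.zeros((1, 5, 3)), top)


def test_shifted_dihedrals_relocate_branch_cut(rng):
    # angles clustered around +-pi wrap badly unshifted; the shifted
    # convention makes the series unimodal
    top = _four_atom_topology()
    base = np.array([[-0.5, 1.0, 0], [0, 0, 0], [1, 0, 0], [1.5, -1.0, 0],
                     [2.5, -1.0, 0], [3.0, 0.0, 0]], dtype=float)
    frames = np.repeat(base[None], 200, axis=0)
    frames += 0.05 * rng.standard_normal(frames.shape)
    psi_col = 1
    raw = backbone_dihedrals(frames, top).values[:, psi_col]
    shifted = backbone_dihedrals(frames, top, shifted=True).values[:, psi_col]
    assert raw.std() > 1.0          # wrap artifact dominates
    assert shifted.std() < 0.5      # removed by the shift
    np.testing.assert_allclose(np.exp(1j * shifted), np.exp(1j * raw),
                               atol=1e-10)


# ---------------------------------------------------------------------------
# feature spec dispatch
# ---------------------------------------------------------------------------

def test_feature_spec_dispatch_matches_direct_calls(rng):
    from mdcompress.features import FeatureSpec, build_features
    top = _four_atom_topology()
    frames = rng.standard_normal((5, 6, 3)) * 3
    ref = frames[0]

    contact = build_features(
        FeatureSpec("contact", selection="backbone", d0=2.0), frames, top)
    pairs = enumerate_pairs(top, "backbone", 0)
    expected = exponential_contacts(pairwise_distances(frames, pairs), 2.0)
    np.testing.assert_allclose(contact.values, expected.values, atol=1e-12)

    dihed = build_features(FeatureSpec("dihedral"), frames, top)
    np.testing.assert_allclose(
        dihed.values, backbone_dihedrals(frames, top).values, atol=1e-12)

    pos = build_features(FeatureSpec("position", selection="all"),
                         frames, top, reference=ref)
    assert pos.n_features == 18


def test_feature_spec_validation():
    from mdcompress.features import FeatureSpec, build_features
    with pytest.raises(ValueError, match="family"):
        FeatureSpec("angles")
    with pytest.raises(ValueError, match="d0"):
        FeatureSpec("contact", d0=-1.0)
    with pytest.raises(ValueError, match="distinct"):
        FeatureSpec("distance", pairs=np.array([[1, 1]]))
    with pytest.raises(ValueError, match="reference"):
        build_features(FeatureSpec("position"), np.zeros((1, 6, 3)),
                       _four_atom_topology())


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def test_align_identity_frame(rng):
    ref = rng.standard_normal((20, 3)) * 5
    fm = align_and_flatten(ref[None], ref, np.arange(20))
    np.testing.assert_allclose(fm.values[0], ref.ravel(), atol=1e-10)


def test_align_recovers_rigidly_moved_frame(rng):
    ref = rng.standard_normal((20, 3)) * 5
    moved = random_rigid_motion(ref[None], rng)[0]
    aligned = superpose(moved, ref, np.arange(20))
    rmsd = np.sqrt(((aligned - ref) ** 2).sum(axis=1).mean())
    assert rmsd < 1e-8


def test_align_never_increases_rmsd(rng):
    ref = rng.standard_normal((15, 3)) * 5
    for _ in range(5):
        frame = ref + rng.standard_normal((15, 3))
        frame = random_rigid_motion(frame[None], rng)[0]
        before = np.sqrt(((frame - ref) ** 2).sum(axis=1).mean())
        aligned = superpose(frame, ref, np.arange(15))
        after = np.sqrt(((aligned - ref) ** 2).sum(axis=1).mean())
        assert after <= before + 1e-12


def test_position_feature_count_577_atoms(rng):
    ref = rng.standard_normal((577, 3)) * 10
    frames = ref[None] + 0.1 * rng.standard_normal((2, 577, 3))
    fm = align_and_flatten(frames, ref, np.arange(30))
    assert fm.n_features == 1731


def test_align_requires_three_atoms(rng):
    ref = rng.standard_normal((5, 3))
    with pytest.raises(ValueError, match="3 atoms"):
        align_and_flatten(ref[None], ref, np.array([0, 1]))
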
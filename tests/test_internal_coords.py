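"""Internal-coordinate round trips, NeRF geometric identities, chirality."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pepdiff.internal_coords import (
    AngleEmbedding,
    IDEAL_GEOMETRY,
    ResidueAngleTable,
    bond_angle,
    dihedral,
    embed_angles,
    extract_angles,
    nerf_place,
    nerf_reconstruct,
    unembed_angles,
    wrap_angle,
)
from pepdiff.io_structures import BackboneStructure

from conftest import random_angle_table


# ----------------------------------------------------------------------
# extraction
def test_ideal_helix_angles_extracted(helix_chain):
    structure, table, _ = helix_chain
    out = extract_angles(structure)
    valid = out.valid_mask
    assert np.allclose(out.angles[valid], table.angles[valid], atol=1e-6)
    # the stated torsions specifically
    assert np.allclose(np.degrees(out.phi[1:]), -57.0, atol=1e-5)
    assert np.allclose(np.degrees(out.psi[:-1]), -47.0, atol=1e-5)


def test_two_residue_chain_masks_termini():
    table = random_angle_table(2, np.random.default_rng(0))
    structure = nerf_reconstruct(table)
    out = extract_angles(structure)
    assert not out.valid_mask[0, 0]          # phi_1
    assert not out.valid_mask[1, 1]          # psi_2
    assert not out.valid_mask[1, 2]          # omega_2
    assert out.valid_mask[0, 3] and out.valid_mask[1, 3]


def test_extract_requires_two_residues():
    coords = np.zeros((1, 3, 3))
    coords[0] = [[0, 0, 0], [1.46, 0, 0], [2.0, 1.0, 0]]
    s = BackboneStructure([1], ["GLY"], coords)
    with pytest.raises(ValueError):
        extract_angles(s)


def test_collinear_atoms_error_names_residue():
    coords = np.zeros((2, 3, 3))
    coords[0] = [[0, 0, 0], [1, 0, 0], [2, 0, 0]]  # collinear N-CA-C
    coords[1] = [[3, 1, 0], [4, 1, 0], [4, 2, 0]]
    s = BackboneStructure([1, 2], ["GLY", "GLY"], coords)
    with pytest.raises(ValueError, match="residue 1"):
        extract_angles(s)


def test_extract_invariant_under_rigid_motion():
    rng = np.random.default_rng(3)
    table = random_angle_table(20, rng)
    s = nerf_reconstruct(table)
    ref = extract_angles(s).angles
    for seed in range(5):
        r = np.random.default_rng(seed)
        R = Rotation.random(rng=r).as_matrix()
        t = r.normal(scale=50.0, size=3)
        moved = BackboneStructure(
            s.residue_ids, s.residue_names,
            (s.atom_coords.reshape(-1, 3) @ R.T + t.reshape(1, 3)).reshape(-1, 3, 3),
        )
        out = extract_angles(moved).angles
        assert np.abs(wrap_angle(out - ref)).max() < 1e-9


# ----------------------------------------------------------------------
# embedding
@pytest.mark.parametrize("angle,expected", [
    (0.0, (1.0, 0.0)),
    (np.pi / 2, (0.0, 1.0)),
    (np.pi, (-1.0, 0.0)),
    (-np.pi + 1e-12, (-1.0, 0.0)),
])
def test_embed_angle_values(angle, expected):
    angles = np.full((3, 6), angle)
    angles[:, 3:] = 1.9  # valid bond angles
    table = ResidueAngleTable.from_angles(angles)
    emb = embed_angles(table)
    # phi of a middle residue carries the requested angle
    np.testing.assert_allclose(emb.values[1, 0:2], expected, atol=1e-9)
    norms = emb.values[:, 0::2] ** 2 + emb.values[:, 1::2] ** 2
    np.testing.assert_allclose(norms, 1.0, atol=1e-12)


def test_unembed_examples_and_scale_invariance():
    v = np.zeros((1, 12))
    v[0, 0] = 2.0                 # phi pair (2, 0): non-unit, still angle 0
    v[0, 2], v[0, 3] = 0.0, 1.0   # psi = pi/2
    v[0, 4] = 1.0                 # omega = 0
    v[0, 7::2] = 1.0              # bond-angle pairs (0, 1) -> pi/2
    table = unembed_angles(AngleEmbedding(v), clamp_bond_angles=False,
                           valid_mask=np.ones((1, 6), dtype=bool))
    assert table.angles[0, 0] == 0.0
    assert np.isclose(table.angles[0, 1], np.pi / 2)
    assert np.isclose(table.angles[0, 3], np.pi / 2)


def test_unembed_zero_norm_pair_falls_back_to_sentinel():
    v = np.zeros((2, 12))
    v[:, 0::2] = 1.0
    v[1, 0:2] = 0.0  # degenerate phi pair
    mask = np.ones((2, 6), dtype=bool)
    table = unembed_angles(AngleEmbedding(v), valid_mask=mask)
    assert np.isclose(table.angles[1, 0], IDEAL_GEOMETRY.phi_ideal)


def test_unembed_inverts_embed():
    for seed in range(20):
        table = random_angle_table(15, np.random.default_rng(seed))
        back = unembed_angles(embed_angles(table), valid_mask=table.valid_mask,
                              clamp_bond_angles=False)
        assert np.abs(wrap_angle(back.angles - table.angles)).max() < 1e-12


# ----------------------------------------------------------------------
# NeRF
def test_nerf_place_satisfies_geometric_identities():
    rng = np.random.default_rng(7)
    for _ in range(50):
        A, B, C = rng.normal(size=(3, 3))
        l = rng.uniform(1.0, 2.0)
        theta = rng.uniform(0.2, 2.9)
        tau = rng.uniform(-np.pi, np.pi)
        try:
            D = nerf_place(A, B, C, l, theta, tau)
        except ValueError:
            continue
        assert abs(np.linalg.norm(D - C) - l) < 1e-9
        assert abs(bond_angle(B, C, D) - theta) < 1e-9
        assert abs(wrap_angle(dihedral(A, B, C, D) - tau)) < 1e-9


def test_nerf_place_periodic_in_tau():
    A, B, C = np.array([0.0, 0, 0]), np.array([1.0, 0, 0]), np.array([1.0, 1, 0])
    d1 = nerf_place(A, B, C, 1.0, 1.2, 0.7)
    d2 = nerf_place(A, B, C, 1.0, 1.2, 0.7 + 2 * np.pi)
    np.testing.assert_allclose(d1, d2, atol=1e-9)


def test_nerf_place_mirror_symmetry():
    A, B, C = np.array([0.0, 0, 0]), np.array([1.0, 0, 0]), np.array([1.0, 1, 0])
    dp = nerf_place(A, B, C, 1.0, np.pi / 2, np.pi / 2)
    dm = nerf_place(A, B, C, 1.0, np.pi / 2, -np.pi / 2)
    # frame plane is z=0: mirror images across it
    np.testing.assert_allclose(dp[:2], dm[:2], atol=1e-9)
    np.testing.assert_allclose(dp[2], -dm[2], atol=1e-9)


def test_nerf_place_rejects_collinear_frame():
    with pytest.raises(ValueError):
        nerf_place([0, 0, 0], [1, 0, 0], [2, 0, 0], 1.0, 1.5, 0.0)


def test_angle_roundtrip_through_reconstruction():
    for seed in range(25):
        table = random_angle_table(30, np.random.default_rng(seed))
        out = extract_angles(nerf_reconstruct(table))
        err = np.abs(wrap_angle(out.angles - table.angles))[table.valid_mask]
        assert err.max() < 1e-6


def test_coordinate_roundtrip_up_to_rigid_transform():
    rng = np.random.default_rng(9)
    table = random_angle_table(25, rng)
    s = nerf_reconstruct(table)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(scale=30.0, size=3)
    moved = BackboneStructure(
        s.residue_ids, s.residue_names,
        (s.atom_coords.reshape(-1, 3) @ R.T + t).reshape(-1, 3, 3),
    )
    rebuilt = nerf_reconstruct(extract_angles(moved))
    a = moved.atom_coords.reshape(-1, 3)
    b = rebuilt.atom_coords.reshape(-1, 3)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    rot, rssd = Rotation.align_vectors(a, b)
    rmsd = np.sqrt(((rot.apply(b) - a) ** 2).sum(axis=1).mean())
    assert rmsd < 1e-6


def test_reconstructed_bond_lengths_match_constants():
    table = random_angle_table(20, np.random.default_rng(4))
    X = nerf_reconstruct(table).atom_coords
    n_ca = np.linalg.norm(X[:, 1] - X[:, 0], axis=1)
    ca_c = np.linalg.norm(X[:, 2] - X[:, 1], axis=1)
    c_n = np.linalg.norm(X[1:, 0] - X[:-1, 2], axis=1)
    assert np.abs(n_ca - IDEAL_GEOMETRY.l_n_ca).max() < 1e-9
    assert np.abs(ca_c - IDEAL_GEOMETRY.l_ca_c).max() < 1e-9
    assert np.abs(c_n - IDEAL_GEOMETRY.l_c_n).max() < 1e-9


def test_trans_chain_calpha_spacing():
    angles = np.tile(IDEAL_GEOMETRY.sentinels(), (10, 1))
    table = ResidueAngleTable.from_angles(angles)  # omega = pi throughout
    ca = nerf_reconstruct(table).calpha
    d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    assert np.all(np.abs(d - 3.80) < 0.05)


def test_backbone_chirality_right_handed_helix():
    """The canonical L-helix torsions reconstruct to a right-handed helix
    (positive C-alpha virtual torsion on every 4-residue window), and the
    mirror image of that chain is left-handed: the rebuild realizes, and
    extraction distinguishes, backbone chirality."""
    angles = np.tile(IDEAL_GEOMETRY.sentinels(), (12, 1))
    angles[:, 0] = np.deg2rad(-57.0)
    angles[:, 1] = np.deg2rad(-47.0)
    s = nerf_reconstruct(ResidueAngleTable.from_angles(angles))
    ca = s.calpha
    virtual = [dihedral(ca[i], ca[i + 1], ca[i + 2], ca[i + 3]) for i in range(9)]
    assert all(v > 0 for v in virtual)
    mirrored = s.atom_coords * np.array([1.0, 1.0, -1.0])
    ms = BackboneStructure(s.residue_ids, s.residue_names, mirrored)
    mca = ms.calpha
    assert all(
        dihedral(mca[i], mca[i + 1], mca[i + 2], mca[i + 3]) < 0 for i in range(9)
    )
    # mirroring negates every extracted torsion
    out = extract_angles(ms)
    ref = extract_angles(s)
    valid = ref.valid_mask[:, :2]
    assert np.allclose(out.angles[:, :2][valid], -ref.angles[:, :2][valid], atol=1e-9)
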
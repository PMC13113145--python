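"""Metric oracles: contacts vs brute force, closed-form examples,
rigid-transform invariance."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pepdiff.fixtures import make_ideal_chain
from pepdiff.internal_coords import IDEAL_GEOMETRY, ResidueAngleTable, extract_angles
from pepdiff.io_structures import BackboneStructure
from pepdiff.metrics import (
    aromaticity,
    assign_secondary,
    clash_count,
    evaluate_batch,
    evaluate_complex,
    gravy,
    helicity,
    interface_contacts,
    isoelectric_point,
    length_contact_correlation,
    radius_of_gyration,
    rama_density,
    rama_helix_fraction,
    sequence_identity,
    shape_ratio,
)


def brute_force_contacts(a, b, cutoff=4.5):
    n = 0
    for p in a:
        for q in b:
            if np.linalg.norm(p - q) <= cutoff:
                n += 1
    return n


# ----------------------------------------------------------------------
def test_contacts_cutoff_boundary():
    lig = np.array([[0.0, 0, 0]])
    tgt = np.array([[4.4, 0, 0], [4.6, 0, 0]])
    assert interface_contacts(lig, tgt) == 1
    assert interface_contacts(lig, np.array([[4.5, 0, 0]])) == 1  # <= cutoff


def test_contacts_disjoint_chains():
    rng = np.random.default_rng(0)
    a = rng.normal(size=(30, 3))
    b = rng.normal(size=(30, 3)) + 100.0
    assert interface_contacts(a, b) == 0


def test_contacts_match_brute_force():
    rng = np.random.default_rng(1)
    for _ in range(40):
        a = rng.uniform(0, 12, size=(rng.integers(1, 40), 3))
        b = rng.uniform(0, 12, size=(rng.integers(1, 40), 3))
        assert interface_contacts(a, b) == brute_force_contacts(a, b)


# ----------------------------------------------------------------------
def test_radius_of_gyration_closed_forms():
    assert radius_of_gyration(np.array([[1.0, 2.0, 3.0]])) == 0.0
    assert np.isclose(radius_of_gyration(np.array([[0.0, 0, 0], [2.0, 0, 0]])), 1.0)
    square = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
    assert np.isclose(radius_of_gyration(square), np.sqrt(0.5))


# ----------------------------------------------------------------------
@pytest.mark.parametrize("a,b,expected", [
    ("ACDE", "ACDE", 100.0),
    ("ACDE", "ACDEFGHI", 50.0),
    ("AAAA", "CCCC", 0.0),
])
def test_sequence_identity_examples(a, b, expected):
    assert sequence_identity(a, b) == expected


def test_sequence_identity_symmetric_denominator():
    assert sequence_identity("ACDEFGHI", "ACDE") == 50.0


# ----------------------------------------------------------------------
def _table(phi_deg, psi_deg, n=10):
    angles = np.tile(IDEAL_GEOMETRY.sentinels(), (n, 1))
    angles[:, 0] = np.deg2rad(phi_deg)
    angles[:, 1] = np.deg2rad(psi_deg)
    return ResidueAngleTable.from_angles(angles)


def test_secondary_structure_windows():
    helix = _table(-57, -47)
    strand = _table(-135, 135)
    coil = _table(60, 60)
    assert set(assign_secondary(helix)[1:-1]) == {"H"}
    assert helicity(helix) == 1.0
    assert rama_helix_fraction(helix) == 1.0
    assert set(assign_secondary(strand)[1:-1]) == {"E"}
    assert helicity(strand) == 0.0
    assert rama_helix_fraction(strand) == 0.0
    assert helicity(coil) == 0.0


def test_masked_termini_labelled_coil():
    labels = assign_secondary(_table(-57, -47))
    assert labels[0] == "C" and labels[-1] == "C"  # phi_1 / psi_L masked


def test_mixed_table_half_helix():
    angles = np.tile(IDEAL_GEOMETRY.sentinels(), (10, 1))
    # residues 1..10; torsion-defined ones are 2..9: plant 4 helix, 4 strand
    angles[:5, 0], angles[:5, 1] = np.deg2rad(-57), np.deg2rad(-47)
    angles[5:, 0], angles[5:, 1] = np.deg2rad(-135), np.deg2rad(135)
    t = ResidueAngleTable.from_angles(angles)
    assert rama_helix_fraction(t) == 0.5


def test_rama_density_mass_and_location():
    t = _table(-57, -47, n=12)
    h = rama_density(t)
    assert h.shape == (36, 36)
    assert h.sum() == 10  # torsion-defined residues
    # all mass in the single helical bin
    assert h.max() == 10


# ----------------------------------------------------------------------
def test_clash_examples(helix_chain):
    s, _, _ = helix_chain
    assert clash_count(s) == 0
    coords = np.zeros((2, 3, 3))
    coords[0] = [[0, 0, 0], [1.46, 0, 0], [2.4, 1.1, 0]]
    coords[1] = [[20, 0, 0], [21.46, 0, 0], [22.4, 1.1, 0]]
    far = BackboneStructure([1, 2], ["GLY", "GLY"], coords)
    assert clash_count(far) == 0
    coords2 = coords.copy()
    coords2[1] = coords[0] + np.array([1.0, 0, 0])  # overlapping distant residue
    near = BackboneStructure([1, 5], ["GLY", "GLY"], coords2)
    # residue ids are not adjacent in index (0 vs 1 are adjacent) ->
    # adjacency exclusion applies to chain positions, use two chains
    assert clash_count([far, near]) > 0
    assert clash_count([far, near], clash_cutoff=0.0) == 0


def test_clash_adjacent_residues_excluded(helix_chain):
    s, _, _ = helix_chain
    # shrinking the cutoff to a covalent-bond distance still reports zero
    # because bonded/adjacent pairs are excluded by construction
    assert clash_count(s, clash_cutoff=1.4) == 0


# ----------------------------------------------------------------------
def test_shape_ratio_limits():
    line = np.column_stack([np.linspace(0, 10, 20), np.zeros(20), np.zeros(20)])
    assert shape_ratio(line) == pytest.approx(1e6)
    tetra = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
    assert np.isclose(shape_ratio(tetra), 1.0, atol=1e-9)


def test_shape_ratio_monotone_under_stretch():
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(50, 3))
    base = shape_ratio(pts)
    for k in (1.5, 2.0, 4.0):
        stretched = pts * np.array([k, 1.0, 1.0])
        assert shape_ratio(stretched) >= base


# ----------------------------------------------------------------------
def test_gravy_kyte_doolittle():
    assert gravy("III") == pytest.approx(4.5)
    assert gravy("RRR") == pytest.approx(-4.5)


def test_aromaticity_fraction():
    assert aromaticity("FWYA") == pytest.approx(0.75)


def test_isoelectric_point_root_contract():
    from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint
    for seq in ("G", "ACDEFGHIKL", "KKKK", "DDDD"):
        pi = isoelectric_point(seq)
        assert abs(IsoelectricPoint(seq).charge_at_pH(pi)) < 1e-4
    assert 5.0 < isoelectric_point("G") < 7.5  # near terminal-pKa midpoint


# ----------------------------------------------------------------------
def test_length_contact_correlation():
    lin = [(i, 2 * i + 1) for i in range(10)]
    assert length_contact_correlation(lin) == pytest.approx(1.0)
    anti = [(i, -3 * i) for i in range(10)]
    assert length_contact_correlation(anti) == pytest.approx(-1.0)
    rng = np.random.default_rng(3)
    rand = list(zip(rng.integers(5, 30, 1000), rng.integers(0, 40, 1000)))
    assert abs(length_contact_correlation(rand)) < 0.1
    assert np.isnan(length_contact_correlation([(1, 2), (3, 4)]))
    assert np.isnan(length_contact_correlation([(1, 2)] * 5))


# ----------------------------------------------------------------------
def test_evaluate_complex_and_rigid_invariance(toy_pair):
    tgt = toy_pair.target.structure
    bnd = toy_pair.binder.structure
    report = evaluate_complex(tgt, bnd, binder_sequence=toy_pair.binder.sequence,
                              native_sequence=toy_pair.binder.sequence)
    assert report.contacts == toy_pair.metadata["planted_contacts"]
    assert report.seq_identity == 100.0
    assert 0.0 <= report.helicity <= 1.0

    rng = np.random.default_rng(4)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(scale=40.0, size=3)

    def move(s):
        return BackboneStructure(
            s.residue_ids, s.residue_names,
            (s.atom_coords.reshape(-1, 3) @ R.T + t).reshape(-1, 3, 3),
            chain_id=s.chain_id)

    moved = evaluate_complex(move(tgt), move(bnd),
                             binder_sequence=toy_pair.binder.sequence)
    assert moved.contacts == report.contacts
    assert moved.clashes == report.clashes
    assert np.isclose(moved.rg, report.rg, atol=1e-6)
    assert np.isclose(moved.shape_ratio, report.shape_ratio, atol=1e-4)
    assert np.isclose(moved.helicity, report.helicity, atol=1e-6)


def test_plddt_hook_records_mean(toy_pair):
    plddt = np.full(toy_pair.binder.structure.n_residues, 55.0)
    report = evaluate_complex(toy_pair.target.structure, toy_pair.binder.structure,
                              binder_sequence=toy_pair.binder.sequence, plddt=plddt)
    assert report.metadata["mean_plddt"] == pytest.approx(55.0)
    with pytest.raises(ValueError):
        evaluate_complex(toy_pair.target.structure, toy_pair.binder.structure,
                         binder_sequence=toy_pair.binder.sequence,
                         plddt=np.ones(3))


def test_helix_binder_reports_full_helicity(helix_chain):
    s, _, seq = helix_chain
    target, _, _ = make_ideal_chain("strand", 20, seed=4)
    target = target.translated(np.array([40.0, 0.0, 0.0]))
    report = evaluate_complex(target, s, binder_sequence=seq)
    assert report.helicity == 1.0


def test_evaluate_batch_rows_and_aggregate(toy_pair, helix_chain):
    s, _, seq = helix_chain
    target, _, _ = make_ideal_chain("coil", 20, seed=5)
    target = target.translated(np.array([40.0, 0.0, 0.0]))
    reports = [
        evaluate_complex(toy_pair.target.structure, toy_pair.binder.structure,
                         binder_sequence=toy_pair.binder.sequence),
        evaluate_complex(target, s, binder_sequence=seq),
    ]
    df, agg = evaluate_batch(reports)
    assert len(df) == 2
    assert "helicity" in agg and {"mean", "median", "sd"} <= set(agg["helicity"])
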
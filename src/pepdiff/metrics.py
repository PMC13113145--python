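"""Evaluation metrics for designed peptide binders.

Three families of metrics are computed from the Cartesian coordinates
and the co-generated sequence:

* interface: heavy-atom contact count across the target/binder chains
  at a 4.5 A Euclidean cutoff;
* topology: radius of gyration, gyration-tensor shape anisotropy,
  torsion-window secondary structure (helicity, helical Ramachandran
  fraction, full Ramachandran density) and steric clash count;
* sequence/physicochemistry: global-alignment identity against the
  native ligand with a max-length denominator, Kyte-Doolittle GRAVY,
  aromaticity and the isoelectric point.

Secondary structure is assigned by a torsion-window classifier rather
than hydrogen-bond geometry: a residue with phi in [-100, -30] deg and
psi in [-67, -7] deg is helical (H), phi in [-180, -90] and psi in
[90, 180] is strand (E), anything else coil (C).  Generated backbones
carry no side chains, so contact and clash counting fall back to
backbone heavy atoms; the report metadata records this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .internal_coords import ResidueAngleTable, extract_angles
from .io_structures import BackboneStructure, validate_model_sequence

__all__ = [
    "MetricReport",
    "interface_contacts",
    "radius_of_gyration",
    "sequence_identity",
    "assign_secondary",
    "helicity",
    "rama_helix_fraction",
    "rama_density",
    "clash_count",
    "shape_ratio",
    "gravy",
    "aromaticity",
    "isoelectric_point",
    "length_contact_correlation",
    "evaluate_complex",
    "evaluate_batch",
]

CONTACT_CUTOFF = 4.5        # A, heavy-atom interface contact threshold
CLASH_CUTOFF = 2.5          # A, heavy-atom steric clash threshold
SHAPE_RATIO_FLOOR = 1e-6    # floor on the smallest principal radius
SHAPE_RATIO_CAP = 1e6
PKA_TABLE = "Bjellqvist (biopython IsoelectricPoint)"

# torsion windows in degrees: (phi_lo, phi_hi, psi_lo, psi_hi)
HELIX_WINDOW = (-100.0, -30.0, -67.0, -7.0)
STRAND_WINDOW = (-180.0, -90.0, 90.0, 180.0)


@dataclass
class MetricReport:
    """One evaluated complex; fractions in [0, 1], distances in angstroms."""

    contacts: int
    rg: float
    helicity: float
    rama_helix: float
    shape_ratio: float
    clashes: int
    gravy: float
    aromaticity: float
    isoelectric_point: float
    seq_identity: float | None = None
    metadata: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = asdict(self)
        row.pop("metadata")
        return row


# ----------------------------------------------------------------------
def interface_contacts(
    ligand_atoms: np.ndarray,
    target_atoms: np.ndarray,
    d_cutoff: float = CONTACT_CUTOFF,
) -> int:
    """Number of cross-chain heavy-atom pairs within ``d_cutoff`` (<=)."""
    lig = np.asarray(ligand_atoms, dtype=float).reshape(-1, 3)
    tgt = np.asarray(target_atoms, dtype=float).reshape(-1, 3)
    if lig.size == 0 or tgt.size == 0:
        return 0
    tree_l = cKDTree(lig)
    tree_t = cKDTree(tgt)
    return int(tree_l.count_neighbors(tree_t, d_cutoff))


def radius_of_gyration(coords: np.ndarray) -> float:
    """Root-mean-square distance to the centroid (unit masses)."""
    x = np.asarray(coords, dtype=float).reshape(-1, 3)
    if x.shape[0] == 0:
        raise ValueError("radius of gyration needs at least one atom")
    c = x.mean(axis=0)
    return float(np.sqrt(((x - c) ** 2).sum(axis=1).mean()))


_aligner: PairwiseAligner | None = None


def _global_aligner() -> PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = PairwiseAligner()
        a.mode = "global"
        a.match_score = 1.0
        a.mismatch_score = 0.0
        a.open_gap_score = -1.0
        a.extend_gap_score = -1.0
        _aligner = a
    return _aligner


def sequence_identity(pred_seq: str, nat_seq: str) -> float:
    """Global-alignment identity in percent with max-length denominator.

    Needleman-Wunsch with match 1 / mismatch 0 / linear gap -1; the
    identity count is divided by max(L_pred, L_nat) so length
    discrepancies are penalized.
    """
    validate_model_sequence(pred_seq)
    validate_model_sequence(nat_seq)
    if not pred_seq or not nat_seq:
        return 0.0
    alignment = _global_aligner().align(pred_seq, nat_seq)[0]
    n_match = alignment.counts().identities
    return 100.0 * n_match / max(len(pred_seq), len(nat_seq))


# ----------------------------------------------------------------------
def assign_secondary(angles: ResidueAngleTable) -> list[str]:
    """Per-residue H/E/C labels from (phi, psi) torsion windows.

    Residues whose phi or psi is masked (chain termini) are labelled C.
    """
    phi = np.degrees(angles.phi)
    psi = np.degrees(angles.psi)
    valid = angles.valid_mask[:, 0] & angles.valid_mask[:, 1]
    labels = []
    for i in range(angles.length):
        if not valid[i]:
            labels.append("C")
        elif HELIX_WINDOW[0] <= phi[i] <= HELIX_WINDOW[1] and \
                HELIX_WINDOW[2] <= psi[i] <= HELIX_WINDOW[3]:
            labels.append("H")
        elif STRAND_WINDOW[0] <= phi[i] <= STRAND_WINDOW[1] and \
                STRAND_WINDOW[2] <= psi[i] <= STRAND_WINDOW[3]:
            labels.append("E")
        else:
            labels.append("C")
    return labels


def _valid_phi_psi(angles: ResidueAngleTable) -> np.ndarray:
    return angles.valid_mask[:, 0] & angles.valid_mask[:, 1]


def helicity(angles: ResidueAngleTable) -> float:
    """Fraction of torsion-defined residues assigned H."""
    labels = np.array(assign_secondary(angles))
    valid = _valid_phi_psi(angles)
    if valid.sum() == 0:
        return 0.0
    return float((labels[valid] == "H").mean())


def rama_helix_fraction(angles: ResidueAngleTable) -> float:
    """Fraction of torsion-defined residues inside the helical window."""
    return helicity(angles)


def rama_density(angles: ResidueAngleTable, bins: int = 36) -> np.ndarray:
    """(bins, bins) histogram of defined (phi, psi) pairs over (-pi, pi]^2."""
    valid = _valid_phi_psi(angles)
    edges = np.linspace(-np.pi, np.pi, bins + 1)
    h, _, _ = np.histogram2d(angles.phi[valid], angles.psi[valid], bins=(edges, edges))
    return h


# ----------------------------------------------------------------------
def clash_count(
    structures: BackboneStructure | list[BackboneStructure],
    clash_cutoff: float = CLASH_CUTOFF,
) -> int:
    """Heavy-atom pairs strictly closer than ``clash_cutoff``, excluding
    pairs within one residue and pairs between adjacent residues of the
    same chain (those distances are fixed by covalent geometry)."""
    if isinstance(structures, BackboneStructure):
        structures = [structures]
    coords, chain_idx, res_idx = [], [], []
    for ci, s in enumerate(structures):
        xyz, res = s.heavy_atoms()
        coords.append(xyz)
        chain_idx.append(np.full(len(xyz), ci))
        res_idx.append(res)
    xyz = np.concatenate(coords)
    chain_idx = np.concatenate(chain_idx)
    res_idx = np.concatenate(res_idx)
    if clash_cutoff <= 0:
        return 0
    tree = cKDTree(xyz)
    count = 0
    for i, j in tree.query_pairs(r=clash_cutoff):
        if np.linalg.norm(xyz[i] - xyz[j]) >= clash_cutoff:
            continue
        if chain_idx[i] == chain_idx[j] and abs(int(res_idx[i]) - int(res_idx[j])) <= 1:
            continue
        count += 1
    return count


def shape_ratio(calpha_coords: np.ndarray, cap: float = SHAPE_RATIO_CAP) -> float:
    """Largest over smallest principal radius of the gyration tensor.

    1 for a sphere-like cloud, large for elongated chains; the smallest
    radius is floored so a perfectly linear chain reports ``cap``.
    """
    x = np.asarray(calpha_coords, dtype=float).reshape(-1, 3)
    x = x - x.mean(axis=0)
    gyr = (x[:, :, None] * x[:, None, :]).mean(axis=0)
    eig = np.sort(np.linalg.eigvalsh(gyr))
    r_max = math.sqrt(max(eig[-1], 0.0))
    r_min = max(math.sqrt(max(eig[0], 0.0)), SHAPE_RATIO_FLOOR)
    return float(min(r_max / r_min, cap))


# ----------------------------------------------------------------------
def gravy(seq: str) -> float:
    """Grand average of hydropathicity (mean Kyte-Doolittle score)."""
    validate_model_sequence(seq)
    return float(ProteinAnalysis(seq).gravy())


def aromaticity(seq: str) -> float:
    """Fraction of aromatic residues (F, W, Y)."""
    validate_model_sequence(seq)
    return float(ProteinAnalysis(seq).aromaticity())


def isoelectric_point(seq: str) -> float:
    """pH at which the peptide's net charge is zero.

    Root-found (bisection-style brentq) on the Bjellqvist-table charge
    curve, so the returned pH satisfies |net charge| < 1e-4.
    """
    validate_model_sequence(seq)
    ip = IsoelectricPoint(seq)
    charge = ip.charge_at_pH
    lo, hi = 0.0, 14.0
    if charge(lo) < 0:
        return lo
    if charge(hi) > 0:
        return hi
    return float(brentq(charge, lo, hi, xtol=1e-8))


def length_contact_correlation(records: list[tuple[int, int]]) -> float:
    """Pearson r between binder length and contact count.

    Returns nan (the flagged undefined result) for fewer than 3 records
    or zero variance in either variable.
    """
    if len(records) < 3:
        return float("nan")
    arr = np.asarray(records, dtype=float)
    if arr[:, 0].std() == 0 or arr[:, 1].std() == 0:
        return float("nan")
    r = np.corrcoef(arr[:, 0], arr[:, 1])[0, 1]
    return float(r)


# ----------------------------------------------------------------------
def evaluate_complex(
    target: BackboneStructure,
    binder: BackboneStructure,
    binder_sequence: str | None = None,
    native_sequence: str | None = None,
    d_cutoff: float = CONTACT_CUTOFF,
    clash_cutoff: float = CLASH_CUTOFF,
    plddt: np.ndarray | None = None,
) -> MetricReport:
    """Run the full metric suite on one target/binder complex.

    ``plddt`` optionally accepts an externally computed per-residue
    confidence table for the binder; only its mean is recorded in the
    report metadata (no structure-prediction model is run here).
    """
    seq = binder_sequence if binder_sequence is not None else binder.sequence()
    lig_xyz, _ = binder.heavy_atoms()
    tgt_xyz, _ = target.heavy_atoms()
    angles = extract_angles(binder)
    report = MetricReport(
        contacts=interface_contacts(lig_xyz, tgt_xyz, d_cutoff),
        rg=radius_of_gyration(binder.calpha),
        helicity=helicity(angles),
        rama_helix=rama_helix_fraction(angles),
        shape_ratio=shape_ratio(binder.calpha),
        clashes=clash_count([target, binder], clash_cutoff),
        gravy=gravy(seq),
        aromaticity=aromaticity(seq),
        isoelectric_point=isoelectric_point(seq),
        seq_identity=None if native_sequence is None
        else sequence_identity(seq, native_sequence),
        metadata={
            "d_cutoff": d_cutoff,
            "clash_cutoff": clash_cutoff,
            "backbone_only_atoms": binder.heavy_atom_coords is None,
            "pka_table": PKA_TABLE,
        },
    )
    if plddt is not None:
        plddt = np.asarray(plddt, dtype=float)
        if plddt.shape[0] != binder.n_residues:
            raise ValueError("pLDDT table length disagrees with binder length")
        report.metadata["mean_plddt"] = float(plddt.mean())
    return report


def evaluate_batch(reports: list[MetricReport]) -> tuple[pd.DataFrame, dict]:
    """One row per complex plus mean/median/SD aggregates per metric."""
    df = pd.DataFrame([r.as_row() for r in reports])
    numeric = df.select_dtypes(include=[np.number])
    aggregate = {
        col: {
            "mean": float(numeric[col].mean()),
            "median": float(numeric[col].median()),
            "sd": float(numeric[col].std(ddof=0)),
        }
        for col in numeric.columns
    }
    return df, aggregate
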
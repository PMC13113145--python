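"""Self-contained synthetic fixtures with known ground truth.

Everything the test-suite and desk-scale experiments need is generated
here from seeds: idealized secondary-structure chains built from stated
torsions (helix phi=-57/psi=-47 deg, strand phi=-135/psi=135 deg, coil
drawn inside allowed Ramachandran regions, omega=180 deg throughout),
toy target/binder complexes with a controlled minimum interface
distance, and per-residue resolution values drawn uniformly from a
stated range.  No downloads, no external data.

Coil torsions are sampled only inside stereochemically allowed windows
so even "random" fixtures satisfy the same no-forbidden-region
invariant expected of generated structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .internal_coords import (
    IDEAL_GEOMETRY,
    GeometryConstants,
    ResidueAngleTable,
    nerf_reconstruct,
)
from .io_structures import BackboneStructure, CANONICAL_AA, ResolutionMap, one_to_three
from .metrics import interface_contacts
from .training import ChainRecord, ComplexPair

__all__ = ["FixtureSpec", "make_ideal_chain", "make_toy_complex", "make_dataset"]

IDEAL_TORSIONS = {
    "helix": (np.deg2rad(-57.0), np.deg2rad(-47.0)),
    "strand": (np.deg2rad(-135.0), np.deg2rad(135.0)),
}
# allowed (phi, psi) sampling box for coil fixtures, degrees: the broad
# beta/polyproline basin, fully outside the helical torsion window
COIL_PHI_RANGE = (-160.0, -60.0)
COIL_PSI_RANGE = (60.0, 170.0)

KINDS = ("helix", "strand", "coil", "mixed")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one toy complex."""

    kind: str = "helix"
    target_length: int = 24
    binder_length: int = 10
    interface_distance: float = 4.0
    resolution_range: tuple[float, float] = (1.5, 3.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.target_length < 4 or self.binder_length < 4:
            raise ValueError("chain lengths must be >= 4")
        if self.resolution_range[0] <= 0:
            raise ValueError("resolution lower bound must be positive")


def _torsion_rows(kind: str, length: int, rng: np.random.Generator) -> np.ndarray:
    phi = np.empty(length)
    psi = np.empty(length)
    if kind in IDEAL_TORSIONS:
        phi[:], psi[:] = IDEAL_TORSIONS[kind]
    elif kind == "coil":
        phi[:] = np.deg2rad(rng.uniform(*COIL_PHI_RANGE, size=length))
        psi[:] = np.deg2rad(rng.uniform(*COIL_PSI_RANGE, size=length))
    elif kind == "mixed":
        half = length // 2
        phi[:half], psi[:half] = IDEAL_TORSIONS["helix"]
        phi[half:], psi[half:] = IDEAL_TORSIONS["strand"]
    else:  # pragma: no cover - guarded by FixtureSpec
        raise ValueError(kind)
    angles = np.empty((length, 6))
    angles[:, 0] = phi
    angles[:, 1] = psi
    angles[:, 2] = np.pi
    angles[:, 3] = IDEAL_GEOMETRY.theta1_ideal
    angles[:, 4] = IDEAL_GEOMETRY.theta2_ideal
    angles[:, 5] = IDEAL_GEOMETRY.theta3_ideal
    return angles


def make_ideal_chain(
    kind: str,
    length: int,
    seed: int,
    chain_id: str = "A",
    constants: GeometryConstants = IDEAL_GEOMETRY,
) -> tuple[BackboneStructure, ResidueAngleTable, str]:
    """An idealized chain with known torsions plus a seeded random
    canonical sequence; the structure is the NeRF rebuild of the table."""
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}")
    rng = np.random.default_rng(seed)
    table = ResidueAngleTable.from_angles(_torsion_rows(kind, length, rng), constants)
    sequence = "".join(rng.choice(list(CANONICAL_AA), size=length))
    structure = nerf_reconstruct(table, constants,
                                 residue_names=one_to_three(sequence),
                                 chain_id=chain_id)
    return structure, table, sequence


def _min_cross_distance(a: np.ndarray, b: np.ndarray) -> float:
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


def make_toy_complex(spec: FixtureSpec) -> ComplexPair:
    """A target/binder pair rigidly docked at a controlled distance.

    The binder is randomly re-oriented and translated along +x until the
    minimum cross-chain heavy-atom distance equals
    ``spec.interface_distance`` (to ~1e-3 A).  The per-residue target
    resolution is drawn uniformly from ``spec.resolution_range``.  The
    planted interface contact count is stored in ``pair.metadata``.
    """
    rng = np.random.default_rng(spec.seed)
    tgt_struct, _, tgt_seq = make_ideal_chain(
        spec.kind, spec.target_length, int(rng.integers(2**31)), chain_id="A")
    binder_kind = spec.kind if spec.kind != "mixed" else "helix"
    bnd_struct, _, bnd_seq = make_ideal_chain(
        binder_kind, spec.binder_length, int(rng.integers(2**31)), chain_id="B")

    # seeded random orientation, then 1-D search on the x-offset
    R = Rotation.random(rng=rng).as_matrix()
    rotated = bnd_struct.atom_coords.reshape(-1, 3) @ R.T
    rotated = rotated.reshape(bnd_struct.atom_coords.shape)
    bnd_struct = BackboneStructure(
        residue_ids=bnd_struct.residue_ids,
        residue_names=bnd_struct.residue_names,
        atom_coords=rotated,
        chain_id="B",
    )
    tgt_xyz, _ = tgt_struct.heavy_atoms()
    bnd_xyz, _ = bnd_struct.heavy_atoms()

    def gap(s: float) -> float:
        return _min_cross_distance(tgt_xyz, bnd_xyz + np.array([s, 0.0, 0.0])) \
            - spec.interface_distance

    span = float(np.abs(tgt_xyz).max() + np.abs(bnd_xyz).max())
    hi = span + spec.interface_distance + 10.0
    lo = 0.0
    if gap(lo) > 0:
        lo = -hi
    s_star = brentq(gap, lo, hi, xtol=1e-4)
    bnd_struct = bnd_struct.translated(np.array([s_star, 0.0, 0.0]))

    resmap = ResolutionMap(
        rng.uniform(*spec.resolution_range, size=spec.target_length),
        source="fixture",
    )
    planted = interface_contacts(bnd_struct.heavy_atoms()[0], tgt_xyz)
    pair = ComplexPair(
        target=ChainRecord(tgt_struct, tgt_seq, resmap),
        binder=ChainRecord(bnd_struct, bnd_seq),
        pair_id=f"toy-{spec.kind}-{spec.seed}",
    )
    pair.metadata = {
        "planted_contacts": planted,
        "interface_distance": spec.interface_distance,
    }
    return pair


def make_dataset(n_pairs: int, seed: int) -> list[ComplexPair]:
    """Reproducible toy pairs with varied kinds, lengths and resolutions."""
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n_pairs):
        spec = FixtureSpec(
            kind=KINDS[i % len(KINDS)],
            target_length=int(rng.integers(20, 29)),
            binder_length=int(rng.integers(8, 16)),
            interface_distance=float(rng.uniform(3.8, 6.0)),
            seed=int(rng.integers(2**31)),
        )
        pairs.append(make_toy_complex(spec))
    return pairs
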
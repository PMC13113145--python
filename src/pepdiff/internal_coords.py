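"""Backbone internal coordinates and NeRF reconstruction.

A polypeptide backbone is parameterized per residue by a 6-vector of
angles: the three torsions (phi, psi, omega) and the three bond angles
around the N(i)-CA(i)-C(i)-N(i+1)-CA(i+1) placement cycle.  Working in
this space instead of Cartesian coordinates removes the redundant degrees
of freedom that let coordinate-space generative models break bonds: bond
lengths and the bond-angle/torsion split are explicit, so a chain rebuilt
from any angle table automatically satisfies ideal covalent geometry.

Angle conventions (i is 1-based over residues, termini masked):

* ``phi_i``   : C(i-1)-N(i)-CA(i)-C(i)        (undefined at i=1)
* ``psi_i``   : N(i)-CA(i)-C(i)-N(i+1)        (undefined at i=L)
* ``omega_i`` : CA(i)-C(i)-N(i+1)-CA(i+1)     (undefined at i=L)
* ``theta1_i``: angle N(i)-CA(i)-C(i)
* ``theta2_i``: angle CA(i)-C(i)-N(i+1)       (undefined at i=L)
* ``theta3_i``: angle C(i)-N(i+1)-CA(i+1)     (undefined at i=L)

Masked entries hold ideal-geometry sentinel values and are excluded from
losses and metrics.  Torsions live on the unit circle; for the diffusion
model every angle is embedded as a (cos, sin) pair, giving a 12-wide
continuous state per residue with no wrap-around discontinuity.

Cartesian coordinates are recovered by the natural extension reference
frame (NeRF) algorithm: each atom is placed from the three preceding
atoms plus a bond length, bond angle and torsion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_structures import BackboneStructure

__all__ = [
    "GeometryConstants",
    "IDEAL_GEOMETRY",
    "ResidueAngleTable",
    "AngleEmbedding",
    "dihedral",
    "bond_angle",
    "extract_angles",
    "embed_angles",
    "unembed_angles",
    "nerf_place",
    "nerf_reconstruct",
    "wrap_angle",
]

ANGLE_NAMES = ("phi", "psi", "omega", "theta1", "theta2", "theta3")


@dataclass(frozen=True)
class GeometryConstants:
    """Fixed covalent geometry (Engh-Huber bond lengths) and the
    ideal-angle sentinels used for masked terminal entries."""

    l_n_ca: float = 1.458
    l_ca_c: float = 1.525
    l_c_n: float = 1.329
    phi_ideal: float = -1.0472
    psi_ideal: float = -0.7854
    omega_ideal: float = np.pi
    theta1_ideal: float = 1.9373
    theta2_ideal: float = 2.0280
    theta3_ideal: float = 2.1240

    def sentinels(self) -> np.ndarray:
        return np.array([
            self.phi_ideal, self.psi_ideal, self.omega_ideal,
            self.theta1_ideal, self.theta2_ideal, self.theta3_ideal,
        ])

    def as_dict(self) -> dict[str, float]:
        return {
            "l_n_ca": self.l_n_ca, "l_ca_c": self.l_ca_c, "l_c_n": self.l_c_n,
            "phi_ideal": self.phi_ideal, "psi_ideal": self.psi_ideal,
            "omega_ideal": self.omega_ideal, "theta1_ideal": self.theta1_ideal,
            "theta2_ideal": self.theta2_ideal, "theta3_ideal": self.theta3_ideal,
        }


IDEAL_GEOMETRY = GeometryConstants()


def wrap_angle(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap to (-pi, pi]."""
    w = -(np.mod(-np.asarray(a, dtype=float) + np.pi, 2 * np.pi) - np.pi)
    return w


@dataclass
class ResidueAngleTable:
    """Per-residue 6-angle backbone state with a validity mask.

    ``angles`` is (L, 6) in the order phi, psi, omega, theta1, theta2,
    theta3 (radians; torsions wrapped to (-pi, pi], bond angles in
    (0, pi)).  ``valid_mask`` is (L, 6) boolean; False marks terminal
    entries that are geometrically undefined and carry sentinel values.
    """

    angles: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.angles.shape != self.valid_mask.shape or self.angles.shape[1] != 6:
            raise ValueError("angles and valid_mask must both have shape (L, 6)")
        theta = self.angles[:, 3:]
        mask_t = self.valid_mask[:, 3:]
        if np.any((theta[mask_t] <= 0) | (theta[mask_t] >= np.pi)):
            raise ValueError("bond angles must lie strictly inside (0, pi)")

    @property
    def length(self) -> int:
        return self.angles.shape[0]

    @property
    def phi(self) -> np.ndarray:
        return self.angles[:, 0]

    @property
    def psi(self) -> np.ndarray:
        return self.angles[:, 1]

    @property
    def omega(self) -> np.ndarray:
        return self.angles[:, 2]

    def copy(self) -> "ResidueAngleTable":
        return ResidueAngleTable(self.angles.copy(), self.valid_mask.copy())

    @staticmethod
    def standard_mask(length: int) -> np.ndarray:
        """Validity pattern of an untruncated chain: phi_1 and the four
        (i, i+1)-spanning angles of the last residue are undefined."""
        mask = np.ones((length, 6), dtype=bool)
        mask[0, 0] = False            # phi_1
        mask[-1, 1] = False           # psi_L
        mask[-1, 2] = False           # omega_L
        mask[-1, 4] = False           # theta2_L
        mask[-1, 5] = False           # theta3_L
        return mask

    @classmethod
    def from_angles(
        cls,
        angles: np.ndarray,
        constants: GeometryConstants = IDEAL_GEOMETRY,
        valid_mask: np.ndarray | None = None,
    ) -> "ResidueAngleTable":
        """Build a table from an (L, 6) angle matrix, stamping sentinels
        onto the masked terminal entries."""
        angles = np.array(angles, dtype=float)
        if valid_mask is None:
            valid_mask = cls.standard_mask(angles.shape[0])
        sent = constants.sentinels()
        out = np.where(valid_mask, angles, sent[None, :])
        out[:, :3] = wrap_angle(out[:, :3])
        return cls(out, valid_mask)


@dataclass
class AngleEmbedding:
    """(L, 12) unit-circle embedding: (cos a, sin a) per angle in table order."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 12:
            raise ValueError("embedding must have shape (L, 12)")

    @property
    def length(self) -> int:
        return self.values.shape[0]


# ----------------------------------------------------------------------
# elementary geometry
def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at b formed by a-b-c, in (0, pi)."""
    u = np.asarray(a, float) - b
    v = np.asarray(c, float) - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("degenerate bond angle: coincident atoms")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.arccos(cosang))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion p0-p1-p2-p3 in (-pi, pi] (IUPAC convention)."""
    b0 = np.asarray(p1, float) - p0
    b1 = np.asarray(p2, float) - p1
    b2 = np.asarray(p3, float) - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = np.linalg.norm(b1)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("dihedral undefined: collinear atoms")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(b1 / b1n, n1), n2))
    return float(wrap_angle(np.arctan2(y, x)))


# ----------------------------------------------------------------------
def extract_angles(structure: BackboneStructure) -> ResidueAngleTable:
    """Measure the per-residue 6-angle table from Cartesian backbone atoms."""
    L = structure.n_residues
    if L < 2:
        raise ValueError("need at least 2 residues to define backbone angles")
    X = structure.atom_coords  # (L, 3, 3): N, CA, C
    angles = np.tile(IDEAL_GEOMETRY.sentinels(), (L, 1))
    mask = ResidueAngleTable.standard_mask(L)

    def _try(fn, *args, residue: int):
        try:
            return fn(*args)
        except ValueError as exc:
            raise ValueError(f"residue {residue + 1}: {exc}") from exc

    for i in range(L):
        N, CA, C = X[i]
        angles[i, 3] = _try(bond_angle, N, CA, C, residue=i)  # theta1
        if i > 0:
            Cprev = X[i - 1, 2]
            angles[i, 0] = _try(dihedral, Cprev, N, CA, C, residue=i)  # phi
        if i < L - 1:
            Nnext, CAnext = X[i + 1, 0], X[i + 1, 1]
            angles[i, 1] = _try(dihedral, N, CA, C, Nnext, residue=i)        # psi
            angles[i, 2] = _try(dihedral, CA, C, Nnext, CAnext, residue=i)   # omega
            angles[i, 4] = _try(bond_angle, CA, C, Nnext, residue=i)         # theta2
            angles[i, 5] = _try(bond_angle, C, Nnext, CAnext, residue=i)     # theta3
    return ResidueAngleTable(angles, mask)


def embed_angles(table: ResidueAngleTable) -> AngleEmbedding:
    """Map each angle to its (cos, sin) pair; shape (L, 12)."""
    a = table.angles
    out = np.empty((table.length, 12))
    out[:, 0::2] = np.cos(a)
    out[:, 1::2] = np.sin(a)
    return AngleEmbedding(out)


def unembed_angles(
    embedding: AngleEmbedding,
    constants: GeometryConstants = IDEAL_GEOMETRY,
    valid_mask: np.ndarray | None = None,
    clamp_bond_angles: bool = True,
) -> ResidueAngleTable:
    """Invert the unit-circle embedding by the two-argument arctangent.

    Pairs need not be unit norm (diffusion perturbs the embedded space);
    a zero-norm pair falls back to the sentinel for that angle.  Bond
    angles are reflected into (0, pi) when ``clamp_bond_angles`` is set,
    since a noisy pair can unembed to a negative angle that has no
    geometric meaning.
    """
    v = embedding.values
    cos, sin = v[:, 0::2], v[:, 1::2]
    angles = np.arctan2(sin, cos)
    degenerate = (cos == 0) & (sin == 0)
    if np.any(degenerate):
        sent = constants.sentinels()
        angles = np.where(degenerate, sent[None, :], angles)
    if clamp_bond_angles:
        eps = 1e-3
        angles[:, 3:] = np.clip(np.abs(angles[:, 3:]), eps, np.pi - eps)
    angles[:, :3] = wrap_angle(angles[:, :3])
    if valid_mask is None:
        valid_mask = ResidueAngleTable.standard_mask(v.shape[0])
    return ResidueAngleTable.from_angles(angles, constants, valid_mask)


# ----------------------------------------------------------------------
# NeRF
def nerf_place(
    rA: np.ndarray, rB: np.ndarray, rC: np.ndarray,
    l: float, theta: float, tau: float,
) -> np.ndarray:
    """Place atom D from frame atoms A, B, C so that |D-C| = l,
    angle(B, C, D) = theta and dihedral(A, B, C, D) = tau."""
    if l <= 0:
        raise ValueError("bond length must be positive")
    if not (0 < theta < np.pi):
        raise ValueError("bond angle must lie in (0, pi)")
    rA, rB, rC = (np.asarray(p, float) for p in (rA, rB, rC))
    bc = rC - rB
    nbc = np.linalg.norm(bc)
    ab = rB - rA
    if nbc < 1e-12:
        raise ValueError("degenerate frame: B and C coincide")
    bc /= nbc
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("degenerate frame: A, B, C are collinear")
    n /= nn
    m = np.cross(n, bc)
    # local displacement in the (bc, m, n) frame
    d_local = np.array([
        -l * np.cos(theta),
        l * np.sin(theta) * np.cos(tau),
        l * np.sin(theta) * np.sin(tau),
    ])
    R = np.stack([bc, m, n], axis=1)
    return rC + R @ d_local


def nerf_reconstruct(
    table: ResidueAngleTable,
    constants: GeometryConstants = IDEAL_GEOMETRY,
    residue_names: list[str] | None = None,
    chain_id: str = "A",
) -> BackboneStructure:
    """Rebuild Cartesian N/CA/C coordinates from an angle table.

    The first residue is seeded canonically: N at the origin, CA on +x,
    C in the xy-plane at bond angle theta1.  Every later atom is placed
    by :func:`nerf_place`, so all bond lengths equal ``constants``
    exactly and the produced chain realises the table's angles.
    """
    L = table.length
    a = table.angles
    X = np.zeros((L, 3, 3))
    X[0, 0] = [0.0, 0.0, 0.0]
    X[0, 1] = [constants.l_n_ca, 0.0, 0.0]
    t1 = a[0, 3]
    X[0, 2] = X[0, 1] + constants.l_ca_c * np.array([-np.cos(t1), np.sin(t1), 0.0])
    for i in range(L - 1):
        N, CA, C = X[i]
        psi, omega = a[i, 1], a[i, 2]
        th2, th3 = a[i, 4], a[i, 5]
        Nn = nerf_place(N, CA, C, constants.l_c_n, th2, psi)
        CAn = nerf_place(CA, C, Nn, constants.l_n_ca, th3, omega)
        Cn = nerf_place(C, Nn, CAn, constants.l_ca_c, a[i + 1, 3], a[i + 1, 0])
        X[i + 1] = [Nn, CAn, Cn]
    if residue_names is None:
        residue_names = ["GLY"] * L
    return BackboneStructure(
        residue_ids=list(range(1, L + 1)),
        residue_names=list(residue_names),
        atom_coords=X,
        chain_id=chain_id,
    )
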
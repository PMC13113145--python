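"""Structure and sequence IO.

Reads and writes the formats the pipeline touches: PDB backbones (via
gemmi), FASTA sequences (via biopython) and a plain-text sidecar table for
per-residue resolution values.  Only the three backbone atoms N/CA/C are
required per residue; residues with a missing backbone atom are dropped
with a logged warning rather than imputed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Canonical one-letter amino-acid alphabet in the fixed published ordering
#: used everywhere a 20-way categorical is indexed.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}

BACKBONE_ATOMS = ("N", "CA", "C")


@dataclass
class BackboneStructure:
    """An ordered single-chain protein backbone.

    ``atom_coords`` has shape (L, 3, 3): per residue the Cartesian
    positions of N, CA, C in angstroms, ordered by chain sequence
    position (1-based residue indexing is kept in ``residue_ids``).
    ``heavy_atom_coords``/``heavy_atom_residues`` optionally carry all
    non-hydrogen atoms for contact and clash metrics; when absent the
    backbone atoms stand in.
    """

    residue_ids: list[int]
    residue_names: list[str]
    atom_coords: np.ndarray
    chain_id: str = "A"
    heavy_atom_coords: np.ndarray | None = None
    heavy_atom_residues: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.atom_coords = np.asarray(self.atom_coords, dtype=float)
        if self.atom_coords.ndim != 3 or self.atom_coords.shape[1:] != (3, 3):
            raise ValueError("atom_coords must have shape (L, 3, 3)")
        if len(self.residue_ids) != self.atom_coords.shape[0]:
            raise ValueError("residue_ids length does not match atom_coords")

    @property
    def n_residues(self) -> int:
        return self.atom_coords.shape[0]

    @property
    def calpha(self) -> np.ndarray:
        """(L, 3) C-alpha coordinates."""
        return self.atom_coords[:, 1, :]

    def heavy_atoms(self) -> tuple[np.ndarray, np.ndarray]:
        """All heavy-atom coordinates and their residue indices (0-based).

        Falls back to the backbone atoms when no side-chain atoms were
        retained (generated structures have none).
        """
        if self.heavy_atom_coords is not None:
            return self.heavy_atom_coords, self.heavy_atom_residues
        coords = self.atom_coords.reshape(-1, 3)
        res = np.repeat(np.arange(self.n_residues), 3)
        return coords, res

    def sequence(self) -> str:
        return "".join(_THREE_TO_ONE.get(n, "G") for n in self.residue_names)

    def translated(self, shift: np.ndarray) -> "BackboneStructure":
        """A copy rigidly shifted by ``shift`` (used when planting complexes)."""
        shift = np.asarray(shift, dtype=float)
        heavy = None if self.heavy_atom_coords is None else self.heavy_atom_coords + shift
        return BackboneStructure(
            residue_ids=list(self.residue_ids),
            residue_names=list(self.residue_names),
            atom_coords=self.atom_coords + shift,
            chain_id=self.chain_id,
            heavy_atom_coords=heavy,
            heavy_atom_residues=None if heavy is None else self.heavy_atom_residues.copy(),
        )


@dataclass
class ResolutionMap:
    """Per-residue experimental resolution in angstroms."""

    per_residue_resolution: np.ndarray
    source: str = "fixture"

    def __post_init__(self) -> None:
        r = np.asarray(self.per_residue_resolution, dtype=float)
        if r.ndim != 1:
            raise ValueError("resolution map must be one-dimensional")
        if not np.all(np.isfinite(r)) or np.any(r <= 0):
            raise ValueError("resolution values must be strictly positive and finite")
        self.per_residue_resolution = r

    def __len__(self) -> int:
        return self.per_residue_resolution.shape[0]


# ----------------------------------------------------------------------
# PDB
def read_pdb(path: str | Path, chain: str | None = None) -> BackboneStructure:
    """Read one chain of a PDB file into a :class:`BackboneStructure`.

    Residues missing any of N/CA/C are dropped with a warning.  Raises if
    the requested chain is absent (naming the chains that are present) or
    if no residue has a complete backbone.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")
    model = st[0]
    names = [ch.name for ch in model]
    if chain is None:
        chain = names[0]
    if chain not in names:
        raise ValueError(f"{path}: chain {chain!r} not found; available chains: {names}")

    res_ids: list[int] = []
    res_names: list[str] = []
    bb: list[np.ndarray] = []
    heavy_xyz: list[np.ndarray] = []
    heavy_res: list[int] = []
    for res in model[chain]:
        if res.is_water():
            continue
        atoms = {a.name: a for a in res}
        if not all(n in atoms for n in BACKBONE_ATOMS):
            logger.warning(
                "dropping residue %s %s%s: incomplete backbone",
                res.name, res.seqid.num, res.seqid.icode.strip(),
            )
            continue
        idx = len(res_ids)
        res_ids.append(res.seqid.num)
        res_names.append(res.name)
        bb.append(np.array([[atoms[n].pos.x, atoms[n].pos.y, atoms[n].pos.z]
                            for n in BACKBONE_ATOMS]))
        for a in res:
            if a.element.is_hydrogen:
                continue
            heavy_xyz.append(np.array([a.pos.x, a.pos.y, a.pos.z]))
            heavy_res.append(idx)

    if not res_ids:
        raise ValueError(f"{path}: chain {chain!r} has no residue with a complete backbone")
    return BackboneStructure(
        residue_ids=res_ids,
        residue_names=res_names,
        atom_coords=np.stack(bb),
        chain_id=chain,
        heavy_atom_coords=np.stack(heavy_xyz),
        heavy_atom_residues=np.asarray(heavy_res, dtype=int),
    )


def write_pdb(structure: BackboneStructure, path: str | Path) -> None:
    """Write backbone ATOM records (N/CA/C per residue, occupancy 1.00)."""
    if structure.n_residues == 0:
        raise ValueError("cannot write an empty structure")
    if np.any(np.abs(structure.atom_coords) >= 10000.0):
        raise ValueError("coordinate magnitude >= 10000 A overflows the PDB field width")

    st = gemmi.Structure()
    st.name = "pepdiff"
    model = gemmi.Model("1")
    ch = gemmi.Chain(structure.chain_id)
    for i in range(structure.n_residues):
        res = gemmi.Residue()
        res.name = structure.residue_names[i]
        res.seqid = gemmi.SeqId(int(structure.residue_ids[i]), " ")
        for j, name in enumerate(BACKBONE_ATOMS):
            at = gemmi.Atom()
            at.name = name
            at.element = gemmi.Element("N" if name == "N" else "C")
            at.occ = 1.0
            at.b_iso = 0.0
            x, y, z = structure.atom_coords[i, j]
            at.pos = gemmi.Position(float(x), float(y), float(z))
            res.add_atom(at)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.write_pdb(str(path))


def read_header_resolution(path: str | Path) -> float | None:
    """Global resolution from the PDB header (REMARK 2), if recorded."""
    st = gemmi.read_structure(str(path))
    res = st.resolution
    return float(res) if res and res > 0 else None


def read_resolution(
    path: str | Path | None,
    n_residues: int,
    sidecar: str | Path | None = None,
    default: float = 2.0,
) -> ResolutionMap:
    """Resolve a per-residue resolution map for a target of ``n_residues``.

    Priority: explicit two-column sidecar table (residue_index value),
    length-checked; else the PDB header global value broadcast; else
    ``default`` broadcast with a warning.
    """
    if n_residues <= 0:
        raise ValueError("n_residues must be positive")
    if sidecar is not None:
        table = np.loadtxt(str(sidecar), dtype=float, ndmin=2)
        values = table[:, -1]
        if values.shape[0] != n_residues:
            raise ValueError(
                f"sidecar resolution table has {values.shape[0]} entries, expected {n_residues}"
            )
        if np.any(values <= 0):
            raise ValueError("sidecar resolution values must be positive")
        return ResolutionMap(values, source="sidecar-table")
    if path is not None:
        global_res = read_header_resolution(path)
        if global_res is not None:
            return ResolutionMap(np.full(n_residues, global_res), source="header-global")
    warnings.warn(
        f"no resolution information available; broadcasting default {default} A",
        stacklevel=2,
    )
    return ResolutionMap(np.full(n_residues, default), source="fixture")


def write_resolution_sidecar(resmap: ResolutionMap, path: str | Path) -> None:
    rows = np.column_stack(
        [np.arange(1, len(resmap) + 1), resmap.per_residue_resolution]
    )
    np.savetxt(str(path), rows, fmt=["%d", "%.4f"])


# ----------------------------------------------------------------------
# FASTA
def validate_model_sequence(seq: str) -> str:
    """Reject sequences outside the 20-letter canonical alphabet."""
    for i, c in enumerate(seq, start=1):
        if c not in CANONICAL_AA:
            raise ValueError(f"non-canonical residue {c!r} at position {i}")
    return seq


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def one_to_three(seq: str) -> list[str]:
    return [_ONE_TO_THREE[c] for c in seq]


def seq_to_indices(seq: str) -> np.ndarray:
    """Map a canonical sequence to integer class indices."""
    validate_model_sequence(seq)
    lut = {c: i for i, c in enumerate(CANONICAL_AA)}
    return np.array([lut[c] for c in seq], dtype=int)
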
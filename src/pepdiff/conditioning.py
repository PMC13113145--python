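"""Resolution-weighted multimodal target context.

The denoiser conditions on a per-residue "context memory" for the target
protein that fuses two modalities:

* geometric features: rigid-motion-invariant backbone descriptors
  (torsion trig embedding, sorted C-alpha neighbour distances, local
  frame scalars) passed through a learnable width-3 sequence-local
  convolution and projected to 256 features;
* semantic features: a per-residue language-model embedding (L x 1280)
  projected to 256 features.

Experimental resolution enters twice.  First, each residue's resolution
R_i (angstroms, larger = worse) is mapped to a reliability weight
w_i = 1 / (R_i + eps), and the raw geometric descriptors are gated row
by row with w_i, so unreliable residues are attenuated at the source.
Second, the weight vector rides along with the context so the denoiser
can inject it again through its resolution MLP.

The default embedding provider is a deterministic stub (seeded random
projection of one-hot residues to 1280 features) so the whole pipeline
runs with no model download; a real language-model provider can be
plugged in behind the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .internal_coords import extract_angles, embed_angles
from .io_structures import BackboneStructure, CANONICAL_AA, ResolutionMap, seq_to_indices

__all__ = [
    "ResolutionWeights",
    "TargetContext",
    "EmbeddingProvider",
    "StubEmbeddingProvider",
    "CachedEmbeddingProvider",
    "resolution_weights",
    "gate_features",
    "geo_descriptors",
    "ConditioningEncoder",
]

DEFAULT_EPSILON = 1e-6
PROVIDER_DIM = 1280
GEO_DIM = 256
SEQ_DIM = 256
KNN_NEIGHBORS = 16
_DIST_SCALE = 0.1       # descriptors carry distances in units of 10 A
_KNN_PAD = 3.0          # sentinel (scaled) distance for chains shorter than k+1


@dataclass
class ResolutionWeights:
    """Per-residue reliability weights w_i = 1 / (R_i + epsilon)."""

    w: np.ndarray
    epsilon: float = DEFAULT_EPSILON


@dataclass
class TargetContext:
    """Fused conditioning memory for one target.

    ``memory`` is the feature-wise concatenation of ``geo_part`` and
    ``seq_part`` (kept as an autodiff tensor so the encoder trains
    jointly with the denoiser); ``weights`` is the resolution weight
    vector the denoiser's correction MLP consumes.
    """

    memory: Tensor
    geo_part: Tensor
    seq_part: Tensor
    weights: ResolutionWeights

    @property
    def length(self) -> int:
        return self.memory.shape[0]


class EmbeddingProvider(Protocol):
    """Anything mapping a canonical sequence to an (L, 1280) matrix."""

    provider_name: str

    def __call__(self, sequence: str) -> np.ndarray: ...


class StubEmbeddingProvider:
    """Deterministic stand-in for a frozen protein language model.

    Each residue's 20-way one-hot is lifted to 1280 features by a fixed
    random projection regenerated from ``seed``, so the embedding is
    bit-identical across processes and requires no download.
    """

    def __init__(self, seed: int = 1280):
        self.seed = seed
        self.provider_name = f"onehot-stub-{seed}"
        rng = np.random.default_rng(seed)
        self._projection = rng.standard_normal((len(CANONICAL_AA), PROVIDER_DIM))
        self._projection /= np.sqrt(len(CANONICAL_AA))

    def __call__(self, sequence: str) -> np.ndarray:
        idx = seq_to_indices(sequence)
        return self._projection[idx]


class CachedEmbeddingProvider:
    """Serves precomputed per-sequence embeddings from an npz container.

    Lets real language-model embeddings be computed offline once and
    replayed deterministically; keys are the sequences themselves.
    """

    def __init__(self, path: str):
        self.path = str(path)
        self.provider_name = "cached-file"
        self._store = np.load(self.path)

    def __call__(self, sequence: str) -> np.ndarray:
        if sequence not in self._store.files:
            raise KeyError(f"no cached embedding for sequence of length {len(sequence)}")
        emb = np.asarray(self._store[sequence], dtype=float)
        if emb.shape != (len(sequence), PROVIDER_DIM):
            raise ValueError("cached embedding has wrong shape")
        return emb


def resolution_weights(
    resmap: ResolutionMap, epsilon: float = DEFAULT_EPSILON
) -> ResolutionWeights:
    """Inverse-proportional reliability weights with smoothing."""
    r = resmap.per_residue_resolution
    if np.any(r <= 0):
        raise ValueError("resolution values must be positive")
    return ResolutionWeights(w=1.0 / (r + epsilon), epsilon=epsilon)


def gate_features(features: np.ndarray, weights: ResolutionWeights) -> np.ndarray:
    """Scale feature row i by w_i (element-wise gating broadcast over
    the feature axis); preserves each row's direction, not magnitude."""
    f = np.asarray(features, dtype=float)
    if f.shape[0] != weights.w.shape[0]:
        raise ValueError("feature rows and weight vector lengths disagree")
    return f * weights.w[:, None]


# ----------------------------------------------------------------------
def geo_descriptors(structure: BackboneStructure, k: int = KNN_NEIGHBORS) -> np.ndarray:
    """Raw per-residue geometric descriptors, invariant to rigid motion.

    Concatenates (per residue): the 12-wide trig embedding of the
    backbone angles, the sorted scaled distances to the k nearest
    C-alpha neighbours (padded for short chains), and six local-frame
    scalar products.  Shape (L, 12 + k + 6).
    """
    L = structure.n_residues
    if L < 3:
        raise ValueError("geometric encoding needs at least 3 residues")
    trig = embed_angles(extract_angles(structure)).values  # (L, 12)

    ca = structure.calpha
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    d_sorted = np.sort(d, axis=1)[:, :k] * _DIST_SCALE
    if d_sorted.shape[1] < k:
        pad = np.full((L, k - d_sorted.shape[1]), _KNN_PAD)
        d_sorted = np.concatenate([d_sorted, pad], axis=1)
    d_sorted = np.where(np.isfinite(d_sorted), d_sorted, _KNN_PAD)

    def unit(v: np.ndarray) -> np.ndarray:
        n = np.linalg.norm(v, axis=-1, keepdims=True)
        return np.where(n > 1e-12, v / np.maximum(n, 1e-12), 0.0)

    N, CA, C = structure.atom_coords[:, 0], ca, structure.atom_coords[:, 2]
    u_next = np.zeros_like(ca)
    u_prev = np.zeros_like(ca)
    u_next[:-1] = unit(ca[1:] - ca[:-1])
    u_prev[1:] = unit(ca[:-1] - ca[1:])
    n_dir = unit(N - CA)
    c_dir = unit(C - CA)
    frame = np.stack([
        (u_next * u_prev).sum(-1),
        np.r_[np.linalg.norm(ca[1:] - ca[:-1], axis=1), 0.0] * _DIST_SCALE,
        np.r_[0.0, np.linalg.norm(ca[:-1] - ca[1:], axis=1)] * _DIST_SCALE,
        (n_dir * c_dir).sum(-1),
        (u_next * c_dir).sum(-1),
        (u_prev * n_dir).sum(-1),
    ], axis=1)
    return np.concatenate([trig, d_sorted, frame], axis=1)


DESCRIPTOR_DIM = 12 + KNN_NEIGHBORS + 6


class ConditioningEncoder:
    """Learnable half of the context pipeline.

    Holds the width-3 convolution and projection for the geometric
    branch and the 1280 -> 256 projection for the semantic branch.  All
    parameters are initialised from ``parameter_seed`` with fan-in
    scaling so two encoders built from the same seed are bit-identical.
    """

    def __init__(
        self,
        parameter_seed: int = 0,
        geo_dim: int = GEO_DIM,
        seq_dim: int = SEQ_DIM,
        descriptor_dim: int = DESCRIPTOR_DIM,
    ):
        self.geo_dim = geo_dim
        self.seq_dim = seq_dim
        self.descriptor_dim = descriptor_dim
        rng = np.random.default_rng(parameter_seed)

        def lin(fan_in: int, fan_out: int) -> Tensor:
            return ad.parameter(rng.standard_normal((fan_in, fan_out)) / np.sqrt(fan_in))

        self.params: dict[str, Tensor] = {
            "geo_conv_W": lin(3 * descriptor_dim, geo_dim),
            "geo_conv_b": ad.parameter(np.zeros(geo_dim)),
            "geo_proj_W": lin(geo_dim, geo_dim),
            "geo_proj_b": ad.parameter(np.zeros(geo_dim)),
            "seq_proj_W": lin(PROVIDER_DIM, seq_dim),
            "seq_proj_b": ad.parameter(np.zeros(seq_dim)),
        }

    @property
    def context_dim(self) -> int:
        return self.geo_dim + self.seq_dim

    def geo_encoder(
        self,
        structure: BackboneStructure,
        weights: ResolutionWeights | None = None,
    ) -> Tensor:
        """Gated descriptors -> width-3 conv -> GELU -> projection (L, 256)."""
        desc = geo_descriptors(structure)
        if weights is not None:
            desc = gate_features(desc, weights)
        L, D = desc.shape
        padded = np.zeros((L + 2, D))
        padded[1:-1] = desc
        windows = np.concatenate([padded[:-2], padded[1:-1], padded[2:]], axis=1)
        h = ad.matmul(ad.constant(windows), self.params["geo_conv_W"]) + self.params["geo_conv_b"]
        h = ad.gelu(h)
        return ad.matmul(h, self.params["geo_proj_W"]) + self.params["geo_proj_b"]

    def fuse_context(
        self,
        geo_gated: Tensor,
        sequence: str,
        provider: EmbeddingProvider,
        weights: ResolutionWeights,
    ) -> TargetContext:
        """Project the provider embedding and concatenate with the
        (already gated) geometric features into the (L, 512) memory."""
        if geo_gated.shape[0] != len(sequence):
            raise ValueError(
                f"structure length {geo_gated.shape[0]} != sequence length {len(sequence)}"
            )
        emb = provider(sequence)
        if emb.shape != (len(sequence), PROVIDER_DIM):
            raise ValueError("provider must return an (L, 1280) matrix")
        seq_part = ad.matmul(ad.constant(emb), self.params["seq_proj_W"]) + self.params["seq_proj_b"]
        memory = ad.concat_rows(geo_gated, seq_part)
        return TargetContext(memory=memory, geo_part=geo_gated,
                             seq_part=seq_part, weights=weights)

    def build_context(
        self,
        structure: BackboneStructure,
        sequence: str,
        resmap: ResolutionMap,
        provider: EmbeddingProvider,
        epsilon: float = DEFAULT_EPSILON,
    ) -> TargetContext:
        """Full conditioning pipeline for one target chain."""
        if structure.n_residues != len(sequence):
            raise ValueError("structure and sequence lengths disagree")
        if len(resmap) != structure.n_residues:
            raise ValueError("resolution map length disagrees with structure")
        w = resolution_weights(resmap, epsilon)
        geo = self.geo_encoder(structure, weights=w)
        return self.fuse_context(geo, sequence, provider, w)
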
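"""Conditional noise-prediction network and sequence decoder.

Both branches are pre-layer-norm transformer decoders: per block a
self-attention over binder positions, a cross-attention that reads the
target context memory, and a GELU feed-forward, each with a residual
connection.  The noise branch receives the noised angle embedding x_t,
a sinusoidal positional encoding and a sinusoidal time-step embedding,
and predicts the injected Gaussian noise (L, 12).  The sequence branch
is architecturally identical but consumes clean angle embeddings and
has no time injection; it emits 20-way residue logits.

Before the context enters attention, its resolution weight vector is
lifted through a two-layer SiLU MLP and added to the memory rows, so
the network can re-modulate its trust in each target residue; the
context then receives its own positional encoding.

The default configuration matches the full model (4 layers, 8 heads of
64, width 512, FFN expansion 4); the memorization experiment uses a
reduced copy (2 layers, width 64).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .conditioning import ConditioningEncoder, TargetContext
from .io_structures import CANONICAL_AA

__all__ = [
    "DenoiserConfig",
    "SequenceLogits",
    "time_embedding",
    "positional_encoding",
    "PepDiffModel",
]

N_CLASSES = len(CANONICAL_AA)
ANGLE_CHANNELS = 12


@dataclass(frozen=True)
class DenoiserConfig:
    """Architecture hyperparameters shared by both decoder branches."""

    n_layers: int = 4
    n_heads: int = 8
    model_dim: int = 512
    head_dim: int = 64
    ffn_ratio: int = 4
    dropout: float = 0.0
    parameter_seed: int = 0
    context_dim: int = 512

    def __post_init__(self) -> None:
        if self.model_dim != self.n_heads * self.head_dim:
            raise ValueError("model_dim must equal n_heads * head_dim")
        if self.model_dim % 2 != 0:
            raise ValueError("model_dim must be even for sinusoidal embeddings")

    def as_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def reduced(parameter_seed: int = 0) -> "DenoiserConfig":
        """The small configuration used for desk-scale memorization runs."""
        return DenoiserConfig(n_layers=2, n_heads=4, model_dim=64, head_dim=16,
                              parameter_seed=parameter_seed)


@dataclass
class SequenceLogits:
    """(L, 20) logits over the canonical alphabet (ACDEFGHIKLMNPQRSTVWY)."""

    values: np.ndarray

    def argmax_sequence(self) -> str:
        return "".join(CANONICAL_AA[i] for i in self.values.argmax(axis=1))


def _sinusoid(pos: np.ndarray, dim: int) -> np.ndarray:
    """Interleaved sin/cos ladder with geometric frequencies (base 10000)."""
    pos = np.asarray(pos, dtype=float)[:, None]
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / half)
    args = pos * freqs[None, :]
    out = np.empty((pos.shape[0], dim))
    out[:, 0::2] = np.sin(args)
    out[:, 1::2] = np.cos(args)
    return out


def time_embedding(t: int, dim: int) -> np.ndarray:
    if t < 0:
        raise ValueError("time step must be nonnegative")
    if dim % 2 != 0:
        raise ValueError("embedding dimension must be even")
    return _sinusoid(np.array([t]), dim)[0]


def positional_encoding(L: int, dim: int) -> np.ndarray:
    if dim % 2 != 0:
        raise ValueError("embedding dimension must be even")
    return _sinusoid(np.arange(L), dim)


# ----------------------------------------------------------------------
class _DecoderBranch:
    """One pre-LN transformer decoder stack (parameters + forward)."""

    def __init__(self, config: DenoiserConfig, out_dim: int, rng: np.random.Generator,
                 prefix: str):
        self.config = config
        self.prefix = prefix
        d, c = config.model_dim, config.context_dim
        f = config.ffn_ratio * d

        def lin(fan_in: int, fan_out: int) -> Tensor:
            return ad.parameter(rng.standard_normal((fan_in, fan_out)) / np.sqrt(fan_in))

        p: dict[str, Tensor] = {
            "in_W": lin(ANGLE_CHANNELS, d), "in_b": ad.parameter(np.zeros(d)),
            "out_W": lin(d, out_dim), "out_b": ad.parameter(np.zeros(out_dim)),
            "final_ln_g": ad.parameter(np.ones(d)), "final_ln_b": ad.parameter(np.zeros(d)),
        }
        for i in range(config.n_layers):
            p.update({
                f"l{i}_ln1_g": ad.parameter(np.ones(d)), f"l{i}_ln1_b": ad.parameter(np.zeros(d)),
                f"l{i}_self_Wq": lin(d, d), f"l{i}_self_Wk": lin(d, d),
                f"l{i}_self_Wv": lin(d, d), f"l{i}_self_Wo": lin(d, d),
                f"l{i}_self_bo": ad.parameter(np.zeros(d)),
                f"l{i}_ln2_g": ad.parameter(np.ones(d)), f"l{i}_ln2_b": ad.parameter(np.zeros(d)),
                f"l{i}_cross_Wq": lin(d, d), f"l{i}_cross_Wk": lin(c, d),
                f"l{i}_cross_Wv": lin(c, d), f"l{i}_cross_Wo": lin(d, d),
                f"l{i}_cross_bo": ad.parameter(np.zeros(d)),
                f"l{i}_ln3_g": ad.parameter(np.ones(d)), f"l{i}_ln3_b": ad.parameter(np.zeros(d)),
                f"l{i}_ffn_W1": lin(d, f), f"l{i}_ffn_b1": ad.parameter(np.zeros(f)),
                f"l{i}_ffn_W2": lin(f, d), f"l{i}_ffn_b2": ad.parameter(np.zeros(d)),
            })
        self.params = p

    # -- attention helper ------------------------------------------------
    def _attend(self, q_in: Tensor, kv_in: Tensor, Wq: Tensor, Wk: Tensor,
                Wv: Tensor, Wo: Tensor, bo: Tensor) -> Tensor:
        cfg = self.config
        H, dh = cfg.n_heads, cfg.head_dim
        L = q_in.shape[0]
        Lk = kv_in.shape[0]
        q = ad.matmul(q_in, Wq).reshape(L, H, dh).transpose(1, 0, 2)
        k = ad.matmul(kv_in, Wk).reshape(Lk, H, dh).transpose(1, 0, 2)
        v = ad.matmul(kv_in, Wv).reshape(Lk, H, dh).transpose(1, 0, 2)
        scores = ad.matmul(q, k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
        attn = ad.softmax(scores)
        mixed = ad.matmul(attn, v).transpose(1, 0, 2).reshape(L, H * dh)
        return ad.matmul(mixed, Wo) + bo

    def forward(self, x: Tensor, memory: Tensor) -> Tensor:
        p = self.params
        h = x
        for i in range(self.config.n_layers):
            n1 = ad.layer_norm(h, p[f"l{i}_ln1_g"], p[f"l{i}_ln1_b"])
            h = h + self._attend(n1, n1, p[f"l{i}_self_Wq"], p[f"l{i}_self_Wk"],
                                 p[f"l{i}_self_Wv"], p[f"l{i}_self_Wo"], p[f"l{i}_self_bo"])
            n2 = ad.layer_norm(h, p[f"l{i}_ln2_g"], p[f"l{i}_ln2_b"])
            h = h + self._attend(n2, memory, p[f"l{i}_cross_Wq"], p[f"l{i}_cross_Wk"],
                                 p[f"l{i}_cross_Wv"], p[f"l{i}_cross_Wo"], p[f"l{i}_cross_bo"])
            n3 = ad.layer_norm(h, p[f"l{i}_ln3_g"], p[f"l{i}_ln3_b"])
            ff = ad.matmul(n3, p[f"l{i}_ffn_W1"]) + p[f"l{i}_ffn_b1"]
            ff = ad.matmul(ad.gelu(ff), p[f"l{i}_ffn_W2"]) + p[f"l{i}_ffn_b2"]
            h = h + ff
        h = ad.layer_norm(h, p["final_ln_g"], p["final_ln_b"])
        return ad.matmul(h, p["out_W"]) + p["out_b"]

    def embed_input(self, x: np.ndarray) -> Tensor:
        p = self.params
        return ad.matmul(ad.constant(x), p["in_W"]) + p["in_b"]


class PepDiffModel:
    """Joint model: conditioning encoder + noise branch + sequence branch.

    All learnable parameters live in one flat dict so a single optimizer
    updates both branches and the encoder in the same backward pass.
    """

    def __init__(self, config: DenoiserConfig | None = None,
                 encoder: ConditioningEncoder | None = None):
        self.config = config or DenoiserConfig()
        rng = np.random.default_rng(self.config.parameter_seed)
        self.encoder = encoder or ConditioningEncoder(
            parameter_seed=int(rng.integers(2**31)))
        if self.encoder.context_dim != self.config.context_dim:
            raise ValueError("encoder context width disagrees with config.context_dim")
        self.noise_branch = _DecoderBranch(self.config, ANGLE_CHANNELS, rng, "noise")
        self.seq_branch = _DecoderBranch(self.config, N_CLASSES, rng, "seq")
        c = self.config.context_dim
        def lin(fan_in, fan_out):
            return ad.parameter(rng.standard_normal((fan_in, fan_out)) / np.sqrt(fan_in))
        # two-layer SiLU MLP lifting the resolution weight scalar to the
        # context width; its output is added to the memory rows
        self.res_mlp = {
            "W1": lin(1, c), "b1": ad.parameter(np.zeros(c)),
            "W2": lin(c, c), "b2": ad.parameter(np.zeros(c)),
        }

    # ------------------------------------------------------------------
    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for k, v in self.encoder.params.items():
            out[f"enc.{k}"] = v
        for k, v in self.noise_branch.params.items():
            out[f"noise.{k}"] = v
        for k, v in self.seq_branch.params.items():
            out[f"seq.{k}"] = v
        for k, v in self.res_mlp.items():
            out[f"resmlp.{k}"] = v
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters().values())

    # ------------------------------------------------------------------
    def _corrected_memory(self, context: TargetContext,
                          positions: np.ndarray | None = None) -> Tensor:
        w = ad.constant(context.weights.w[:, None])
        h = ad.silu(ad.matmul(w, self.res_mlp["W1"]) + self.res_mlp["b1"])
        lift = ad.matmul(h, self.res_mlp["W2"]) + self.res_mlp["b2"]
        mem = context.memory + lift
        Lt = context.length
        if positions is None:
            positions = np.arange(Lt)
        pe = _sinusoid(positions, self.config.context_dim)
        return mem + ad.constant(pe)

    def predict_noise_graph(self, x_t: np.ndarray, t: int, context: TargetContext,
                            positions: np.ndarray | None = None) -> Tensor:
        """Noise prediction as an autodiff graph (training path)."""
        x_t = np.asarray(x_t, dtype=float)
        L, d = x_t.shape[0], self.config.model_dim
        q = self.noise_branch.embed_input(x_t)
        q = q + ad.constant(positional_encoding(L, d) + time_embedding(t, d)[None, :])
        mem = self._corrected_memory(context, positions)
        return self.noise_branch.forward(q, mem)

    def predict_noise(self, x_t: np.ndarray, t: int, context: TargetContext,
                      positions: np.ndarray | None = None) -> np.ndarray:
        return self.predict_noise_graph(x_t, t, context, positions).data

    def predict_sequence_graph(self, angle_embedding: np.ndarray,
                               context: TargetContext) -> Tensor:
        """Sequence logits as an autodiff graph (no time injection)."""
        x = np.asarray(angle_embedding, dtype=float)
        L, d = x.shape[0], self.config.model_dim
        q = self.seq_branch.embed_input(x)
        q = q + ad.constant(positional_encoding(L, d))
        mem = self._corrected_memory(context)
        return self.seq_branch.forward(q, mem)

    def predict_sequence(self, angle_embedding: np.ndarray,
                         context: TargetContext) -> SequenceLogits:
        return SequenceLogits(self.predict_sequence_graph(angle_embedding, context).data)

    # ------------------------------------------------------------------
    # checkpointing: a single npz weights container + JSON sidecar
    def save(self, path: str | Path, metadata: dict | None = None) -> None:
        path = Path(path)
        arrays = {k: p.data for k, p in self.parameters().items()}
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {"config": self.config.as_dict(),
                   "encoder_dims": {"geo": self.encoder.geo_dim,
                                    "seq": self.encoder.seq_dim,
                                    "descriptor": self.encoder.descriptor_dim}}
        if metadata:
            sidecar.update(metadata)
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path, config: DenoiserConfig | None = None) -> "PepDiffModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        saved_cfg = DenoiserConfig(**sidecar["config"])
        if config is not None and config != saved_cfg:
            diffs = [k for k in saved_cfg.as_dict()
                     if saved_cfg.as_dict()[k] != config.as_dict()[k]]
            raise ValueError(f"checkpoint config mismatch in fields: {diffs}")
        model = cls(saved_cfg)
        with np.load(path.with_suffix(".npz")) as data:
            params = model.parameters()
            missing = set(params) - set(data.files)
            if missing:
                raise ValueError(f"checkpoint missing parameters: {sorted(missing)[:5]}")
            for k, p in params.items():
                if p.data.shape != data[k].shape:
                    raise ValueError(f"parameter {k} shape mismatch")
                p.data = data[k].astype(np.float64)
        return model
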
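# Methods

## Model

`pepdiff` is a conditional denoising-diffusion model for peptide-binder
backbones, formulated in backbone internal coordinates. Each residue i
of a binder of length L is described by six angles:

* torsions φ_i (C_{i−1}–N_i–Cα_i–C_i), ψ_i (N_i–Cα_i–C_i–N_{i+1}) and
  ω_i (Cα_i–C_i–N_{i+1}–Cα_{i+1}), wrapped to (−π, π];
* bond angles θ₁ᵢ = ∠(N_i, Cα_i, C_i), θ₂ᵢ = ∠(Cα_i, C_i, N_{i+1}),
  θ₃ᵢ = ∠(C_i, N_{i+1}, Cα_{i+1}), in (0, π).

φ₁ and the four (i, i+1)-spanning angles of the last residue are
geometrically undefined; they carry ideal-geometry sentinel values and
a validity mask, and masked entries are excluded from losses and
metrics. Because angles live on a torus, every angle is embedded as a
(cos α, sin α) pair before entering the network, giving an (L, 12)
continuous state with no wrap-around discontinuity; angles are
recovered with atan2, which is scale-invariant, so the noisy pairs need
not be renormalised. The diffusion process operates on this 12-channel
embedded state, where additive Gaussian noise is well defined; this is
one of the genuinely open design choices (diffusing 6 raw angles is the
alternative) and the embedded space was chosen because the trigonometric
embedding exists precisely to remove the periodicity discontinuity that
raw-angle noise would reintroduce.

Cartesian backbones are reconstructed by the natural extension
reference frame (NeRF) algorithm: the first residue is seeded
canonically (N at the origin, Cα on +x, C in the xy-plane at angle θ₁)
and each subsequent atom D is placed from the three preceding atoms
A, B, C plus a bond length l, bond angle θ and torsion τ such that
|D−C| = l, ∠(B,C,D) = θ and dihedral(A,B,C,D) = τ. Correctness is
defined by these three identities (verified to 1e-9 in tests) rather
than any particular trigonometric convention, since θ vs π−θ
conventions vary between formulations. The placement cycle consumes
(ψ_i, θ₂ᵢ) → N_{i+1}, (ω_i, θ₃ᵢ) → Cα_{i+1}, (φ_{i+1}, θ₁ᵢ₊₁) →
C_{i+1}; this also fixes the otherwise arbitrary assignment of θ₁–θ₃
to atom triples. Bond lengths are the Engh–Huber values
l(N–Cα) = 1.458 Å, l(Cα–C) = 1.525 Å, l(C–N) = 1.329 Å, immutable per
run and recorded in sampling metadata. Rebuilding from internal
coordinates guarantees ideal covalent geometry exactly and realises
backbone chirality correctly: the canonical L-helix torsions
(φ = −57°, ψ = −47°) reconstruct to a right-handed helix, and the
mirror image is distinguishable by the sign of extracted torsions.

## Diffusion

Forward process: x_t = √ᾱ_t·x₀ + √(1−ᾱ_t)·ε with ᾱ_t = ∏_{s≤t}(1−β_s),
t = 1..T (t = 0 is data). Two schedule families are provided: a linear
ramp β_t from 0.001 to 0.02 (training default) and the squared-cosine
ᾱ profile with offset s = 0.008 and β clipped at 0.999. Both appear in
the source method description (linear for training, cosine for
inference stability); since they parameterise the same closed form,
the family is a config field recorded in run metadata, with linear as
default. Reverse sampling is the ε-prediction DDPM update

    x_{t−1} = (x_t − ((1−α_t)/√(1−ᾱ_t))·ε_θ) / √α_t + σ_t·z,

with σ_t = √β_t (the "large" DDPM variance; σ is otherwise
unspecified) and z forced to 0 at t = 1 so the returned conformation is
deterministic given the final prediction. Sampled bond-angle pairs can
unembed outside (0, π); the sampler reflects |θ| into (1e-3, π−1e-3)
when building the returned angle table so the table invariant (and
NeRF's domain requirement) always holds. Generation-time binder length
is a required user input; the source method never states how lengths
are chosen at inference.

## Conditioning

The target context memory is an (L_tgt, 512) matrix, the feature-wise
concatenation of:

* a geometric branch: per-residue rigid-motion-invariant descriptors
  (the 12-wide torsion trig embedding, sorted scaled distances to the
  k = 16 nearest Cα neighbours, and six local-frame scalar products),
  gated row-wise by the resolution weight w_i = 1/(R_i + ε) with
  ε = 1e-6, then passed through a learnable width-3 sequence-local
  convolution, GELU, and a projection to 256 features. "Graph
  convolution with kernel size 3" is ambiguous in the source; a
  width-3 kernel is a sequence-convolution notion, so the convolution
  runs over sequence-local windows of invariant descriptors. Gating is
  applied to the raw descriptors (before the learnable encoder) so
  unreliable residues are attenuated at the source.
* a semantic branch: a per-residue (L, 1280) embedding from a
  pluggable provider, projected to 256 features. The default provider
  is a deterministic stub — each residue's 20-way one-hot lifted to
  1280 features by a fixed seeded random projection — so the package
  builds and tests with no model download; a frozen protein language
  model fits behind the same interface.

The context type guarantees memory = concat(geo_part, seq_part); the
fusing linear map of the conditioned architecture is folded into the
denoiser's K/V projections, which read the 512-wide memory directly.
Per-residue resolution comes from a sidecar two-column table when
given, else the PDB header value broadcast, else a 2.0 Å default with
a warning; how "local" resolution should be obtained for X-ray entries
(which report one global value) is left to the user via the sidecar.

## Network

Both branches are pre-layer-norm transformer decoders with n_layers
blocks of (self-attention over binder positions → cross-attention to
the target memory → GELU feed-forward), each residual. Defaults: 4
layers, 8 heads × 64 = width 512, FFN expansion 4. Self-attention
precedes cross-attention (the standard decoder order; the source names
both without ordering them). The noise branch input is the noised
(L, 12) state projected to model width plus sinusoidal positional and
time-step embeddings (interleaved sin/cos, base 10000); the sequence
branch is identical minus the time embedding and consumes clean angle
embeddings (it is not part of the diffusion chain). Before attention,
the context memory is corrected by adding the resolution weight vector
lifted through a two-layer SiLU MLP to the context width — addition
rather than concatenation keeps the printed 512 context width — and
receives its own positional encoding. Weights are initialised with
fan-in scaling from a recorded parameter seed; all forward passes are
bit-deterministic.

The whole stack runs on a compact reverse-mode autodiff engine over
float64 numpy arrays (`pepdiff.autodiff`), exposing exactly the
operations the model uses; gradients are verified against central
differences in the test suite. At desk scale (reduced model, chains of
tens of residues) this trains in minutes on one CPU.

## Training

L_total = λ_geo·L_geo + λ_seq·L_seq with λ_geo = λ_seq = 1 by default
(the weights are unprinted in the source). L_geo is the mean squared
error between predicted and injected noise over unmasked channels;
L_seq is the per-residue mean cross-entropy of the native binder
sequence — a mean rather than the printed sum so magnitudes are
length-independent. Per optimizer step one complex pair is drawn, a
small batch of uniform time steps t ∈ {1..T} is averaged for L_geo,
and a single Adam update covers both branches, the conditioning
encoder and the resolution MLP. Optimizer, learning rate and batch
size are unprinted in the source and are config fields; desk-scale
defaults are Adam with peak lr 1e-3, 4 time steps per update (at 2e-3
the sequence branch oscillates instead of converging) and a cosine
learning-rate ramp down to 5% of the peak, which damps the
gradient-noise floor Adam otherwise sustains late in training and
makes the final loss reproducibly low across seeds. Divergence
(non-finite loss) aborts with a diagnostic. Dataset procedures:
bidirectional symmetry augmentation appends a role-swapped twin per
pair (the swapped-in conditioning chain receives a default resolution
map when it has none), and redundancy filtering removes test sequences
with ≥ 30% global-alignment identity to any training sequence using
the in-package Needleman–Wunsch scorer (match 1, mismatch 0, gap −1,
identity divided by max length) rather than an external clustering
binary.

## Metrics

Interface contacts: cross-chain heavy-atom pairs with Euclidean
distance ≤ 4.5 Å (the ≤ follows the printed indicator function),
computed with a KD-tree and checked against a brute-force double loop
in tests. Radius of gyration: RMS distance of Cα atoms to their
centroid, unit masses. Secondary structure: a torsion-window
classifier — H for φ ∈ [−100°, −30°] and ψ ∈ [−67°, −7°], E for
φ ∈ [−180°, −90°] and ψ ∈ [90°, 180°], else C; termini with undefined
torsions are C. This replaces hydrogen-bond-based assignment, which
needs an external binary and full-atom geometry; the window method is
deterministic and self-contained, and is the package's documented
deviation. Helicity and the helical Ramachandran fraction are the H
fraction over torsion-defined residues; the Ramachandran density is a
36×36 histogram over (−π, π]². Clashes: heavy-atom pairs strictly
closer than 2.5 Å, excluding intra-residue pairs and same-chain
adjacent-residue pairs (fixed by covalent geometry); the source
reports clash counts without defining them, so cutoff and exclusions
are package choices recorded here. Shape ratio: largest over smallest
principal radius of the gyration tensor (smallest floored at 1e-6,
ratio capped at 1e6) — also undefined in the source and flagged as a
package definition. GRAVY and aromaticity use the Kyte–Doolittle table
and F/W/Y fraction; the isoelectric point is root-found on the
Bjellqvist-table charge curve so the returned pH has |net charge|
< 1e-4. Generated backbones carry no side chains, so contact/clash
counting falls back to backbone heavy atoms and the report metadata
records it.

## Synthetic fixtures

The fixture generator emulates the structure of a curated complex
corpus at desk scale: idealized chains with known torsions (helix
φ = −57°/ψ = −47°, strand φ = −135°/ψ = 135°, ω = 180°; coil sampled
uniformly from φ ∈ [−160°, −60°], ψ ∈ [60°, 170°], a broad allowed
basin disjoint from the helical window, so even random fixtures avoid
forbidden regions), seeded random canonical sequences, binders rigidly
docked at a controlled minimum interface distance (root-found to
~1e-3 Å, planted contact count stored as ground truth), and
per-residue resolutions drawn uniformly from 1.5–3.5 Å — a typical
crystallographic range. Default sizes are targets of 20–28 and binders
of 8–15 residues. What the fixtures deliberately do not emulate: real
interface physics (hydrogen bonding, desolvation), side chains,
cofactors, and realistic sequence–structure covariation. Passing tests
therefore demonstrate the correctness of the machinery (geometry,
diffusion algebra, conditioning, optimization, metrics), not
biological validity of designs trained on toy data.

## The memorization experiment

The strongest end-to-end check trains a reduced model (2 layers,
4 heads × 16 = width 64, T = 100, linear schedule) for 2000 steps on
one toy complex, then requires (a) a deterministic end-of-training
loss estimate (averaged over a fixed grid of time steps and noise
draws) below 0.05, (b) reverse sampling from pure noise to reproduce
the memorized binder conformation to < 0.3 rad mean absolute circular
error over defined angles, and (c) the sequence branch argmax to
recover ≥ 90% of the binder residues on the sampled conformation.
Success requires conditioning, both decoder branches, the losses, the
optimizer, the sampler and the angle/coordinate conversions to be
simultaneously correct; a sign error in a single dihedral convention
breaks it.

## Numerical choices and limitations

Float64 throughout; dihedrals via the atan2 formulation (IUPAC sign,
cross-checked against an independent structural library); collinear
frames rejected with the offending residue named; zero-norm embedded
pairs fall back to sentinels; t-indexing is 1-based with β stored at
index t−1. Known limitations: no side-chain or carbonyl-O modelling,
no cis-proline handling, no cofactor/heteroatom awareness, the stub
embedding provider carries no evolutionary information, and desk-scale
experiments use toy fixtures — headline statistics of the full-scale
system (trained on thousands of curated complexes) are out of reach of
this repository and are not claimed.
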
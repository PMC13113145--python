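# pepdiff

Resolution-aware internal-coordinate diffusion for de novo peptide
binder design.

Peptide binders against protein–protein interaction (PPI) interfaces
must adapt flexibly to flat, groove-poor surfaces. `pepdiff` generates
binder backbones with a conditional denoising-diffusion model that
operates entirely in backbone internal coordinates — per residue the
6-vector a_i = [φ_i, ψ_i, ω_i, θ₁ᵢ, θ₂ᵢ, θ₃ᵢ] of torsions and bond
angles, embedded on the unit circle as (cos α, sin α) pairs — rather
than in Cartesian space. Working on this angular manifold removes the
redundant degrees of freedom that let coordinate-space generators break
bonds: Cartesian backbones are rebuilt by the natural extension
reference frame (NeRF) algorithm with fixed Engh–Huber bond lengths, so
every generated chain satisfies ideal covalent geometry and backbone
chirality by construction.

The model is conditioned on the target protein through a per-residue
context memory that fuses rigid-motion-invariant geometric descriptors
with language-model-style sequence embeddings, and it is
resolution-aware: each target residue's experimental resolution R_i (Å)
is mapped to a reliability weight w_i = 1/(R_i + ε) that gates the
geometric features, so poorly resolved regions contribute less. A
parallel, architecturally identical decoder branch co-generates the
amino-acid sequence, trained jointly with the noise predictor under a
composite loss

    L_total = λ_geo · MSE(ε_θ(x_t, c, t), ε) + λ_seq · CE(y | x_0, c).

The forward process is the standard DDPM chain
x_t = √ᾱ_t·x_0 + √(1−ᾱ_t)·ε with a linear β schedule (0.001 → 0.02;
a squared-cosine schedule is also available), and sampling uses the
ε-prediction DDPM reverse update. Designs are scored with an
interface/topology/physicochemistry metric suite: heavy-atom interface
contacts at 4.5 Å, radius of gyration, gyration-tensor shape ratio,
torsion-window secondary structure (helicity, Ramachandran density),
steric clashes, Needleman–Wunsch global sequence identity with a
max-length denominator, GRAVY, aromaticity and isoelectric point.

Everything runs on one CPU with no downloads: the neural network stack
is built on a compact in-package reverse-mode autodiff engine over
numpy, and a seeded stub stands in for the frozen language-model
embedding provider (a real provider can be plugged in behind the same
interface).

## Worked example

Generate a toy dataset, train a reduced model, sample binders for one
target and score them:

```sh
pepdiff fixtures --out-dir runs/fx --n-pairs 2 --seed 3
pepdiff train    --data-dir runs/fx --out-dir runs/tr \
                 --steps 60 --seed 3 --diffusion-steps 50
pepdiff sample   --checkpoint runs/tr/checkpoint \
                 --target-pdb runs/fx/pair_000_target.pdb \
                 --target-fasta runs/fx/pair_000_target.fasta \
                 --resolution-sidecar runs/fx/pair_000_target.res \
                 --binder-length 10 --n-samples 2 --seed 5 --out-dir runs/sm
pepdiff evaluate runs/sm --target-pdb runs/fx/pair_000_target.pdb \
                 --out-dir runs/ev
```

`runs/ev/metrics.csv` then holds one row per generated binder, e.g.

```
complex,contacts,rg,helicity,rama_helix,shape_ratio,clashes,gravy,aromaticity,isoelectric_point,seq_identity
sample_000,124,3.5062368274262368,0.0,0.0,3.3276103360997675,52,-2.5700000000000003,0.0,3.2472892538924754,
sample_001,30,3.8330296594208613,0.0,0.0,6.17288367951648,55,-3.5,0.0,3.0796989079438806,
```

Columns mean: cross-chain heavy-atom contacts within 4.5 Å (interface
density), radius of gyration in Å (compactness), helical fraction and
helical-window Ramachandran fraction (secondary structure), principal
radius ratio (shape anisotropy), steric clash count, and the three
sequence physicochemistry scores of the co-generated sequence. A model
trained for only 60 steps still emits essentially noise-shaped angle
tables — hence the tight, clash-ridden coils above (backbone covalent
geometry is nonetheless exact, because the chains are NeRF rebuilds);
the memorization experiment below shows what convergence looks like.
Every output directory contains a `run.json` recording the exact
configuration and seeds, so reruns are reproducible.

The strongest end-to-end check is the built-in memorization experiment
(`pepdiff.experiments.run_memorization_experiment`): a reduced model
(2 layers, width 64, T = 100) trained for 2000 steps on a single toy
complex reaches a total loss near 0.012, reverse sampling from pure
noise then reproduces the memorized binder conformation to ~0.011 rad
mean angular error, and the sequence branch recovers 100% of its
residues.

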
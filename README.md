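# bbdiff

Programmable denoising-diffusion generation of protein backbones, at desk
scale: a polymer-structured Gaussian prior, correlated diffusion with
low-temperature sampling, a sub-quadratic random-graph denoiser with
consensus structure synthesis, and composable conditioners for symmetry,
substructure, distances, shape and classifier guidance.

## Who this is for

Researchers and students who want a small, fully testable implementation of
the machinery behind diffusion-based backbone generators — every component
validated against closed forms, oracles or exactness contracts on synthetic
data — rather than a trained production model. All training structures come
from the built-in synthetic generator; nothing is downloaded.

## The model

**Prior.** A length-N CA trace is modeled as a chain-correlated Gaussian: a
centered random walk whose step size is set so the ensemble obeys the
collapsed-polymer law

    E[Rg²] = r0² · N^(2ν),      r0 = 2.0 Å, ν = 0.4 (defaults)

plus an optional global-translation mode. An O(N) whitening transform maps
the prior to an identity-covariance latent, where the diffusion is the
standard variance-preserving process z_t = α(t) z₀ + σ(t) ε with log-SNR
linear in t.

**Denoiser.** A random geometry graph (chain neighbours + k nearest + random
long-range edges sampled ∝ distance⁻², constant per-node budget ⇒ edge count
linear in N) carries per-edge predictions of residue j's clean position in
residue i's local frame — invariant features, local-frame outputs, hence an
SE(3)-equivariant map x_t ↦ x̂₀. Global coordinates are synthesized by a
consensus solver that alternates per-node Kabsch rotation fits with a sparse
weighted least-squares position solve.

**Sampling.** Reverse-time Euler–Maruyama with the score scaled by an inverse
temperature λ and ψ Langevin corrector sub-steps per grid step: λ = 1, ψ = 0
is standard ancestral sampling; λ > 1 trades diversity for likelihood, with
the exact Gaussian limit N(μ, Σ/λ) used as the validation target.

**Conditioning.** Conditioners compose freely; hard transforms (exact
symmetry tessellation over Cn/Dn/T/O/I, replacement clamping of registered
substructure) are applied every step, soft energies (harmonic distances,
entropic-optimal-transport shape cost, classifier log-probabilities) add
their gradients to the score.

## Worked example

`examples/03_train_and_sample.py` trains the desk-scale denoiser on noised
synthetic helices (seconds on one CPU) and samples backbones at two
temperatures:

```
training loss: 325.8 -> 53.2 over 5 epochs
lambda=  1: Rg =  20.4 ± 0.73 Å,  helix fraction = 0.99
lambda=  8: Rg =  21.5 ± 0.01 Å,  helix fraction = 1.00
```

The loss drop shows the edge regressor learning local helix geometry from
noised examples. Sampled 50-residue backbones are almost entirely helical
(the training distribution), with a radius of gyration near the ~21 Å of a
straight 50-residue helix; raising the inverse temperature from 1 to 8
collapses the Rg spread from ±0.73 Å to ±0.01 Å — the quality-for-diversity
trade of low-temperature sampling. One sample is written to
`sample_lambda1.pdb`.

The other examples each demonstrate one capability and print what they
compute: the prior's Rg scaling law (`01`), closed-form tempering on a
Gaussian toy (`02`), exact symmetric assembly up to a 60,000-residue
icosahedral complex (`04`), half-structure infilling (`05`), and composed
shape + distance guidance (`06`).

A thin CLI wraps the same library calls:

```bash
bbdiff train --epochs 5 --n-structures 50 --seed 1 --out-dir run/
bbdiff sample --length 50 --steps 150 --seed 0 --weights run/weights.npz \
              --symmetry C4 --out-dir samples/
bbdiff analyze samples/ --out stats.tsv
```

Every run writes a JSON manifest (seed, settings, conditioner stack,
version) from which it can be reproduced exactly.

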
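"""Train the desk-scale graph denoiser and sample backbones from it.

The denoiser predicts, per random-graph edge, where residue j sits in residue
i's local frame at t=0, then synthesizes global coordinates by consensus.
Training is streaming ridge regression over noised synthetic helices —
seconds on one CPU — after which reverse diffusion yields helix-like
backbones whose diversity shrinks at low temperature.
"""

import numpy as np

from bbdiff import (DiffusionSchedule, PolymerPrior, SamplerSettings,
                    make_ideal_helix, radius_of_gyration, reverse_sample,
                    ss_fractions, train_denoiser, write_pdb)

sched = DiffusionSchedule(n_steps=150)
rng = np.random.default_rng(0)
train = [make_ideal_helix(int(n), seed=i, jitter=0.15)
         for i, n in enumerate(rng.integers(30, 80, 50))]
model = train_denoiser(train, sched, PolymerPrior(2), n_epochs=5, seed=3)
print(f"training loss: {model.loss_history[0]:.1f} -> "
      f"{model.loss_history[-1]:.1f} over {len(model.loss_history)} epochs")

prior = PolymerPrior(50)
for lam, psi in ((1.0, 0), (8.0, 1)):
    rgs, helix_fracs = [], []
    for k in range(4):
        s = reverse_sample(prior, sched, model,
                          SamplerSettings(lambda_=lam, psi=psi, n_steps=100,
                                          seed=10 + k), 50)
        rgs.append(radius_of_gyration(s))
        helix_fracs.append(ss_fractions(s)[0])
        if lam == 1.0 and k == 0:
            write_pdb(s, "sample_lambda1.pdb")
    print(f"lambda={lam:3.0f}: Rg = {np.mean(rgs):5.1f} ± {np.std(rgs):4.2f} Å,"
          f"  helix fraction = {np.mean(helix_fracs):.2f}")

print("\nThe falling loss shows the edge regressor learning helix geometry;")
print("sampled backbones are strongly helical, and the Rg spread collapses at")
print("lambda=8 — less conformational diversity, higher-likelihood samples.")
print("One sample was written to sample_lambda1.pdb.")
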
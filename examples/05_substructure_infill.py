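"""Protein infilling: clamp half a structure and regenerate the rest.

Replacement conditioning substitutes noise-matched reference coordinates for
the clamped residues at every reverse step, so at t=0 the clamped half equals
the reference exactly while the free half is sampled fresh each seed.
"""

import numpy as np

from bbdiff import (DiffusionSchedule, PolymerPrior, SamplerSettings,
                    kabsch_rmsd, make_ideal_helix, make_substructure_conditioner,
                    make_synthetic_set, reverse_sample, train_denoiser)

sched = DiffusionSchedule(n_steps=150)
rng = np.random.default_rng(0)
train = [make_ideal_helix(int(n), seed=i, jitter=0.15)
         for i, n in enumerate(rng.integers(30, 80, 40))]
model = train_denoiser(train, sched, PolymerPrior(2), n_epochs=4, seed=3)

reference = make_ideal_helix(60)
mask = np.zeros(60, bool)
mask[:30] = True  # clamp the first half
prior = PolymerPrior(60)
cond = make_substructure_conditioner(reference, mask, prior, sched)

outs = [reverse_sample(prior, sched, model,
                       SamplerSettings(n_steps=80, seed=s), 60, [cond])
        for s in (1, 2)]
for k, s in enumerate(outs):
    clamp_dev = np.abs(s.ca[:30] - reference.ca[:30]).max()
    print(f"seed {k + 1}: clamped-half max deviation = {clamp_dev:.1e} Å")
free_diff = kabsch_rmsd(outs[0].ca[30:], outs[1].ca[30:])
print(f"free-half RMSD between the two seeds = {free_diff:.2f} Å")

print("\nThe clamped half reproduces the reference exactly (deviation 0) at")
print("t=0, while the regenerated half genuinely varies from seed to seed.")
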
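"""Compose soft conditioners: shape guidance and distance restraints.

On a Gaussian toy with an analytic denoiser, an entropic-optimal-transport
energy pulls the sampled point set toward an L-shaped target cloud, and a
harmonic restraint pins a chosen pair distance — both act through gradients
added to the score, and both compose freely.
"""

import warnings

import numpy as np

# during guidance the transport plan only needs moderate precision; silence
# the cap warning from the capped scaling iterations
warnings.filterwarnings("ignore", category=RuntimeWarning)

from bbdiff import (DiffusionSchedule, GaussianToyDenoiser, IdentityPrior,
                    SamplerSettings, compose, make_distance_conditioner,
                    make_shape_conditioner, reverse_sample_array)
from bbdiff.ot import sinkhorn_divergence

sched = DiffusionSchedule(n_steps=100)
n_pts = 9
arm = np.linspace(0, 6, 6)
cloud = np.concatenate([np.stack([np.zeros(6), arm, np.zeros(6)], 1),
                        np.stack([arm[1:4], np.zeros(3), np.zeros(3)], 1)])
den = GaussianToyDenoiser(np.zeros(3 * n_pts), 4.0 * np.eye(3 * n_pts), sched)

shape = make_shape_conditioner(cloud, epsilon=1.0, weight=0.3, max_iters=200)
dist = make_distance_conditioner([(0, 8)], [6.0], 1.0)
stack = compose([shape, dist])

for label, conds in (("unconditioned", []), ("shape+distance", [stack])):
    costs, dists = [], []
    for seed in range(8):
        x = reverse_sample_array(IdentityPrior(n_pts), sched, den.contract(),
                                 SamplerSettings(n_steps=100, seed=seed),
                                 (n_pts, 3), conds)
        costs.append(sinkhorn_divergence(x, cloud, 1.0)[0])
        dists.append(np.linalg.norm(x[8] - x[0]))
    print(f"{label:15s}: OT cost to L-cloud = {np.mean(costs):6.2f},  "
          f"d(0,8) = {np.mean(dists):5.2f} Å (target 6.0)")

print("\nGuidance lowers the transport cost to the target shape and moves the")
print("restrained pair toward its 6 Å target, without any retraining — the")
print("conditioners simply add gradients to the reverse-time score.")
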
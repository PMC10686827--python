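"""Low-temperature reverse sampling on a Gaussian toy with exact answers.

For Gaussian data the optimal denoiser is analytic, so the reverse sampler can
be checked against closed forms: at inverse temperature lambda the sampled
distribution should be N(mu, Sigma/lambda) — same mean, covariance shrunk by
lambda.  This is the quality/diversity dial used for backbone generation.
"""

import numpy as np

from bbdiff import (DiffusionSchedule, GaussianToyDenoiser, IdentityPrior,
                    SamplerSettings, reverse_sample_array)

mu = np.array([1.0, -2.0, 0.5])
sigma = np.array([[1.0, 0.5, 0.0], [0.5, 2.0, 0.3], [0.0, 0.3, 0.7]])
sched = DiffusionSchedule(n_steps=300)
den = GaussianToyDenoiser(mu, sigma, sched)

for lam in (1.0, 2.0, 4.0):
    settings = SamplerSettings(lambda_=lam, psi=2 if lam > 1 else 0,
                               n_steps=300, seed=0)
    x = reverse_sample_array(IdentityPrior(1), sched, den.contract(),
                             settings, (8000, 1, 3)).reshape(8000, 3)
    cov = np.cov(x.T)
    print(f"lambda={lam:3.0f}  mean={np.round(x.mean(0), 2)}  "
          f"tr(cov)={np.trace(cov):5.2f}  expected tr(Sigma)/lambda="
          f"{np.trace(sigma) / lam:5.2f}")

print("\nThe sampled covariance trace tracks tr(Sigma)/lambda: raising the")
print("inverse temperature concentrates samples near the mode while leaving")
print("the mean untouched — the quality-for-diversity trade of tempering.")
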
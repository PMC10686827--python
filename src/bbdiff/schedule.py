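"""Variance-preserving diffusion schedule with log-SNR linear in time.

In the whitened latent space the forward process is the standard
variance-preserving (VP) diffusion: z_t = alpha(t) z_0 + sigma(t) eps with
alpha^2 + sigma^2 = 1.  The schedule is parameterized by a log signal-to-noise
ratio that falls linearly from ``logsnr_max`` at t=0 to ``logsnr_min`` at t=1
(natural-log units), a common smooth choice.  The correlated coordinate-space
process is the image of this standard process under the prior's unwhitening
map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DiffusionSchedule:
    """VP schedule on t in [0, 1] plus the reverse-integration step grid."""

    n_steps: int = 200
    logsnr_max: float = 10.0
    logsnr_min: float = -10.0

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.logsnr_max <= self.logsnr_min:
            raise ValueError("logsnr_max must exceed logsnr_min")

    def logsnr(self, t):
        t = np.asarray(t, dtype=float)
        return self.logsnr_max + t * (self.logsnr_min - self.logsnr_max)

    def alpha(self, t):
        """Signal amplitude; alpha(0) ~ 1, alpha(1) ~ 0, strictly decreasing."""
        return np.sqrt(self._alpha_sq(t))

    def sigma(self, t):
        """Noise amplitude; sigma = sqrt(1 - alpha^2) (variance preserving)."""
        return np.sqrt(1.0 - self._alpha_sq(t))

    def _alpha_sq(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or np.any(t > 1):
            raise ValueError("t must lie in [0, 1]")
        return 1.0 / (1.0 + np.exp(-self.logsnr(t)))

    def beta(self, t):
        """Instantaneous VP noise rate beta(t) = -d log alpha^2 / dt."""
        # for log-SNR linear in t: beta = (logsnr_max - logsnr_min) * sigma(t)^2
        return (self.logsnr_max - self.logsnr_min) * (1.0 - self._alpha_sq(t))

    def grid(self) -> np.ndarray:
        """Uniform reverse-time grid from t=1 down to t=1/n_steps."""
        return np.linspace(1.0, 1.0 / self.n_steps, self.n_steps)
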
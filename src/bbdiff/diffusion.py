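"""Forward noising, score conversion and (low-temperature) reverse sampling.

The diffusion runs in the whitened latent space of the polymer prior, where it
is the textbook variance-preserving process; coordinate space sees the image
of that process under the prior's correlation structure.  The reverse-time
integrator is Euler–Maruyama on a uniform grid with optional Langevin
corrector sub-steps.  Low-temperature sampling multiplies the score by an
inverse temperature ``lambda_`` in both the predictor and the corrector; the
corrector's stationary law at fixed t is then p_t^lambda, so with corrector
equilibration the sampler approaches the tempered target (for Gaussian data,
N(mu, Sigma/lambda)) as t -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .prior import IdentityPrior, PolymerPrior
from .schedule import DiffusionSchedule

Array = np.ndarray


@dataclass
class DenoiserContract:
    """A callable (x_t, t) -> predicted x_0 plus metadata.

    ``fn`` must accept arrays of shape (n_residues, d) — or (batch, n, d) when
    ``batched`` — and return the same shape.  ``n_residues`` of None marks a
    length-agnostic denoiser.
    """

    fn: Callable[[Array, float], Array]
    n_residues: int | None = None
    batched: bool = False

    def __call__(self, x_t: Array, t: float) -> Array:
        out = np.asarray(self.fn(x_t, t), dtype=float)
        if out.shape != np.shape(x_t):
            raise ValueError(f"denoiser output shape {out.shape} != input {np.shape(x_t)}")
        return out


@dataclass(frozen=True)
class SamplerSettings:
    """Reverse-sampling knobs.

    lambda_ : inverse temperature (>= 1); 1 is the standard reverse process.
    psi : number of Langevin corrector sub-steps per grid step (>= 0).
    corrector_snr : dimensionless corrector step-size ratio (Song-style rule).
    """

    lambda_: float = 1.0
    psi: int = 0
    n_steps: int = 200
    seed: int = 0
    corrector_snr: float = 0.25

    def __post_init__(self) -> None:
        if self.lambda_ < 1.0:
            raise ValueError("inverse temperature lambda_ must be >= 1")
        if self.psi < 0:
            raise ValueError("psi must be >= 0")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")


def forward_marginal(prior, schedule: DiffusionSchedule, x0: Array, t: float,
                     seed: int | np.random.Generator = 0) -> Array:
    """Sample x_t = alpha(t) x0 + sigma(t) * unwhiten(z), z ~ N(0, I).

    At t=0 returns x0 exactly; at t=1 the marginal is the prior (the signal
    term is numerically negligible at the schedule's terminal log-SNR).
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must lie in [0, 1]")
    x0 = np.asarray(x0, dtype=float)
    if t == 0.0:
        return x0.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal(x0.shape)
    return schedule.alpha(t) * x0 + schedule.sigma(t) * prior.unwhiten(z)


def score_from_denoiser(prior, schedule: DiffusionSchedule, denoiser, x_t: Array,
                        t: float) -> Array:
    """Coordinate-space score: C^+ (alpha(t) xhat0 - x_t) / sigma(t)^2.

    C is the prior covariance; the identity is the standard conversion between
    the optimal denoiser and the marginal score of a diffusion whose base
    noise has covariance C.
    """
    if not 0.0 < t <= 1.0:
        raise ValueError("score is undefined at t=0; t must lie in (0, 1]")
    x_t = np.asarray(x_t, dtype=float)
    xhat0 = denoiser(x_t, t)
    resid = schedule.alpha(t) * xhat0 - x_t
    return prior.solve_covariance(resid) / schedule.sigma(t) ** 2


class GaussianToyDenoiser:
    """Analytic optimal denoiser for Gaussian data N(mu, Sigma) in whitened
    space — the closed-form oracle used to validate the sampler.

    E[x0 | x_t] = mu + Sigma alpha (alpha^2 Sigma + sigma^2 I)^{-1} (x_t - alpha mu).
    """

    def __init__(self, mu: Array, sigma_mat: Array, schedule: DiffusionSchedule):
        self.mu = np.asarray(mu, dtype=float)
        self.sigma_mat = np.atleast_2d(np.asarray(sigma_mat, dtype=float))
        self.schedule = schedule
        self.dim = self.mu.size

    def __call__(self, x_t: Array, t: float) -> Array:
        a = float(self.schedule.alpha(t))
        s2 = float(self.schedule.sigma(t)) ** 2
        gram = a**2 * self.sigma_mat + s2 * np.eye(self.dim)
        flat = np.asarray(x_t, dtype=float).reshape(-1, self.dim)
        gain = np.linalg.solve(gram, (flat - a * self.mu).T).T
        out = self.mu + a * gain @ self.sigma_mat.T
        return out.reshape(np.shape(x_t))

    def contract(self) -> DenoiserContract:
        return DenoiserContract(self, n_residues=None, batched=True)


def _conditioner_score(conditioners, x: Array, t: float) -> Array | None:
    """Sum of soft-energy score contributions (-grad U + guidance) at x."""
    total = None
    for cond in conditioners or []:
        g = cond.score_contribution(x, t)
        if g is not None:
            total = g if total is None else total + g
    return total


def _apply_hard(conditioners, x: Array, t: float) -> Array:
    for cond in conditioners or []:
        if cond.has_hard_transform:
            x = cond.hard_transform(x, t)
    return x


def reverse_sample_array(prior, schedule: DiffusionSchedule, denoiser,
                         settings: SamplerSettings, shape: tuple[int, ...],
                         conditioners: Sequence | None = None,
                         rng: np.random.Generator | None = None) -> Array:
    """Integrate the reverse-time process from t=1 to t=0 and return raw
    coordinates of the requested shape (..., n_residues, d).

    The predictor is Euler–Maruyama on the whitened VP SDE with the score
    scaled by ``settings.lambda_``; each grid step is followed by
    ``settings.psi`` Langevin corrector sub-steps at the same temperature.
    Hard conditioner transforms are applied after every update; soft
    conditioner gradients are added to the score before every update.
    """
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    lam = settings.lambda_
    grid = DiffusionSchedule(settings.n_steps, schedule.logsnr_max,
                             schedule.logsnr_min).grid()
    z = rng.standard_normal(shape)
    x = _apply_hard(conditioners, prior.unwhiten(z), 1.0)
    z = prior.whiten(x)

    def whitened_score(z_cur: Array, t: float) -> Array:
        x_cur = prior.unwhiten(z_cur)
        xhat0 = denoiser(x_cur, t)
        if not np.all(np.isfinite(xhat0)):
            raise FloatingPointError(f"denoiser returned non-finite values at t={t:.4f}")
        zhat0 = prior.whiten(xhat0)
        score = (schedule.alpha(t) * zhat0 - z_cur) / schedule.sigma(t) ** 2
        extra = _conditioner_score(conditioners, x_cur, t)
        if extra is not None:
            # soft constraints are annealed in with the signal amplitude: they
            # are statements about the clean structure, so their pull fades at
            # high noise and reaches full strength as t -> 0
            score = score + schedule.alpha(t) ** 2 * prior.unwhiten_transpose(extra)
        return score

    h = 1.0 / settings.n_steps
    for k, t in enumerate(grid):
        beta = float(schedule.beta(t))
        score = whitened_score(z, t)
        if not np.all(np.isfinite(score)):
            raise FloatingPointError(f"non-finite score at step {k} (t={t:.4f})")
        noise = rng.standard_normal(shape)
        z = z + h * (0.5 * beta * z + beta * lam * score) + np.sqrt(beta * h) * noise
        t_next = max(t - h, grid[-1])
        x = _apply_hard(conditioners, prior.unwhiten(z), t_next)
        z = prior.whiten(x)
        for _ in range(settings.psi):
            score = whitened_score(z, t_next)
            # SNR-adaptive Langevin step: eps ~ (r * ||noise|| / ||score||)^2
            noise = rng.standard_normal(shape)
            s_norm = np.linalg.norm(score) + 1e-12
            n_norm = np.linalg.norm(noise)
            eps = 2.0 * (settings.corrector_snr * n_norm / (lam * s_norm)) ** 2
            z = z + eps * lam * score + np.sqrt(2.0 * eps) * noise
            x = _apply_hard(conditioners, prior.unwhiten(z), t_next)
            z = prior.whiten(x)

    # terminal denoise at the last grid time, then hard constraints at t=0
    t_min = float(grid[-1])
    x0 = denoiser(prior.unwhiten(z), t_min)
    x0 = _apply_hard(conditioners, x0, 0.0)
    return x0


def reverse_sample(prior, schedule: DiffusionSchedule, denoiser,
                   settings: SamplerSettings, n_residues: int,
                   conditioners: Sequence | None = None):
    """Sample one backbone structure by reverse diffusion over the CA trace.

    Conditioners may change the problem size (e.g. symmetry tessellation); the
    prior is rebuilt at the expanded size in that case by the caller — here the
    conditioners' ``setup`` hooks are honoured.
    """
    from .geometry import structure_from_ca

    n_total = n_residues
    for cond in conditioners or []:
        n_total = cond.setup(n_total)
    if n_total != prior.n_residues:
        if isinstance(prior, PolymerPrior):
            prior = PolymerPrior(n_total, prior.r0, prior.nu, prior.centroid_sigma)
        elif isinstance(prior, IdentityPrior):
            prior = IdentityPrior(n_total)
        else:
            raise ValueError("prior size does not match the conditioned problem size")
    ca = reverse_sample_array(prior, schedule, denoiser, settings,
                              (n_total, 3), conditioners)
    structure = structure_from_ca(ca)
    for cond in conditioners or []:
        structure = cond.finalize_structure(structure)
    return structure
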
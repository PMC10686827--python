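"""Correlated Gaussian polymer prior over CA coordinates.

The prior encodes two biophysical facts about collapsed polymers:

* **chain correlation** — neighbouring residues move together, captured by a
  discrete random-walk (cumulative-sum) covariance structure; and
* **radius-of-gyration scaling** — globular chains obey Rg ≈ r0 · N^nu, with
  r0 ~ 2 Å and nu ~ 0.4 for natural single-domain proteins.

Construction: per spatial dimension, coordinates are x = delta * P L z + s_c 1 z_1,
where L is the cumulative-sum (random walk) operator, P removes the centroid,
z is i.i.d. standard normal, and the first latent coordinate z_1 drives an
independent global-translation mode of standard deviation ``centroid_sigma``.
The walk step delta is chosen per length from the closed form
E[Rg^2]_walk = delta^2 (N^2-1)/(6N) per dimension so that the full 3D prior
satisfies E[Rg^2] = r0^2 N^(2 nu) exactly in expectation.

The latent map is exactly invertible in O(N): cumulative sums forward,
first differences backward.  When centroid_sigma = 0 the centroid direction is
outside the modeled subspace (whiten maps it to zero), mirroring the fact that
a free-floating polymer's absolute position carries no information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PolymerPrior:
    """Chain- and Rg-constrained Gaussian prior over (n_residues, 3) CA coords."""

    n_residues: int
    r0: float = 2.0
    nu: float = 0.4
    centroid_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if not 0.0 < self.nu < 1.0:
            raise ValueError("nu must lie in (0, 1)")
        if self.centroid_sigma < 0:
            raise ValueError("centroid_sigma must be >= 0")

    # -- derived constants -----------------------------------------------------

    @property
    def delta(self) -> float:
        """Random-walk step amplitude enforcing E[Rg^2] = r0^2 N^(2 nu) in 3D."""
        n = self.n_residues
        if n == 1:
            return 0.0
        return self.r0 * n**self.nu * np.sqrt(2.0 * n / (n**2 - 1.0))

    @property
    def mean_sq_rg(self) -> float:
        """Closed-form E[Rg^2] (3D) under the prior."""
        if self.n_residues == 1:
            return 0.0
        return self.r0**2 * float(self.n_residues) ** (2 * self.nu)

    # -- linear maps -----------------------------------------------------------

    def _check(self, arr: np.ndarray) -> np.ndarray:
        arr = np.asarray(arr, dtype=float)
        if arr.ndim < 2 or arr.shape[-2] != self.n_residues:
            raise ValueError(
                f"expected (..., {self.n_residues}, d) array, got shape {arr.shape}"
            )
        return arr

    def unwhiten(self, z: np.ndarray) -> np.ndarray:
        """Map i.i.d. standard-normal latents to prior-covariance coordinates.

        Acts independently on each trailing column (spatial dimension) and
        broadcasts over leading batch axes.
        """
        z = self._check(z)
        # the centered walk is invariant to z_1 (a constant shift of every
        # partial sum); dropping it explicitly keeps the map well conditioned
        # even when the centroid mode makes z_1 large
        zw = z.copy()
        zw[..., 0:1, :] = 0.0
        walk = np.cumsum(zw, axis=-2) * self.delta
        walk = walk - walk.mean(axis=-2, keepdims=True)
        if self.centroid_sigma > 0:
            walk = walk + self.centroid_sigma * z[..., 0:1, :]
        return walk

    def whiten(self, x: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`unwhiten` (minimum-norm on the modeled subspace)."""
        x = self._check(x)
        mean = x.mean(axis=-2, keepdims=True)
        xc = x - mean
        if self.n_residues == 1:
            z = np.zeros_like(x)
            if self.centroid_sigma > 0:
                z = mean / self.centroid_sigma
            return z
        y = xc / self.delta if self.delta > 0 else np.zeros_like(xc)
        z = np.empty_like(y)
        # the centered walk is invariant to z_1 (a constant added to every
        # partial sum), so z_1 is free to carry the centroid mode
        z[..., 0:1, :] = 0.0
        z[..., 1:, :] = np.diff(y, axis=-2)
        if self.centroid_sigma > 0:
            z[..., 0:1, :] = mean / self.centroid_sigma
        return z

    def unwhiten_transpose(self, v: np.ndarray) -> np.ndarray:
        """Adjoint R^T of the unwhitening map (needed to push coordinate-space
        energy gradients into the whitened latent)."""
        v = self._check(v)
        vc = v - v.mean(axis=-2, keepdims=True)
        # adjoint of cumsum is reversed cumsum; row 0 is excluded from the
        # walk in the forward map, so it receives no walk contribution
        out = np.flip(np.cumsum(np.flip(vc, axis=-2), axis=-2), axis=-2) * self.delta
        out = out.copy()
        out[..., 0:1, :] = 0.0
        if self.centroid_sigma > 0:
            out[..., 0:1, :] += self.centroid_sigma * v.sum(axis=-2, keepdims=True)
        return out

    def covariance(self) -> np.ndarray:
        """Dense per-dimension covariance matrix R R^T (for small N only)."""
        n = self.n_residues
        eye = np.eye(n)
        # row k of the result is R e_k, i.e. the k-th column of R
        r_t = self.unwhiten(eye[..., None])[..., 0]
        return r_t.T @ r_t

    def solve_covariance(self, v: np.ndarray) -> np.ndarray:
        """Apply the covariance pseudo-inverse C^+ = R^{+T} R^{+} to (..., n, d)."""
        return self.whiten_transpose(self.whiten(v))

    def whiten_transpose(self, v: np.ndarray) -> np.ndarray:
        """Adjoint of :meth:`whiten` (the map (R^+)^T)."""
        v = self._check(v)
        if self.n_residues == 1:
            if self.centroid_sigma > 0:
                return v / self.centroid_sigma
            return np.zeros_like(v)
        # whiten = D ∘ scale ∘ center (+ centroid row); adjoint in reverse order
        w = np.zeros_like(v)
        # adjoint of z[1:] = diff(y): y_adj = -diff_adjoint
        y_adj = np.zeros_like(v)
        y_adj[..., 1:, :] += v[..., 1:, :]
        y_adj[..., :-1, :] -= v[..., 1:, :]
        y_adj = y_adj / self.delta if self.delta > 0 else np.zeros_like(y_adj)
        y_adj = y_adj - y_adj.mean(axis=-2, keepdims=True)
        w += y_adj
        if self.centroid_sigma > 0:
            w = w + v[..., 0:1, :] / (self.centroid_sigma * self.n_residues)
        return w

    # -- sampling --------------------------------------------------------------

    def sample(self, n_samples: int, seed: int | np.random.Generator = 0) -> np.ndarray:
        """Draw (n_samples, n_residues, 3) CA coordinate samples."""
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        z = rng.standard_normal((n_samples, self.n_residues, 3))
        return self.unwhiten(z)


def build_prior(n_residues: int, r0: float = 2.0, nu: float = 0.4,
                centroid_sigma: float = 0.0) -> PolymerPrior:
    """Construct the chain/Rg-constrained polymer prior (see module docstring)."""
    return PolymerPrior(n_residues, r0, nu, centroid_sigma)


def sample_prior(prior: PolymerPrior, n_samples: int, seed: int = 0) -> np.ndarray:
    """Seeded prior samples, shape (n_samples, n_residues, 3)."""
    return prior.sample(n_samples, seed)


class IdentityPrior:
    """Trivial prior with identity covariance — used for closed-form Gaussian
    toys where the polymer structure is irrelevant."""

    def __init__(self, n_residues: int):
        self.n_residues = n_residues
        self.centroid_sigma = 1.0

    def unwhiten(self, z):
        return np.asarray(z, dtype=float)

    def whiten(self, x):
        return np.asarray(x, dtype=float)

    def unwhiten_transpose(self, v):
        return np.asarray(v, dtype=float)

    def whiten_transpose(self, v):
        return np.asarray(v, dtype=float)

    def solve_covariance(self, v):
        return np.asarray(v, dtype=float)

    def sample(self, n_samples, seed=0):
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        return rng.standard_normal((n_samples, self.n_residues, 3))
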
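"""Composable conditioning primitives for the reverse diffusion process.

A :class:`Conditioner` can contribute, per reverse step, a *hard transform*
(an idempotent map applied to the coordinates after every update — exact
constraints) and/or a *soft score contribution* (the gradient of a log-density
term added to the model score before every update — penalties and guidance).
Conditioners compose: hard transforms apply in list order, energies add.

Built-ins: symmetry tessellation (exact Cn/Dn/T/O/I assemblies), registered
substructure clamping (replacement infilling/outfilling), harmonic
inter-residue distance restraints, entropic-OT shape guidance against a point
cloud, and generic classifier guidance with a toy helix-content classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .structures import BackboneStructure, PointCloudShape, CHAIN_ALPHABET
from .symmetry import SymmetryGroup
from . import ot

Array = np.ndarray


@dataclass
class Conditioner:
    """A composable conditioning unit.

    Parameters
    ----------
    name : identifier used in run manifests.
    hard_fn : optional idempotent coordinate map (coords, t) -> coords.
    energy_fn : optional (coords, t) -> (energy, grad) pair; its *negative*
        gradient enters the score.
    guidance_fn : optional (coords, t) -> (log_prob, grad); its gradient enters
        the score with a positive sign (classifier guidance).
    setup_fn : optional problem-size hook n -> n_total (e.g. tessellation).
    params : free-form parameter record for the manifest.
    """

    name: str
    hard_fn: Callable[[Array, float], Array] | None = None
    energy_fn: Callable[[Array, float], tuple[float, Array]] | None = None
    guidance_fn: Callable[[Array, float], tuple[float, Array]] | None = None
    setup_fn: Callable[[int], int] | None = None
    finalize_fn: Callable[[BackboneStructure], BackboneStructure] | None = None
    params: dict = field(default_factory=dict)

    @property
    def has_hard_transform(self) -> bool:
        return self.hard_fn is not None

    def hard_transform(self, coords: Array, t: float) -> Array:
        if self.hard_fn is None:
            return coords
        return self.hard_fn(coords, t)

    def energy(self, coords: Array, t: float = 0.0) -> float:
        if self.energy_fn is None:
            return 0.0
        val, _ = self.energy_fn(coords, t)
        if not np.isfinite(val):
            raise FloatingPointError(f"conditioner {self.name}: non-finite energy")
        return float(val)

    def energy_gradient(self, coords: Array, t: float = 0.0) -> Array:
        if self.energy_fn is None:
            return np.zeros_like(coords)
        _, grad = self.energy_fn(coords, t)
        return grad

    def score_contribution(self, coords: Array, t: float) -> Array | None:
        """-grad(energy) + grad(log classifier), or None if purely hard."""
        total = None
        if self.energy_fn is not None:
            _, grad = self.energy_fn(coords, t)
            total = -grad
        if self.guidance_fn is not None:
            logp, grad = self.guidance_fn(coords, t)
            if not np.isfinite(logp):
                raise FloatingPointError(f"conditioner {self.name}: non-finite log-prob")
            total = grad if total is None else total + grad
        return total

    def setup(self, n_residues: int) -> int:
        return self.setup_fn(n_residues) if self.setup_fn else n_residues

    def finalize_structure(self, structure: BackboneStructure) -> BackboneStructure:
        return self.finalize_fn(structure) if self.finalize_fn else structure


# ---------------------------------------------------------------------------
# symmetry


def make_symmetry_conditioner(group: SymmetryGroup, soft_weight: float = 0.0
                              ) -> Conditioner:
    """Tessellate an asymmetric unit through every group element.

    The hard transform orbit-averages the complex — each subunit is pulled
    back through its group element, the estimates are averaged, and the
    average is re-tessellated — which is the orthogonal projection onto the
    G-invariant subspace.  Applied to a bare asymmetric unit (n residues) the
    transform expands it to order x n residues.  A soft variant (quadratic
    symmetry-deviation energy with weight ``soft_weight``) is also available.
    """
    mats = group.matrices
    order = group.order
    state: dict = {"n_au": None}

    def setup(n_residues: int) -> int:
        state["n_au"] = n_residues
        return n_residues * order

    def expand(au: Array) -> Array:
        return np.einsum("gij,nj->gni", mats, au).reshape(order * au.shape[0], 3)

    def symmetrize(coords: Array, t: float) -> Array:
        coords = np.asarray(coords, dtype=float)
        n = coords.shape[0]
        n_au = state["n_au"]
        if n_au is None:
            # infer: a complex if the size divides the order, else a bare AU
            n_au = n // order if n % order == 0 else n
        if n == n_au and (n_au * order != n):
            return expand(coords)
        if n == n_au * order:
            blocks = coords.reshape(order, n_au, 3)
            # pull each subunit back through its group element and average:
            # this is the orthogonal projection onto the G-invariant subspace
            au = np.einsum("gji,gnj->ni", mats, blocks) / order
            return expand(au)
        raise ValueError(
            f"symmetry conditioner: got {n} residues, expected an asymmetric "
            f"unit of {n_au} or a complex of {n_au * order}")

    def energy(coords: Array, t: float) -> tuple[float, Array]:
        sym = symmetrize(coords, t)
        if sym.shape != coords.shape:
            return 0.0, np.zeros_like(coords)
        diff = coords - sym
        # projection residual: grad of 0.5*w*||(I-P)x||^2 is w*(I-P)x
        return 0.5 * soft_weight * float((diff**2).sum()), soft_weight * diff

    def finalize(structure: BackboneStructure) -> BackboneStructure:
        """Relabel chains so each symmetry copy gets fresh chain ids."""
        n = structure.n_residues
        n_au = state["n_au"] or n // order
        if n != n_au * order:
            return structure
        au_chains = structure.chain_ids[:n_au]
        uniq = list(dict.fromkeys(au_chains))
        chain_ids = structure.chain_ids.copy()
        for g in range(order):
            for ci, cid in enumerate(uniq):
                new_id = CHAIN_ALPHABET[(g * len(uniq) + ci) % len(CHAIN_ALPHABET)]
                block = slice(g * n_au, (g + 1) * n_au)
                mask = au_chains == cid
                sel = np.zeros(n, dtype=bool)
                sel[block] = mask
                chain_ids[sel] = new_id
        res_ids = np.tile(structure.res_ids[:n_au], order)
        return BackboneStructure(structure.coords, chain_ids, res_ids)

    return Conditioner(
        name=f"symmetry:{group.name}",
        hard_fn=symmetrize,
        energy_fn=energy if soft_weight > 0 else None,
        setup_fn=setup,
        finalize_fn=finalize,
        params={"group": group.name, "order": order, "soft_weight": soft_weight},
    )


def tessellate(structure: BackboneStructure, group: SymmetryGroup
               ) -> BackboneStructure:
    """Replicate a structure's asymmetric unit through every group element.

    Convenience wrapper for one-shot assembly building: returns a complex with
    ``group.order`` subunits, chains relabelled per copy.
    """
    cond = make_symmetry_conditioner(group)
    n_au = structure.n_residues
    cond.setup(n_au)
    full_ca = cond.hard_transform(structure.ca, 0.0)
    # rigidly move each residue copy (keeps N/C/O consistent with rotation)
    order = group.order
    coords = np.einsum("gij,naj->gnai", group.matrices, structure.coords)
    coords = coords.reshape(order * n_au, 4, 3)
    out = BackboneStructure(coords, np.tile(structure.chain_ids, order),
                            np.tile(structure.res_ids, order))
    out = cond.finalize_structure(out)
    # consistency: the CA trace must agree with the hard transform
    assert np.allclose(out.ca, full_ca, atol=1e-8)
    return out


def symmetry_deviation(structure_or_ca, group: SymmetryGroup) -> float:
    """Max atom deviation when acting with each g in G and matching subunits."""
    ca = structure_or_ca.ca if hasattr(structure_or_ca, "ca") else np.asarray(structure_or_ca)
    order = group.order
    n = ca.shape[0]
    if n % order != 0:
        raise ValueError("structure size is not a multiple of the group order")
    n_au = n // order
    blocks = ca.reshape(order, n_au, 3)
    worst = 0.0
    for g in range(order):
        moved = blocks @ group.matrices[g].T  # g acting on every subunit
        # subunit k (built with element e_k) maps to the subunit built with g*e_k
        perm = group.table[g]
        dev = np.abs(moved - blocks[perm]).max()
        worst = max(worst, float(dev))
    return worst


# ---------------------------------------------------------------------------
# registered substructure (replacement infilling)


def make_substructure_conditioner(reference: BackboneStructure | Array,
                                  clamp_mask: Array, prior, schedule,
                                  noise_seed: int = 0) -> Conditioner:
    """Clamp masked residues to a reference via replacement conditioning.

    At each reverse step the clamped residues are overwritten with the
    reference CA coordinates noised to the current time t by the forward
    marginal.  The noise draw is a deterministic function of (t, noise_seed),
    which makes the transform idempotent at fixed t; at t=0 the clamped
    residues equal the reference exactly.
    """
    ref_ca = reference.ca if hasattr(reference, "ca") else np.asarray(reference, float)
    mask = np.asarray(clamp_mask, dtype=bool)
    if mask.shape[0] != ref_ca.shape[0]:
        raise ValueError("clamp mask length must match the reference length")
    if mask.sum() < 1:
        # empty mask: no-op conditioner (sampling proceeds unconditionally)
        return Conditioner(name="substructure:empty", params={"n_clamped": 0})

    from .diffusion import forward_marginal
    from .prior import PolymerPrior

    if isinstance(prior, PolymerPrior) and prior.n_residues != ref_ca.shape[0]:
        prior = PolymerPrior(ref_ca.shape[0], prior.r0, prior.nu, prior.centroid_sigma)

    def clamp(coords: Array, t: float) -> Array:
        coords = np.asarray(coords, dtype=float)
        if coords.shape[0] < mask.shape[0]:
            raise ValueError("clamp mask longer than the sampled structure")
        if t == 0.0:
            noised = ref_ca
        else:
            # derive the per-time noise stream deterministically: same t, same noise
            t_key = int(round(t * 1_000_000)) & 0x7FFFFFFF
            rng = np.random.default_rng((noise_seed << 1) ^ t_key)
            noised = forward_marginal(prior, schedule, ref_ca, t, rng)
        out = coords.copy()
        idx = np.where(mask)[0]
        out[idx] = noised[idx]
        return out

    return Conditioner(
        name="substructure",
        hard_fn=clamp,
        params={"n_clamped": int(mask.sum()), "noise_seed": noise_seed},
    )


# ---------------------------------------------------------------------------
# distance restraints


def make_distance_conditioner(pairs: Sequence[tuple[int, int]],
                              targets: Sequence[float],
                              force_constant: float = 1.0) -> Conditioner:
    """Harmonic restraints on CA-CA distances: U = sum k (d_ij - d0)^2 / 2."""
    pairs_arr = np.asarray(pairs, dtype=int).reshape(-1, 2)
    targets_arr = np.asarray(targets, dtype=float).reshape(-1)
    if pairs_arr.shape[0] != targets_arr.shape[0]:
        raise ValueError("pairs and targets must have equal length")
    if np.any(pairs_arr[:, 0] == pairs_arr[:, 1]):
        raise ValueError("distance restraint pairs must reference distinct residues")
    if np.any(targets_arr <= 0):
        raise ValueError("target distances must be positive")

    def energy(coords: Array, t: float) -> tuple[float, Array]:
        # broadcasts over leading batch axes: coords is (..., n, 3)
        coords = np.asarray(coords, dtype=float)
        i, j = pairs_arr[:, 0], pairs_arr[:, 1]
        dvec = coords[..., i, :] - coords[..., j, :]
        dist = np.linalg.norm(dvec, axis=-1)
        resid = dist - targets_arr
        val = 0.5 * force_constant * float((resid**2).sum())
        grad = np.zeros_like(coords)
        unit = dvec / np.maximum(dist, 1e-12)[..., None]
        contrib = force_constant * resid[..., None] * unit
        for p in range(pairs_arr.shape[0]):
            grad[..., i[p], :] += contrib[..., p, :]
            grad[..., j[p], :] -= contrib[..., p, :]
        return val, grad

    return Conditioner(
        name="distance",
        energy_fn=energy,
        params={"n_pairs": int(pairs_arr.shape[0]), "force_constant": force_constant},
    )


# ---------------------------------------------------------------------------
# shape guidance (entropic optimal transport)


def make_shape_conditioner(point_cloud: PointCloudShape | Array,
                           epsilon: float = 1.0, weight: float = 1.0,
                           max_iters: int = 500, tol: float = 1e-6
                           ) -> Conditioner:
    """Soft shape energy: entropic-OT cost between CA coordinates and a cloud."""
    pts = point_cloud.points if isinstance(point_cloud, PointCloudShape) \
        else np.asarray(point_cloud, float)
    if pts.shape[0] < 1:
        raise ValueError("point cloud must be non-empty")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")

    def energy(coords: Array, t: float) -> tuple[float, Array]:
        val, grad, _ = ot.sinkhorn_divergence(np.asarray(coords, float), pts,
                                              epsilon, max_iters=max_iters,
                                              tol=tol)
        return weight * val, weight * grad

    return Conditioner(
        name="shape",
        energy_fn=energy,
        params={"n_points": int(pts.shape[0]), "epsilon": epsilon, "weight": weight},
    )


# ---------------------------------------------------------------------------
# classifier guidance


def make_classifier_conditioner(log_prob_fn: Callable[[Array, float], tuple[float, Array]],
                                guidance_scale: float = 1.0) -> Conditioner:
    """Generic classifier guidance: adds scale * grad log p(c | x, t) to the score.

    ``log_prob_fn`` must return (log_prob, gradient) for CA coordinates.
    """

    def guidance(coords: Array, t: float) -> tuple[float, Array]:
        logp, grad = log_prob_fn(coords, t)
        return guidance_scale * logp, guidance_scale * np.asarray(grad, float)

    cond = Conditioner(
        name="classifier",
        guidance_fn=guidance if guidance_scale != 0 else None,
        params={"guidance_scale": guidance_scale},
    )
    return cond


def helix_content_log_prob(coords: Array, t: float = 0.0,
                           target_dist: float = 6.2, width: float = 0.8
                           ) -> tuple[float, Array]:
    """Toy helix-content classifier: soft count of i,i+4 CA distances near
    the ideal helical value (~6.2 Å).  Returns (log_prob, gradient)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 5:
        return 0.0, np.zeros_like(coords)
    i = np.arange(n - 4)
    dvec = coords[i + 4] - coords[i]
    dist = np.linalg.norm(dvec, axis=-1)
    z = (dist - target_dist) / width
    scores = np.exp(-0.5 * z**2)
    logp = float(scores.sum() / (n - 4))
    grad = np.zeros_like(coords)
    coef = (scores * (-z / width) / (n - 4))[:, None]
    unit = dvec / np.maximum(dist, 1e-12)[:, None]
    np.add.at(grad, i + 4, coef * unit)
    np.add.at(grad, i, -coef * unit)
    return logp, grad


# ---------------------------------------------------------------------------
# composition


def compose(conditioner_list: Sequence[Conditioner]) -> Conditioner:
    """Compose conditioners: hard transforms in list order, energies summed."""
    conds = list(conditioner_list)

    def hard(coords: Array, t: float) -> Array:
        for c in conds:
            if c.has_hard_transform:
                coords = c.hard_transform(coords, t)
        return coords

    def energy(coords: Array, t: float) -> tuple[float, Array]:
        total_v, total_g = 0.0, np.zeros_like(np.asarray(coords, float))
        for c in conds:
            if c.energy_fn is not None:
                v, g = c.energy_fn(coords, t)
                total_v += v
                total_g = total_g + g
        return total_v, total_g

    def guidance(coords: Array, t: float) -> tuple[float, Array]:
        total_v, total_g = 0.0, np.zeros_like(np.asarray(coords, float))
        for c in conds:
            if c.guidance_fn is not None:
                v, g = c.guidance_fn(coords, t)
                total_v += v
                total_g = total_g + g
        return total_v, total_g

    def setup(n: int) -> int:
        for c in conds:
            n = c.setup(n)
        return n

    def finalize(structure: BackboneStructure) -> BackboneStructure:
        for c in conds:
            structure = c.finalize_structure(structure)
        return structure

    any_hard = any(c.hard_fn is not None for c in conds)
    any_energy = any(c.energy_fn is not None for c in conds)
    any_guidance = any(c.guidance_fn is not None for c in conds)
    return Conditioner(
        name="compose[" + ",".join(c.name for c in conds) + "]",
        hard_fn=hard if any_hard else None,
        energy_fn=energy if any_energy else None,
        guidance_fn=guidance if any_guidance else None,
        setup_fn=setup if any(c.setup_fn for c in conds) else None,
        finalize_fn=finalize if any(c.finalize_fn for c in conds) else None,
        params={"members": [c.name for c in conds]},
    )
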
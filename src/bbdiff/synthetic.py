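"""Idealized synthetic backbones: helices, strands, hairpins and coils.

These generators provide reproducible desk-scale training and test fixtures.
They emulate the coarse geometry of real secondary structure (CA-CA virtual
bond of ~3.8 Å, helical rise/twist, strand pleating) but are not meant to be
physically relaxed backbones: there are no hydrogen bonds, no side chains and
no Ramachandran statistics.  All outputs are single conformations, exactly
reproducible from their seed.
"""

from __future__ import annotations

import numpy as np

from .geometry import backbone_from_ca
from .structures import BackboneStructure

# ideal helix parameterization: textbook alpha-helix dimensions
HELIX_RISE = 1.5  # Å per residue along the axis
HELIX_TWIST = np.deg2rad(100.0)  # per residue
HELIX_RADIUS = 2.3  # Å, CA helix radius

# idealized strand: ~3.8 Å virtual bond with alternating pleat
STRAND_RISE = 3.35
STRAND_PLEAT = 0.9

CA_CLASH_CUTOFF = 2.0  # Å, hard lower bound for non-bonded CA pairs


def _finalize(ca: np.ndarray, jitter: float, rng: np.random.Generator | None
              ) -> BackboneStructure:
    if jitter > 0:
        if rng is None:
            raise ValueError("jitter requires a seed")
        ca = ca + jitter * rng.standard_normal(ca.shape)
    n = ca.shape[0]
    return BackboneStructure(
        backbone_from_ca(ca), np.full(n, "A"), np.arange(1, n + 1)
    )


def helix_ca(n_residues: int, phase: float = 0.0) -> np.ndarray:
    """CA trace of an ideal alpha-helix along +z."""
    i = np.arange(n_residues)
    ang = phase + HELIX_TWIST * i
    return np.stack(
        [HELIX_RADIUS * np.cos(ang), HELIX_RADIUS * np.sin(ang), HELIX_RISE * i], axis=-1
    )


def strand_ca(n_residues: int) -> np.ndarray:
    """CA trace of an idealized (pleated, extended) beta-strand along +x."""
    i = np.arange(n_residues)
    return np.stack(
        [STRAND_RISE * i, STRAND_PLEAT * (-1.0) ** i, np.zeros(n_residues)], axis=-1
    )


def make_ideal_helix(n_residues: int, seed: int | None = None,
                     jitter: float = 0.0) -> BackboneStructure:
    """An ideal alpha-helical backbone, optionally with small Gaussian jitter."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed) if seed is not None else None
    return _finalize(helix_ca(n_residues), jitter, rng)


def make_ideal_strand(n_residues: int, seed: int | None = None,
                      jitter: float = 0.0) -> BackboneStructure:
    """An idealized extended beta-strand."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed) if seed is not None else None
    return _finalize(strand_ca(n_residues), jitter, rng)


def make_hairpin(n_residues: int, seed: int | None = None,
                 jitter: float = 0.0) -> BackboneStructure:
    """A beta-hairpin: two antiparallel strands joined by a tight turn."""
    if n_residues < 6:
        raise ValueError("a hairpin needs at least 6 residues")
    rng = np.random.default_rng(seed) if seed is not None else None
    n_turn = 4
    n_arm = (n_residues - n_turn) // 2
    n_arm2 = n_residues - n_turn - n_arm
    up = strand_ca(n_arm)
    # semicircular turn connecting strand ends, then the return strand
    sep = 4.8  # inter-strand separation
    start = up[-1]
    turn_angles = np.linspace(0, np.pi, n_turn + 2)[1:-1]
    r = sep / 2.0
    turn = np.stack(
        [start[0] + 2.0 * np.sin(turn_angles),
         start[1] + r - r * np.cos(turn_angles),
         np.full(n_turn, start[2])], axis=-1)
    down = strand_ca(n_arm2)[::-1].copy()
    down[:, 1] = -down[:, 1] + start[1] + sep
    down[:, 0] += start[0] - down[-1, 0] + 0.0
    # align the return strand to continue from the turn exit
    down = down - down[0] + turn[-1] + np.array([-STRAND_RISE, 0.3, 0.0])
    ca = np.concatenate([up, turn, down], axis=0)
    return _finalize(ca, jitter, rng)


def make_random_coil(n_residues: int, seed: int = 0) -> BackboneStructure:
    """A self-avoiding random coil with 3.8 Å virtual bonds."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    ca = _self_avoiding_walk(n_residues, rng)
    return _finalize(ca, 0.0, None)


def _self_avoiding_walk(n: int, rng: np.random.Generator,
                        min_dist: float = 4.0, bond: float = 3.8) -> np.ndarray:
    """Random CA walk with bend angles in a coil-like range and clash rejection."""
    pts = [np.zeros(3)]
    d = np.array([1.0, 0.0, 0.0])
    attempts = 0
    while len(pts) < n:
        # bend angle 65-130 deg (coil-like, clearly non-extended), uniform
        # azimuth around the previous direction
        theta = np.deg2rad(rng.uniform(65, 130))
        phi = rng.uniform(0, 2 * np.pi)
        # build orthonormal basis around d
        a = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        e1 = np.cross(d, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        nd = (np.cos(theta) * d
              + np.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2))
        cand = pts[-1] + bond * nd
        prev = np.asarray(pts[:-1]) if len(pts) > 1 else None
        if prev is None or len(prev) == 0 or \
                np.min(np.linalg.norm(prev - cand, axis=1)) >= min_dist:
            pts.append(cand)
            d = nd
            attempts = 0
        else:
            attempts += 1
            if attempts > 200:
                # dead end: back up a few steps and retry
                drop = min(5, len(pts) - 1)
                del pts[-drop:]
                if not pts:
                    pts = [np.zeros(3)]
                d = np.array([1.0, 0.0, 0.0])
                attempts = 0
    return np.asarray(pts)


_PRIMITIVES = ("helix", "strand", "hairpin", "coil")


def _segment_ca(kind: str, length: int, rng: np.random.Generator) -> np.ndarray:
    if kind == "helix":
        return helix_ca(length, phase=rng.uniform(0, 2 * np.pi))
    if kind == "strand":
        return strand_ca(length)
    if kind == "hairpin":
        length = max(length, 8)
        up = strand_ca(length // 2)
        rest = length - length // 2
        down = strand_ca(rest)[::-1].copy()
        down[:, 1] += 4.8
        down = down - down[0] + up[-1] + np.array([0.5, 4.8, 0.0])
        return np.concatenate([up, down])
    if kind == "coil":
        return _self_avoiding_walk(length, rng)
    raise ValueError(f"unknown primitive {kind!r}")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()


def _min_nonbonded(ca: np.ndarray) -> float:
    from scipy.spatial.distance import pdist, squareform

    n = ca.shape[0]
    if n < 3:
        return np.inf
    dm = squareform(pdist(ca))
    mask = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) >= 2
    return float(dm[mask].min())


def make_synthetic_set(n_structures: int, length_range: tuple[int, int],
                       composition: dict[str, float] | None = None,
                       seed: int = 0) -> list[BackboneStructure]:
    """A reproducible set of synthetic backbones mixing generator primitives.

    Each structure is a sequence of secondary-structure segments (drawn from
    ``composition`` over helix/strand/hairpin/coil) joined by short loops,
    placed with random rigid motions and re-drawn until no non-bonded CA pair
    comes closer than 2 Å.

    Parameters
    ----------
    n_structures : number of structures (0 gives an empty list).
    length_range : (min_len, max_len) inclusive residue counts.
    composition : weights over {"helix", "strand", "hairpin", "coil"}; they
        are normalized internally.  Default favours helices over strands
        roughly as in natural single-domain proteins.
    seed : master seed; the set is byte-identical for identical seeds.
    """
    if n_structures < 0:
        raise ValueError("n_structures must be >= 0")
    if not length_range or len(length_range) != 2 or length_range[0] > length_range[1]:
        raise ValueError("length_range must be (min_len, max_len) with min <= max")
    if length_range[0] < 1:
        raise ValueError("length_range must be positive")
    if composition is None:
        composition = {"helix": 0.45, "strand": 0.2, "hairpin": 0.15, "coil": 0.2}
    kinds = [k for k in _PRIMITIVES if composition.get(k, 0) > 0]
    weights = np.array([composition[k] for k in kinds], dtype=float)
    if not kinds or not np.isclose(weights.sum(), 1.0, atol=1e-6):
        raise ValueError("composition weights must cover the primitives and sum to 1")
    weights = weights / weights.sum()

    rng = np.random.default_rng(seed)
    out: list[BackboneStructure] = []
    for _ in range(n_structures):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        for _attempt in range(100):
            ca = _compose_chain(length, kinds, weights, rng)
            if _min_nonbonded(ca) >= CA_CLASH_CUTOFF:
                break
        else:  # pragma: no cover - extremely unlikely at these densities
            raise RuntimeError("could not place a clash-free structure")
        out.append(BackboneStructure(
            backbone_from_ca(ca), np.full(length, "A"), np.arange(1, length + 1)))
    return out


def _compose_chain(length: int, kinds, weights, rng: np.random.Generator) -> np.ndarray:
    """Concatenate randomly oriented segments, re-drawing clashing placements."""
    ca = np.zeros((0, 3))
    while ca.shape[0] < length:
        remaining = length - ca.shape[0]
        if remaining <= 6:
            seg_len = remaining
            kind = "coil"
        else:
            seg_len = int(min(remaining, rng.integers(8, 21)))
            kind = kinds[rng.choice(len(kinds), p=weights)]
        placed = None
        for _ in range(60):
            seg = _segment_ca(kind, seg_len, rng)[:remaining]
            seg = (seg - seg[0]) @ _random_rotation(rng).T
            if ca.shape[0] == 0:
                placed = seg
                break
            # attach via a fresh bond direction from the current terminus
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            cand = seg + ca[-1] + 3.8 * direction
            if cand.shape[0] == 0:
                placed = cand
                break
            # clash check: the junction residue may sit near the terminus it
            # bonds to, every later residue must clear the whole chain
            ok = True
            if ca.shape[0] > 1:
                d0 = ((ca[:-1] - cand[0]) ** 2).sum(-1).min()
                ok = d0 >= (CA_CLASH_CUTOFF + 0.5) ** 2
            if ok and cand.shape[0] > 1:
                d1 = (((ca[:, None, :] - cand[None, 1:, :]) ** 2).sum(-1)).min()
                ok = d1 >= (CA_CLASH_CUTOFF + 0.5) ** 2
            if ok:
                placed = cand
                break
        if placed is None:
            # dead end: drop the last segment worth of residues and retry
            ca = ca[: max(ca.shape[0] - 12, 0)]
            continue
        ca = np.concatenate([ca, placed]) if ca.shape[0] else placed
    return ca[:length]
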
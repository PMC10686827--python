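"""Structural statistics of backbone samples and superposition utilities.

All metrics operate on the CA trace and are invariant under global rigid
motions.  Contacts default to CA-CA <= 8 Å at sequence separation >= 3;
secondary structure is assigned from CA-trace distances (no hydrogen-bond
geometry is available for pure backbone samples), calibrated against the
idealized generators in :mod:`bbdiff.synthetic`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structures import BackboneStructure

CONTACT_CUTOFF = 8.0  # Å
CONTACT_MIN_SEP = 3
LONG_RANGE_SEP = 12


@dataclass(frozen=True)
class StructureStats:
    """Per-structure summary statistics."""

    n_residues: int
    radius_of_gyration: float
    relative_contact_order: float
    contact_density: float
    long_range_contact_fraction: float
    helix_fraction: float
    strand_fraction: float
    coil_fraction: float

    def as_dict(self) -> dict:
        return asdict(self)


def _ca(structure_or_ca) -> np.ndarray:
    if hasattr(structure_or_ca, "ca"):
        return structure_or_ca.ca
    return np.atleast_2d(np.asarray(structure_or_ca, dtype=float))


def radius_of_gyration(structure_or_ca) -> float:
    """Root-mean-square CA distance from the CA centroid (Å)."""
    ca = _ca(structure_or_ca)
    centered = ca - ca.mean(axis=0)
    return float(np.sqrt((centered**2).sum(axis=1).mean()))


def _contact_pairs(ca: np.ndarray, cutoff: float, min_separation: int
                   ) -> np.ndarray:
    n = ca.shape[0]
    if n < 2:
        return np.zeros((0, 2), dtype=int)
    dm = squareform(pdist(ca))
    i, j = np.triu_indices(n, k=min_separation)
    mask = dm[i, j] <= cutoff
    return np.stack([i[mask], j[mask]], axis=1)


def contact_order(structure_or_ca, cutoff: float = CONTACT_CUTOFF,
                  min_separation: int = CONTACT_MIN_SEP) -> float:
    """Relative contact order: mean |i-j| over contacts, divided by length.

    Returns 0 when the structure has no contacts at the given cutoff.
    """
    ca = _ca(structure_or_ca)
    n = ca.shape[0]
    if n < 2:
        raise ValueError("contact order needs at least 2 residues")
    pairs = _contact_pairs(ca, cutoff, min_separation)
    if pairs.shape[0] == 0:
        return 0.0
    seps = np.abs(pairs[:, 1] - pairs[:, 0])
    return float(seps.sum() / (n * pairs.shape[0]))


def contact_density(structure_or_ca, cutoff: float = CONTACT_CUTOFF,
                    min_separation: int = CONTACT_MIN_SEP) -> float:
    """Contacts per residue."""
    ca = _ca(structure_or_ca)
    pairs = _contact_pairs(ca, cutoff, min_separation)
    return float(pairs.shape[0] / ca.shape[0])


def long_range_contact_fraction(structure_or_ca, cutoff: float = CONTACT_CUTOFF,
                                min_separation: int = CONTACT_MIN_SEP,
                                long_sep: int = LONG_RANGE_SEP) -> float:
    """Fraction of contacts with sequence separation >= ``long_sep``."""
    ca = _ca(structure_or_ca)
    pairs = _contact_pairs(ca, cutoff, min_separation)
    if pairs.shape[0] == 0:
        return 0.0
    seps = np.abs(pairs[:, 1] - pairs[:, 0])
    return float((seps >= long_sep).mean())


def assign_secondary_structure(structure_or_ca) -> np.ndarray:
    """Per-residue H/E/C labels from CA-trace geometry.

    A residue is helical when the local i,i+3 and i,i+4 CA distances sit in the
    alpha-helical window; extended (strand) when consecutive i,i+2 distances
    are near-maximal.  Calls require a 5-residue context; short termini fall
    back to coil.  Deterministic.
    """
    ca = _ca(structure_or_ca)
    n = ca.shape[0]
    labels = np.full(n, "C", dtype="U1")
    if n < 5:
        return labels
    d = lambda k: np.linalg.norm(ca[k:] - ca[:-k], axis=1)  # noqa: E731
    d2, d3, d4 = d(2), d(3), d(4)
    # alpha helix: d(i,i+2) ~ 5.4, d(i,i+3) ~ 5.1, d(i,i+4) ~ 6.2 Å
    helix_window = ((d2[: n - 4] > 4.9) & (d2[: n - 4] < 6.0)
                    & (d3[: n - 4] > 4.4) & (d3[: n - 4] < 5.8)
                    & (d4 > 5.5) & (d4 < 6.9))
    # extended strand: two consecutive near-maximal i,i+2 spans (~6.7 Å)
    strand_window = (d2 > 6.5) & (d2 < 7.3)
    strand_run = strand_window[: n - 3] & strand_window[1 : n - 2]
    for i in np.where(helix_window)[0]:
        labels[i : i + 5] = "H"
    for i in np.where(strand_run)[0]:
        if np.all(labels[i : i + 4] == "C"):
            labels[i : i + 4] = "E"
    return labels


def ss_fractions(structure_or_ca) -> tuple[float, float, float]:
    """(helix, strand, coil) fractions; they sum to 1."""
    labels = assign_secondary_structure(structure_or_ca)
    n = labels.size
    h = float((labels == "H").mean()) if n else 0.0
    e = float((labels == "E").mean()) if n else 0.0
    return h, e, 1.0 - h - e


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray,
                return_transform: bool = False):
    """Optimal rigid-superposition RMSD (reflections excluded).

    Uses the SVD form of the Kabsch algorithm; ``coords_b`` is superposed onto
    ``coords_a``.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must both have shape (n, 3)")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = bc.T @ ac
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, 1.0, d])
    rot = u @ corr @ vt
    moved = bc @ rot
    rmsd = float(np.sqrt(((moved - ac) ** 2).sum(axis=1).mean()))
    if return_transform:
        return rmsd, rot, a.mean(axis=0) - b.mean(axis=0) @ rot
    return rmsd


def structure_stats(structure: BackboneStructure) -> StructureStats:
    """Compute the full statistics record for one structure."""
    h, e, c = ss_fractions(structure)
    return StructureStats(
        n_residues=structure.n_residues,
        radius_of_gyration=radius_of_gyration(structure),
        relative_contact_order=contact_order(structure) if structure.n_residues > 1 else 0.0,
        contact_density=contact_density(structure),
        long_range_contact_fraction=long_range_contact_fraction(structure),
        helix_fraction=h,
        strand_fraction=e,
        coil_fraction=c,
    )
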
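"""Residue local frames and idealized backbone reconstruction.

Local frames follow the standard backbone convention: origin at CA, rotation
built by Gram–Schmidt from the C-CA and N-CA directions.  The same convention
(applied to an idealized backbone rebuilt from the CA trace) is used whenever
only CA coordinates are available, e.g. on noisy intermediate states of the
diffusion, so that every stage of the pipeline shares one frame definition.
"""

from __future__ import annotations

import numpy as np

from .structures import ATOM_NAMES, BackboneStructure

# idealized peptide placement constants (Å / degrees)
_N_CA = 1.46
_CA_C = 1.52
_HALF_ANGLE = np.deg2rad(55.5)  # half of the ~111 deg N-CA-C angle


class DegenerateFrameError(ValueError):
    """Raised when N/CA/C are collinear and no frame can be built."""


def _normalize(v: np.ndarray, axis: int = -1) -> np.ndarray:
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    return v / np.maximum(n, 1e-12)


def residue_frames(structure: BackboneStructure) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue frames from N/CA/C.

    Returns
    -------
    origins : (n, 3) CA positions
    rotations : (n, 3, 3) right-handed orthonormal matrices whose columns are
        the frame axes expressed in global coordinates.
    """
    n_xyz = structure.coords[:, 0, :]
    ca = structure.coords[:, 1, :]
    c_xyz = structure.coords[:, 2, :]
    return frames_from_nca(n_xyz, ca, c_xyz)


def frames_from_nca(n_xyz: np.ndarray, ca: np.ndarray, c_xyz: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Gram–Schmidt frames from explicit N/CA/C coordinate arrays."""
    e1 = c_xyz - ca
    norm1 = np.linalg.norm(e1, axis=-1)
    if np.any(norm1 < 1e-8):
        bad = int(np.argmin(norm1))
        raise DegenerateFrameError(f"residue {bad}: C and CA coincide")
    e1 = e1 / norm1[:, None]
    v = n_xyz - ca
    v = v - (v * e1).sum(-1, keepdims=True) * e1
    norm2 = np.linalg.norm(v, axis=-1)
    if np.any(norm2 < 1e-8):
        bad = int(np.argmin(norm2))
        raise DegenerateFrameError(f"residue {bad}: N, CA, C are collinear")
    e2 = v / norm2[:, None]
    e3 = np.cross(e1, e2)
    rot = np.stack([e1, e2, e3], axis=-1)  # columns are axes
    return ca.copy(), rot


def backbone_from_ca(ca: np.ndarray) -> np.ndarray:
    """Rebuild idealized N/CA/C/O backbone coordinates from a CA trace.

    The construction is deterministic and SE(3)-equivariant: each residue's
    atoms are placed in a local frame spanned by the directions to its chain
    neighbours, with the N-CA-C angle fixed at ~111° so that frames are never
    degenerate even on a perfectly straight trace.

    Parameters
    ----------
    ca : (n, 3) CA coordinates.

    Returns
    -------
    coords : (n, 4, 3) backbone coordinates ordered N, CA, C, O.
    """
    ca = np.asarray(ca, dtype=float)
    n = ca.shape[0]
    coords = np.empty((n, 4, 3))
    coords[:, 1, :] = ca
    if n == 1:
        # isolated residue: arbitrary but fixed orientation
        e1, e2 = np.array([1.0, 0, 0]), np.array([0, 1.0, 0])
        s, c = np.sin(_HALF_ANGLE), np.cos(_HALF_ANGLE)
        coords[0, 0] = ca[0] + _N_CA * (-s * e1 + c * e2)
        coords[0, 2] = ca[0] + _CA_C * (s * e1 + c * e2)
        coords[0, 3] = coords[0, 2] + 1.23 * e2
        return coords

    prev = np.empty_like(ca)
    nxt = np.empty_like(ca)
    prev[1:] = ca[:-1]
    nxt[:-1] = ca[1:]
    # virtual neighbours at the termini: step back along the adjacent bond so
    # the local basis stays non-degenerate and equivariant (for n=2 the chain
    # is a single bond and the fixed fallback directions below apply)
    if n >= 3:
        prev[0] = ca[0] - (ca[2] - ca[1])
        nxt[-1] = ca[-1] + (ca[-2] - ca[-3])
    else:
        prev[0] = 2 * ca[0] - ca[1]
        nxt[-1] = 2 * ca[-1] - ca[-2]

    u = _normalize(prev - ca)  # toward previous residue
    v = _normalize(nxt - ca)  # toward next residue
    e1 = v - u
    e1n = np.linalg.norm(e1, axis=-1, keepdims=True)
    # if prev and next coincide directionally, fall back to a fixed direction
    fallback = np.tile(np.array([1.0, 0, 0]), (n, 1))
    e1 = np.where(e1n > 1e-8, e1 / np.maximum(e1n, 1e-12), fallback)
    b = -(u + v)  # exterior bisector
    b = b - (b * e1).sum(-1, keepdims=True) * e1
    bn = np.linalg.norm(b, axis=-1, keepdims=True)
    # straight segment: pick any direction orthogonal to e1, consistently
    alt = np.cross(e1, np.where(np.abs(e1[:, [0]]) < 0.9,
                                np.array([1.0, 0, 0]), np.array([0, 1.0, 0])))
    alt = _normalize(alt)
    e2 = np.where(bn > 1e-8, b / np.maximum(bn, 1e-12), alt)

    s, c = np.sin(_HALF_ANGLE), np.cos(_HALF_ANGLE)
    coords[:, 0] = ca + _N_CA * (-s * e1 + c * e2)  # N leans toward prev
    coords[:, 2] = ca + _CA_C * (s * e1 + c * e2)  # C leans toward next
    # carbonyl O: off the C atom, away from CA, tilted out of the N-CA-C plane
    e3 = np.cross(e1, e2)
    coords[:, 3] = coords[:, 2] + 1.23 * _normalize(c * e1 - s * e2 + 0.4 * e3)
    return coords


def structure_from_ca(ca: np.ndarray, chain_ids=None, res_ids=None) -> BackboneStructure:
    """Wrap a CA trace into a full BackboneStructure with idealized N/C/O."""
    ca = np.asarray(ca, dtype=float)
    n = ca.shape[0]
    if chain_ids is None:
        chain_ids = np.full(n, "A")
    if res_ids is None:
        res_ids = np.arange(1, n + 1)
    return BackboneStructure(backbone_from_ca(ca), np.asarray(chain_ids), np.asarray(res_ids))


def ca_frames(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Frames derived from a bare CA trace via the idealized backbone."""
    coords = backbone_from_ca(np.asarray(ca, dtype=float))
    return frames_from_nca(coords[:, 0], coords[:, 1], coords[:, 2])


def random_rigid_motion(rng: np.random.Generator, translation_scale: float = 10.0
                        ) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random rotation matrix and a Gaussian translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_matrix()
    trans = translation_scale * rng.standard_normal(3)
    return rot, trans


def apply_rigid(coords: np.ndarray, rot: np.ndarray, trans: np.ndarray) -> np.ndarray:
    """Apply x -> R x + b over the last axis of any (..., 3) array."""
    return coords @ rot.T + trans
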
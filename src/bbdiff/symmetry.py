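"""Finite rotation point groups used for symmetric-assembly conditioning.

Supported groups: cyclic Cn (order n), dihedral Dn (order 2n), tetrahedral T
(12), octahedral O (24) and icosahedral I (60).  Rotation sets come from
scipy's exact point-group constructors; closure and group order are verified
numerically at construction time rather than trusted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

_ORDERS = {"T": 12, "O": 24, "I": 60}


@dataclass(frozen=True)
class SymmetryGroup:
    """A finite rotation group: name, (order, 3, 3) matrices, multiplication table."""

    name: str
    matrices: np.ndarray
    table: np.ndarray  # table[a, b] = index of matrices[a] @ matrices[b]

    @property
    def order(self) -> int:
        return self.matrices.shape[0]

    def __post_init__(self) -> None:
        mats = self.matrices
        if mats.ndim != 3 or mats.shape[1:] != (3, 3):
            raise ValueError("matrices must have shape (order, 3, 3)")
        eye = np.eye(3)
        for i, m in enumerate(mats):
            if not np.allclose(m @ m.T, eye, atol=1e-8) or np.linalg.det(m) < 0:
                raise ValueError(f"element {i} is not a proper rotation")


def _match_element(mats: np.ndarray, target: np.ndarray) -> int:
    devs = np.abs(mats - target).max(axis=(1, 2))
    idx = int(np.argmin(devs))
    if devs[idx] > 1e-8:
        raise ValueError("rotation set is not closed under composition")
    return idx


def _closure_table(mats: np.ndarray) -> np.ndarray:
    order = mats.shape[0]
    table = np.empty((order, order), dtype=int)
    for a in range(order):
        for b in range(order):
            table[a, b] = _match_element(mats, mats[a] @ mats[b])
    return table


def make_symmetry_group(name: str) -> SymmetryGroup:
    """Build a verified rotation group from its Schoenflies name (C4, D3, T, O, I)."""
    name = name.strip()
    m = re.fullmatch(r"([CD])(\d+)|([TOI])", name, flags=re.IGNORECASE)
    if not m:
        raise ValueError(f"unknown symmetry group {name!r} (expected Cn, Dn, T, O or I)")
    if m.group(3):
        label = m.group(3).upper()
        mats = Rotation.create_group(label).as_matrix()
        expected = _ORDERS[label]
    else:
        family, n = m.group(1).upper(), int(m.group(2))
        if n < 1:
            raise ValueError("group index must be >= 1")
        mats = Rotation.create_group(f"{family}{n}").as_matrix()
        expected = n if family == "C" else 2 * n
    if mats.shape[0] != expected:
        raise ValueError(f"group {name}: got {mats.shape[0]} elements, expected {expected}")
    # canonical ordering: identity first
    dev_from_eye = np.abs(mats - np.eye(3)).max(axis=(1, 2))
    order_idx = np.argsort(dev_from_eye, kind="stable")
    if dev_from_eye[order_idx[0]] > 1e-10:
        raise ValueError(f"group {name}: identity element missing")
    mats = mats[order_idx]
    return SymmetryGroup(name.upper() if name[0] in "cdCD" else name.upper(),
                         mats, _closure_table(mats))
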
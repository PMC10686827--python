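"""Backbone data model and PDB input/output.

A :class:`BackboneStructure` holds an ordered list of residues, each with the
four backbone heavy atoms (N, CA, C, O) and a chain label.  All coordinates
are in Ångström.  Residues are numbered 1-based within each chain and chain
labels partition the residue list into contiguous blocks.  Sequence design is
out of scope, so every residue is written as glycine.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

ATOM_NAMES = ("N", "CA", "C", "O")

#: chain label alphabet used when relabelling copies (62 single-char ids)
CHAIN_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be interpreted as a backbone structure."""


@dataclass
class BackboneStructure:
    """Ordered backbone residues with per-residue N/CA/C/O coordinates.

    Parameters
    ----------
    coords : ndarray, shape (n_residues, 4, 3)
        Coordinates in Å, atom axis ordered N, CA, C, O.
    chain_ids : ndarray of str, shape (n_residues,)
        Chain label per residue; labels must form contiguous blocks.
    res_ids : ndarray of int, shape (n_residues,)
        1-based residue index within each chain.
    """

    coords: np.ndarray
    chain_ids: np.ndarray
    res_ids: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        n = self.coords.shape[0]
        if n < 1:
            raise ValueError("structure must contain at least one residue")
        if self.coords.shape != (n, 4, 3):
            raise ValueError(f"coords must have shape (n, 4, 3), got {self.coords.shape}")
        if self.chain_ids.shape != (n,) or self.res_ids.shape != (n,):
            raise ValueError("chain_ids and res_ids must match the residue count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite backbone coordinate")
        # chain labels must be contiguous blocks
        seen: set[str] = set()
        prev = None
        for cid in self.chain_ids:
            if cid != prev:
                if cid in seen:
                    raise ValueError(f"chain {cid!r} appears in non-contiguous blocks")
                seen.add(cid)
                prev = cid

    # -- convenience accessors -------------------------------------------------

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    @property
    def ca(self) -> np.ndarray:
        """CA coordinates, shape (n_residues, 3)."""
        return self.coords[:, 1, :]

    @property
    def chains(self) -> list[str]:
        """Chain labels in order of first appearance."""
        out: list[str] = []
        for cid in self.chain_ids:
            if not out or out[-1] != cid:
                out.append(str(cid))
        return out

    def chain_slices(self) -> dict[str, slice]:
        """Map chain label -> residue slice (contiguous by invariant)."""
        out: dict[str, slice] = {}
        start = 0
        for i in range(1, self.n_residues + 1):
            if i == self.n_residues or self.chain_ids[i] != self.chain_ids[start]:
                out[str(self.chain_ids[start])] = slice(start, i)
                start = i
        return out

    def with_ca(self, ca: np.ndarray) -> "BackboneStructure":
        """Return a copy whose residues are rigidly moved so CA matches ``ca``."""
        ca = np.asarray(ca, dtype=float)
        if ca.shape != (self.n_residues, 3):
            raise ValueError("CA array shape mismatch")
        shift = ca - self.ca
        return BackboneStructure(
            self.coords + shift[:, None, :], self.chain_ids.copy(), self.res_ids.copy()
        )

    def copy(self) -> "BackboneStructure":
        return BackboneStructure(
            self.coords.copy(), self.chain_ids.copy(), self.res_ids.copy()
        )


@dataclass
class PointCloudShape:
    """A target shape given as a bag of 3D points (Å)."""

    points: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 1 or self.points.shape[1] != 3:
            raise ValueError("point cloud must contain at least one x y z point")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite point in point cloud")

    @classmethod
    def from_file(cls, path) -> "PointCloudShape":
        pts = np.loadtxt(path, ndmin=2)
        if pts.shape[1] != 3:
            raise ValueError(f"{path}: expected 3 columns (x y z), got {pts.shape[1]}")
        return cls(pts)


def from_residues(residues) -> BackboneStructure:
    """Build a structure from an iterable of (chain_id, res_id, N, CA, C, O)."""
    chain_ids, res_ids, coords = [], [], []
    for chain_id, res_id, n, ca, c, o in residues:
        chain_ids.append(chain_id)
        res_ids.append(res_id)
        coords.append([n, ca, c, o])
    return BackboneStructure(np.asarray(coords, float), np.asarray(chain_ids), np.asarray(res_ids))


def _rebuild_O(n_xyz: np.ndarray, ca_xyz: np.ndarray, c_xyz: np.ndarray,
               next_n: np.ndarray | None) -> np.ndarray:
    """Place a carbonyl O from N/CA/C (and the next residue's N if available)."""
    if next_n is not None:
        u = c_xyz - ca_xyz
        v = c_xyz - next_n
        d = u / np.linalg.norm(u) + v / np.linalg.norm(v)
    else:
        # terminal residue: put O in the N-CA-C plane, opposite the N-CA direction
        u = c_xyz - ca_xyz
        w = n_xyz - ca_xyz
        d = u / np.linalg.norm(u) - 0.5 * w / np.linalg.norm(w)
    nrm = np.linalg.norm(d)
    if nrm < 1e-9:
        d = np.array([0.0, 0.0, 1.0])
        nrm = 1.0
    return c_xyz + 1.23 * d / nrm


def read_pdb(path) -> BackboneStructure:
    """Read a backbone structure from a PDB file.

    Each residue must provide at least N, CA and C; a missing O is rebuilt from
    ideal peptide geometry.  Non-backbone atoms are ignored.  Residues with
    insertion codes are rejected.
    """
    try:
        pdb_file = bpdb.PDBFile.read(str(path))
        atoms = pdb_file.get_structure(model=1)
    except Exception as exc:  # biotite raises various error types on bad input
        raise PDBParseError(f"{path}: could not parse PDB file: {exc}") from exc
    if atoms.array_length() == 0:
        raise PDBParseError(f"{path}: no ATOM records")
    if np.any(atoms.ins_code != ""):
        raise PDBParseError(f"{path}: insertion codes are not supported")
    mask = np.isin(atoms.atom_name, ATOM_NAMES) & ~atoms.hetero
    atoms = atoms[mask]
    if atoms.array_length() == 0:
        raise PDBParseError(f"{path}: no backbone ATOM records")

    residues = []
    starts = bst.get_residue_starts(atoms, add_exclusive_stop=True)
    for s, e in zip(starts[:-1], starts[1:]):
        res = atoms[s:e]
        chain_id = str(res.chain_id[0])
        res_id = int(res.res_id[0])
        pos: dict[str, np.ndarray] = {}
        for name in ATOM_NAMES:
            hit = res.coord[res.atom_name == name]
            if len(hit):
                pos[name] = hit[0].astype(float)
        for name in ("N", "CA", "C"):
            if name not in pos:
                raise PDBParseError(
                    f"{path}: residue {chain_id}:{res_id} is missing backbone atom {name}"
                )
        residues.append((chain_id, res_id, pos))

    coords = np.empty((len(residues), 4, 3))
    chain_ids = np.empty(len(residues), dtype="U4")
    res_ids = np.empty(len(residues), dtype=int)
    for i, (chain_id, res_id, pos) in enumerate(residues):
        if "O" not in pos:
            next_n = None
            if i + 1 < len(residues) and residues[i + 1][0] == chain_id:
                next_n = residues[i + 1][2]["N"]
            pos["O"] = _rebuild_O(pos["N"], pos["CA"], pos["C"], next_n)
        coords[i] = [pos[n] for n in ATOM_NAMES]
        chain_ids[i] = chain_id
        res_ids[i] = res_id
    return BackboneStructure(coords, chain_ids, res_ids)


def write_pdb(structure: BackboneStructure, path) -> None:
    """Write ATOM records (3-decimal coordinates), TER between chains, END.

    All residues are written as GLY.  Coordinates whose magnitude exceeds the
    fixed-width PDB field (|x| > 9999.999) raise a ValueError.
    """
    if not np.all(np.isfinite(structure.coords)):
        raise ValueError("non-finite coordinate")
    if np.any(np.abs(structure.coords) > 9999.999):
        raise ValueError("coordinate exceeds PDB fixed-width field (|x| > 9999.999 Å)")
    elements = ("N", "C", "C", "O")
    lines: list[str] = []
    serial = 1
    for i in range(structure.n_residues):
        cid = str(structure.chain_ids[i])[:1] or "A"
        rid = int(structure.res_ids[i])
        for name, elem, xyz in zip(ATOM_NAMES, elements, structure.coords[i]):
            lines.append(
                f"ATOM  {serial % 100000:5d} {name:^4s} GLY {cid}{rid % 10000:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {elem:>2s}  "
            )
            serial += 1
        last_in_chain = (i == structure.n_residues - 1
                         or structure.chain_ids[i + 1] != structure.chain_ids[i])
        if last_in_chain:
            lines.append(f"TER   {serial % 100000:5d}      GLY {cid}{rid % 10000:4d}")
            serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
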
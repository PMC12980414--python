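"""Coordinate containers and PDB input/output.

A :class:`MolecularStructure` holds one conformation as flat per-atom
arrays in ångström units.  It is the common currency of the whole
pipeline: the native reference used to parameterize the structure-based
force field, every frame produced by the simulator, and every model
scored against a scattering curve.

PDB parsing and writing are delegated to :mod:`biotite`; this module
only adds validation, chain extraction and the pipeline's conventions
(heavy atoms by default, first altloc, waters and ligands dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as bts
from biotite.structure.io.pdb import PDBFile


class StructureError(ValueError):
    """Raised for unreadable or inconsistent coordinate input."""


_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O", "TIP", "TIP3"}


@dataclass
class MolecularStructure:
    """One conformation: per-atom records plus Cartesian coordinates (Å)."""

    serial: np.ndarray      # (n,) int
    name: np.ndarray        # (n,) str, atom names e.g. "CA"
    element: np.ndarray     # (n,) str, e.g. "C"
    res_index: np.ndarray   # (n,) int, 1-based residue numbers
    res_name: np.ndarray    # (n,) str
    chain_id: np.ndarray    # (n,) str
    coord: np.ndarray       # (n, 3) float, Å
    title: str = ""

    def __post_init__(self) -> None:
        self.serial = np.asarray(self.serial, dtype=np.int64)
        self.name = np.asarray(self.name, dtype="U6")
        self.element = np.asarray(self.element, dtype="U2")
        self.res_index = np.asarray(self.res_index, dtype=np.int64)
        self.res_name = np.asarray(self.res_name, dtype="U5")
        self.chain_id = np.asarray(self.chain_id, dtype="U4")
        self.coord = np.asarray(self.coord, dtype=np.float64)
        if self.coord.ndim != 2 or self.coord.shape[1] != 3:
            raise StructureError("coord must have shape (n_atoms, 3)")

    # -- basic queries -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return int(self.coord.shape[0])

    def chains(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_id:
            seen.setdefault(str(c), None)
        return list(seen)

    def residue_ids(self) -> np.ndarray:
        """Sorted unique residue numbers."""
        return np.unique(self.res_index)

    def validate(self) -> None:
        """Check the container invariants; raise StructureError on failure."""
        if self.n_atoms == 0:
            raise StructureError("structure contains no atoms")
        if not np.all(np.isfinite(self.coord)):
            raise StructureError("non-finite coordinates")
        if len(np.unique(self.serial)) != self.n_atoms:
            raise StructureError("atom serial numbers are not unique")
        for n in (self.serial, self.name, self.element, self.res_index,
                  self.res_name, self.chain_id):
            if len(n) != self.n_atoms:
                raise StructureError("per-atom arrays have inconsistent length")
        # residues must form contiguous, non-decreasing blocks per chain
        for cid in self.chains():
            res = self.res_index[self.chain_id == cid]
            if np.any(np.diff(res) < 0):
                raise StructureError(
                    f"residue numbers not non-decreasing in chain {cid!r}")

    def copy(self) -> "MolecularStructure":
        return MolecularStructure(
            self.serial.copy(), self.name.copy(), self.element.copy(),
            self.res_index.copy(), self.res_name.copy(), self.chain_id.copy(),
            self.coord.copy(), self.title)

    def with_coord(self, coord: np.ndarray) -> "MolecularStructure":
        """Same topology, new coordinates (used for trajectory frames)."""
        coord = np.asarray(coord, dtype=np.float64)
        if coord.shape != self.coord.shape:
            raise StructureError("replacement coordinates have wrong shape")
        return replace(self, coord=coord)

    def subset(self, mask: np.ndarray) -> "MolecularStructure":
        mask = np.asarray(mask, dtype=bool)
        return MolecularStructure(
            self.serial[mask], self.name[mask], self.element[mask],
            self.res_index[mask], self.res_name[mask], self.chain_id[mask],
            self.coord[mask], self.title)

    def radius_of_gyration(self, weights: np.ndarray | None = None) -> float:
        w = np.ones(self.n_atoms) if weights is None else np.asarray(weights)
        com = np.average(self.coord, axis=0, weights=w)
        return float(np.sqrt(np.average(
            np.sum((self.coord - com) ** 2, axis=1), weights=w)))


# -- biotite bridge ----------------------------------------------------

def _from_atom_array(arr: bts.AtomArray, title: str = "") -> MolecularStructure:
    n = arr.array_length()
    return MolecularStructure(
        serial=np.arange(1, n + 1),
        name=arr.atom_name.astype("U6"),
        element=arr.element.astype("U2"),
        res_index=arr.res_id.astype(np.int64),
        res_name=arr.res_name.astype("U5"),
        chain_id=arr.chain_id.astype("U4"),
        coord=np.asarray(arr.coord, dtype=np.float64),
        title=title,
    )


def _to_atom_array(s: MolecularStructure) -> bts.AtomArray:
    arr = bts.AtomArray(s.n_atoms)
    arr.coord = np.asarray(s.coord, dtype=np.float32)
    arr.atom_name = s.name
    arr.element = s.element
    arr.res_id = s.res_index
    arr.res_name = s.res_name
    arr.chain_id = s.chain_id
    arr.hetero = np.zeros(s.n_atoms, dtype=bool)
    return arr


def _locate_bad_record(path: str) -> str:
    """Best-effort scan for the first malformed ATOM/HETATM line."""
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith(("ATOM", "HETATM")):
                    try:
                        float(line[30:38]); float(line[38:46]); float(line[46:54])
                    except (ValueError, IndexError):
                        return f" (malformed record at line {lineno})"
    except OSError:
        pass
    return ""


def read_structure(path, model: int = 1, strip_hydrogens: bool = True,
                   keep_het: bool = False) -> MolecularStructure:
    """Read one MODEL of a PDB file.

    Hydrogens are stripped by default (the structure-based model acts on
    heavy atoms); waters and ligand HETATM records are dropped unless
    ``keep_het``; only the first altloc of each atom is kept.
    """
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=model, altloc="first")
    except Exception as exc:  # biotite raises several error types
        raise StructureError(
            f"cannot parse PDB file {path!s}: {exc}{_locate_bad_record(str(path))}"
        ) from exc
    if arr.array_length() == 0:
        raise StructureError(f"no atoms found in {path!s}")
    mask = np.ones(arr.array_length(), dtype=bool)
    if strip_hydrogens:
        mask &= ~np.isin(arr.element, ("H", "D"))
    mask &= ~np.isin(arr.res_name, sorted(_WATER_NAMES))
    if not keep_het:
        mask &= ~arr.hetero
    arr = arr[mask]
    if arr.array_length() == 0:
        raise StructureError(f"no atoms left after filtering in {path!s}")
    s = _from_atom_array(arr, title=str(path))
    s.validate()
    return s


def write_structure(s: MolecularStructure, path) -> None:
    """Write a structure (or call with a list for a multi-model file)."""
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(s))
    pdb.write(str(path))


def write_trajectory_pdb(frames: list[MolecularStructure], path) -> None:
    """Write frames as a multi-model PDB."""
    if not frames:
        raise StructureError("no frames to write")
    stack = bts.stack([_to_atom_array(f) for f in frames])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# -- chain operations --------------------------------------------------

def extract_chain(s: MolecularStructure, chain_id: str) -> MolecularStructure:
    """Return only the atoms of one chain (coordinates untouched)."""
    mask = s.chain_id == chain_id
    if not np.any(mask):
        raise StructureError(
            f"chain {chain_id!r} not present; available chains: {s.chains()}")
    return s.subset(mask)


def merge_structures(parts: list[MolecularStructure],
                     title: str = "") -> MolecularStructure:
    """Concatenate structures (e.g. re-assemble chains); serials renumbered."""
    if not parts:
        raise StructureError("nothing to merge")
    cat = lambda attr: np.concatenate([getattr(p, attr) for p in parts])
    n = sum(p.n_atoms for p in parts)
    return MolecularStructure(
        serial=np.arange(1, n + 1),
        name=cat("name"), element=cat("element"),
        res_index=cat("res_index"), res_name=cat("res_name"),
        chain_id=cat("chain_id"),
        coord=np.concatenate([p.coord for p in parts], axis=0),
        title=title,
    )
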
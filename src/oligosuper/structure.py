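"""Lightweight in-memory model of a protein assembly.

The containers here hold only what rigid superposition needs: chains of
standard amino-acid residues with named heavy atoms, plus any
biological-assembly (BIOMT) operators carried by the source file.
Coordinates are in Angstrom throughout; indexing is 0-based internally,
author residue numbering is kept only for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: three-letter -> one-letter codes for the 20 standard amino acids
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Atom:
    """A single atom: PDB name, element symbol, position in Angstrom."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    serial: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    resname: str
    seqnum: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def get(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.resname, "X")


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        """One-letter sequence in residue order (non-standard residues as X)."""
        return "".join(r.one_letter for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """(N, 3) array of C-alpha positions; residues without CA are skipped."""
        coords = [r.get("CA").coords for r in self.residues if r.get("CA") is not None]
        if not coords:
            return np.empty((0, 3))
        return np.array(coords)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class BiomtOperator:
    """One rigid operator from a REMARK 350 biological-assembly block."""

    rotation: np.ndarray
    translation: np.ndarray
    applies_to: list[str]
    assembly_index: int = 1

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-5) or np.linalg.det(R) < 0:
            raise ValueError("BIOMT rotation must be a proper orthonormal matrix")

    @property
    def is_identity(self) -> bool:
        return bool(
            np.allclose(self.rotation, np.eye(3), atol=1e-6)
            and np.allclose(self.translation, 0.0, atol=1e-6)
        )

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class Assembly:
    """An ordered set of protein chains plus source metadata."""

    chains: list[Chain]
    id: str = ""
    biomt: list[BiomtOperator] = field(default_factory=list)
    title: str = ""

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError(f"{self.id or 'assembly'}: contains no protein chains")
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain identifiers: {ids}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in {self.id or 'assembly'}")

    def subset(self, chain_ids: list[str]) -> "Assembly":
        """Assembly restricted to the given chains, in the given order."""
        return replace(self, chains=[self.chain(cid) for cid in chain_ids])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Assembly":
        """Copy with every atom moved by x -> R x + t."""
        new_chains = []
        for c in self.chains:
            new_res = []
            for r in c.residues:
                new_atoms = [
                    replace(a, coords=rotation @ a.coords + translation)
                    for a in r.atoms
                ]
                new_res.append(replace(r, atoms=new_atoms))
            new_chains.append(replace(c, residues=new_res))
        return replace(self, chains=new_chains)

    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)
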
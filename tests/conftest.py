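"""Shared fixtures: hand-written PDB snippets and synthetic assemblies."""

from __future__ import annotations

import numpy as np
import pytest

from oligosuper import FixtureSpec, make_cyclic_assembly


def pdb_atom_line(serial, name, resname, chain, resnum, x, y, z,
                  occ=1.00, altloc=" ", element=None):
    element = element or name[0]
    name_field = name if len(name) >= 4 else f" {name}"
    return (
        f"ATOM  {serial:5d} {name_field:<4s}{altloc}{resname:>3s} {chain}"
        f"{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def two_residue_pdb() -> str:
    lines = [
        pdb_atom_line(1, "N", "ALA", "A", 1, 11.104, 6.134, -6.504),
        pdb_atom_line(2, "CA", "ALA", "A", 1, 11.639, 6.071, -5.147),
        pdb_atom_line(3, "C", "ALA", "A", 1, 10.800, 6.900, -4.200),
        pdb_atom_line(4, "O", "ALA", "A", 1, 9.600, 7.000, -4.400),
        pdb_atom_line(5, "CB", "ALA", "A", 1, 12.000, 4.700, -4.800),
        pdb_atom_line(6, "N", "GLY", "A", 2, 10.100, 6.600, -3.000),
        pdb_atom_line(7, "CA", "GLY", "A", 2, 9.300, 7.300, -2.000),
        pdb_atom_line(8, "C", "GLY", "A", 2, 8.000, 6.600, -1.600),
        pdb_atom_line(9, "O", "GLY", "A", 2, 7.600, 5.600, -2.200),
        "TER",
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def altloc_pdb() -> str:
    lines = [
        pdb_atom_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0),
        pdb_atom_line(2, "CA", "ALA", "A", 1, 1.0, 0.0, 0.0, occ=0.60, altloc="A"),
        pdb_atom_line(3, "CA", "ALA", "A", 1, 9.0, 9.0, 9.0, occ=0.40, altloc="B"),
        pdb_atom_line(4, "C", "ALA", "A", 1, 2.0, 1.0, 0.0),
        pdb_atom_line(5, "O", "ALA", "A", 1, 2.0, 2.0, 1.0),
        "END",
    ]
    return "\n".join(lines) + "\n"


REMARK_350_C2 = """\
REMARK 350 BIOMOLECULE: 1
REMARK 350 APPLY THE FOLLOWING TO CHAINS: A
REMARK 350   BIOMT1   1  1.000000  0.000000  0.000000        0.00000
REMARK 350   BIOMT2   1  0.000000  1.000000  0.000000        0.00000
REMARK 350   BIOMT3   1  0.000000  0.000000  1.000000        0.00000
REMARK 350   BIOMT1   2 -1.000000  0.000000  0.000000        0.00000
REMARK 350   BIOMT2   2  0.000000 -1.000000  0.000000        0.00000
REMARK 350   BIOMT3   2  0.000000  0.000000  1.000000       10.00000
"""


@pytest.fixture
def biomt_pdb(two_residue_pdb) -> str:
    """Monomer with an identity operator and a 180-degree z rotation."""
    return REMARK_350_C2 + two_residue_pdb


@pytest.fixture
def c3_pair():
    """Unperturbed C3 assembly and a copy whose chain order is rotated."""
    from oligosuper.fixtures import shift_chain_order

    ref = make_cyclic_assembly(FixtureSpec(n_fold=3, protomer_length=30, seed=7))
    tgt = shift_chain_order(ref, 1)
    return ref, tgt


@pytest.fixture
def quasi_c5_pair():
    """Quasi-symmetric C5 pair: a shared irregular ring (per-protomer
    rigid offsets) in two slightly different conformations, with the
    target's chain order rotated by 2."""
    from oligosuper.fixtures import perturb_assembly, shift_chain_order

    ref = make_cyclic_assembly(
        FixtureSpec(n_fold=5, protomer_length=30,
                    rot_perturbation=3.0, trans_perturbation=0.8, seed=11)
    )
    tgt = shift_chain_order(perturb_assembly(ref, 1.0, 0.2, seed=99), 2)
    return ref, tgt


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
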
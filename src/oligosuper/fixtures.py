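"""Programmatic generation of synthetic symmetric assemblies.

Every stage of the superposition pipeline can be exercised without any
external structure: an idealised alpha-helical protomer (rise 1.5 A,
100 degrees per residue, radius 2.3 A, full backbone plus CB) is copied
n times around the z axis at ring radius 15 A to form an exact Cn
assembly.  Optional per-protomer rigid perturbations emulate
quasi-symmetry (identical sequences, distinct conformations), a hinge
bend emulates domain flexibility, and a cyclic shift of the chain order
emulates depositions whose ring starts at a different subunit.
Everything is reproducible bit-for-bit from the spec and its seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np

from .structure import Assembly, Atom, Chain, Residue, THREE_TO_ONE

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

RING_RADIUS = 15.0      # A, protomer centroid distance from the symmetry axis
HELIX_RISE = 1.5        # A per residue
HELIX_TWIST = 100.0     # degrees per residue
HELIX_RADIUS = 2.3      # A


@dataclass(frozen=True)
class FixtureSpec:
    n_fold: int = 3
    protomer_length: int = 30
    rot_perturbation: float = 0.0    # degrees, per-protomer rigid rotation
    trans_perturbation: float = 0.0  # Angstrom, per-protomer rigid shift
    label_shift: int = 0             # cyclic rotation of the chain order
    hinge: tuple[int, int, float] | None = None  # (start, stop, degrees), chain 0
    seed: int = 0


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def _rz(angle_deg: float) -> np.ndarray:
    return _rotation_about_axis(np.array([0.0, 0.0, 1.0]), angle_deg)


def make_protomer(length: int, seed: int = 0) -> Chain:
    """Idealised alpha-helical protomer with N/CA/C/O (+CB except Gly).

    The C-alpha trace follows a standard helix parametrisation, giving
    consecutive CA-CA distances of ~3.8 A; the remaining backbone atoms
    are placed in the local helix frame with realistic bond lengths.  The
    sequence is drawn deterministically from the seed.
    """
    if length < 5:
        raise ValueError("protomer needs at least 5 residues")
    rng = random.Random(seed)
    letters = sorted(ONE_TO_THREE)
    sequence = "".join(rng.choice(letters) for _ in range(length))

    t = np.radians(HELIX_TWIST) * np.arange(length)
    ca = np.column_stack([
        HELIX_RADIUS * np.cos(t),
        HELIX_RADIUS * np.sin(t),
        HELIX_RISE * np.arange(length),
    ])
    residues = []
    for i, letter in enumerate(sequence):
        prev_i, next_i = max(i - 1, 0), min(i + 1, length - 1)
        tang = ca[next_i] - ca[prev_i]
        tang = tang / np.linalg.norm(tang)
        radial = ca[i] - np.array([0.0, 0.0, ca[i][2]])
        radial = radial / np.linalg.norm(radial)
        binorm = np.cross(tang, radial)

        def _unit(v: np.ndarray) -> np.ndarray:
            return v / np.linalg.norm(v)

        pos = {
            "N": ca[i] + 1.46 * _unit(-tang - 0.4 * radial),
            "CA": ca[i],
            "C": ca[i] + 1.52 * _unit(tang - 0.4 * radial),
        }
        pos["O"] = pos["C"] + 1.23 * _unit(radial + 0.4 * binorm)
        atoms = [
            Atom("N", "N", pos["N"]),
            Atom("CA", "C", pos["CA"]),
            Atom("C", "C", pos["C"]),
            Atom("O", "O", pos["O"]),
        ]
        if letter != "G":
            atoms.append(Atom("CB", "C", ca[i] + 1.53 * _unit(radial - 0.6 * binorm)))
        residues.append(Residue(resname=ONE_TO_THREE[letter], seqnum=i + 1, atoms=atoms))
    return Chain(chain_id="A", residues=residues)


def _transform_chain(chain: Chain, R: np.ndarray, t: np.ndarray, chain_id: str) -> Chain:
    moved = Assembly(chains=[chain], id="tmp").transformed(R, t)
    out = moved.chains[0]
    out.chain_id = chain_id
    return out


def apply_hinge(chain: Chain, start: int, stop: int, angle_deg: float) -> Chain:
    """Rotate residues [start, stop) about an axis through the first
    hinge residue's C-alpha — a two-domain bend for flexibility tests."""
    pivot = chain.residues[start].get("CA").coords
    R = _rotation_about_axis(np.array([0.0, 1.0, 0.0]), angle_deg)
    residues = []
    for k, res in enumerate(chain.residues):
        if start <= k < stop:
            atoms = [
                Atom(a.name, a.element, R @ (a.coords - pivot) + pivot,
                     a.occupancy, a.altloc, a.serial)
                for a in res.atoms
            ]
            residues.append(Residue(res.resname, res.seqnum, res.icode, atoms))
        else:
            residues.append(res)
    return Chain(chain_id=chain.chain_id, residues=residues)


def make_cyclic_assembly(spec: FixtureSpec) -> Assembly:
    """Cn assembly: n protomer copies related by 360/n-degree rotations
    about z, centroids on a ring of radius 15 A.

    Chain k (label A, B, C, ... in ring order) is the protomer rotated by
    k*360/n degrees.  Per-protomer rigid perturbations (fixed magnitude,
    random axis/direction from the seed) break the symmetry; a hinge bend
    on chain 0 creates quasi-symmetry; ``label_shift`` rotates the order
    in which chains are stored, keeping their labels, so the permutation
    search has something to recover.
    """
    n = spec.n_fold
    protomer = make_protomer(spec.protomer_length, spec.seed)
    centroid = protomer.ca_coords().mean(axis=0)
    base = _transform_chain(
        protomer, np.eye(3), np.array([RING_RADIUS, 0.0, 0.0]) - centroid, "A"
    )
    rng = np.random.default_rng(spec.seed)
    labels = [chr(ord("A") + k) for k in range(n)]
    chains = []
    for k in range(n):
        R = _rz(k * 360.0 / n)
        chain = _transform_chain(base, R, np.zeros(3), labels[k])
        if spec.hinge is not None and k == 0:
            chain = apply_hinge(chain, spec.hinge[0], spec.hinge[1], spec.hinge[2])
        if spec.rot_perturbation or spec.trans_perturbation:
            axis = rng.standard_normal(3)
            Rp = _rotation_about_axis(axis, spec.rot_perturbation)
            center = chain.ca_coords().mean(axis=0)
            shift_dir = rng.standard_normal(3)
            shift = spec.trans_perturbation * shift_dir / np.linalg.norm(shift_dir)
            chain = _transform_chain(
                chain, Rp, center - Rp @ center + shift, chain.chain_id
            )
        chains.append(chain)
    k = spec.label_shift % n
    chains = chains[n - k:] + chains[: n - k]
    return Assembly(chains=chains, id=f"C{n}-fixture")


def shift_chain_order(a: Assembly, k: int) -> Assembly:
    """Rotate the order in which chains are stored (last ``k`` first),
    keeping their labels — a relabelled deposition of the same ring."""
    n = len(a.chains)
    k = k % n
    return Assembly(chains=a.chains[n - k:] + a.chains[: n - k], id=a.id,
                    biomt=a.biomt, title=a.title)


def perturb_assembly(a: Assembly, rot_deg: float, trans: float, seed: int) -> Assembly:
    """Apply an independent rigid perturbation (fixed magnitudes, random
    axis/direction) to every chain — a second conformational state of the
    same assembly."""
    rng = np.random.default_rng(seed)
    chains = []
    for chain in a.chains:
        R = _rotation_about_axis(rng.standard_normal(3), rot_deg)
        center = chain.ca_coords().mean(axis=0)
        d = rng.standard_normal(3)
        shift = trans * d / np.linalg.norm(d) if trans else np.zeros(3)
        chains.append(_transform_chain(chain, R, center - R @ center + shift,
                                       chain.chain_id))
    return Assembly(chains=chains, id=a.id, biomt=a.biomt, title=a.title)


# --- side-chain fixtures for symmetric-atom remapping -----------------------

#: idealised side-chain atom offsets (A) in a local residue frame
IDEAL_SIDECHAINS: dict[str, list[tuple[str, tuple[float, float, float]]]] = {
    "ASP": [("CB", (1.5, 0.0, 0.0)), ("CG", (2.3, 1.2, 0.0)),
            ("OD1", (3.5, 1.2, 0.6)), ("OD2", (1.7, 2.2, -0.4))],
    "GLU": [("CB", (1.5, 0.0, 0.0)), ("CG", (2.3, 1.2, 0.0)),
            ("CD", (3.5, 1.4, 0.8)), ("OE1", (4.6, 1.2, 0.3)),
            ("OE2", (3.4, 1.9, 1.9))],
    "LEU": [("CB", (1.5, 0.0, 0.0)), ("CG", (2.3, 1.2, 0.2)),
            ("CD1", (3.7, 0.9, 0.5)), ("CD2", (2.2, 2.2, -0.9))],
    "VAL": [("CB", (1.5, 0.0, 0.0)), ("CG1", (2.3, 1.2, 0.4)),
            ("CG2", (2.2, -1.0, -1.0))],
    "ARG": [("CB", (1.5, 0.0, 0.0)), ("CG", (2.3, 1.2, 0.0)),
            ("CD", (3.7, 1.0, 0.3)), ("NE", (4.5, 2.2, 0.5)),
            ("CZ", (5.8, 2.2, 0.7)), ("NH1", (6.5, 1.1, 0.7)),
            ("NH2", (6.4, 3.4, 0.9))],
    "PHE": [("CB", (1.5, 0.0, 0.0)), ("CG", (2.3, 1.2, 0.0)),
            ("CD1", (3.6, 1.2, 0.4)), ("CD2", (1.8, 2.4, -0.4)),
            ("CE1", (4.3, 2.4, 0.4)), ("CE2", (2.5, 3.6, -0.4)),
            ("CZ", (3.8, 3.6, 0.0))],
    "TYR": [("CB", (1.5, 0.0, 0.0)), ("CG", (2.3, 1.2, 0.0)),
            ("CD1", (3.6, 1.2, 0.4)), ("CD2", (1.8, 2.4, -0.4)),
            ("CE1", (4.3, 2.4, 0.4)), ("CE2", (2.5, 3.6, -0.4)),
            ("CZ", (3.8, 3.6, 0.0)), ("OH", (4.5, 4.8, 0.0))],
}

#: which atom-name pairs of each type are label-swappable
SWAPPABLE = {
    "ARG": [("NH1", "NH2")], "ASP": [("OD1", "OD2")], "GLU": [("OE1", "OE2")],
    "LEU": [("CD1", "CD2")], "PHE": [("CD1", "CD2"), ("CE1", "CE2")],
    "TYR": [("CD1", "CD2"), ("CE1", "CE2")], "VAL": [("CG1", "CG2")],
}


def make_sidechain_chain(
    length: int,
    seed: int = 0,
    noise: float = 0.0,
    flip_fraction: float = 0.0,
    chain_id: str = "A",
) -> Chain:
    """Chain of residues from the symmetric-side-chain types with full
    idealised side chains, spaced along x.

    ``noise`` adds isotropic Gaussian jitter (A) to every atom;
    ``flip_fraction`` swaps the coordinates of the equivalent atom pairs
    in that fraction of residues (labels keep their names, so the swap is
    a pure naming ambiguity for the remapper to resolve).
    """
    rng = np.random.default_rng(seed)
    names = sorted(IDEAL_SIDECHAINS)
    residues = []
    for i in range(length):
        resname = names[rng.integers(len(names))]
        origin = np.array([8.0 * i, 0.0, 0.0])
        R = _rotation_about_axis(rng.standard_normal(3), float(rng.uniform(0, 360)))
        atoms = [
            Atom("N", "N", origin + R @ np.array([-1.2, -0.6, 0.0])),
            Atom("CA", "C", origin),
            Atom("C", "C", origin + R @ np.array([0.9, -1.2, 0.2])),
            Atom("O", "O", origin + R @ np.array([1.1, -2.4, 0.2])),
        ]
        for name, off in IDEAL_SIDECHAINS[resname]:
            atoms.append(Atom(name, name[0], origin + R @ np.array(off)))
        # draw unconditionally so chains built from the same seed share
        # sequence and geometry regardless of noise/flip settings
        jitter = rng.normal(0.0, 1.0, (len(atoms), 3))
        if noise:
            for a, dx in zip(atoms, jitter):
                a.coords = a.coords + noise * dx
        if rng.random() < flip_fraction:
            lookup = {a.name: a for a in atoms}
            for n1, n2 in SWAPPABLE[resname]:
                c1 = lookup[n1].coords.copy()
                lookup[n1].coords = lookup[n2].coords.copy()
                lookup[n2].coords = c1
        residues.append(Residue(resname=resname, seqnum=i + 1, atoms=atoms))
    return Chain(chain_id=chain_id, residues=residues)
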
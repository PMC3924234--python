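"""Rigid-body superposition: atom mapping, least-squares (Kabsch/McLachlan)
fitting, Gaussian-weighted iterative fitting and symmetric side-chain
remapping.

The standard fit solves the classical weighted orthogonal Procrustes
problem by SVD with a determinant correction, so the returned rotation is
always proper.  The weighted fit iterates the same solver with Gaussian
weights ``w_i = exp(-d_i^2 / c)`` so that atoms in the rigid common core
dominate and flexible regions are down-weighted; the "core" is reported as
the atoms deviating by less than 2 Angstrom under the converged transform.

Side chains of Arg, Asp, Glu, Leu, Phe, Tyr and Val carry chemically
equivalent atom pairs whose PDB names are arbitrary (e.g. Asp OD1/OD2);
for heavy-atom superpositions the label swap giving the smaller deviation
is chosen per residue before a final re-fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import NoCorrespondenceError
from .seqalign import AlignmentResult
from .structure import Atom, Chain

#: chemically equivalent atom-name pairs, swapped jointly per residue
SYMMETRIC_SIDECHAIN_PAIRS: dict[str, list[tuple[str, str]]] = {
    "ARG": [("NH1", "NH2")],
    "ASP": [("OD1", "OD2")],
    "GLU": [("OE1", "OE2")],
    "LEU": [("CD1", "CD2")],
    "PHE": [("CD1", "CD2"), ("CE1", "CE2")],
    "TYR": [("CD1", "CD2"), ("CE1", "CE2")],
    "VAL": [("CG1", "CG2")],
}

CORE_CUTOFF = 2.0  # Angstrom; deviation below which an atom counts as core


@dataclass
class RigidTransform:
    """Proper rotation plus translation, applied as x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) <= 0:
            raise ValueError("rotation must be proper orthonormal (det +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.atleast_2d(coords) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class MappedPair:
    """One ref/tgt atom correspondence, with provenance for reporting."""

    ref_chain: str
    tgt_chain: str
    ref_resindex: int
    tgt_resindex: int
    atom_name: str
    ref_atom: Atom
    tgt_atom: Atom
    ref_resname: str = ""
    tgt_resname: str = ""


@dataclass
class AtomMapping:
    pairs: list[MappedPair]
    level: str
    per_chain_counts: list[tuple[str, str, int]] = field(default_factory=list)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        ref = np.array([p.ref_atom.coords for p in self.pairs])
        tgt = np.array([p.tgt_atom.coords for p in self.pairs])
        return ref, tgt

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_atoms: int
    deviations: np.ndarray
    method: str
    mapping: AtomMapping | None = None
    weights: np.ndarray | None = None
    core_count: int | None = None
    core_rmsd: float | None = None
    weighted_rmsd: float | None = None
    n_aligned: int | None = None
    permutation: object | None = None
    converged: bool = True
    warnings: list[str] = field(default_factory=list)


def build_atom_mapping(
    ref_chain: Chain,
    tgt_chain: Chain,
    aln: AlignmentResult,
    level: str = "ca",
) -> AtomMapping:
    """Pair atoms of aligned residues by identical atom name at a selection
    level (``ca``, ``backbone`` or ``heavy``).

    Mismatched residue types contribute only the atom names they share —
    which always includes the backbone.  Hydrogens never map.
    """
    from .structure import BACKBONE_ATOMS

    pairs: list[MappedPair] = []
    for ri, tj in aln.pairs:
        rres, tres = ref_chain.residues[ri], tgt_chain.residues[tj]
        for atom in rres.atoms:
            if atom.is_hydrogen:
                continue
            if level == "ca" and atom.name != "CA":
                continue
            if level == "backbone" and atom.name not in BACKBONE_ATOMS:
                continue
            other = tres.get(atom.name)
            if other is None or other.is_hydrogen:
                continue
            pairs.append(
                MappedPair(
                    ref_chain=ref_chain.chain_id,
                    tgt_chain=tgt_chain.chain_id,
                    ref_resindex=ri,
                    tgt_resindex=tj,
                    atom_name=atom.name,
                    ref_atom=atom,
                    tgt_atom=other,
                    ref_resname=rres.resname,
                    tgt_resname=tres.resname,
                )
            )
    if not pairs:
        raise NoCorrespondenceError(
            f"no mappable atoms between chains {ref_chain.chain_id!r} "
            f"and {tgt_chain.chain_id!r} at level {level!r}"
        )
    counts = [(ref_chain.chain_id, tgt_chain.chain_id, len(pairs))]
    return AtomMapping(pairs=pairs, level=level, per_chain_counts=counts)


def lsq_fit(
    ref: np.ndarray,
    tgt: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of ``tgt`` onto ``ref`` (Kabsch SVD).

    Minimises the (weighted) sum of squared deviations over all proper
    rotations and translations; returns the transform and the resulting
    *unweighted* RMSD over all pairs.  Requires at least 3 pairs spanning
    a non-degenerate geometry.
    """
    ref = np.asarray(ref, dtype=float)
    tgt = np.asarray(tgt, dtype=float)
    if ref.shape != tgt.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (N, 3)")
    n = ref.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 atom pairs to fit, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    wn = w / w.sum()

    mu_ref = wn @ ref
    mu_tgt = wn @ tgt
    A = ref - mu_ref
    B = tgt - mu_tgt
    H = (B * wn[:, None]).T @ A  # covariance, tgt -> ref
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if S[1] + S[2] < 1e-12 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear) geometry: rotation not determined")
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_ref - R @ mu_tgt
    transform = RigidTransform(R, t)
    return transform, rmsd_value(ref, tgt, transform)


def deviations(ref: np.ndarray, tgt: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Per-pair Euclidean deviation of transformed target from reference."""
    return np.linalg.norm(np.atleast_2d(ref) - transform.apply(tgt), axis=1)


def rmsd_value(ref: np.ndarray, tgt: np.ndarray, transform: RigidTransform) -> float:
    d = deviations(ref, tgt, transform)
    return float(np.sqrt(np.mean(d**2)))


def standard_fit(mapping: AtomMapping) -> SuperpositionResult:
    """Plain least-squares superposition over the whole mapping."""
    ref, tgt = mapping.coords()
    transform, r = lsq_fit(ref, tgt)
    dev = deviations(ref, tgt, transform)
    return SuperpositionResult(
        transform=transform,
        rmsd=r,
        n_atoms=len(mapping),
        deviations=dev,
        method="standard",
        mapping=mapping,
    )


def weighted_fit(
    mapping: AtomMapping,
    c: float = 2.0,
    tol: float = 1e-4,
    max_iter: int = 100,
    core_cutoff: float = CORE_CUTOFF,
) -> SuperpositionResult:
    """Gaussian-weighted iterative superposition locating the rigid core.

    Starting from uniform weights, alternately fit and reweight with
    ``w_i = exp(-d_i^2 / c)`` (``c`` in Angstrom^2) until the largest
    weight change drops below ``tol``.  Reports the core (deviation <
    ``core_cutoff``), the RMSD over that core, and the weighted RMSD
    ``sqrt(sum(w d^2)/sum(w))``.
    """
    ref, tgt = mapping.coords()
    n = len(mapping)
    w = np.ones(n)
    transform, _ = lsq_fit(ref, tgt, w)
    converged = False
    for _ in range(max_iter):
        d = deviations(ref, tgt, transform)
        w_new = np.exp(-(d**2) / c)
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            converged = True
            break
        w = w_new
        transform, _ = lsq_fit(ref, tgt, w)
    d = deviations(ref, tgt, transform)
    core = d < core_cutoff
    core_rmsd = float(np.sqrt(np.mean(d[core] ** 2))) if core.any() else float("nan")
    weighted_rmsd = float(np.sqrt(np.sum(w * d**2) / np.sum(w)))
    msgs = [] if converged else ["weighted fit did not converge; returning last iterate"]
    if msgs:
        warnings.warn(msgs[0], stacklevel=2)
    return SuperpositionResult(
        transform=transform,
        rmsd=float(np.sqrt(np.mean(d**2))),
        n_atoms=n,
        deviations=d,
        method="weighted",
        mapping=mapping,
        weights=w,
        core_count=int(core.sum()),
        core_rmsd=core_rmsd,
        weighted_rmsd=weighted_rmsd,
        converged=converged,
        warnings=msgs,
    )


def _residue_groups(mapping: AtomMapping) -> dict[tuple, list[int]]:
    groups: dict[tuple, list[int]] = {}
    for k, p in enumerate(mapping.pairs):
        key = (p.ref_chain, p.ref_resindex, p.tgt_chain, p.tgt_resindex)
        groups.setdefault(key, []).append(k)
    return groups


def remap_symmetric_sidechains(
    mapping: AtomMapping,
    transform: RigidTransform,
) -> tuple[AtomMapping, int]:
    """Resolve symmetric side-chain naming ambiguity under a fixed transform.

    For every mapped residue pair of equal type carrying equivalent atom
    pairs, evaluate swapping the *target* labels (jointly for the ring
    pairs of Phe/Tyr) and keep whichever labelling yields the smaller sum
    of squared deviations.  Returns the updated mapping and the number of
    residues swapped; the caller re-fits afterwards.
    """
    from dataclasses import replace as _replace

    pairs = list(mapping.pairs)
    n_swapped = 0
    for _key, idxs in _residue_groups(mapping).items():
        p0 = pairs[idxs[0]]
        if p0.ref_resname != p0.tgt_resname:
            continue
        name_pairs = SYMMETRIC_SIDECHAIN_PAIRS.get(p0.ref_resname)
        if name_pairs is None:
            continue
        by_name = {pairs[k].atom_name: k for k in idxs}
        if not all(n1 in by_name and n2 in by_name for n1, n2 in name_pairs):
            continue
        cur = swp = 0.0
        for n1, n2 in name_pairs:
            k1, k2 = by_name[n1], by_name[n2]
            r1, r2 = pairs[k1].ref_atom.coords, pairs[k2].ref_atom.coords
            t1 = transform.apply(pairs[k1].tgt_atom.coords)[0]
            t2 = transform.apply(pairs[k2].tgt_atom.coords)[0]
            cur += np.sum((r1 - t1) ** 2) + np.sum((r2 - t2) ** 2)
            swp += np.sum((r1 - t2) ** 2) + np.sum((r2 - t1) ** 2)
        if swp < cur:
            n_swapped += 1
            for n1, n2 in name_pairs:
                k1, k2 = by_name[n1], by_name[n2]
                a1, a2 = pairs[k1].tgt_atom, pairs[k2].tgt_atom
                pairs[k1] = _replace(pairs[k1], tgt_atom=a2)
                pairs[k2] = _replace(pairs[k2], tgt_atom=a1)
    return AtomMapping(pairs=pairs, level=mapping.level,
                       per_chain_counts=mapping.per_chain_counts), n_swapped
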
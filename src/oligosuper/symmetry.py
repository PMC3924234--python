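"""Chain replica detection, spatial reordering and the cyclic
chain-permutation search.

An oligomer with an n-fold rotation axis can have its subunits listed in
any order in the coordinate file, and two depositions of the same ring
often start the ring at different subunits.  Pairing chains naively by
file order then inflates the RMSD.  The remedy implemented here:

1. detect *replicas* — chains whose pairwise sequence identity reaches a
   threshold (default 95%) are assumed related by rotational symmetry;
2. reorder each structure so spatially adjacent chains become consecutive
   (greedy nearest-centroid walk from the first chain);
3. enumerate the n cyclic shifts of the target chain order, superpose the
   whole complex rigidly for each shift, and keep the shift with the
   lowest C-alpha RMSD.

Only the n rotations of the ring are tried — never all n! bijections and
no reflections — which also handles many dihedral assemblies in practice.
The whole complex is fitted as one rigid body per shift, so subunit
interfaces stay intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ChainCountMismatchError, NoCorrespondenceError
from .seqalign import AlignParams, cached_align
from .structure import Assembly, Chain
from .superpose import lsq_fit


@dataclass
class ReplicaGroups:
    """Partition of chain indices into ≥ threshold-identity groups."""

    groups: list[list[int]]
    identity_matrix: np.ndarray
    threshold: float = 0.95

    @property
    def rotational_symmetry_assumed(self) -> bool:
        return any(len(g) >= 2 for g in self.groups)


@dataclass
class ChainPermutation:
    """One cyclic re-pairing of target chains onto reference chains."""

    shift: int
    pairing: list[tuple[str, str]]
    ca_rmsd: float
    admissible: bool = True

    @property
    def n_chains(self) -> int:
        return len(self.pairing)


@dataclass
class PermutationSearch:
    """Outcome of the exhaustive cyclic-shift enumeration."""

    best: ChainPermutation
    evaluated: list[ChainPermutation] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def detect_replica_groups(
    a: Assembly,
    threshold: float = 0.95,
    params: AlignParams = AlignParams(),
) -> ReplicaGroups:
    """Group chains by pairwise sequence identity (single linkage).

    A homo-oligomer yields one group of n; a monomer one group of one.
    Rotational symmetry is assumed as soon as any group has ≥ 2 members.
    """
    n = len(a.chains)
    ident = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            res = cached_align(a.chains[i].sequence, a.chains[j].sequence, params)
            ident[i, j] = ident[j, i] = res.identity
    # single-linkage components over the >= threshold graph (union-find)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if ident[i, j] >= threshold:
                parent[find(i)] = find(j)
    comp: dict[int, list[int]] = {}
    for i in range(n):
        comp.setdefault(find(i), []).append(i)
    groups = sorted(comp.values(), key=lambda g: g[0])
    return ReplicaGroups(groups=groups, identity_matrix=ident, threshold=threshold)


def chain_centroid(c: Chain) -> np.ndarray:
    """Unweighted mean of the chain's C-alpha coordinates."""
    ca = c.ca_coords()
    if ca.shape[0] == 0:
        raise ValueError(f"chain {c.chain_id!r} has no C-alpha atoms")
    return ca.mean(axis=0)


def reorder_by_adjacency(a: Assembly) -> list[int]:
    """Greedy nearest-centroid walk so spatially adjacent chains become
    consecutive.

    Starts from the first chain in file order; repeatedly appends the
    unvisited chain whose centroid is closest to the last appended
    chain's centroid.  Distances within ``tie_tol`` (0.01 A — below any
    genuine centroid asymmetry but above PDB coordinate precision) of the
    minimum count as tied and are broken by file order, so an exactly
    symmetric ring is walked deterministically instead of at the mercy of
    floating-point or format-rounding noise.  Returns chain indices.
    """
    n = len(a.chains)
    if n == 1:
        return [0]
    tie_tol = 1e-2
    centroids = np.array([chain_centroid(c) for c in a.chains])
    order = [0]
    remaining = list(range(1, n))
    while remaining:
        last = centroids[order[-1]]
        dists = np.array([np.linalg.norm(centroids[k] - last) for k in remaining])
        tied = np.nonzero(dists <= dists.min() + tie_tol)[0]
        pick = remaining[min(tied)]  # remaining is ascending -> file order
        order.append(pick)
        remaining.remove(pick)

    # Canonicalise the traversal direction.  A greedy walk may run around
    # the ring either way depending on the start chain's local spacing; a
    # reversed ring can never be matched by cyclic shifts alone.  Both
    # the ring normal (from the centroid polygon in walk order) and the
    # summed chain end-to-end vector are intrinsic and rotate with the
    # structure, so requiring a non-negative scalar product between them
    # gives congruent assemblies the same orientation.
    if n >= 3:
        ring = centroids[order] - centroids[order].mean(axis=0)
        normal = np.sum(np.cross(ring, np.roll(ring, -1, axis=0)), axis=0)
        polarity = np.zeros(3)
        for c in a.chains:
            ca = c.ca_coords()
            if ca.shape[0] >= 2:
                polarity += ca[-1] - ca[0]
        if normal @ polarity < 0:
            order = [order[0]] + order[1:][::-1]
    return order


def cyclic_permutations(order: list) -> list[list]:
    """All n rotations of a chain order; shift k moves the last k elements
    to the front ("clockwise"), shift 0 first."""
    n = len(order)
    return [list(order[n - k:]) + list(order[: n - k]) for k in range(n)]


def _pooled_ca_pairs(
    ref_chains: list[Chain],
    tgt_chains: list[Chain],
    params: AlignParams,
    min_coverage: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Pool aligned C-alpha pairs over all chain pairs of one shift.

    The shift is inadmissible when any chain pair aligns fewer residues
    than ``min_coverage`` of the shorter chain.
    """
    refs, tgts = [], []
    admissible = True
    for rc, tc in zip(ref_chains, tgt_chains):
        res = cached_align(rc.sequence, tc.sequence, params)
        pairs = [
            (rc.residues[i].get("CA"), tc.residues[j].get("CA"))
            for i, j in res.pairs
        ]
        pairs = [(ra, ta) for ra, ta in pairs if ra is not None and ta is not None]
        if len(pairs) < min_coverage * min(len(rc), len(tc)):
            admissible = False
        refs.extend(ra.coords for ra, _ in pairs)
        tgts.extend(ta.coords for _, ta in pairs)
    if not refs:
        return np.empty((0, 3)), np.empty((0, 3)), False
    return np.array(refs), np.array(tgts), admissible


def find_best_permutation(
    ref: Assembly,
    tgt: Assembly,
    reorder: bool = True,
    params: AlignParams = AlignParams(),
    min_coverage: float = 0.5,
) -> PermutationSearch:
    """Search the n cyclic shifts of the target chain order for the one
    minimising the whole-complex standard C-alpha RMSD.

    Each shift pools the per-chain-pair aligned C-alpha atoms and fits the
    complex as a single rigid body.  Shifts where some chain pair covers
    less than ``min_coverage`` of the shorter chain are recorded but not
    eligible to win.  Ties go to the smallest shift; if no shift is
    admissible, the identity pairing is returned with a warning.
    """
    if len(ref.chains) != len(tgt.chains):
        raise ChainCountMismatchError(
            f"chain count mismatch: reference has {len(ref.chains)}, "
            f"target has {len(tgt.chains)}"
        )
    ref_order = reorder_by_adjacency(ref) if reorder else list(range(len(ref.chains)))
    tgt_order = reorder_by_adjacency(tgt) if reorder else list(range(len(tgt.chains)))
    ref_chains = [ref.chains[i] for i in ref_order]

    evaluated: list[ChainPermutation] = []
    warnings: list[str] = []
    for shift, rotated in enumerate(cyclic_permutations(tgt_order)):
        tgt_chains = [tgt.chains[i] for i in rotated]
        R, T, admissible = _pooled_ca_pairs(ref_chains, tgt_chains, params, min_coverage)
        if R.shape[0] >= 3:
            _, rmsd = lsq_fit(R, T)
        else:
            rmsd, admissible = float("inf"), False
        evaluated.append(
            ChainPermutation(
                shift=shift,
                pairing=[(rc.chain_id, tc.chain_id) for rc, tc in zip(ref_chains, tgt_chains)],
                ca_rmsd=rmsd,
                admissible=admissible,
            )
        )
    admissibles = [p for p in evaluated if p.admissible]
    if admissibles:
        # RMSDs quantised so exactly-degenerate shifts (perfect symmetry)
        # tie deterministically and fall through to the smallest shift
        best = min(admissibles, key=lambda p: (round(p.ca_rmsd, 9), p.shift))
    else:
        if not np.isfinite(evaluated[0].ca_rmsd):
            raise NoCorrespondenceError(
                "no chain pair could be aligned under any cyclic shift"
            )
        best = evaluated[0]
        warnings.append(
            "no cyclic shift met the alignment-coverage rule; "
            "falling back to the identity pairing"
        )
    return PermutationSearch(best=best, evaluated=evaluated, warnings=warnings)
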
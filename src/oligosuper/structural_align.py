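"""Sequence-independent residue correspondence from C-alpha geometry.

When two chains share a fold but not a sequence, residue equivalence must
come from the coordinates.  The procedure here is the classical iterative
superposition/dynamic-programming scheme:

* seed transforms are generated by rigidly fitting every length-L window
  of the reference C-alpha trace onto every length-L window of the target
  (stride 4) and keeping the K best;
* for each seed, alternate (a) scoring residue pairs by proximity under
  the current transform with the bounded kernel ``S_ij = 1 / (1 +
  (d_ij/d0)^2)``, (b) a global dynamic-programming alignment of the score
  matrix with *zero end-gap* penalties (free terminal gaps, affine
  internal gaps), and (c) a rigid re-fit on the aligned pairs closer than
  an inclusion cutoff — until the aligned set stops changing;
* the seed aligning the most residues wins (ties: lowest final RMSD).

All numeric constants are exposed in :class:`StructureAlignParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NoCorrespondenceError
from .structure import Assembly
from .superpose import (
    AtomMapping,
    MappedPair,
    RigidTransform,
    SuperpositionResult,
    deviations,
    lsq_fit,
)


@dataclass(frozen=True)
class StructureAlignParams:
    seed_length: int = 20        # residues per fragment window
    seed_stride: int = 4
    n_seeds: int = 5
    d0: float = 5.0              # Angstrom, proximity-score half-width
    include_cutoff: float = 8.0  # Angstrom, pairs kept for the re-fit
    gap_open: float = 0.2        # on the score scale (max score 1)
    gap_extend: float = 0.05
    max_iter: int = 30


@dataclass
class StructuralCorrespondence:
    pairs: list[tuple[int, int]]
    n_aligned: int
    final_rmsd: float
    seed_id: int
    transform: RigidTransform
    score: float = 0.0
    score_history: list[float] = field(default_factory=list)


def fragment_seeds(
    ref_ca: np.ndarray,
    tgt_ca: np.ndarray,
    params: StructureAlignParams = StructureAlignParams(),
) -> list[RigidTransform]:
    """Candidate transforms from all-vs-all fragment superpositions.

    Windows shrink to the shorter chain when either has fewer than
    ``seed_length`` residues.  Transforms are returned best-first by
    fragment RMSD.
    """
    n, m = len(ref_ca), len(tgt_ca)
    L = min(params.seed_length, n, m)
    results = []
    for i in range(0, n - L + 1, params.seed_stride):
        for j in range(0, m - L + 1, params.seed_stride):
            try:
                tf, r = lsq_fit(ref_ca[i:i + L], tgt_ca[j:j + L])
            except ValueError:  # degenerate (collinear) window
                continue
            results.append((r, i, j, tf))
    results.sort(key=lambda t: (t[0], t[1], t[2]))
    return [tf for _, _, _, tf in results[: params.n_seeds]]


def _zega_dp(S: np.ndarray, gap_open: float, gap_extend: float) -> tuple[list[tuple[int, int]], float]:
    """Global alignment of a similarity matrix with free end gaps and
    affine internal gaps (three-state Gotoh recursion, maximisation).

    Leading overhangs are free through the border initialisation of the
    gap states; trailing overhangs are free because the optimum is taken
    over the whole last row and column.  Returns the aligned (ref, tgt)
    index pairs and the DP score.
    """
    n, m = S.shape
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)   # pair state
    X = np.full((n + 1, m + 1), NEG)   # gap in target (consumes ref rows)
    Y = np.full((n + 1, m + 1), NEG)   # gap in reference (consumes tgt cols)
    M[0, 0] = 0.0
    X[1:, 0] = 0.0                     # free leading ref overhang
    Y[0, 1:] = 0.0                     # free leading tgt overhang
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)

    def _argmax3(a: float, b: float, c: float) -> tuple[float, int]:
        if a >= b and a >= c:
            return a, 0
        if b >= c:
            return b, 1
        return c, 2

    for i in range(1, n + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        for j in range(1, m + 1):
            best, arg = _argmax3(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1])
            Mi[j] = best + S[i - 1, j - 1]
            ptrM[i, j] = arg
            best, arg = _argmax3(Mi1[j] - gap_open, Xi1[j] - gap_extend,
                                 Yi1[j] - gap_open)
            Xi[j] = best
            ptrX[i, j] = arg
            best, arg = _argmax3(Mi[j - 1] - gap_open, Xi[j - 1] - gap_open,
                                 Yi[j - 1] - gap_extend)
            Yi[j] = best
            ptrY[i, j] = arg

    # free trailing gaps: best end anywhere on the last row or column
    score, end = NEG, (0, n, m)
    for s, V in enumerate((M, X, Y)):
        j = int(np.argmax(V[n, :]))
        if V[n, j] > score:
            score, end = V[n, j], (s, n, j)
        i = int(np.argmax(V[:, m]))
        if V[i, m] > score:
            score, end = V[i, m], (s, i, m)

    pairs: list[tuple[int, int]] = []
    state, i, j = end
    while i > 0 or j > 0:
        if state == 0:
            if i == 0 and j == 0:
                break
            pairs.append((i - 1, j - 1))
            state = int(ptrM[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            if j == 0:
                break  # free leading ref overhang
            state = int(ptrX[i, j])
            i -= 1
        else:
            if i == 0:
                break  # free leading tgt overhang
            state = int(ptrY[i, j])
            j -= 1
    pairs.reverse()
    return pairs, float(score)


def structure_align(
    ref_ca: np.ndarray,
    tgt_ca: np.ndarray,
    params: StructureAlignParams = StructureAlignParams(),
) -> StructuralCorrespondence:
    """Iterative structural alignment of two C-alpha traces.

    Requires at least 8 residues on each side.  Raises
    :class:`NoCorrespondenceError` when no residue pair survives the
    inclusion cutoff for any seed.
    """
    ref_ca = np.asarray(ref_ca, dtype=float)
    tgt_ca = np.asarray(tgt_ca, dtype=float)
    if len(ref_ca) < 8 or len(tgt_ca) < 8:
        raise ValueError("structural alignment needs at least 8 residues per chain")

    best: StructuralCorrespondence | None = None
    for seed_id, tf in enumerate(fragment_seeds(ref_ca, tgt_ca, params)):
        pairs_prev: list[tuple[int, int]] | None = None
        history: list[float] = []
        pairs: list[tuple[int, int]] = []
        score = 0.0
        for _ in range(params.max_iter):
            moved = tf.apply(tgt_ca)
            diff = ref_ca[:, None, :] - moved[None, :, :]
            d = np.sqrt(np.sum(diff**2, axis=2))
            S = 1.0 / (1.0 + (d / params.d0) ** 2)
            pairs, score = _zega_dp(S, params.gap_open, params.gap_extend)
            history.append(score)
            close = [(i, j) for i, j in pairs if d[i, j] < params.include_cutoff]
            if len(close) < 3:
                pairs = close
                break
            try:
                tf, _ = lsq_fit(ref_ca[[i for i, _ in close]],
                                tgt_ca[[j for _, j in close]])
            except ValueError:  # degenerate aligned set; keep last transform
                pairs = close
                break
            if close == pairs_prev:
                pairs = close
                break
            pairs_prev = close
            pairs = close
        if not pairs:
            continue
        dev = deviations(ref_ca[[i for i, _ in pairs]], tgt_ca[[j for _, j in pairs]], tf)
        cand = StructuralCorrespondence(
            pairs=pairs,
            n_aligned=len(pairs),
            final_rmsd=float(np.sqrt(np.mean(dev**2))),
            seed_id=seed_id,
            transform=tf,
            score=score,
            score_history=history,
        )
        if (
            best is None
            or cand.n_aligned > best.n_aligned
            or (cand.n_aligned == best.n_aligned and cand.final_rmsd < best.final_rmsd)
        ):
            best = cand
    if best is None:
        raise NoCorrespondenceError("no structural correspondence found")
    return best


def structure_superpose(
    ref: Assembly,
    tgt: Assembly,
    pairing: list[tuple[str, str]],
    params: StructureAlignParams = StructureAlignParams(),
) -> SuperpositionResult:
    """Structure-based superposition of a whole assembly.

    Runs :func:`structure_align` for every mapped chain pair, pools the
    aligned C-alpha pairs and performs one whole-complex rigid fit.
    """
    mapped: list[MappedPair] = []
    counts = []
    n_aligned = 0
    for ref_id, tgt_id in pairing:
        rc, tc = ref.chain(ref_id), tgt.chain(tgt_id)
        # residue indices that actually carry a CA
        r_idx = [k for k, res in enumerate(rc.residues) if res.get("CA") is not None]
        t_idx = [k for k, res in enumerate(tc.residues) if res.get("CA") is not None]
        try:
            corr = structure_align(
                np.array([rc.residues[k].get("CA").coords for k in r_idx]),
                np.array([tc.residues[k].get("CA").coords for k in t_idx]),
                params,
            )
        except NoCorrespondenceError as exc:
            raise NoCorrespondenceError(
                f"no structural correspondence for chain pair "
                f"{ref_id!r} / {tgt_id!r}"
            ) from exc
        for i, j in corr.pairs:
            ri, tj = r_idx[i], t_idx[j]
            mapped.append(
                MappedPair(
                    ref_chain=ref_id,
                    tgt_chain=tgt_id,
                    ref_resindex=ri,
                    tgt_resindex=tj,
                    atom_name="CA",
                    ref_atom=rc.residues[ri].get("CA"),
                    tgt_atom=tc.residues[tj].get("CA"),
                    ref_resname=rc.residues[ri].resname,
                    tgt_resname=tc.residues[tj].resname,
                )
            )
        counts.append((ref_id, tgt_id, len(corr.pairs)))
        n_aligned += len(corr.pairs)
    mapping = AtomMapping(pairs=mapped, level="ca", per_chain_counts=counts)
    R, T = mapping.coords()
    tf, r = lsq_fit(R, T)
    dev = deviations(R, T, tf)
    return SuperpositionResult(
        transform=tf,
        rmsd=r,
        n_atoms=len(mapping),
        deviations=dev,
        method="structure",
        mapping=mapping,
        n_aligned=n_aligned,
    )
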
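# Methods

This note records the models and procedures implemented in `oligosuper`,
the parameters that matter, and the design choices made where the design
was genuinely open.

## Problem setting

Two protein assemblies sharing an n-fold rotation axis are to be
superposed rigidly.  RMSD after an optimal rigid fit is only meaningful
once atomic equivalence is fixed, and for oligomers that equivalence has
three layers: which chain maps to which chain, which residue to which
residue, and which atom to which atom.  Errors at the chain level
dominate: pairing a ring's chains in the wrong register inflates RMSD by
the inter-subunit distance scale (tens of Å), swamping the genuine
conformational signal.

## Chain-level mapping

**Replica detection.**  All chain pairs within each structure are aligned
globally and grouped by single linkage at an identity threshold (default
0.95, the PDB's clustering convention for "identical" chains; the
boundary is inclusive).  Identity is counted as identical aligned pairs
over the *shorter* chain length, which is robust to disordered termini;
alignment-length denominators differ near the boundary and the threshold
is user-configurable precisely because of that ambiguity.  Rotational
symmetry is assumed as soon as any group has two members.

**Spatial reordering.**  Chains are reordered by a greedy
nearest-centroid walk (centroid = unweighted mean of Cα positions)
starting from the first chain in file order.  Two robustness measures are
layered on the plain walk:

- distances within 0.01 Å of the minimum count as *tied* and are resolved
  by file order.  The tolerance sits far below any genuine centroid
  asymmetry but above both floating-point noise and PDB format rounding
  (10⁻³ Å per coordinate); without it, an exactly symmetric ring's walk
  direction is decided by the last bit of the distance computation;
- the traversal orientation is canonicalised.  A greedy walk may run
  around a ring either way depending on the start chain's local spacing,
  and a reversed ring can never be matched by cyclic shifts alone.  The
  ring normal (summed cross products of consecutive centroid polygon
  vertices) and the summed chain end-to-end Cα vector are both intrinsic
  and rotate with the structure; requiring a non-negative scalar product
  between them gives congruent assemblies the same orientation.  The
  signal degrades when chains' end-to-end vectors are nearly orthogonal
  to the ring axis; reordering can be disabled (`--no-reorder`) exactly
  as for hetero-oligomers whose adjacency walk misbehaves.

**Cyclic-shift search.**  Only the n rotations of the target's
adjacency-ordered chain list are enumerated — not all n! bijections, and
no reflections; many dihedral assemblies are still handled because a
dihedral ring's rotations include the relevant mappings.  For each shift
the per-chain-pair Cα correspondences (from the cached sequence
alignments) are pooled and the *whole complex* is fitted as one rigid
body, so subunit interfaces cannot be torn apart by per-chain fits.  A
shift is admissible only if every chain pair aligns at least 50% of the
shorter chain; this keeps e.g. α-to-β pairings of pseudo-symmetric
tetramers available (they align well) while rejecting unalignable
pairings.  The minimum-RMSD admissible shift wins; RMSDs are quantised at
10⁻⁹ Å before comparison so that exactly degenerate shifts (a perfect
ring, where all n shifts give RMSD ≈ 10⁻¹⁵) fall through to the
deterministic smallest-shift tie-break.  If nothing is admissible the
identity pairing is used with a warning.  All three superposition methods
then share the single permutation chosen on the standard Cα criterion,
keeping their RMSDs comparable.

## Superposition methods

**Standard.**  The weighted orthogonal Procrustes problem is solved in
closed form by SVD of the weighted covariance with a determinant
correction, so the rotation is always proper (det +1).  Degenerate
geometry (fewer than 3 pairs, or collinear point sets, detected via the
two smaller singular values) is an error.  The McLachlan and Kabsch
formulations solve the same convex-over-rotations problem with a unique
optimum; the SVD route is used.

**Gaussian-weighted iterative.**  Starting from uniform weights the
solver alternates a weighted fit with reweighting wᵢ = exp(−dᵢ²/c),
c = 2.0 Å² (configurable), until the largest weight change is below 10⁻⁴
or 100 iterations.  Non-convergence returns the last iterate with a
warning rather than failing.  Reported are the *core* — atoms deviating
by less than 2.0 Å under the converged transform — the RMSD over that
core (the headline "weighted RMSD"), and the Σw-weighted RMSD
sqrt(Σwd²/Σw); both are emitted because reporting conventions differ.
Two behaviours worth knowing:

- a residue adjacent to a hinge pivot moves only fractionally and will
  sit inside the 2 Å core band; with moderate bends (~30°) such boundary
  atoms dominate the core RMSD even though the fixed domain fits to
  ~0.05 Å.  Only when the mobile domain swings clear of the band does the
  core RMSD drop to the numerical floor;
- the iteration is a fixed-point scheme with multiple basins: when the
  mobile domain is both large and internally rigid, a very large swing
  can make the solver converge onto *that* domain instead of the larger
  fixed one.  The uniform-weight initial fit decides the basin.

**Symmetric side-chain relabelling.**  Arg NH1/NH2, Asp OD1/OD2, Glu
OE1/OE2, Leu CD1/CD2, Val CG1/CG2 and the Phe/Tyr ring pairs CD1/CD2 +
CE1/CE2 (swapped jointly, preserving ring geometry) are chemically
equivalent but arbitrarily named.  For heavy-atom superpositions, after
the initial fit each mapped residue pair of equal type is tested with the
target labels swapped under the *fixed* transform and the labelling with
the smaller summed squared deviation is kept, followed by one final
re-fit.  The per-residue minimisation under a fixed transform makes the
step monotone (never increases the objective); a single pass is used
rather than alternating to convergence, since the first pass captures
essentially all genuine flips and keeps the procedure deterministic.
His/Asn/Gln "flips" are excluded — exchanging N and O is not a chemical
equivalence.  Of the residue names listed for this treatment one is a
duplicate (Phe appears twice); the seven unique types are implemented.

**Structure-based.**  For chains with unrelated sequences the residue
correspondence comes from geometry alone.  Seeds: every length-20 window
of the reference Cα trace is rigidly fitted onto every length-20 window
of the target (stride 4) and the 5 best transforms are kept (degenerate
windows skipped).  Each seed is refined by iterating (i) score matrix
Sᵢⱼ = 1/(1 + (dᵢⱼ/d₀)²) with d₀ = 5 Å under the current transform,
(ii) global dynamic programming with free end gaps and affine internal
gaps (open 0.2, extend 0.05 on the score scale; three-state Gotoh
recursion, best end taken over the final row/column), (iii) re-fit on
aligned pairs closer than 8 Å — until the aligned set repeats, at most 30
iterations.  The seed aligning the most residues wins, ties broken by
final RMSD.  The kernel's exact form is not critical — any bounded,
monotone-decreasing function of distance behaves equivalently; this one
is used for its boundedness (scores in (0, 1]).  All constants are
exposed in `StructureAlignParams`.  Per-chain-pair correspondences are
pooled for one whole-complex fit, consistent with the chain-mapping
philosophy above.

## Input handling

PDB parsing is delegated to gemmi and reduced to standard amino-acid
polymer residues: HETATM ligands, waters and nucleic acids are dropped;
selenomethionine is mapped to methionine (SE→SD) since it substitutes 1:1
in the polymer.  Alternate locations keep the highest-occupancy conformer
(ties: altloc "A", then file order).  Multi-model files use the first
model unless told otherwise.  Biological units are expanded from
REMARK 350 operators *before* chain selection and atom selection; copies
beyond the first get deterministic numeric suffixes (A, A2, A3 …) so
mapping tables stay unambiguous, and an identity operator never
duplicates a chain.  The writer emits fixed-width 8.3 ATOM records, so
round-trips preserve coordinates to 10⁻³ Å; multi-character biounit chain
ids are remapped to unused single characters on write, keeping the chain
column distinct.  Atom selection levels: `ca` (CA atoms), `backbone`
(N/CA/C/O), `heavy` (all non-hydrogen).  Requesting a 4-character id
fetches from RCSB only when fetching is explicitly enabled.

## Sequence alignment

Needleman–Wunsch with BLOSUM62, gap open 11 / extend 1 on that scale, and
zero end-gap penalties, via Biopython's `PairwiseAligner`.  Free end gaps
mean disordered termini cost nothing — important both for identity
estimates and for pairing truncated constructs.  Among co-optimal
alignments the aligner's first traceback is taken; the two sequences are
passed in a canonical internal order (indices swapped back afterwards) so
the chosen traceback — and hence the identity — is symmetric in its
arguments.

## Synthetic assemblies (what the fixtures do and do not show)

The generator builds an idealised α-helical protomer (rise 1.5 Å,
100°/residue, helix radius 2.3 Å, full backbone plus CB, sequence drawn
deterministically from the seed) and places n copies at ring radius 15 Å
related by 360/n° rotations about z — an *exact* C*n* assembly,
reproducible bit-for-bit from (spec, seed).  Quasi-symmetry is emulated
by per-protomer rigid perturbations (fixed rotation/translation
magnitudes, random axes), flexibility by a hinge bend on a residue range,
and deposition differences by rotating the stored chain order.  Paired
test structures derive the target from the reference (shared ring
irregularity plus smaller independent perturbation), mirroring two
crystal forms of one molecule; with fully independent perturbations the
adjacency walk's start-dependence would dominate, which no chain-mapping
method using cyclic shifts alone can overcome.  Dedicated side-chain
fixtures place full idealised side chains of the seven symmetric residue
types, with optional label flips and noise, for the relabelling tests.

What passing on these fixtures does *not* show: real crystal structures
have missing loops, alternate conformations interacting with symmetry,
genuinely irregular rings, domain motions that are not single rigid
hinges, and sequence variation between depositions.  The worked-example
test on deposited entries covers that ground but requires network access
to fetch the files.

## Numerical choices

- Fit degeneracy: error if fewer than 3 pairs or the second and third
  singular values vanish (collinear input).
- Weighted-fit convergence: max |Δw| < 10⁻⁴, cap 100 iterations.
- Permutation tie-break: RMSD quantised at 10⁻⁹ Å, then smallest shift.
- Adjacency tie tolerance: 0.01 Å.
- Structural-alignment iteration cap 30 per seed; aligned-set repetition
  is the convergence test; the DP score is non-decreasing across
  iterations in practice and asserted on fixtures.
- Problem sizes in tests and the acceptance script (rings of 2–8 chains,
  protomers of 20–30 residues, 100-trial oracle batteries) were chosen to
  exercise every code path at sub-minute cost.

## Known limitations

- Only cyclic chain permutations are searched; assemblies whose chain
  correspondence requires a reflection or an arbitrary bijection
  (complex dihedral packings, some hetero-oligomers) need manual chain
  selection or reordering off.
- Helical and icosahedral symmetries are out of scope.
- The structure method aligns chains pairwise under a shared final fit;
  topology-permuted (non-sequential) alignments are not found.
- Hydrogens are ignored throughout; nucleic acids and ligands are not
  superposed.
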
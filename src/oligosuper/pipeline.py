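"""End-to-end orchestration: read structures, detect symmetry, search the
chain permutation, superpose with the requested method(s), write reports.

The flow for a multi-chain target mirrors the symmetry-aware protocol:
replica detection -> spatial chain reordering -> cyclic permutation
search on the standard C-alpha RMSD -> superposition of the optimal
permutation with any of the three methods (standard, weighted,
structure).  Monomers skip the symmetry machinery entirely.  All three
methods share the single permutation chosen by the standard C-alpha
search, so their RMSDs are directly comparable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ChainCountMismatchError, EmptyStructureError
from .pdbio import build_biological_unit, fetch_pdb, read_pdb, write_pdb
from .seqalign import AlignParams, cached_align
from .structural_align import StructureAlignParams, structure_superpose
from .structure import Assembly
from .superpose import (
    AtomMapping,
    SuperpositionResult,
    build_atom_mapping,
    deviations,
    remap_symmetric_sidechains,
    standard_fit,
    weighted_fit,
)
from .symmetry import (
    ChainPermutation,
    PermutationSearch,
    ReplicaGroups,
    detect_replica_groups,
    find_best_permutation,
)

METHODS = ("standard", "weighted", "structure")


@dataclass
class RunConfig:
    method: str = "standard"          # standard | weighted | structure | all
    level: str = "ca"                 # ca | backbone | heavy
    reorder: bool = True
    identity_threshold: float = 0.95
    biounit: int | None = None        # REMARK 350 biomolecule index, or None
    chains_ref: list[str] | None = None
    chains_tgt: list[str] | None = None
    align_params: AlignParams = field(default_factory=AlignParams)
    structure_params: StructureAlignParams = field(default_factory=StructureAlignParams)
    gaussian_c: float = 2.0           # A^2, weight width of the weighted fit
    min_coverage: float = 0.5
    model_index: int = 0
    fetch: bool = False               # allow 4-char ids to be downloaded

    def __post_init__(self) -> None:
        if self.method not in METHODS + ("all",):
            raise ValueError(f"unknown method {self.method!r}")
        if self.level not in ("ca", "backbone", "heavy"):
            raise ValueError(f"unknown atom level {self.level!r}")
        if not 0.0 < self.identity_threshold <= 1.0:
            raise ValueError("identity threshold must be in (0, 1]")


@dataclass
class Report:
    ref: Assembly
    tgt: Assembly
    config: RunConfig
    results: dict[str, SuperpositionResult]
    replica_groups_ref: ReplicaGroups
    replica_groups_tgt: ReplicaGroups
    permutation: ChainPermutation
    permutation_search: PermutationSearch | None
    warnings: list[str] = field(default_factory=list)

    @property
    def best_rmsd(self) -> float:
        return min(r.rmsd for r in self.results.values())


def _load(source, config: RunConfig, which: str) -> Assembly:
    if isinstance(source, Assembly):
        a = source
    else:
        if (
            isinstance(source, str)
            and len(source.strip()) == 4
            and "\n" not in source
            and not Path(source).exists()
        ):
            if not config.fetch:
                raise EmptyStructureError(
                    f"{source!r} looks like a PDB id but fetching is disabled "
                    "(pass fetch=True / --fetch)"
                )
            a = read_pdb(fetch_pdb(source), label=source.strip().lower())
        else:
            a = read_pdb(source)
    chains = config.chains_ref if which == "ref" else config.chains_tgt
    if chains:
        a = a.subset(chains)
    if config.biounit is not None:
        a = build_biological_unit(a, config.biounit)
    return a


def _sequence_mapping(ref: Assembly, tgt: Assembly, perm: ChainPermutation,
                      config: RunConfig) -> AtomMapping:
    """Pool per-chain-pair sequence-based atom mappings at the config level."""
    all_pairs = []
    counts = []
    for ref_id, tgt_id in perm.pairing:
        rc, tc = ref.chain(ref_id), tgt.chain(tgt_id)
        aln = cached_align(rc.sequence, tc.sequence, config.align_params)
        m = build_atom_mapping(rc, tc, aln, config.level)
        all_pairs.extend(m.pairs)
        counts.append((ref_id, tgt_id, len(m.pairs)))
    return AtomMapping(pairs=all_pairs, level=config.level, per_chain_counts=counts)


def superimpose(ref_source, tgt_source, config: RunConfig = RunConfig()) -> Report:
    """Run the full symmetry-aware superposition and collect a report.

    ``ref_source``/``tgt_source`` may be paths, raw PDB text, 4-character
    PDB ids (with ``config.fetch``) or pre-built :class:`Assembly`
    objects.
    """
    ref = _load(ref_source, config, "ref")
    tgt = _load(tgt_source, config, "tgt")
    warnings: list[str] = []

    groups_ref = detect_replica_groups(ref, config.identity_threshold, config.align_params)
    groups_tgt = detect_replica_groups(tgt, config.identity_threshold, config.align_params)

    if len(ref.chains) != len(tgt.chains):
        raise ChainCountMismatchError(
            f"chain count mismatch: {ref.id} has {len(ref.chains)} chains, "
            f"{tgt.id} has {len(tgt.chains)}"
        )

    search: PermutationSearch | None = None
    if len(tgt.chains) > 1:
        search = find_best_permutation(
            ref, tgt,
            reorder=config.reorder,
            params=config.align_params,
            min_coverage=config.min_coverage,
        )
        perm = search.best
        warnings.extend(search.warnings)
    else:
        perm = ChainPermutation(
            shift=0,
            pairing=[(ref.chains[0].chain_id, tgt.chains[0].chain_id)],
            ca_rmsd=float("nan"),
        )

    methods = list(METHODS) if config.method == "all" else [config.method]
    results: dict[str, SuperpositionResult] = {}
    for method in methods:
        if method == "structure":
            res = structure_superpose(ref, tgt, perm.pairing, config.structure_params)
        else:
            mapping = _sequence_mapping(ref, tgt, perm, config)
            if method == "standard":
                res = standard_fit(mapping)
                if config.level == "heavy":
                    remapped, n_swapped = remap_symmetric_sidechains(mapping, res.transform)
                    if n_swapped:
                        res = standard_fit(remapped)
                        res.warnings.append(
                            f"symmetric side-chain labels swapped in {n_swapped} residues"
                        )
            else:
                res = weighted_fit(mapping, c=config.gaussian_c)
        res.permutation = perm
        results[method] = res
        warnings.extend(res.warnings)

    return Report(
        ref=ref,
        tgt=tgt,
        config=config,
        results=results,
        replica_groups_ref=groups_ref,
        replica_groups_tgt=groups_tgt,
        permutation=perm,
        permutation_search=search,
        warnings=warnings,
    )


def write_outputs(report: Report, prefix: str | Path) -> list[Path]:
    """Write the superposed target PDB plus CSV tables.

    Files: ``{prefix}_target_superposed.pdb`` (target moved onto the
    reference by the best available transform), ``{prefix}_summary.csv``,
    ``{prefix}_permutations.csv`` (every evaluated cyclic shift) and
    ``{prefix}_atom_map.csv``.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []

    first = next(iter(report.results.values()))
    moved = report.tgt.transformed(first.transform.rotation, first.transform.translation)
    pdb_path = prefix.parent / f"{prefix.name}_target_superposed.pdb"
    write_pdb(moved, pdb_path)
    written.append(pdb_path)

    summary_path = prefix.parent / f"{prefix.name}_summary.csv"
    with open(summary_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([
            "method", "level", "rmsd", "n_atoms", "core_count", "core_rmsd",
            "weighted_rmsd", "n_aligned", "shift", "pairing",
        ])
        for method, res in report.results.items():
            w.writerow([
                method,
                "ca" if method == "structure" else report.config.level,
                f"{res.rmsd:.6f}",
                res.n_atoms,
                res.core_count if res.core_count is not None else "",
                f"{res.core_rmsd:.6f}" if res.core_rmsd is not None else "",
                f"{res.weighted_rmsd:.6f}" if res.weighted_rmsd is not None else "",
                res.n_aligned if res.n_aligned is not None else "",
                report.permutation.shift,
                ";".join(f"{a}->{b}" for a, b in report.permutation.pairing),
            ])
    written.append(summary_path)

    perm_path = prefix.parent / f"{prefix.name}_permutations.csv"
    with open(perm_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["shift", "ca_rmsd", "admissible", "pairing"])
        evaluated = (
            report.permutation_search.evaluated
            if report.permutation_search is not None
            else [report.permutation]
        )
        for p in evaluated:
            w.writerow([
                p.shift,
                f"{p.ca_rmsd:.6f}" if np.isfinite(p.ca_rmsd) else "",
                p.admissible,
                ";".join(f"{a}->{b}" for a, b in p.pairing),
            ])
    written.append(perm_path)

    map_path = prefix.parent / f"{prefix.name}_atom_map.csv"
    with open(map_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([
            "ref_chain", "ref_resname", "ref_resnum", "tgt_chain",
            "tgt_resname", "tgt_resnum", "atom", "deviation",
        ])
        res = first
        if res.mapping is not None:
            ref_xyz, tgt_xyz = res.mapping.coords()
            dev = deviations(ref_xyz, tgt_xyz, res.transform)
            for p, d in zip(res.mapping.pairs, dev):
                w.writerow([
                    p.ref_chain,
                    p.ref_resname,
                    report.ref.chain(p.ref_chain).residues[p.ref_resindex].seqnum,
                    p.tgt_chain,
                    p.tgt_resname,
                    report.tgt.chain(p.tgt_chain).residues[p.tgt_resindex].seqnum,
                    p.atom_name,
                    f"{d:.4f}",
                ])
    written.append(map_path)
    return written
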
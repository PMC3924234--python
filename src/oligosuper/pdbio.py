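"""PDB reading/writing, biological-unit expansion and atom selection.

Parsing is delegated to gemmi; the result is converted into the package's
own :class:`~oligosuper.structure.Assembly` containers, keeping only
standard amino-acid polymer residues.  Selenomethionine (MSE) is mapped to
methionine (SE -> SD); all other modified or hetero residues, waters and
nucleic acids are dropped.  Alternate locations are resolved by keeping
the highest-occupancy conformer (ties: altloc "A", then file order).
"""

from __future__ import annotations

import string
import urllib.request
from pathlib import Path

import gemmi
import numpy as np

from .errors import EmptyStructureError, MissingAssemblyError, PDBParseError
from .structure import (
    Assembly,
    Atom,
    BACKBONE_ATOMS,
    BiomtOperator,
    Chain,
    Residue,
    THREE_TO_ONE,
)

RCSB_URL = "https://files.rcsb.org/download/{}.pdb"

ATOM_LEVELS = ("ca", "backbone", "heavy")


def fetch_pdb(pdb_id: str, timeout: float = 30.0) -> str:
    """Download PDB text for a 4-character entry id from RCSB."""
    pdb_id = pdb_id.strip().lower()
    if len(pdb_id) != 4:
        raise ValueError(f"{pdb_id!r} is not a 4-character PDB id")
    with urllib.request.urlopen(RCSB_URL.format(pdb_id), timeout=timeout) as fh:
        return fh.read().decode()


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, tie -> 'A'/first."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name in order:
        group = by_name[name]
        best = max(
            enumerate(group),
            key=lambda t: (t[1].occupancy, t[1].altloc == "A", -t[0]),
        )[1]
        out.append(best)
    return out


def _convert_residue(res: gemmi.Residue) -> Residue | None:
    name = res.name
    is_mse = name == "MSE"
    if name not in THREE_TO_ONE and not is_mse:
        return None
    if res.het_flag == "H" and not is_mse:
        return None
    atoms = []
    for a in res:
        aname = a.name
        elem = a.element.name.upper()
        if is_mse and aname == "SE":
            aname, elem = "SD", "S"
        altloc = "" if a.altloc in ("\x00", " ") else a.altloc
        atoms.append(
            Atom(
                name=aname,
                element=elem,
                coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                occupancy=a.occ,
                altloc=altloc,
                serial=a.serial,
            )
        )
    if not atoms:
        return None
    icode = res.seqid.icode.strip()
    return Residue(
        resname="MET" if is_mse else name,
        seqnum=res.seqid.num,
        icode=icode,
        atoms=_resolve_altlocs(atoms),
    )


def _convert_operators(st: gemmi.Structure, all_chain_ids: list[str]) -> list[BiomtOperator]:
    ops = []
    for i, asm in enumerate(st.assemblies):
        index = int(asm.name) if asm.name.isdigit() else i + 1
        for gen in asm.generators:
            chains = [c for c in gen.chains if c in all_chain_ids] or list(all_chain_ids)
            for op in gen.operators:
                mat = np.array(op.transform.mat.tolist())
                vec = np.array([op.transform.vec.x, op.transform.vec.y, op.transform.vec.z])
                ops.append(
                    BiomtOperator(
                        rotation=mat,
                        translation=vec,
                        applies_to=chains,
                        assembly_index=index,
                    )
                )
    return ops


def read_pdb(source: str | Path, label: str = "", model_index: int = 0) -> Assembly:
    """Read a PDB file, path or raw text into an :class:`Assembly`.

    Only standard amino-acid ATOM records (plus MSE) are retained.  For
    multi-model (NMR) files the first model is used unless ``model_index``
    says otherwise.  REMARK 350 operators, if present, are captured on the
    returned assembly for later biological-unit expansion.
    """
    text: str
    if isinstance(source, Path):
        text = source.read_text()
        label = label or source.stem
    elif "\n" in source or source.lstrip()[:6] in ("ATOM  ", "HETATM", "REMARK", "HEADER", "MODEL "):
        text = source
        label = label or "input"
    else:
        p = Path(source)
        if not p.exists():
            raise PDBParseError(f"no such file: {source}")
        text = p.read_text()
        label = label or p.stem

    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{label}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{label}: no models found")
    if model_index >= len(st):
        raise PDBParseError(
            f"{label}: model {model_index} requested but file has {len(st)} model(s)"
        )
    model = st[model_index]

    chains = []
    for gch in model:
        residues = [r for r in (_convert_residue(res) for res in gch) if r is not None]
        if residues:
            chains.append(Chain(chain_id=gch.name, residues=residues))
    if not chains:
        raise EmptyStructureError(f"{label}: no standard protein residues found")

    biomt = _convert_operators(st, [c.chain_id for c in chains])
    info = dict(st.info) if hasattr(st, "info") else {}
    title = info.get("_struct.title", "")
    return Assembly(chains=chains, id=label, biomt=biomt, title=title)


def build_biological_unit(a: Assembly, assembly_index: int = 1) -> Assembly:
    """Expand an asymmetric unit into a biological assembly via its
    REMARK 350 operators.

    Every operator is applied to the chains it names; generated copies are
    appended with a deterministic numeric suffix (A, A2, A3, ...).  An
    identity operator simply keeps the original chain.  Raises
    :class:`MissingAssemblyError` when the file carries no operators for
    the requested assembly.
    """
    ops = [op for op in a.biomt if op.assembly_index == assembly_index]
    if not ops:
        raise MissingAssemblyError(
            f"{a.id or 'assembly'}: no REMARK 350 assembly information "
            f"for biomolecule {assembly_index}"
        )
    counts: dict[str, int] = {}
    new_chains: list[Chain] = []
    for op in ops:
        for cid in op.applies_to:
            src = a.chain(cid)
            counts[cid] = counts.get(cid, 0) + 1
            new_id = cid if counts[cid] == 1 else f"{cid}{counts[cid]}"
            if op.is_identity:
                chain = Chain(chain_id=new_id, residues=src.residues)
            else:
                moved = Assembly(chains=[src], id="tmp").transformed(
                    op.rotation, op.translation
                )
                chain = Chain(chain_id=new_id, residues=moved.chains[0].residues)
            new_chains.append(chain)
    return Assembly(chains=new_chains, id=a.id, biomt=a.biomt, title=a.title)


def select_atoms(a: Assembly, level: str) -> list[tuple[str, list[Atom]]]:
    """Per-chain ordered atom lists at a selection level.

    ``ca`` keeps C-alpha atoms, ``backbone`` keeps N/CA/C/O, ``heavy``
    keeps every non-hydrogen atom.  Residues missing the requested atoms
    contribute what they have; an entirely empty selection is an error.
    """
    if level not in ATOM_LEVELS:
        raise ValueError(f"unknown atom selection level {level!r}; expected one of {ATOM_LEVELS}")
    out = []
    total = 0
    for chain in a.chains:
        atoms: list[Atom] = []
        for res in chain.residues:
            for atom in res.atoms:
                if level == "ca" and atom.name != "CA":
                    continue
                if level == "backbone" and atom.name not in BACKBONE_ATOMS:
                    continue
                if atom.is_hydrogen:
                    continue
                atoms.append(atom)
        total += len(atoms)
        out.append((chain.chain_id, atoms))
    if total == 0:
        raise EmptyStructureError(f"{a.id or 'assembly'}: atom selection {level!r} is empty")
    return out


def _chain_id_map(ids: list[str]) -> dict[str, str]:
    """Map arbitrary chain ids onto unique single characters for the
    one-column PDB chain field (multi-char biounit copies get fresh
    letters deterministically)."""
    pool = string.ascii_uppercase + string.ascii_lowercase + string.digits
    mapping: dict[str, str] = {}
    used: set[str] = set()
    for cid in ids:
        if len(cid) == 1 and cid not in used:
            mapping[cid] = cid
            used.add(cid)
    for cid in ids:
        if cid in mapping:
            continue
        for ch in pool:
            if ch not in used:
                mapping[cid] = ch
                used.add(ch)
                break
        else:
            raise ValueError("too many chains for PDB single-character chain ids")
    return mapping


def write_pdb(a: Assembly, path: str | Path) -> None:
    """Write standard fixed-width ATOM records (8.3 coordinates)."""
    idmap = _chain_id_map(a.chain_ids)
    lines = []
    if a.title:
        lines.append(f"TITLE     {a.title[:70]}")
    serial = 0
    for chain in a.chains:
        cid = idmap[chain.chain_id]
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                name = atom.name if len(atom.name) >= 4 else f" {atom.name}"
                x, y, z = atom.coords
                lines.append(
                    f"ATOM  {serial % 100000:5d} {name:<4s}{atom.altloc or ' '}"
                    f"{res.resname:>3s} {cid}{res.seqnum % 10000:4d}{res.icode or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
        serial += 1
        lines.append(f"TER   {serial % 100000:5d}      {chain.residues[-1].resname:>3s} {cid}"
                     f"{chain.residues[-1].seqnum % 10000:4d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
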
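"""Read and write PDB / mmCIF coordinate files into :class:`StructureModel`.

Parsing is delegated to gemmi; this module normalises its output to the
screen's conventions: first model only, hydrogens dropped, alternate
locations collapsed to the highest-occupancy conformer (ties broken by
altloc letter), waters retained but flagged.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, List, Optional, Set

import gemmi

from .model import (
    NO_GAMMA_CODES,
    NUCLEOTIDE_CODES,
    PURINE_RING_ATOMS,
    WATER_CODES,
    Atom,
    LigandInstance,
    Residue,
    StructureModel,
)

logger = logging.getLogger(__name__)


class StructureParseError(ValueError):
    """Raised for unreadable files or empty coordinate sections."""


def _detect_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".cif", ".mmcif"):
        return "mmcif"
    if ext in (".pdb", ".ent"):
        return "pdb"
    # fall back to sniffing the first bytes
    with open(path, "rb") as fh:
        head = fh.read(2048).decode("ascii", "replace")
    if head.lstrip().startswith("data_") or "_atom_site." in head:
        return "mmcif"
    return "pdb"


def _collapse_altlocs(atoms: List[Atom]) -> List[Atom]:
    """Keep one conformer per atom name: highest occupancy, then altloc order."""
    by_name: dict[str, Atom] = {}
    order: List[str] = []
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None:
            by_name[a.name] = a
            order.append(a.name)
        elif (a.occupancy, -ord(a.altloc or "~")) > (prev.occupancy, -ord(prev.altloc or "~")):
            by_name[a.name] = a
    return [by_name[n] for n in order]


def read_structure(path: str, format: str = "auto") -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Parameters
    ----------
    path:
        Coordinate file. ``format='auto'`` infers pdb/mmcif from the
        extension, falling back to content sniffing.

    Only model 1 is kept; hydrogens (and deuteriums) are excluded.
    """
    if not os.path.exists(path):
        raise StructureParseError(f"no such file: {path}")
    fmt = _detect_format(path) if format == "auto" else format
    if fmt not in ("pdb", "mmcif"):
        raise ValueError(f"unknown format {format!r}")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(path)
        else:
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if len(st) == 0 or sum(len(ch) for ch in st[0]) == 0:
        raise StructureParseError(f"{path}: empty coordinate section")
    st.setup_entities()

    entry_id = st.name.strip() or os.path.splitext(os.path.basename(path))[0]
    model = StructureModel(entry_id=entry_id, source_format=fmt)
    gmodel = st[0]  # first coordinate model only
    for chain in gmodel:
        for gres in chain:
            atoms = []
            for ga in gres:
                if ga.element.is_hydrogen:
                    continue
                atoms.append(
                    Atom(
                        name=ga.name,
                        element=ga.element.name,
                        position=[ga.pos.x, ga.pos.y, ga.pos.z],
                        altloc=(ga.altloc or "").strip("\x00"),
                        occupancy=min(max(ga.occ, 0.0), 1.0),
                    )
                )
            if not atoms:
                continue
            comp = gres.name.strip()
            if comp in WATER_CODES or gres.is_water():
                category = "water"
            elif gres.het_flag == "H":
                category = "ligand"
            else:
                category = "polymer"
            model.add_residue(
                Residue(
                    comp_id=comp,
                    seq_num=gres.seqid.num,
                    chain_id=chain.name,
                    icode=(gres.seqid.icode or "").strip(),
                    category=category,
                    atoms=_collapse_altlocs(atoms),
                )
            )
    return model


def write_structure(model: StructureModel, path: str, format: str = "auto") -> None:
    """Write *model* as PDB or mmCIF (used for synthetic fixtures)."""
    fmt = format
    if fmt == "auto":
        ext = os.path.splitext(path)[1].lower()
        fmt = "mmcif" if ext in (".cif", ".mmcif") else "pdb"
    st = gemmi.Structure()
    st.name = model.entry_id
    gmodel = gemmi.Model("1")
    for chain_id, residues in model.chains.items():
        gchain = gemmi.Chain(chain_id)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.comp_id
            gres.seqid = gemmi.SeqId(res.seq_num, res.icode or " ")
            gres.het_flag = "A" if res.category == "polymer" else "H"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.position)
                ga.occ = a.occupancy
                if a.altloc:
                    ga.altloc = a.altloc
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    if fmt == "pdb":
        st.write_pdb(path)
    elif fmt == "mmcif":
        st.make_mmcif_document().write_file(path)
    else:
        raise ValueError(f"unknown format {format!r}")


def extract_ligands(
    model: StructureModel, codes: Optional[Iterable[str]] = None
) -> List[LigandInstance]:
    """Enumerate adenine-nucleotide ligand instances in *model*.

    One :class:`LigandInstance` per non-polymer residue whose component code
    is in *codes* (default: the full supported nucleotide set). Instances
    missing every purine ring atom are excluded with a warning.
    """
    wanted: Set[str] = set(codes) if codes is not None else set(NUCLEOTIDE_CODES)
    unknown = wanted - NUCLEOTIDE_CODES
    if unknown:
        raise ValueError(f"unsupported nucleotide codes: {sorted(unknown)}")
    out: List[LigandInstance] = []
    for res in model.residues():
        if res.category != "ligand" or res.comp_id not in wanted:
            continue
        ring = [res.atom(n) for n in PURINE_RING_ATOMS]
        ring = [a for a in ring if a is not None]
        if not ring:
            logger.warning(
                "%s: ligand %s/%s%s has no purine ring atoms; excluded",
                model.entry_id, res.comp_id, res.chain_id, res.seq_num,
            )
            continue
        pg = None if res.comp_id in NO_GAMMA_CODES else res.atom("PG")
        out.append(
            LigandInstance(
                residue=res,
                comp_id=res.comp_id,
                purine_ring_atoms=ring,
                c5=res.atom("C5"),
                pg=pg,
            )
        )
    out.sort(key=lambda li: (li.residue.chain_id, li.residue.seq_num, li.residue.icode))
    return out
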
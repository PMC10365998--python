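"""Core atomic data model shared by all pipeline stages.

A :class:`StructureModel` is a minimal chain -> residue -> atom hierarchy
holding only what the geometric screen and the superposition stages need:
author residue numbering, heavy-atom coordinates, and a polymer / ligand /
water category per residue. Only the first coordinate model of multi-model
files is represented and hydrogens are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

#: Adenine-nucleotide component codes recognised by the ligand registry.
#: ANP/ACP/APC/ZAN/AGS are the five non-hydrolyzable ATP analogs; ADP and
#: AMP are admitted only in the criterion-1-only screening mode.
NUCLEOTIDE_CODES = frozenset({"ATP", "ANP", "ACP", "APC", "ZAN", "AGS", "ADP", "AMP"})

#: Codes lacking a gamma-phosphate (no PG atom by construction).
NO_GAMMA_CODES = frozenset({"ADP", "AMP"})

#: The nine purine ring atoms of an adenine moiety, PDB naming.
PURINE_RING_ATOMS = ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6")

WATER_CODES = frozenset({"HOH", "WAT", "DOD", "H2O"})


@dataclass
class Atom:
    """A heavy atom with PDB-convention name and Cartesian position in Å."""

    name: str
    element: str
    position: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be 3 finite components")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    """One residue (polymer monomer, ligand, or water) with its atoms."""

    comp_id: str
    seq_num: int
    chain_id: str
    icode: str = ""
    category: str = "polymer"  # polymer | ligand | water
    atoms: List[Atom] = field(default_factory=list)

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.chain_id, self.seq_num, self.icode, self.comp_id)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self, names) -> Optional[np.ndarray]:
        """Stacked positions for *names*, or None if any atom is missing."""
        rows = []
        for n in names:
            a = self.atom(n)
            if a is None:
                return None
            rows.append(a.position)
        return np.vstack(rows)


@dataclass
class StructureModel:
    """Parsed atomic structure: ordered chains of residues, one model."""

    entry_id: str
    chains: Dict[str, List[Residue]] = field(default_factory=dict)
    source_format: str = "pdb"

    def add_residue(self, res: Residue) -> None:
        self.chains.setdefault(res.chain_id, []).append(res)

    def residues(self, category: Optional[str] = None) -> Iterator[Residue]:
        for reslist in self.chains.values():
            for res in reslist:
                if category is None or res.category == category:
                    yield res

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a rigid-transformed deep copy (x -> R x + t)."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        out = StructureModel(self.entry_id, {}, self.source_format)
        for res in self.residues():
            new = Residue(res.comp_id, res.seq_num, res.chain_id, res.icode, res.category)
            for a in res.atoms:
                new.atoms.append(
                    Atom(a.name, a.element, R @ a.position + t, a.altloc, a.occupancy)
                )
            out.add_residue(new)
        return out


@dataclass
class LigandInstance:
    """One adenine-nucleotide residue with its screen-relevant atoms resolved.

    ``c5`` anchors the adenine-ring distance criterion and ``pg`` the
    gamma-phosphate criterion; ``pg`` is absent for ADP/AMP by definition.
    """

    residue: Residue
    comp_id: str
    purine_ring_atoms: List[Atom]
    c5: Optional[Atom]
    pg: Optional[Atom]

    def __post_init__(self) -> None:
        if self.comp_id not in NUCLEOTIDE_CODES:
            raise ValueError(f"unsupported nucleotide code {self.comp_id!r}")
        if self.comp_id in NO_GAMMA_CODES and self.pg is not None:
            raise ValueError(f"{self.comp_id} cannot carry a gamma-phosphate PG atom")

    @property
    def label(self) -> str:
        r = self.residue
        return f"{self.comp_id}/{r.chain_id}{r.seq_num}{r.icode}".strip()

    def heavy_atom_coords(self) -> np.ndarray:
        return np.vstack([a.position for a in self.residue.atoms])

    def purine_coords(self) -> np.ndarray:
        return np.vstack([a.position for a in self.purine_ring_atoms])
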
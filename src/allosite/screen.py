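"""Geometric screen for the cross-subunit aromatic-sandwich ATP binding mode.

Two distance criteria drive the screen: (1) adenine C5 to the CG gamma-carbon
of paired aromatic residues (Tyr/Trp/Phe/His) within 5 Å, and (2) the
gamma-phosphate phosphorus PG to an arginine CZ within 5 Å. On top of these,
hits are triaged into tiers: a paired aromatic contact (T1), the pair drawn
from two different chains (T2), both pair members pi-stacked against the
adenine ring (T3), and finally an Arg-gamma-phosphate contact completing the
full sandwich mode (T4). Stacking is assessed by ring-centroid distance and
interplanar angle between least-squares ring planes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import LigandInstance, Residue, StructureModel
from .structure_io import StructureParseError, extract_ligands, read_structure

logger = logging.getLogger(__name__)

#: Aromatic side-chain ring atom names (heavy atoms only).
RING_ATOMS = {
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    # Trp uses the full 9-atom bicyclic system for centroid and plane.
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}

FULL_MODE_CODES = ("ATP", "ANP", "ACP", "APC", "ZAN", "AGS")
CRITERION1_EXTRA_CODES = ("ADP", "AMP")

TIER_ORDER = {None: 0, "T1_pair_contact": 1, "T2_cross_subunit": 2,
              "T3_dual_stacking": 3, "T4_full": 4}


@dataclass(frozen=True)
class ScreenCriteria:
    """Cutoffs and atom anchors for the two distance criteria plus stacking."""

    d_aromatic: float = 5.0
    d_arg: float = 5.0
    aromatic_set: frozenset = frozenset({"TYR", "TRP", "PHE", "HIS"})
    aromatic_anchor_atom: str = "CG"
    adenine_anchor_atom: str = "C5"
    gamma_atom: str = "PG"
    arg_anchor_atom: str = "CZ"
    stacking_centroid_max: float = 5.0
    stacking_angle_max: float = 30.0

    def __post_init__(self):
        for name in ("d_aromatic", "d_arg", "stacking_centroid_max", "stacking_angle_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class AromaticContact:
    """An aromatic residue whose CG lies within the cutoff of adenine C5."""

    residue: Residue
    chain_id: str
    distance_c5_cg: float
    stacked: bool = False
    stacking_angle: Optional[float] = None
    centroid_distance: Optional[float] = None
    no_stack_reason: Optional[str] = None

    @property
    def label(self) -> str:
        return f"{self.residue.comp_id}{self.residue.seq_num}:{self.chain_id}"


@dataclass
class BindingModeHit:
    entry_id: str
    ligand: LigandInstance
    aromatic_pair: Tuple[AromaticContact, AromaticContact]
    cross_subunit: bool
    n_stacked: int
    arg_contacts: List[Tuple[Residue, float]]
    tier: str


class CriterionInapplicableError(ValueError):
    """The ligand lacks the atom a criterion is anchored on."""


def _lsq_plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through >=3 points."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[-1]


def find_aromatic_contacts(
    model: StructureModel, ligand: LigandInstance, criteria: ScreenCriteria = ScreenCriteria()
) -> List[AromaticContact]:
    """Criterion 1: aromatic residues with CG within ``d_aromatic`` of adenine C5.

    Returns contacts sorted by distance (ties by chain, residue number).
    Polymer residues only; aromatics lacking a CG atom are skipped with a
    warning.
    """
    if ligand.c5 is None:
        raise CriterionInapplicableError(
            f"ligand {ligand.label} has no {criteria.adenine_anchor_atom} atom"
        )
    c5 = ligand.c5.position
    contacts: List[AromaticContact] = []
    for res in model.residues("polymer"):
        if res.comp_id not in criteria.aromatic_set:
            continue
        cg = res.atom(criteria.aromatic_anchor_atom)
        if cg is None:
            logger.warning(
                "%s %s%s lacks atom %s; skipped",
                res.comp_id, res.chain_id, res.seq_num, criteria.aromatic_anchor_atom,
            )
            continue
        d = float(np.linalg.norm(cg.position - c5))
        if d <= criteria.d_aromatic:
            contacts.append(AromaticContact(res, res.chain_id, d))
    contacts.sort(key=lambda c: (c.distance_c5_cg, c.chain_id, c.residue.seq_num))
    return contacts


def find_arginine_gamma_contacts(
    model: StructureModel, ligand: LigandInstance, criteria: ScreenCriteria = ScreenCriteria()
) -> List[Tuple[Residue, float]]:
    """Criterion 2: arginines with CZ within ``d_arg`` of the gamma-phosphate PG.

    Empty for ligands without a gamma-phosphate (ADP/AMP mode).
    """
    if ligand.pg is None:
        return []
    pg = ligand.pg.position
    out: List[Tuple[Residue, float]] = []
    for res in model.residues("polymer"):
        if res.comp_id != "ARG":
            continue
        cz = res.atom(criteria.arg_anchor_atom)
        if cz is None:
            continue
        d = float(np.linalg.norm(cz.position - pg))
        if d <= criteria.d_arg:
            out.append((res, d))
    out.sort(key=lambda t: (t[1], t[0].chain_id, t[0].seq_num))
    return out


def assess_stacking(
    ligand: LigandInstance, contact: AromaticContact,
    criteria: ScreenCriteria = ScreenCriteria(),
) -> AromaticContact:
    """Judge pi-stacking of the contact's ring against the adenine ring.

    Stacked iff ring-centroid distance <= ``stacking_centroid_max`` and the
    interplanar angle (between least-squares planes, folded into [0, 90]
    degrees) <= ``stacking_angle_max``.
    """
    ring_names = RING_ATOMS.get(contact.residue.comp_id)
    if ring_names is None:
        return replace(contact, stacked=False, no_stack_reason="not aromatic")
    ring = contact.residue.coords(ring_names)
    if ring is None:
        return replace(contact, stacked=False, no_stack_reason="missing ring atoms")
    if len(ligand.purine_ring_atoms) < 3:
        return replace(contact, stacked=False, no_stack_reason="incomplete purine ring")
    purine = ligand.purine_coords()
    centroid_d = float(np.linalg.norm(ring.mean(axis=0) - purine.mean(axis=0)))
    cosang = abs(float(np.dot(_lsq_plane_normal(ring), _lsq_plane_normal(purine))))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    stacked = (centroid_d <= criteria.stacking_centroid_max
               and angle <= criteria.stacking_angle_max)
    return replace(
        contact, stacked=stacked, stacking_angle=angle, centroid_distance=centroid_d,
        no_stack_reason=None if stacked else "geometry outside cutoffs",
    )


def _pair_tier(a: AromaticContact, b: AromaticContact,
               arg_contacts: Sequence, has_pg: bool) -> str:
    cross = a.chain_id != b.chain_id
    if not cross:
        return "T1_pair_contact"
    if not (a.stacked and b.stacked):
        return "T2_cross_subunit"
    if arg_contacts and has_pg:
        return "T4_full"
    return "T3_dual_stacking"


def classify_site(
    contacts: Sequence[AromaticContact],
    arg_contacts: Sequence[Tuple[Residue, float]],
    ligand: LigandInstance,
    entry_id: str = "",
) -> Optional[BindingModeHit]:
    """Assign a tier to one ligand site, or None with fewer than 2 contacts.

    All aromatic pairs are evaluated; the site's tier is the best tier any
    pair achieves, and among pairs achieving it the one with the smallest
    summed C5-CG distance is reported. This keeps the tier monotone under
    cutoff changes: tightening a cutoff only removes candidate pairs.
    """
    if len(contacts) < 2:
        return None
    best: Optional[Tuple[int, float, AromaticContact, AromaticContact]] = None
    for a, b in combinations(contacts, 2):
        if a.residue.key == b.residue.key:
            continue
        tier = _pair_tier(a, b, arg_contacts, ligand.pg is not None)
        rank = TIER_ORDER[tier]
        summed = a.distance_c5_cg + b.distance_c5_cg
        if best is None or (rank, -summed) > (best[0], -best[1]):
            best = (rank, summed, a, b)
    if best is None:
        return None
    rank, _, a, b = best
    tier = {1: "T1_pair_contact", 2: "T2_cross_subunit",
            3: "T3_dual_stacking", 4: "T4_full"}[rank]
    pair = tuple(sorted((a, b), key=lambda c: (c.chain_id, c.residue.seq_num)))
    return BindingModeHit(
        entry_id=entry_id,
        ligand=ligand,
        aromatic_pair=pair,  # type: ignore[arg-type]
        cross_subunit=a.chain_id != b.chain_id,
        n_stacked=int(a.stacked) + int(b.stacked),
        arg_contacts=list(arg_contacts),
        tier=tier,
    )


def screen_model(
    model: StructureModel,
    criteria: ScreenCriteria = ScreenCriteria(),
    mode: str = "full",
) -> List[dict]:
    """Screen every nucleotide ligand instance of one structure.

    Returns one record per ligand instance (tier None when the site does not
    reach T1). ``mode='criterion1_only'`` admits ADP/AMP and skips the
    arginine criterion, so T4 is unreachable.
    """
    if mode not in ("full", "criterion1_only"):
        raise ValueError(f"unknown screen mode {mode!r}")
    codes = set(FULL_MODE_CODES)
    if mode == "criterion1_only":
        codes |= set(CRITERION1_EXTRA_CODES)
    rows = []
    for lig in extract_ligands(model, codes):
        if lig.c5 is None:
            logger.warning("%s: ligand %s lacks C5; skipped", model.entry_id, lig.label)
            continue
        contacts = [
            assess_stacking(lig, c, criteria)
            for c in find_aromatic_contacts(model, lig, criteria)
        ]
        args = ([] if mode == "criterion1_only"
                else find_arginine_gamma_contacts(model, lig, criteria))
        hit = classify_site(contacts, args, lig, model.entry_id)
        rows.append(_hit_record(model.entry_id, lig, hit))
    return rows


def _hit_record(entry_id: str, lig: LigandInstance, hit: Optional[BindingModeHit]) -> dict:
    rec = {
        "entry_id": entry_id,
        "ligand_comp": lig.comp_id,
        "ligand_chain": lig.residue.chain_id,
        "ligand_seq": lig.residue.seq_num,
        "tier": hit.tier if hit else "none",
        "aromatic1": "", "aromatic2": "", "d1": np.nan, "d2": np.nan,
        "cross_subunit": bool(hit.cross_subunit) if hit else False,
        "n_stacked": hit.n_stacked if hit else 0,
        "arg_list": "",
    }
    if hit is not None:
        a, b = hit.aromatic_pair
        rec.update(
            aromatic1=a.label, aromatic2=b.label,
            d1=round(a.distance_c5_cg, 3), d2=round(b.distance_c5_cg, 3),
            arg_list=";".join(
                f"ARG{r.seq_num}:{r.chain_id}@{d:.2f}" for r, d in hit.arg_contacts
            ),
        )
    return rec


@dataclass
class HitTable:
    """Per-ligand screen rows plus per-tier summary counts."""

    table: pd.DataFrame
    errors: List[dict] = field(default_factory=list)

    @property
    def tier_counts(self) -> dict:
        counts = {t: 0 for t in ("none", "T1_pair_contact", "T2_cross_subunit",
                                 "T3_dual_stacking", "T4_full")}
        if len(self.table):
            counts.update(self.table["tier"].value_counts().to_dict())
        return counts

    def entry_tiers(self) -> pd.Series:
        """Max tier per entry (a structure's tier is the best over its ligands)."""
        if not len(self.table):
            return pd.Series(dtype=object)
        ranked = self.table.assign(
            _r=self.table["tier"].map(lambda t: TIER_ORDER.get(None if t == "none" else t, 0))
        )
        idx = ranked.groupby("entry_id")["_r"].idxmax()
        return self.table.loc[idx].set_index("entry_id")["tier"]

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary_json(self) -> str:
        return json.dumps(
            {"n_sites": int(len(self.table)),
             "n_entries": int(self.table["entry_id"].nunique()) if len(self.table) else 0,
             "tier_counts_sites": self.tier_counts,
             "tier_counts_entries": (self.entry_tiers().value_counts().to_dict()
                                     if len(self.table) else {}),
             "n_errors": len(self.errors)},
            indent=2, sort_keys=True,
        )


COLUMNS = ["entry_id", "ligand_comp", "ligand_chain", "ligand_seq", "tier",
           "aromatic1", "aromatic2", "d1", "d2", "cross_subunit", "n_stacked", "arg_list"]


def screen_library(
    paths: Iterable[str],
    criteria: ScreenCriteria = ScreenCriteria(),
    mode: str = "full",
) -> HitTable:
    """Screen a library of structure files; unreadable files become error rows."""
    rows: List[dict] = []
    errors: List[dict] = []
    for path in paths:
        try:
            model = read_structure(path)
        except StructureParseError as exc:
            errors.append({"path": str(path), "error": str(exc)})
            logger.warning("skipping %s: %s", path, exc)
            continue
        rows.extend(screen_model(model, criteria, mode))
    df = pd.DataFrame(rows, columns=COLUMNS)
    if len(df):
        df = df.sort_values(
            ["entry_id", "ligand_chain", "ligand_seq"], kind="mergesort"
        ).reset_index(drop=True)
    return HitTable(table=df, errors=errors)
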
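"""Ground-truth-labelled synthetic fixtures: binding-site structures and
sequence families.

Structures: a minimal one- or two-chain model around an idealised
adenine-nucleotide ligand (planar purine, standard 1.4 Å ring bonds, a PA/PB/PG
phosphate chain). Aromatic side chains are placed so the requested C5–CG
distance, ring interplanar angle and centroid height above the purine plane
are realised exactly, and an arginine CZ is set at the requested distance
from PG. Decoy modes violate one screen criterion each, so the intended
screen tier is known by construction and recorded in a sidecar label.

Sequences: phosphoketolase-like families derived from a random reference
with the eight-anchor motif planted at a controlled prevalence and identity
band; per-sequence labels are returned alongside the FASTA records.

Scaffold residues are glycine (no CG atom) to avoid accidental aromatic
contacts; nothing here aims at physical realism beyond what the geometric
screen measures.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import Atom, LigandInstance, Residue, StructureModel
from .motif import MotifSpec, RA_ANCHOR_INDEX, scan_sequence
from .structure_io import write_structure

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# ---------------------------------------------------------------------------
# idealised ring geometry


def _hexagon(radius: float = 1.39) -> np.ndarray:
    ang = np.radians(np.arange(6) * 60.0)
    return np.stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)], axis=1)


def _fused_pentagon(p_a: np.ndarray, p_b: np.ndarray, away_from: np.ndarray) -> np.ndarray:
    """Three remaining vertices of a regular pentagon sharing edge (p_a, p_b),
    built on the side of the edge facing away from *away_from*."""
    s = np.linalg.norm(p_b - p_a)
    apothem = s / (2 * math.tan(math.pi / 5))
    mid = 0.5 * (p_a + p_b)
    out_dir = mid - away_from
    out_dir = out_dir / np.linalg.norm(out_dir)
    center = mid + apothem * out_dir
    # rotate p_b around center in the direction leading away from p_a
    def rot(v, theta):
        c, s_ = math.cos(theta), math.sin(theta)
        return np.array([c * v[0] - s_ * v[1], s_ * v[0] + c * v[1], v[2]])

    va, vb = p_a - center, p_b - center
    step = 2 * math.pi / 5
    # choose rotation sign that moves vb away from va
    if np.linalg.norm(rot(vb, step) - va) > np.linalg.norm(rot(vb, -step) - va):
        sgn = 1.0
    else:
        sgn = -1.0
    return np.stack([center + rot(vb, sgn * step * k) for k in (1, 2, 3)])


def adenine_coords() -> Dict[str, np.ndarray]:
    """Idealised planar adenine (purine) heavy-atom coordinates, z = 0."""
    hexv = _hexagon()
    names6 = ["N1", "C2", "N3", "C4", "C5", "C6"]
    coords = {n: hexv[i] for i, n in enumerate(names6)}
    # imidazole ring fused on the C4-C5 edge: C4-N9-C8-N7-C5
    pent = _fused_pentagon(coords["C5"], coords["C4"], np.zeros(3))
    coords["N9"], coords["C8"], coords["N7"] = pent[2], pent[1], pent[0]
    # exocyclic amine off C6
    coords["N6"] = coords["C6"] * (1 + 1.35 / np.linalg.norm(coords["C6"]))
    return coords


RING_TEMPLATES: Dict[str, Tuple[Tuple[str, ...], np.ndarray]] = {}


def _ring_template(comp: str) -> Tuple[Tuple[str, ...], np.ndarray]:
    """(names, centred planar coordinates) for an aromatic side-chain ring."""
    if comp in RING_TEMPLATES:
        return RING_TEMPLATES[comp]
    if comp in ("TYR", "PHE"):
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        coords = _hexagon()
    elif comp == "HIS":
        names = ("CG", "ND1", "CE1", "NE2", "CD2")
        r5 = 1.39 / (2 * math.sin(math.pi / 5))
        ang = np.radians(np.arange(5) * 72.0)
        coords = np.stack([r5 * np.cos(ang), r5 * np.sin(ang), np.zeros(5)], axis=1)
    elif comp == "TRP":
        # pentagon CG-CD1-NE1-CE2-CD2 fused to hexagon CD2-CE2-CZ2-CH2-CZ3-CE3
        r5 = 1.39 / (2 * math.sin(math.pi / 5))
        ang = np.radians(np.arange(5) * 72.0)
        pent = np.stack([r5 * np.cos(ang), r5 * np.sin(ang), np.zeros(5)], axis=1)
        p = {n: pent[i] for i, n in enumerate(("CG", "CD1", "NE1", "CE2", "CD2"))}
        # build the fused hexagon on the CD2-CE2 edge
        mid = 0.5 * (p["CE2"] + p["CD2"])
        out = mid / np.linalg.norm(mid)
        a6 = 1.39 * math.sqrt(3) / 2
        c6 = mid + a6 * out
        names = ("CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2")
        def rot(v, theta):
            c, s_ = math.cos(theta), math.sin(theta)
            return np.array([c * v[0] - s_ * v[1], s_ * v[0] + c * v[1], v[2]])
        vb = p["CD2"] - c6
        va = p["CE2"] - c6
        step = math.pi / 3
        sgn = 1.0 if np.linalg.norm(rot(vb, step) - va) > np.linalg.norm(rot(vb, -step) - va) else -1.0
        extra = [c6 + rot(vb, sgn * step * k) for k in (1, 2, 3)]  # CE3, CZ3, CH2
        vz2 = c6 + rot(va, -sgn * step)  # CZ2 adjacent to CE2
        coords = np.stack([p["CG"], p["CD1"], p["NE1"], p["CE2"], p["CD2"],
                           extra[0], extra[1], extra[2], vz2])
    else:
        raise ValueError(f"no ring template for {comp}")
    coords = coords - coords.mean(axis=0)
    RING_TEMPLATES[comp] = (names, coords)
    return RING_TEMPLATES[comp]


# ---------------------------------------------------------------------------
# structural fixture design


@dataclass(frozen=True)
class AromaticPlacement:
    comp_id: str = "TYR"
    chain_id: str = "A"
    d_c5_cg: float = 4.0
    interplanar_angle: float = 0.0   # degrees
    centroid_offset: float = 3.5     # Å above/below the purine plane


@dataclass(frozen=True)
class SiteGeometry:
    """Design parameters for one synthetic binding-site fixture."""

    aromatic1: AromaticPlacement = AromaticPlacement("HIS", "A", 4.0, 0.0, 3.5)
    aromatic2: Optional[AromaticPlacement] = AromaticPlacement("TYR", "B", 4.2, 0.0, 3.5)
    arginine_present: bool = True
    d_pg_cz: float = 3.8
    arginine_chain: str = "B"
    ligand_code: str = "ANP"
    decoy_mode: str = "none"
    seed: int = 0
    entry_id: str = "SYN1"


DECOY_MODES = ("none", "far_aromatic", "single_aromatic", "same_chain",
               "no_stacking", "no_arginine")


def _place_ring(
    placement: AromaticPlacement,
    c5: np.ndarray,
    purine_centroid: np.ndarray,
    side: float,
) -> Dict[str, np.ndarray]:
    """Realise (d_c5_cg, interplanar angle, centroid height) exactly.

    The ring is tilted about an in-plane axis by the requested angle, its
    centroid held at the requested height above (side=+1) or below (side=-1)
    the purine plane, and slid along the C5 -> purine-centroid direction
    until the CG-C5 distance matches the request.
    """
    names, local = _ring_template(placement.comp_id)
    rho = float(np.linalg.norm(local[0]))  # centroid-to-CG radius
    theta = math.radians(placement.interplanar_angle)
    h = side * placement.centroid_offset
    # tilt the ring so CG leans toward the purine plane, maximising reach
    theta_eff = -theta if h > 0 else theta

    # horizontal slide axis: from C5 toward the purine centroid (keeps the
    # ring over the purine so genuinely-close placements also stack)
    ax = purine_centroid - c5
    ax[2] = 0.0
    n_ax = np.linalg.norm(ax)
    ax = ax / n_ax if n_ax > 1e-9 else np.array([1.0, 0.0, 0.0])
    ay = np.array([-ax[1], ax[0], 0.0])
    az = np.array([0.0, 0.0, 1.0])
    frame = np.stack([ax, ay, az], axis=1)  # columns are the local axes

    # tilt about the ay axis; CG vertex points along -ax (toward C5)
    def world(u: float) -> Dict[str, np.ndarray]:
        ct, st = math.cos(theta_eff), math.sin(theta_eff)
        tilt = np.array([[ct, 0.0, st], [0.0, 1.0, 0.0], [-st, 0.0, ct]])
        spin = np.array([[-1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, 1.0]])
        R = frame @ tilt @ spin
        center = c5 + u * ax + np.array([0.0, 0.0, h])
        return {n: center + R @ v for n, v in zip(names, local)}

    def f(u: float) -> float:
        return float(np.linalg.norm(world(u)["CG"] - c5)) - placement.d_c5_cg

    # |CG - C5| is V-shaped in u with its minimum where CG sits directly
    # over C5; of the two roots, keep the one that leaves the ring centroid
    # nearest the purine centroid (better stacking for genuinely close sites)
    u_min = rho * math.cos(theta)
    if f(u_min) > 0:
        raise ValueError(
            f"cannot realise d_c5_cg={placement.d_c5_cg} with "
            f"offset {placement.centroid_offset} and angle {placement.interplanar_angle}"
        )
    half_width = placement.d_c5_cg + 8.0
    roots = [brentq(f, u_min, u_min + half_width, xtol=1e-8)]
    if f(u_min - half_width) > 0:
        roots.append(brentq(f, u_min - half_width, u_min, xtol=1e-8))

    def centroid_dist(u: float) -> float:
        ring = world(u)
        cen = np.mean(list(ring.values()), axis=0)
        return float(np.linalg.norm(cen - purine_centroid))

    u_star = min(roots, key=centroid_dist)
    return world(u_star)


def _backbone(anchor: np.ndarray, away: np.ndarray) -> Dict[str, np.ndarray]:
    """Cheap backbone stubs strung outward from a side-chain anchor."""
    d = away / np.linalg.norm(away)
    perp = np.array([-d[1], d[0], 0.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.array([1.0, 0.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    return {
        "CB": anchor + 1.5 * d,
        "CA": anchor + 3.0 * d,
        "N": anchor + 3.0 * d + 1.4 * perp,
        "C": anchor + 4.4 * d,
        "O": anchor + 4.4 * d + 1.2 * perp,
    }


_ELEMENT = {"N": "N", "O": "O", "P": "P", "S": "S"}


def _elem(atom_name: str) -> str:
    return _ELEMENT.get(atom_name[0], "C")


def _residue(comp: str, seq: int, chain: str, coords: Dict[str, np.ndarray],
             category: str = "polymer") -> Residue:
    res = Residue(comp_id=comp, seq_num=seq, chain_id=chain, category=category)
    for name, pos in coords.items():
        res.atoms.append(Atom(name=name, element=_elem(name), position=pos))
    return res


def make_binding_site_structure(geom: SiteGeometry) -> Tuple[StructureModel, dict]:
    """Emit a minimal fixture realising *geom*, plus its ground-truth label.

    The label records the intended screen tier (derived from the planted
    parameters and the default 5 Å / 30° cutoffs), every planted distance,
    and the realised coordinates' key measurements.
    """
    if geom.decoy_mode not in DECOY_MODES:
        raise ValueError(f"unknown decoy_mode {geom.decoy_mode!r}")
    for p in (geom.aromatic1, geom.aromatic2):
        if p is not None and (p.d_c5_cg <= 0 or p.centroid_offset <= 0):
            raise ValueError("distances must be positive")
    if geom.arginine_present and geom.d_pg_cz <= 0:
        raise ValueError("d_pg_cz must be positive")

    ade = adenine_coords()
    purine = np.stack([ade[n] for n in ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6")])
    pcen = purine.mean(axis=0)
    c5 = ade["C5"]

    model = StructureModel(entry_id=geom.entry_id, source_format="pdb")

    # ligand: adenine + ribose stub + phosphate chain (PG only for triphosphates)
    n9 = ade["N9"]
    outward = n9 - pcen
    outward = outward / np.linalg.norm(outward)
    lig = dict(ade)
    lig["C1'"] = n9 + 1.47 * outward
    chain_dir = outward
    lig["PA"] = n9 + 4.5 * chain_dir
    if geom.ligand_code not in ("AMP",):
        lig["PB"] = n9 + 7.4 * chain_dir
    if geom.ligand_code not in ("ADP", "AMP"):
        lig["PG"] = n9 + 10.3 * chain_dir
    model.add_residue(_residue(geom.ligand_code, 901, "A", lig, category="ligand"))

    placements = [("arom1", geom.aromatic1, +1.0, 706)]
    if geom.aromatic2 is not None:
        placements.append(("arom2", geom.aromatic2, -1.0, 710))
    realized: Dict[str, float] = {}
    for key, plc, side, seqnum in placements:
        ring = _place_ring(plc, c5, pcen, side)
        away = ring["CG"] - pcen
        away = away / np.linalg.norm(away)
        coords = dict(ring)
        coords.update(_backbone(ring["CG"], away))
        model.add_residue(_residue(plc.comp_id, seqnum, plc.chain_id, coords))
        ring_coords = np.stack([v for n, v in ring.items()])
        realized[f"{key}_d_c5_cg"] = float(np.linalg.norm(ring["CG"] - c5))
        realized[f"{key}_centroid_distance"] = float(
            np.linalg.norm(ring_coords.mean(axis=0) - pcen)
        )
        realized[f"{key}_angle"] = plc.interplanar_angle

    if geom.arginine_present and "PG" in lig:
        pg = lig["PG"]
        d = chain_dir
        cz = pg + geom.d_pg_cz * d
        coords = {
            "CZ": cz,
            "NH1": cz + 1.3 * np.array([0.3, 0.9, 0.0]),
            "NH2": cz + 1.3 * np.array([0.3, -0.9, 0.0]),
            "NE": cz + 1.3 * d,
            "CD": cz + 2.7 * d,
        }
        coords.update(_backbone(cz + 2.7 * d, d))
        model.add_residue(_residue("ARG", 711, geom.arginine_chain, coords))
        realized["d_pg_cz"] = float(np.linalg.norm(cz - pg))

    # poly-glycine scaffold, well away from the site
    for chain_id, x0 in (("A", -25.0), ("B", 25.0)):
        if chain_id not in model.chains and chain_id not in ("A", "B"):
            continue
        for i in range(4):
            base = np.array([x0, 4.0 * i, 10.0])
            model.add_residue(
                _residue("GLY", i + 1, chain_id,
                         {"N": base, "CA": base + [0.0, 1.2, 0.8],
                          "C": base + [0.0, 2.4, 0.0], "O": base + [1.1, 2.9, 0.0]})
            )
    # keep residues sorted within chains for deterministic output
    for chain_id in model.chains:
        model.chains[chain_id].sort(key=lambda r: (r.category == "ligand", r.seq_num))

    label = {
        "entry_id": geom.entry_id,
        "decoy_mode": geom.decoy_mode,
        "ligand_code": geom.ligand_code,
        "seed": geom.seed,
        "tier": expected_tier(geom, realized),
        "planted": {
            "aromatic1": geom.aromatic1.__dict__ if geom.aromatic1 else None,
            "aromatic2": geom.aromatic2.__dict__ if geom.aromatic2 else None,
            "arginine_present": geom.arginine_present,
            "d_pg_cz": geom.d_pg_cz if geom.arginine_present else None,
        },
        "realized": realized,
    }
    return model, label


def expected_tier(geom: SiteGeometry, realized: Dict[str, float],
                  d_cut: float = 5.0, cen_cut: float = 5.0,
                  ang_cut: float = 30.0) -> str:
    """Ground-truth tier implied by the planted parameters (default cutoffs)."""
    arom = []
    for key, plc in (("arom1", geom.aromatic1), ("arom2", geom.aromatic2)):
        if plc is None:
            continue
        if plc.d_c5_cg <= d_cut:
            stacked = (plc.interplanar_angle <= ang_cut
                       and realized.get(f"{key}_centroid_distance", np.inf) <= cen_cut)
            arom.append((plc.chain_id, stacked))
    if len(arom) < 2:
        return "none"
    cross = arom[0][0] != arom[1][0]
    if not cross:
        return "T1_pair_contact"
    if not (arom[0][1] and arom[1][1]):
        return "T2_cross_subunit"
    has_arg = (geom.arginine_present and geom.d_pg_cz <= d_cut
               and geom.ligand_code not in ("ADP", "AMP"))
    return "T4_full" if has_arg else "T3_dual_stacking"


def write_fixture(geom: SiteGeometry, outdir: str, basename: Optional[str] = None
                  ) -> Dict[str, str]:
    """Write one fixture as PDB + mmCIF + sidecar JSON label; return the paths."""
    os.makedirs(outdir, exist_ok=True)
    base = basename or geom.entry_id
    model, label = make_binding_site_structure(geom)
    paths = {
        "pdb": os.path.join(outdir, base + ".pdb"),
        "mmcif": os.path.join(outdir, base + ".cif"),
        "label": os.path.join(outdir, base + ".label.json"),
    }
    write_structure(model, paths["pdb"], "pdb")
    write_structure(model, paths["mmcif"], "mmcif")
    with open(paths["label"], "w") as fh:
        json.dump(label, fh, indent=2, sort_keys=True)
    return paths


def random_site_geometry(mode: str, rng: np.random.Generator, entry_id: str,
                         seed: int = 0) -> SiteGeometry:
    """Sample a fixture design for one decoy mode with jittered parameters."""
    def arom(chain: str, far: bool = False, tilted: bool = False) -> AromaticPlacement:
        comp = rng.choice(["TYR", "PHE", "HIS", "TRP"])
        offset = float(rng.uniform(3.3, 3.6))
        # keep the request feasible (the C5-CG distance cannot drop below the
        # centroid height minus the ring's reach) and close enough that the
        # ring centroid stays within stacking range of the purine centroid
        d = rng.uniform(5.6, 7.0) if far else rng.uniform(offset + 0.3, 4.5)
        ang = rng.uniform(55.0, 85.0) if tilted else rng.uniform(0.0, 18.0)
        return AromaticPlacement(str(comp), chain, float(d), float(ang), offset)

    arg_d = float(rng.uniform(3.3, 4.8))
    if mode == "none":
        g = SiteGeometry(arom("A"), arom("B"), True, arg_d, "B", "ANP", mode, seed, entry_id)
    elif mode == "far_aromatic":
        g = SiteGeometry(arom("A", far=True), arom("B", far=True), True, arg_d,
                         "B", "ANP", mode, seed, entry_id)
    elif mode == "single_aromatic":
        g = SiteGeometry(arom("A"), None, True, arg_d, "B", "ANP", mode, seed, entry_id)
    elif mode == "same_chain":
        g = SiteGeometry(arom("A"), arom("A"), True, arg_d, "B", "ANP", mode, seed, entry_id)
    elif mode == "no_stacking":
        g = SiteGeometry(arom("A", tilted=True), arom("B", tilted=True), True, arg_d,
                         "B", "ANP", mode, seed, entry_id)
    elif mode == "no_arginine":
        g = SiteGeometry(arom("A"), arom("B"), False, arg_d, "B", "ANP", mode, seed, entry_id)
    else:
        raise ValueError(f"unknown decoy mode {mode!r}")
    return g


def make_structure_library(
    n: int, outdir: str, seed: int = 0,
    modes: Sequence[str] = DECOY_MODES,
) -> pd.DataFrame:
    """Write *n* fixtures cycling through *modes*; return the label table."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        mode = modes[i % len(modes)]
        geom = random_site_geometry(mode, rng, f"SYN{i:04d}", seed)
        paths = write_fixture(geom, outdir)
        with open(paths["label"]) as fh:
            label = json.load(fh)
        # store paths relative to outdir so the label table is relocatable
        rel = {k: os.path.basename(p) for k, p in paths.items()}
        rows.append({"entry_id": geom.entry_id, "decoy_mode": mode,
                     "tier": label["tier"], **rel})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sequence families


@dataclass(frozen=True)
class FamilyDesign:
    """Design of a phosphoketolase-like synthetic sequence family."""

    n_sequences: int = 200
    length: int = 800
    identity_band: Tuple[float, float] = (70.0, 90.0)
    motif_prevalence: float = 0.75
    fungal_variant_fraction: float = 0.0
    anchor_start: int = 702      # 1-based position of the motif's P anchor
    seed: int = 0

    def __post_init__(self):
        if self.length < self.anchor_start + 51:
            raise ValueError("sequence length too short for the planted motif")
        if not 0.0 <= self.motif_prevalence <= 1.0:
            raise ValueError("motif_prevalence must be in [0, 1]")
        lo, hi = self.identity_band
        if not (0.0 < lo <= hi <= 100.0):
            raise ValueError("invalid identity band")


def _plant_motif(seq: List[str], start0: int, spec: MotifSpec, fungal: bool) -> None:
    for k, (off, allowed) in enumerate(spec.anchors):
        if fungal and k == RA_ANCHOR_INDEX:
            seq[start0 + off] = "K"
        else:
            seq[start0 + off] = sorted(allowed)[0]


def make_reference_sequence(design: FamilyDesign, spec: MotifSpec = MotifSpec()) -> str:
    """Random background sequence with the canonical motif planted."""
    rng = np.random.default_rng(design.seed)
    seq = list(rng.choice(list(AA20), size=design.length))
    start0 = design.anchor_start - 1
    _plant_motif(seq, start0, spec, fungal=False)
    _scrub_accidental_matches(seq, {start0}, spec)
    return "".join(seq)


def _scrub_accidental_matches(seq: List[str], keep_starts: set, spec: MotifSpec) -> None:
    """Destroy motif occurrences at starts not in *keep_starts*."""
    probe = MotifSpec(fungal_variant=True, spacer_slack=spec.spacer_slack,
                      anchors=spec.anchors)
    while True:
        extra = [m for m in scan_sequence("".join(seq), probe)
                 if (m.start - 1) not in keep_starts]
        if not extra:
            return
        for m in extra:
            seq[m.start - 1] = "A"  # break the leading P anchor


def make_sequence_family(
    design: FamilyDesign, spec: MotifSpec = MotifSpec()
) -> Tuple[List[Tuple[str, str]], pd.DataFrame, str]:
    """Generate a labelled family; returns (records, label table, reference).

    Motif-positive members keep every anchor column intact; negatives have
    the leading P anchor destroyed. Identity to the reference is controlled
    by mutating a per-sequence number of non-anchor positions drawn from the
    design band. Deterministic for a given seed.
    """
    rng = np.random.default_rng(design.seed)
    ref = make_reference_sequence(design, spec)
    start0 = design.anchor_start - 1
    anchor_cols = {start0 + off for off, _ in spec.anchors}
    free_cols = [i for i in range(design.length) if i not in anchor_cols]

    n_pos = int(round(design.n_sequences * design.motif_prevalence))
    n_fungal = int(round(n_pos * design.fungal_variant_fraction))

    records: List[Tuple[str, str]] = []
    rows = []
    for i in range(design.n_sequences):
        positive = i < n_pos
        fungal = positive and i < n_fungal
        target_ident = rng.uniform(*design.identity_band)
        n_mut = int(round((1.0 - target_ident / 100.0) * design.length))
        n_mut = min(n_mut, len(free_cols))
        seq = list(ref)
        muts = rng.choice(len(free_cols), size=n_mut, replace=False)
        for idx in muts:
            col = free_cols[idx]
            choices = [a for a in AA20 if a != ref[col]]
            seq[col] = choices[rng.integers(len(choices))]
        if positive:
            _plant_motif(seq, start0, spec, fungal)
            _scrub_accidental_matches(seq, {start0}, spec)
        else:
            seq[start0] = "A"  # break the leading P anchor
            _scrub_accidental_matches(seq, set(), spec)
        seq_id = f"syn{i:04d}|{'motif' if positive else 'nomotif'}"
        records.append((seq_id, "".join(seq)))
        rows.append({"sequence_id": seq_id, "motif_positive": positive,
                     "fungal_variant": fungal,
                     "target_identity": round(target_ident, 2),
                     "seed": design.seed})
    labels = pd.DataFrame(rows)
    return records, labels, ref


def write_fasta(records: Sequence[Tuple[str, str]], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in records:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
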
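"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from allosite import synthetic
from allosite.model import StructureModel
from allosite.screen import RING_ATOMS

MOTIF_OFFSETS = (0, 1, 4, 8, 9, 17, 19, 51)
MOTIF_RESIDUES = "PWHYRHRR"


def planted_motif_sequence(start: int = 702, length: int = 800,
                           background: str = "A") -> str:
    """Background sequence with the eight anchors planted at 1-based *start*."""
    seq = [background] * length
    for off, aa in zip(MOTIF_OFFSETS, MOTIF_RESIDUES):
        seq[start - 1 + off] = aa
    return "".join(seq)


def brute_force_motif_starts(seq: str, allow_k_at_ra: bool = False) -> list:
    """Window-by-window anchor check, independent of the scanner."""
    starts = []
    span = MOTIF_OFFSETS[-1] + 1
    for i in range(len(seq) - span + 1):
        ok = True
        for k, (off, aa) in enumerate(zip(MOTIF_OFFSETS, MOTIF_RESIDUES)):
            allowed = {aa}
            if k == 4 and allow_k_at_ra:
                allowed.add("K")
            if seq[i + off] not in allowed:
                ok = False
                break
        if ok:
            starts.append(i + 1)
    return starts


def brute_force_contacts(model: StructureModel, ligand, cutoff: float = 5.0):
    """O(n^2)-style scan over all polymer residues for C5-CG contacts."""
    c5 = ligand.c5.position
    out = []
    for res in model.residues("polymer"):
        if res.comp_id not in ("TYR", "TRP", "PHE", "HIS"):
            continue
        cg = res.atom("CG")
        if cg is None:
            continue
        d = math.dist(tuple(c5), tuple(cg.position))
        if d <= cutoff:
            out.append((res.chain_id, res.seq_num, round(d, 9)))
    return sorted(out, key=lambda t: t[2])


def brute_force_arg_contacts(model: StructureModel, ligand, cutoff: float = 5.0):
    if ligand.pg is None:
        return []
    pg = ligand.pg.position
    out = []
    for res in model.residues("polymer"):
        if res.comp_id != "ARG":
            continue
        cz = res.atom("CZ")
        if cz is None:
            continue
        d = math.dist(tuple(pg), tuple(cz.position))
        if d <= cutoff:
            out.append((res.chain_id, res.seq_num, round(d, 9)))
    return sorted(out, key=lambda t: t[2])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def t4_geometry() -> synthetic.SiteGeometry:
    """Default sandwich-site design: cross-chain His/Tyr, both stacked, Arg."""
    return synthetic.SiteGeometry()


@pytest.fixture
def t4_model(t4_geometry):
    model, label = synthetic.make_binding_site_structure(t4_geometry)
    return model, label
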
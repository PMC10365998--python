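"""Rigid-body Cα superposition (Kabsch) and inter-site distances.

Cα atoms are paired across two models by identical author residue identity
(chain, residue number, insertion code, component), superposed by the
Kabsch SVD solution with reflections excluded, and summarised as an RMSD —
the comparison used to show that nucleotide binding leaves the overall fold
essentially unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .model import LigandInstance, StructureModel


class InsufficientCorrespondenceError(ValueError):
    """Fewer than 3 matched Cα pairs."""


class DegenerateGeometryError(ValueError):
    """Point set collinear or otherwise rank-deficient."""


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # 3x3, proper (det = +1)
    translation: np.ndarray   # 3-vector, Å
    n_pairs: int
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def pair_calpha(a: StructureModel, b: StructureModel) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Match Cα atoms by identical (chain_id, seq_num, icode, comp_id).

    Unmatched residues are dropped silently; raises if fewer than 3 pairs
    remain.
    """
    bmap = {}
    for res in b.residues("polymer"):
        ca = res.atom("CA")
        if ca is not None:
            bmap[res.key] = ca.position
    pairs = []
    for res in a.residues("polymer"):
        ca = res.atom("CA")
        if ca is not None and res.key in bmap:
            pairs.append((ca.position, bmap[res.key]))
    if len(pairs) < 3:
        raise InsufficientCorrespondenceError(
            f"only {len(pairs)} matched Cα pairs (need >= 3)"
        )
    return pairs


def kabsch_superpose(pairs: List[Tuple[np.ndarray, np.ndarray]]) -> SuperpositionResult:
    """Least-squares optimal rotation + translation mapping mobile -> reference.

    ``pairs`` holds (reference, mobile) coordinate pairs. The rotation is the
    Kabsch SVD solution with the determinant sign corrected so no reflection
    is admitted; RMSD is over residual distances after the transform.
    """
    if len(pairs) < 3:
        raise InsufficientCorrespondenceError(f"need >= 3 pairs, got {len(pairs)}")
    P = np.asarray([p[0] for p in pairs], float)   # reference
    Q = np.asarray([p[1] for p in pairs], float)   # mobile
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2 or np.linalg.matrix_rank(Q0, tol=1e-8) < 2:
        raise DegenerateGeometryError("point set is collinear or degenerate")
    H = Q0.T @ P0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    resid = Q @ R.T + t - P
    rmsd = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, n_pairs=len(pairs), rmsd=rmsd)


def superpose_models(a: StructureModel, b: StructureModel) -> SuperpositionResult:
    """Pair Cα atoms of *a* (reference) and *b* (mobile), then superpose."""
    return kabsch_superpose(pair_calpha(a, b))


def site_distance(
    model: StructureModel, ligand_a: LigandInstance, ligand_b_code: str
) -> float:
    """Centroid distance (Å) from *ligand_a* to the nearest *ligand_b_code* residue.

    Used to measure how far the allosteric nucleotide sits from the
    catalytic cofactor (e.g. TPP).
    """
    ca = ligand_a.heavy_atom_coords().mean(axis=0)
    best: Optional[float] = None
    for res in model.residues():
        if res.comp_id != ligand_b_code or res.category == "polymer":
            continue
        cb = np.vstack([at.position for at in res.atoms]).mean(axis=0)
        d = float(np.linalg.norm(ca - cb))
        if best is None or d < best:
            best = d
    if best is None:
        raise ValueError(f"no residue with code {ligand_b_code!r} in {model.entry_id}")
    return best
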
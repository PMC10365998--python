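"""Positional scanner for the eight-anchor ATP-regulatory motif.

The motif PWx2Hx3YRx7HxRx31R fixes eight residue identities at offsets
(0, 1, 4, 8, 9, 17, 19, 51) from the leading proline: P, W, H, Y, R, H, R, R.
In the reference phosphoketolase these fall on residues 702, 703, 706, 710,
711, 719, 721 and 753. The fungal variant additionally admits K at the
arginine that contacts the reciprocal gamma-phosphate (offset 9). Scanning
uses exact spacing by default; an optional per-gap slack absorbs small
insertions between consecutive anchors.

The module also provides alignment-based percent identity (for the >=60 %
family filter) and a family-level prevalence survey.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner

#: (offset from the leading P, allowed residues) for the eight anchors.
CANONICAL_ANCHORS: Tuple[Tuple[int, frozenset], ...] = (
    (0, frozenset("P")),
    (1, frozenset("W")),
    (4, frozenset("H")),     # H_a
    (8, frozenset("Y")),     # Y'
    (9, frozenset("R")),     # R'_a — K allowed for fungi
    (17, frozenset("H")),    # H_b
    (19, frozenset("R")),    # R_b
    (51, frozenset("R")),    # R_c
)

#: Index of the R_a anchor (the one relaxed to {R, K} in the fungal variant).
RA_ANCHOR_INDEX = 4


@dataclass(frozen=True)
class MotifSpec:
    """The eight-anchor positional motif, optionally with the fungal R->K variant."""

    fungal_variant: bool = False
    spacer_slack: int = 0
    anchors: Tuple[Tuple[int, frozenset], ...] = CANONICAL_ANCHORS

    def __post_init__(self):
        if self.spacer_slack < 0:
            raise ValueError("spacer_slack must be non-negative")
        offsets = [o for o, _ in self.anchors]
        if offsets != sorted(set(offsets)):
            raise ValueError("anchor offsets must be strictly increasing")

    def allowed(self, k: int) -> frozenset:
        allowed = self.anchors[k][1]
        if self.fungal_variant and k == RA_ANCHOR_INDEX:
            allowed = allowed | {"K"}
        return allowed

    @property
    def span(self) -> int:
        return self.anchors[-1][0] + 1


@dataclass
class MotifMatch:
    """One located motif occurrence; positions are 1-based."""

    sequence_id: str
    start: int
    anchor_positions: List[int]
    anchor_residues: List[str]
    used_fungal_variant: bool = False


def _clean(seq: str) -> str:
    return seq.upper().rstrip("*")


def scan_sequence(
    seq: str, spec: MotifSpec = MotifSpec(), sequence_id: str = ""
) -> List[MotifMatch]:
    """Find every motif occurrence in an unaligned amino-acid sequence.

    Matches are reported for each distinct start position, left to right.
    ``X`` in the input never matches an anchor. With ``spacer_slack > 0``
    each inter-anchor gap may stretch by up to that many extra residues;
    the leftmost anchor placement is reported.
    """
    s = _clean(seq)
    n = len(s)
    matches: List[MotifMatch] = []
    offsets = [o for o, _ in spec.anchors]

    def place(start0: int) -> Optional[List[int]]:
        # greedy left-to-right with backtracking over per-gap stretch
        positions = [start0]
        if s[start0] not in spec.allowed(0):
            return None

        def rec(k: int, pos_prev: int) -> Optional[List[int]]:
            if k == len(offsets):
                return []
            gap = offsets[k] - offsets[k - 1]
            for extra in range(spec.spacer_slack + 1):
                p = pos_prev + gap + extra
                if p >= n:
                    break
                if s[p] in spec.allowed(k):
                    rest = rec(k + 1, p)
                    if rest is not None:
                        return [p] + rest
            return None

        rest = rec(1, start0)
        if rest is None:
            return None
        return positions + rest

    max_start = n - spec.span
    for i in range(max(0, max_start) + 1) if n >= spec.span else []:
        placed = place(i)
        if placed is not None:
            matches.append(
                MotifMatch(
                    sequence_id=sequence_id,
                    start=i + 1,
                    anchor_positions=[p + 1 for p in placed],
                    anchor_residues=[s[p] for p in placed],
                    used_fungal_variant=(
                        spec.fungal_variant and s[placed[RA_ANCHOR_INDEX]] == "K"
                    ),
                )
            )
    return matches


def percent_identity(
    a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5
) -> float:
    """Global-alignment percent identity between two protein sequences.

    Needleman–Wunsch with unit match score, zero mismatch and affine gap
    penalties applied over the full length; identity = identical columns /
    all aligned columns (gap columns included), times 100. The argument
    order is canonicalised before aligning, so the measure is exactly
    symmetric even when co-optimal alignments exist.
    """
    a, b = _clean(a), _clean(b)
    if not a or not b:
        raise ValueError("percent identity undefined for empty sequence")
    if a == b:
        return 100.0
    if b < a:
        a, b = b, a
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    ident = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    return 100.0 * ident / len(sa)


@dataclass
class SurveyTable:
    """Per-sequence survey rows plus family-level summary."""

    table: pd.DataFrame
    n_pass_identity: int
    n_motif: int
    errors: List[str] = field(default_factory=list)

    @property
    def prevalence(self) -> float:
        return self.n_motif / self.n_pass_identity if self.n_pass_identity else 0.0

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def read_fasta(path: str) -> List[Tuple[str, str]]:
    """(id, sequence) records from a FASTA file."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]


def motif_survey(
    sequences: Iterable[Tuple[str, str]],
    reference: str,
    min_identity: float = 60.0,
    spec: MotifSpec = MotifSpec(),
) -> SurveyTable:
    """Survey motif prevalence in a family filtered by identity to a reference.

    ``sequences`` is an iterable of (id, sequence). Sequences below
    ``min_identity`` percent identity to the reference are recorded but not
    counted in the prevalence denominator.
    """
    import logging

    if not scan_sequence(reference, spec):
        logging.getLogger(__name__).warning(
            "reference sequence does not contain the motif"
        )
    rows = []
    errors: List[str] = []
    for seq_id, seq in sequences:
        if not seq:
            errors.append(f"{seq_id}: empty sequence")
            continue
        try:
            ident = percent_identity(seq, reference)
        except ValueError as exc:
            errors.append(f"{seq_id}: {exc}")
            continue
        passes = ident >= min_identity
        matches = scan_sequence(seq, spec, sequence_id=seq_id) if passes else []
        rows.append(
            {
                "sequence_id": seq_id,
                "identity_to_reference": round(ident, 2),
                "passes_identity": passes,
                "motif_present": bool(matches),
                "match_start": matches[0].start if matches else pd.NA,
                "anchor_positions": (
                    ",".join(map(str, matches[0].anchor_positions)) if matches else ""
                ),
                "used_fungal_variant": matches[0].used_fungal_variant if matches else False,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["sequence_id", "identity_to_reference", "passes_identity",
                 "motif_present", "match_start", "anchor_positions",
                 "used_fungal_variant"],
    )
    n_pass = int(df["passes_identity"].sum()) if len(df) else 0
    n_motif = int(df["motif_present"].sum()) if len(df) else 0
    return SurveyTable(table=df, n_pass_identity=n_pass, n_motif=n_motif, errors=errors)
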
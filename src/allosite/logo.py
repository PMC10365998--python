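"""Position frequency matrices and information content around motif anchors.

Numeric sequence-logo data: for each anchor of the regulatory motif and a
configurable flank on each side, count residues across motif-positive
sequences and convert column frequencies into information content in bits
(log2 20 minus Shannon entropy, uniform background, gaps excluded).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .motif import MotifMatch, MotifSpec

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
MAX_BITS = math.log2(20.0)


class EmptyMatrixError(ValueError):
    """No matches supplied, or a matrix with no columns."""


@dataclass
class PositionFrequencyMatrix:
    """Per-column residue counts, indexed by offset from the P anchor.

    ``counts[offset][aa]`` is the number of sequences showing amino acid
    ``aa`` at that offset; ``gaps[offset]`` counts sequences whose window
    was truncated (or non-standard) there.
    """

    columns: List[int]
    counts: Dict[int, Dict[str, int]]
    gaps: Dict[int, int]
    n_sequences: int

    def frequencies(self, offset: int) -> Dict[str, float]:
        col = self.counts[offset]
        total = sum(col.values())
        if total == 0:
            return {}
        return {aa: c / total for aa, c in col.items() if c}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        ic = information_content(self)
        for off in self.columns:
            row = {"offset": off, "gaps": self.gaps[off], "bits": ic[off]}
            row.update({aa: self.counts[off].get(aa, 0) for aa in AMINO_ACIDS})
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        ic = information_content(self)
        return json.dumps(
            {
                "n_sequences": self.n_sequences,
                "columns": [
                    {
                        "offset": off,
                        "counts": {aa: c for aa, c in sorted(self.counts[off].items()) if c},
                        "gaps": self.gaps[off],
                        "bits": ic[off],
                    }
                    for off in self.columns
                ],
            },
            indent=2,
        )


def anchor_windows(
    matches: Sequence[Tuple[MotifMatch, str]],
    flank: int = 3,
    spec: MotifSpec = MotifSpec(),
) -> PositionFrequencyMatrix:
    """Build a PFM over anchor-centred windows from motif matches.

    ``matches`` pairs each :class:`MotifMatch` with its full sequence.
    Columns are every offset within ``flank`` of an anchor offset
    (overlapping windows merged), indexed relative to the P anchor. Windows
    running off a sequence end contribute gaps.
    """
    if not matches:
        raise EmptyMatrixError("no motif matches supplied")
    offsets = sorted(
        {o + d for o, _ in spec.anchors for d in range(-flank, flank + 1)}
    )
    counts: Dict[int, Dict[str, int]] = {o: {} for o in offsets}
    gaps: Dict[int, int] = {o: 0 for o in offsets}
    for match, seq in matches:
        s = seq.upper().rstrip("*")
        start0 = match.start - 1
        for off in offsets:
            p = start0 + off
            if 0 <= p < len(s) and s[p] in set(AMINO_ACIDS):
                col = counts[off]
                col[s[p]] = col.get(s[p], 0) + 1
            else:
                gaps[off] += 1
    return PositionFrequencyMatrix(
        columns=offsets, counts=counts, gaps=gaps, n_sequences=len(matches)
    )


def information_content(pfm: PositionFrequencyMatrix) -> Dict[int, Optional[float]]:
    """Per-column information content in bits.

    IC = log2(20) - H(column frequencies); gaps are excluded from the
    frequencies and no small-sample correction is applied. All-gap columns
    are reported as None.
    """
    if not pfm.columns:
        raise EmptyMatrixError("matrix has no columns")
    out: Dict[int, Optional[float]] = {}
    for off in pfm.columns:
        freqs = pfm.frequencies(off)
        if not freqs:
            out[off] = None
            continue
        h = -sum(f * math.log2(f) for f in freqs.values() if f > 0)
        out[off] = max(0.0, MAX_BITS - h)
    return out
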
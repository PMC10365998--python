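"""p-distance matrices and Saitou–Nei neighbor-joining trees.

The family survey feeds gap-free (trivially aligned) motif-positive
sequences into an uncorrected p-distance matrix; neighbor joining then
produces an unrooted tree serialised as Newick. Tie-breaking and
negative-branch handling are deterministic so identical inputs always give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


class InvalidMatrixError(ValueError):
    """Non-symmetric, NaN-bearing, or undersized distance matrix."""


def p_distance(a: str, b: str) -> float:
    """Fraction of mismatched columns among columns where neither has a gap."""
    if len(a) != len(b):
        raise InvalidMatrixError("sequences must be aligned to equal length")
    comparable = 0
    mismatch = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "-." or y in "-.":
            continue
        comparable += 1
        if x != y:
            mismatch += 1
    if comparable == 0:
        raise InvalidMatrixError("no comparable (gap-free) columns between pair")
    return mismatch / comparable


def p_distance_matrix(aligned_seqs: Sequence[str]) -> np.ndarray:
    """Symmetric p-distance matrix over equal-length aligned sequences."""
    n = len(aligned_seqs)
    if n < 2:
        raise InvalidMatrixError("need at least 2 sequences")
    lengths = {len(s) for s in aligned_seqs}
    if len(lengths) != 1:
        raise InvalidMatrixError("ragged sequence lengths; alignment required")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = p_distance(aligned_seqs[i], aligned_seqs[j])
    return D


@dataclass
class _Node:
    label: Optional[str] = None
    children: List[Tuple["_Node", float]] = field(default_factory=list)

    def newick(self) -> str:
        if not self.children:
            return self.label or ""
        inner = ",".join(f"{c.newick()}:{length:.10g}" for c, length in self.children)
        return f"({inner})"


@dataclass
class DistanceMatrixTree:
    """NJ result: the input matrix, the unrooted tree, and its Newick form."""

    labels: List[str]
    D: np.ndarray
    root: _Node
    newick: str
    #: branch lengths before clamping negatives to zero (for diagnostics)
    raw_lengths: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def leaf_distances(self, clamped: bool = True) -> np.ndarray:
        """Leaf-to-leaf path-length matrix implied by the tree topology."""
        # build adjacency over an id-based graph
        adj: Dict[int, List[Tuple[int, float]]] = {}
        leaf_ids: Dict[str, int] = {}
        counter = [0]

        def visit(node: _Node) -> int:
            nid = counter[0]
            counter[0] += 1
            adj.setdefault(nid, [])
            if not node.children:
                leaf_ids[node.label] = nid
            for child, length in node.children:
                if not clamped:
                    key = (id(node), id(child))
                    length = self._raw_by_id.get(key, length)
                cid = visit(child)
                adj[nid].append((cid, length))
                adj[cid].append((nid, length))
            return nid

        self._raw_by_id = getattr(self, "_raw_by_id", {})
        visit(self.root)
        n = len(self.labels)
        out = np.zeros((n, n))
        for i, la in enumerate(self.labels):
            # BFS with accumulated lengths
            dist = {leaf_ids[la]: 0.0}
            stack = [leaf_ids[la]]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for j, lb in enumerate(self.labels):
                out[i, j] = dist[leaf_ids[lb]]
        return out


def neighbor_joining(D: np.ndarray, labels: Sequence[str]) -> DistanceMatrixTree:
    """Saitou–Nei neighbor joining over a symmetric distance matrix.

    At each step the pair minimising the Q-criterion is joined (ties broken
    by the lowest (i, j) index pair); branch lengths come from the standard
    formulas, with negative lengths clamped to zero and the deficit moved to
    the sibling branch. Returns an unrooted tree (trifurcating root) with
    Newick serialisation.
    """
    D = np.asarray(D, float)
    n = len(labels)
    if D.shape != (n, n):
        raise InvalidMatrixError("matrix shape does not match label count")
    if n < 3:
        raise InvalidMatrixError("need at least 3 taxa")
    if np.isnan(D).any():
        raise InvalidMatrixError("matrix contains NaN")
    if not np.allclose(D, D.T, atol=1e-12):
        raise InvalidMatrixError("matrix is not symmetric")
    D0 = D.copy()

    nodes: List[_Node] = [_Node(label=l) for l in labels]
    active = list(range(n))
    dist = {(i, j): D[i, j] for i in range(n) for j in range(n)}
    next_id = n

    def d(i: int, j: int) -> float:
        return dist[(i, j)] if i <= j else dist[(j, i)]

    node_of: Dict[int, _Node] = {i: nodes[i] for i in range(n)}

    def clamp_pair(li: float, lj: float) -> Tuple[float, float, float, float]:
        ci, cj = li, lj
        if ci < 0:
            cj += -ci
            ci = 0.0
        if cj < 0:
            ci += -cj
            cj = 0.0
        return ci, cj, li, lj

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = d(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        ci, cj, ri_raw, rj_raw = clamp_pair(li, lj)
        parent = _Node()
        parent.children.append((node_of[i], ci))
        parent.children.append((node_of[j], cj))
        u = next_id
        next_id += 1
        node_of[u] = parent
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d(i, k) + d(j, k) - dij)
            dist[(min(u, k), max(u, k))] = duk
        dist[(u, u)] = 0.0
        active = [k for k in active if k not in (i, j)] + [u]
        parent._raw = (ri_raw, rj_raw)  # type: ignore[attr-defined]

    # terminal 3-taxon star: closed-form branch lengths
    i, j, k = active
    li = 0.5 * (d(i, j) + d(i, k) - d(j, k))
    lj = 0.5 * (d(i, j) + d(j, k) - d(i, k))
    lk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
    root = _Node()
    for idx, raw in zip((i, j, k), (li, lj, lk)):
        root.children.append((node_of[idx], max(raw, 0.0)))
    root._raw = (li, lj, lk)  # type: ignore[attr-defined]

    tree = DistanceMatrixTree(
        labels=list(labels), D=D0, root=root, newick=root.newick() + ";",
    )
    # record raw (pre-clamp) lengths per edge for the unclamped path query
    raw_by_id: Dict[Tuple[int, int], float] = {}

    def collect(node: _Node) -> None:
        raw = getattr(node, "_raw", None)
        for idx, (child, length) in enumerate(node.children):
            if raw is not None and idx < len(raw):
                raw_by_id[(id(node), id(child))] = raw[idx]
            collect(child)

    collect(root)
    tree._raw_by_id = raw_by_id
    return tree


def write_newick(tree: DistanceMatrixTree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick + "\n")


def write_phylip_matrix(D: np.ndarray, labels: Sequence[str], path: str) -> None:
    """Distance matrix in relaxed PHYLIP square format."""
    with open(path, "w") as fh:
        fh.write(f"{len(labels)}\n")
        for label, row in zip(labels, np.asarray(D, float)):
            fh.write(label + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")
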
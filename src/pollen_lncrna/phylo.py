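"""Neighbor-joining trees with bootstrap support for lncRNA homolog sets.

Distances are p-distances (1 - identity) from pairwise alignments of each
homolog to the reference (query) sequence; all homologs are projected onto
the query's coordinates so bootstrap replicates can resample the same
columns consistently.  Tree construction is the Saitou-Nei algorithm with
the standard Q-criterion, ties broken by the smallest index pair, and
supports are the percentage of replicates containing each internal
bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align


@dataclass
class Node:
    name: str | None = None
    children: list[tuple["Node", float]] = field(default_factory=list)
    confidence: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf():
            return self.name or ""
        inner = ",".join(
            f"{child._newick()}:{length:g}" for child, length in self.children
        )
        label = "" if self.confidence is None else f"{self.confidence:g}"
        return f"({inner}){label}"


@dataclass
class PhyloTree:
    root: Node
    supports: dict[frozenset, float] = field(default_factory=dict)

    def to_newick(self) -> str:
        return self.root.to_newick()

    def bipartitions(self) -> set[frozenset]:
        return tree_bipartitions(self.root)


def tree_bipartitions(root: Node) -> set[frozenset]:
    """Non-trivial leaf bipartitions (as frozensets of the smaller side)."""
    all_leaves = frozenset(root.leaves())
    parts = set()

    def walk(node: Node) -> frozenset:
        if node.is_leaf():
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c, _ in node.children))
        if 1 < len(below) < len(all_leaves) - 1:
            canonical = min(below, all_leaves - below, key=lambda s: (len(s), sorted(s)))
            parts.add(canonical)
        return below

    walk(root)
    return parts


# ---------------------------------------------------------------------------
# Saitou-Nei neighbor joining
# ---------------------------------------------------------------------------

def nj_from_distances(dist: np.ndarray, labels: Sequence[str]) -> Node:
    """Neighbor joining on a symmetric distance matrix.

    Standard Q-matrix agglomeration; at each step the joined pair is the
    Q-minimal pair with ties broken by the smallest (i, j) index pair.  The
    final tree is returned rooted at the last join (an arbitrary root of the
    unrooted NJ topology).
    """
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = np.asarray(dist, dtype=float).copy()
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    nodes: list[Node] = [Node(name=label) for label in labels]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        best = (np.inf, None)
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] < best[0] - 1e-12:
                    best = (q[a, b], (a, b))
        a, b = best[1]
        i, j = active[a], active[b]
        dij = d[i, j]
        li = 0.5 * dij + (totals[a] - totals[b]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = Node(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to the remainder
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : -1] = new_row
        d[: -1, -1] = new_row
        d[-1, -1] = 0.0
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]

    # final three-way join (unrooted star resolution)
    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    li = 0.5 * (dij + dik - djk)
    lj = 0.5 * (dij + djk - dik)
    lk = 0.5 * (dik + djk - dij)
    return Node(children=[
        (nodes[i], max(li, 0.0)), (nodes[j], max(lj, 0.0)), (nodes[k], max(lk, 0.0)),
    ])


# ---------------------------------------------------------------------------
# Alignment projection and bootstrap
# ---------------------------------------------------------------------------

def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -2.5
    aligner.extend_gap_score = -0.5
    return aligner


def project_onto_query(
    query: str, sequences: Mapping[str, str]
) -> tuple[np.ndarray, list[str]]:
    """Align every sequence to the query and stack them on query columns.

    Returns a (n_sequences, len(query)) byte matrix; positions of a
    sequence that align to a query column carry that base, others are the
    gap byte ``-``.  Row order follows the mapping order.
    """
    aligner = _aligner()
    names = list(sequences)
    matrix = np.full((len(names), len(query)), ord("-"), dtype=np.uint8)
    for row, name in enumerate(names):
        seq = sequences[name]
        if seq == query:
            matrix[row] = np.frombuffer(query.encode(), dtype=np.uint8)
            continue
        alignment = aligner.align(query, seq)[0]
        for (qs, qe), (ss, se) in zip(*alignment.aligned):
            block = np.frombuffer(seq[ss:se].encode(), dtype=np.uint8)
            matrix[row, qs:qe] = block
    return matrix, names


def p_distance_matrix(matrix: np.ndarray) -> np.ndarray:
    """Pairwise 1 - identity over columns where both rows are ungapped."""
    n = matrix.shape[0]
    gap = ord("-")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (matrix[i] != gap) & (matrix[j] != gap)
            total = int(both.sum())
            if total == 0:
                d[i, j] = d[j, i] = 1.0
                continue
            diffs = int((matrix[i][both] != matrix[j][both]).sum())
            d[i, j] = d[j, i] = diffs / total
    return d


def nj_tree(
    query_id: str,
    sequences: Mapping[str, str],
    bootstrap: int = 1000,
    seed: int | None = None,
) -> PhyloTree:
    """NJ tree of a homolog set with bootstrap supports.

    ``sequences`` must contain ``query_id``; all members are projected onto
    the query's columns, distances are p-distances, and ``bootstrap``
    replicates resample query columns with replacement.  Supports (percent
    of replicates containing each internal bipartition) are attached to the
    internal nodes of the point-estimate tree.
    """
    if query_id not in sequences:
        raise ValueError(f"query {query_id} missing from sequence set")
    if len(sequences) < 3:
        raise ValueError("need at least 3 sequences")
    matrix, names = project_onto_query(sequences[query_id], sequences)
    root = nj_from_distances(p_distance_matrix(matrix), names)

    supports: dict[frozenset, float] = {}
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        counts: dict[frozenset, int] = {}
        n_cols = matrix.shape[1]
        for _ in range(bootstrap):
            cols = rng.integers(0, n_cols, size=n_cols)
            rep_root = nj_from_distances(p_distance_matrix(matrix[:, cols]), names)
            for part in tree_bipartitions(rep_root):
                counts[part] = counts.get(part, 0) + 1
        supports = {
            part: 100.0 * counts.get(part, 0) / bootstrap
            for part in tree_bipartitions(root)
        }
        _attach_supports(root, supports, frozenset(names))
    return PhyloTree(root=root, supports=supports)


def _attach_supports(root: Node, supports: Mapping[frozenset, float],
                     all_leaves: frozenset) -> None:
    def walk(node: Node) -> frozenset:
        if node.is_leaf():
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c, _ in node.children))
        if 1 < len(below) < len(all_leaves) - 1:
            canonical = min(below, all_leaves - below, key=lambda s: (len(s), sorted(s)))
            if canonical in supports:
                node.confidence = supports[canonical]
        return below

    walk(root)
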
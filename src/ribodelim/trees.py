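"""Distances on sequence-structure alignments and neighbor-joining trees.

Distances use the Jukes-Cantor correction generalised to the 12-letter
joint alphabet: with ``p`` the fraction of differing letters over mutually
ungapped columns, ``d = -(11/12) ln(1 - (12/11) p)``.  Trees are built by
classical neighbor joining with deterministic tie-breaking, and edge
support is estimated by bootstrap resampling of alignment columns.
"""

from __future__ import annotations

import math

import numpy as np
from skbio import TreeNode

from .alignment import GAP, SeqStructAlignment
from .dist import DistanceMatrix


class SaturationError(ValueError):
    """Raised when observed divergence exceeds the correctable range."""


class TreeError(ValueError):
    pass


def jc12_distance(row_a: np.ndarray, row_b: np.ndarray) -> float:
    """12-state Jukes-Cantor distance between two aligned encoded rows."""
    both = (row_a != GAP) & (row_b != GAP)
    n = int(both.sum())
    if n == 0:
        raise TreeError("no mutually ungapped columns")
    p = float(np.sum(row_a[both] != row_b[both])) / n
    if p >= 11.0 / 12.0:
        raise SaturationError(f"observed divergence p={p:.3f} >= 11/12 is saturated")
    return -(11.0 / 12.0) * math.log(1.0 - (12.0 / 11.0) * p)


def pairwise_identity(row_a: np.ndarray, row_b: np.ndarray) -> float:
    """Percent nucleotide identity over mutually ungapped columns.

    Structural states are ignored: two positions match when their
    nucleotides agree, whatever their pairing status.
    """
    both = (row_a != GAP) & (row_b != GAP)
    n = int(both.sum())
    if n == 0:
        raise TreeError("no mutually ungapped columns")
    return 100.0 * float(np.sum(row_a[both] // 3 == row_b[both] // 3)) / n


def jc12_matrix(aln: SeqStructAlignment) -> DistanceMatrix:
    n = len(aln.ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jc12_distance(aln.rows[i], aln.rows[j])
    return DistanceMatrix(list(aln.ids), d)


def identity_matrix(aln: SeqStructAlignment) -> DistanceMatrix:
    """Pairwise-identity complement (100 - %id) as a labelled matrix."""
    n = len(aln.ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 100.0 - pairwise_identity(aln.rows[i], aln.rows[j])
    return DistanceMatrix(list(aln.ids), d)


def nj_merge_order(d: np.ndarray):
    """Yield NJ agglomeration steps (i, j, new) on a plain distance matrix.

    Node ids: leaves ``0..n-1``, internal nodes numbered onward.  Used as
    the guide-tree order for progressive alignment.  The final step joins
    the last two surviving nodes.
    """
    n = d.shape[0]
    active = list(range(n))
    dist = {(i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)}
    nxt = n
    steps = []

    def get(a, b):
        return dist[(a, b) if a < b else (b, a)]

    while len(active) > 2:
        r = len(active)
        R = {a: sum(get(a, b) for b in active if b != a) for a in active}
        best = None
        for ii in range(r):
            for jj in range(ii + 1, r):
                a, b = active[ii], active[jj]
                q = (r - 2) * get(a, b) - R[a] - R[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        for c in active:
            if c not in (a, b):
                du = 0.5 * (get(a, c) + get(b, c) - get(a, b))
                dist[(min(c, nxt), max(c, nxt))] = du
        active = [c for c in active if c not in (a, b)] + [nxt]
        steps.append((a, b, nxt))
        nxt += 1
    a, b = active
    steps.append((a, b, nxt))
    return steps


def nj_tree(d: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (unrooted, trifurcating root) from a distance matrix.

    Q-criterion ties are broken toward the lowest-index pair; negative
    branch lengths are clamped to zero and counted on the returned tree as
    ``tree.negative_branches``.  On an additive input the tree's path
    metric reproduces the input exactly.
    """
    n = len(d.ids)
    if n < 3:
        raise TreeError("neighbor joining needs at least three taxa")
    negative = 0
    nodes: dict[int, TreeNode] = {i: TreeNode(name=d.ids[i]) for i in range(n)}
    active = list(range(n))
    dist = {(i, j): float(d.values[i, j]) for i in range(n) for j in range(i + 1, n)}
    nxt = n

    def get(a, b):
        return dist[(a, b) if a < b else (b, a)]

    def clamp(x):
        nonlocal negative
        if x < 0:
            negative += 1
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        R = {a: sum(get(a, b) for b in active if b != a) for a in active}
        best = None
        for ii in range(r):
            for jj in range(ii + 1, r):
                a, b = active[ii], active[jj]
                q = (r - 2) * get(a, b) - R[a] - R[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        la = 0.5 * get(a, b) + (R[a] - R[b]) / (2.0 * (r - 2))
        lb = get(a, b) - la
        parent = TreeNode(children=[nodes.pop(a), nodes.pop(b)])
        parent.children[0].length = clamp(la)
        parent.children[1].length = clamp(lb)
        nodes[nxt] = parent
        for c in active:
            if c not in (a, b):
                du = 0.5 * (get(a, c) + get(b, c) - get(a, b))
                dist[(min(c, nxt), max(c, nxt))] = du
        active = [c for c in active if c not in (a, b)] + [nxt]
        nxt += 1

    a, b, c = active
    la = 0.5 * (get(a, b) + get(a, c) - get(b, c))
    lb = 0.5 * (get(a, b) + get(b, c) - get(a, c))
    lc = 0.5 * (get(a, c) + get(b, c) - get(a, b))
    root = TreeNode(children=[nodes.pop(a), nodes.pop(b), nodes.pop(c)])
    for child, ln in zip(root.children, (la, lb, lc)):
        child.length = clamp(ln)
    root.negative_branches = negative
    return root


def tree_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalised to its smaller side."""
    tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = tips - side
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
    return out


def bootstrap_support(aln: SeqStructAlignment, n_replicates: int = 100,
                      seed: int | None = None) -> TreeNode:
    """NJ tree with bootstrap supports from alignment-column resampling.

    Each replicate resamples columns with replacement, recomputes the
    JC-corrected distance matrix and its NJ tree; the frequency of each
    bipartition of the point-estimate tree is written (0-100) to
    ``node.support`` and to the internal node names.
    """
    if len(aln.ids) < 4:
        raise TreeError("bootstrap supports need at least four taxa")
    rng = np.random.default_rng(seed)
    tree = nj_tree(jc12_matrix(aln))
    counts: dict[frozenset[str], int] = {b: 0 for b in tree_bipartitions(tree)}
    L = aln.n_cols
    for _ in range(n_replicates):
        cols = np.sort(rng.integers(0, L, size=L))
        rep = SeqStructAlignment.__new__(SeqStructAlignment)
        rep.ids = aln.ids
        rep.rows = aln.rows[:, cols]
        rep_tree = nj_tree(jc12_matrix(rep))
        for b in tree_bipartitions(rep_tree):
            if b in counts:
                counts[b] += 1
    tips = frozenset(aln.ids)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = min(side, tips - side, key=lambda s: (len(s), tuple(sorted(s))))
        if key in counts:
            node.support = 100.0 * counts[key] / n_replicates
            node.name = f"{node.support:g}"
    return tree
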
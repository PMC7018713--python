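"""Compensatory base changes (CBCs) and the CBC species partition.

A CBC is a double substitution at an RNA base pair that changes both
partners while keeping the pairing canonical (e.g. A-U -> G-C); a hemi-CBC
changes one partner only (e.g. G-C -> G-U).  CBCs between the ITS2 regions
of two specimens are a strong indicator that they belong to different
biological species, while their absence suggests conspecificity — the
operational criterion used here to partition ribotypes into cryptic
species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import SeqStructAlignment
from .structures import NUCLEOTIDES, is_canonical


@dataclass(frozen=True)
class CBCCount:
    cbc: int
    hemi: int
    #: comparable pair couples where at least one side pairs non-canonically
    disrupted: int = 0


@dataclass
class CBCMatrix:
    taxa: list[str]
    counts: np.ndarray  # full CBCs only
    hemi: np.ndarray

    def __post_init__(self) -> None:
        for name in ("counts", "hemi"):
            m = np.asarray(getattr(self, name))
            if not np.array_equal(m, m.T) or np.any(np.diag(m) != 0) or np.any(m < 0):
                raise ValueError(f"{name}: CBC matrix must be symmetric, zero-diagonal, non-negative")
            setattr(self, name, m.astype(np.int64))

    def to_frame(self, which: str = "cbc") -> pd.DataFrame:
        m = self.counts if which == "cbc" else self.hemi
        return pd.DataFrame(m, index=self.taxa, columns=self.taxa)


def count_cbc(aln: SeqStructAlignment, i: int, j: int) -> CBCCount:
    """Count CBCs and hemi-CBCs between rows ``i`` and ``j`` of an alignment.

    A column couple (c1, c2) is *comparable* iff both rows pair c1 with c2
    (each through its own structure lifted to alignment columns).  Among
    comparable couples where both rows pair canonically (Watson-Crick or
    G·U): both nucleotides differ -> CBC; exactly one differs -> hemi-CBC.
    Couples with a non-canonical side are skipped and reported as
    ``disrupted``.  Couples where only one row is paired are not
    comparable.
    """
    pt_a = aln.column_pair_table(i)
    pt_b = aln.column_pair_table(j)
    row_a, row_b = aln.rows[i], aln.rows[j]
    cbc = hemi = disrupted = 0
    for c1 in np.flatnonzero(pt_a >= 0):
        c2 = pt_a[c1]
        if c2 <= c1 or pt_b[c1] != c2:
            continue
        a1, a2 = NUCLEOTIDES[row_a[c1] // 3], NUCLEOTIDES[row_a[c2] // 3]
        b1, b2 = NUCLEOTIDES[row_b[c1] // 3], NUCLEOTIDES[row_b[c2] // 3]
        if not (is_canonical(a1, a2) and is_canonical(b1, b2)):
            disrupted += 1
            continue
        diff = (a1 != b1) + (a2 != b2)
        if diff == 2:
            cbc += 1
        elif diff == 1:
            hemi += 1
    return CBCCount(cbc, hemi, disrupted)


def cbc_matrix(aln: SeqStructAlignment) -> CBCMatrix:
    """Full-CBC and hemi-CBC counts over all unordered row pairs."""
    n = len(aln.ids)
    if n < 2:
        raise ValueError("need at least two rows")
    full = np.zeros((n, n), dtype=np.int64)
    hemi = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            c = count_cbc(aln, i, j)
            full[i, j] = full[j, i] = c.cbc
            hemi[i, j] = hemi[j, i] = c.hemi
    return CBCMatrix(list(aln.ids), full, hemi)


def delineate_species(m: CBCMatrix) -> tuple[list[set[str]], list[tuple[str, str]]]:
    """Partition taxa into putative species by zero-CBC connectivity.

    Two taxa are conspecific when no full CBC separates them; species are
    the connected components of the zero-CBC graph.  Pairs joined through a
    component while separated by a direct CBC (a non-transitive zero
    pattern) are returned as conflicts.
    """
    n = len(m.taxa)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if m.counts[i, j] == 0:
                parent[find(i)] = find(j)

    groups: dict[int, set[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(m.taxa[i])
    partition = sorted(groups.values(), key=lambda s: sorted(s)[0])

    conflicts = [
        (m.taxa[i], m.taxa[j])
        for i in range(n)
        for j in range(i + 1, n)
        if find(i) == find(j) and m.counts[i, j] > 0
    ]
    return partition, conflicts
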
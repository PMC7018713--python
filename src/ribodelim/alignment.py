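"""Global sequence-structure alignment over the 12-letter ITS2 alphabet.

Pairwise alignment is affine-gap Gotoh dynamic programming maximising a
12x12 substitution score (nucleotide and structural state scored jointly).
Multiple alignment is progressive: a neighbor-joining guide tree built from
pairwise alignment scores, profiles merged leaf-to-root with a "once a gap,
always a gap" policy.  Inputs are canonicalised by record id before any
computation, so the column content of the result is invariant to input
order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import EncodedSequence, StructureError, parse_dotbracket, STATES

GAP = -1  # gap code inside alignment rows

_NEG = -1e30


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    """12x12 symmetric substitution scores with affine gap penalties.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend`` (the first
    gapped position pays the opening penalty).
    """

    matrix: np.ndarray
    gap_open: float = -8.0
    gap_extend: float = -2.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (12, 12):
            raise AlignmentError(f"scoring matrix must be 12x12, got {m.shape}")
        if not np.allclose(m, m.T):
            raise AlignmentError("scoring matrix must be symmetric")
        if not (self.gap_open <= self.gap_extend <= 0):
            raise AlignmentError("require gap_open <= gap_extend <= 0")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def default(cls, gap_open: float = -8.0, gap_extend: float = -2.0) -> "ScoringScheme":
        """Additive default: +2/-1 on the nucleotide, +2/-2 on the state."""
        m = np.empty((12, 12))
        for a in range(12):
            for b in range(12):
                nt = 2.0 if a // 3 == b // 3 else -1.0
                st = 2.0 if a % 3 == b % 3 else -2.0
                m[a, b] = nt + st
        return cls(m, gap_open, gap_extend)

    @classmethod
    def from_tsv(cls, path) -> "ScoringScheme":
        """Read 12 whitespace-separated rows, then a ``gap_open<TAB>gap_extend`` line."""
        with open(path) as fh:
            lines = [ln.split() for ln in fh if ln.strip() and not ln.startswith("#")]
        if len(lines) != 13:
            raise AlignmentError("expected 12 matrix rows plus one gap-penalty row")
        m = np.array([[float(v) for v in row] for row in lines[:12]])
        go, ge = (float(v) for v in lines[12][:2])
        return cls(m, go, ge)


@dataclass
class SeqStructAlignment:
    """Gapped encoded rows sharing one column space.

    ``rows`` is an (n_seqs, n_cols) int array of 12-letter codes with
    :data:`GAP` marking gaps.  Ungapping any row recovers its input.
    """

    ids: list[str]
    rows: np.ndarray

    def __post_init__(self) -> None:
        if len(self.ids) != self.rows.shape[0]:
            raise AlignmentError("id/row count mismatch")
        if self.rows.size and np.all(self.rows == GAP, axis=0).any():
            raise AlignmentError("alignment contains an all-gap column")

    @property
    def n_cols(self) -> int:
        return self.rows.shape[1]

    def ungapped(self, i: int) -> EncodedSequence:
        row = self.rows[i]
        return EncodedSequence(self.ids[i], row[row != GAP].copy())

    def column_pair_table(self, i: int) -> np.ndarray:
        """Per-row pair table lifted into alignment-column coordinates.

        Returns partner column indices (-1 for unpaired or gap columns); the
        structure is re-derived from the row's own structural-state letters.
        """
        row = self.rows[i]
        nongap_cols = np.flatnonzero(row != GAP)
        struct = "".join(STATES[c % 3] for c in row[nongap_cols])
        try:
            pt = parse_dotbracket(struct)
        except StructureError as exc:  # pragma: no cover - inputs validated upstream
            raise AlignmentError(f"row {self.ids[i]} has invalid structure: {exc}") from exc
        out = np.full(self.rows.shape[1], -1, dtype=np.int64)
        paired = pt >= 0
        out[nongap_cols[paired]] = nongap_cols[pt[paired]]
        return out


def _gotoh(score: np.ndarray, go: float, ge: float):
    """Affine-gap global DP on a precomputed (la x lb) column-score matrix.

    Returns (best score, traceback path) where the path is a list of
    (ia, ib) index pairs with -1 marking a gap.  Ties prefer the diagonal,
    then the vertical (gap in the second sequence), then the horizontal
    move.
    """
    la, lb = score.shape
    M = np.full((la + 1, lb + 1), _NEG)
    E = np.full((la + 1, lb + 1), _NEG)  # gap in first sequence (left move)
    F = np.full((la + 1, lb + 1), _NEG)  # gap in second sequence (up move)
    M[0, 0] = 0.0
    if lb:
        E[0, 1:] = go + ge * np.arange(lb)
        M[0, 1:] = E[0, 1:]
    if la:
        F[1:, 0] = go + ge * np.arange(la)
        M[1:, 0] = F[1:, 0]
    ar = np.arange(1, lb + 1)
    for i in range(1, la + 1):
        F[i, 1:] = np.maximum(F[i - 1, 1:] + ge, M[i - 1, 1:] + go)
        diag = M[i - 1, :-1] + score[i - 1]
        G = np.maximum(diag, F[i, 1:])
        # E[i, j] = go + (j-1)*ge + max_{k<j} (src_k - k*ge) with src_0 the
        # row boundary and src_k = G at column k; a running prefix-max keeps
        # the row update O(lb).  (Chaining E -> open -> E is dominated
        # because gap_open <= gap_extend.)
        prefix = np.concatenate(([M[i, 0]], G[:-1] - ar[:-1] * ge))
        prefix = np.maximum.accumulate(prefix)
        E[i, 1:] = prefix + ar * ge + go - ge
        M[i, 1:] = np.maximum(G, E[i, 1:])
    # traceback
    path: list[tuple[int, int]] = []
    i, j = la, lb
    state = "M"
    while i > 0 or j > 0:
        if state == "M":
            if i > 0 and j > 0 and np.isclose(M[i, j], M[i - 1, j - 1] + score[i - 1, j - 1]):
                path.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            elif i > 0 and np.isclose(M[i, j], F[i, j]):
                state = "F"
            else:
                state = "E"
        elif state == "F":
            path.append((i - 1, GAP))
            if i > 1 and np.isclose(F[i, j], F[i - 1, j] + ge):
                i -= 1
            else:
                i -= 1
                state = "M"
        else:  # E
            path.append((GAP, j - 1))
            if j > 1 and np.isclose(E[i, j], E[i, j - 1] + ge):
                j -= 1
            else:
                j -= 1
                state = "M"
    path.reverse()
    return float(M[la, lb]), path


def _profile(rows: np.ndarray) -> np.ndarray:
    """(n_cols x 12) letter-frequency profile; gaps contribute zero weight."""
    n, L = rows.shape
    prof = np.zeros((L, 12))
    for a in range(12):
        prof[:, a] = (rows == a).sum(axis=0)
    return prof / n


def _pair_score_matrix(pa: np.ndarray, pb: np.ndarray, s: ScoringScheme) -> np.ndarray:
    return pa @ s.matrix @ pb.T


def _merge(rows_a: np.ndarray, ids_a, rows_b: np.ndarray, ids_b, s: ScoringScheme):
    score = _pair_score_matrix(_profile(rows_a), _profile(rows_b), s)
    _, path = _gotoh(score, s.gap_open, s.gap_extend)
    na, nb = rows_a.shape[0], rows_b.shape[0]
    L = len(path)
    out = np.full((na + nb, L), GAP, dtype=np.int64)
    for col, (ia, ib) in enumerate(path):
        if ia != GAP:
            out[:na, col] = rows_a[:, ia]
        if ib != GAP:
            out[na:, col] = rows_b[:, ib]
    return out, list(ids_a) + list(ids_b)


def align_pair(a: EncodedSequence, b: EncodedSequence,
               s: ScoringScheme | None = None) -> SeqStructAlignment:
    """Optimal global pairwise alignment; see :func:`alignment_score`."""
    if len(a) == 0 or len(b) == 0:
        raise AlignmentError("cannot align an empty sequence")
    if s is None:
        s = ScoringScheme.default()
    score = s.matrix[np.ix_(a.codes, b.codes)]
    _, path = _gotoh(score, s.gap_open, s.gap_extend)
    rows = np.full((2, len(path)), GAP, dtype=np.int64)
    for col, (ia, ib) in enumerate(path):
        if ia != GAP:
            rows[0, col] = a.codes[ia]
        if ib != GAP:
            rows[1, col] = b.codes[ib]
    return SeqStructAlignment([a.id, b.id], rows)


def alignment_score(a: EncodedSequence, b: EncodedSequence,
                    s: ScoringScheme | None = None) -> float:
    """Score of the optimal global affine-gap alignment of ``a`` and ``b``."""
    if len(a) == 0 or len(b) == 0:
        raise AlignmentError("cannot align an empty sequence")
    if s is None:
        s = ScoringScheme.default()
    score = s.matrix[np.ix_(a.codes, b.codes)]
    best, _ = _gotoh(score, s.gap_open, s.gap_extend)
    return best


def score_alignment_rows(aln: SeqStructAlignment, i: int, j: int,
                         s: ScoringScheme | None = None) -> float:
    """Score of the pairwise projection of rows ``i``, ``j`` of an MSA."""
    if s is None:
        s = ScoringScheme.default()
    ra, rb = aln.rows[i], aln.rows[j]
    keep = ~((ra == GAP) & (rb == GAP))
    ra, rb = ra[keep], rb[keep]
    total = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(ra, rb):
        if ca == GAP:
            total += s.gap_extend if in_gap_a else s.gap_open
            in_gap_a, in_gap_b = True, False
        elif cb == GAP:
            total += s.gap_extend if in_gap_b else s.gap_open
            in_gap_b, in_gap_a = True, False
        else:
            total += s.matrix[ca, cb]
            in_gap_a = in_gap_b = False
    return total


def align_progressive(seqs: list[EncodedSequence],
                      s: ScoringScheme | None = None) -> SeqStructAlignment:
    """Progressive multiple sequence-structure alignment.

    Guide tree: neighbor joining on pairwise alignment-score distances
    ``d = 1 - s_ab / min(s_aa, s_bb)``; profiles merged in the tree's
    postorder.  Input order is irrelevant: records are sorted by id first.
    """
    if len(seqs) < 2:
        raise AlignmentError("need at least two sequences")
    ids = [q.id for q in seqs]
    if len(set(ids)) != len(ids):
        raise AlignmentError("duplicate sequence ids")
    if s is None:
        s = ScoringScheme.default()
    order = sorted(range(len(seqs)), key=lambda i: seqs[i].id)
    seqs = [seqs[i] for i in order]
    n = len(seqs)
    if n == 2:
        aln = align_pair(seqs[0], seqs[1], s)
        return aln

    self_scores = np.array([float(np.sum(s.matrix[q.codes, q.codes])) for q in seqs])
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sc = alignment_score(seqs[i], seqs[j], s)
            d[i, j] = d[j, i] = max(0.0, 1.0 - sc / min(self_scores[i], self_scores[j]))

    from .trees import nj_merge_order

    clusters: dict[int, tuple[np.ndarray, list[str]]] = {
        i: (seqs[i].codes.reshape(1, -1), [seqs[i].id]) for i in range(n)
    }
    for a_idx, b_idx, new_idx in nj_merge_order(d):
        ra, ia = clusters.pop(a_idx)
        rb, ib = clusters.pop(b_idx)
        clusters[new_idx] = _merge(ra, ia, rb, ib, s)
    (rows, out_ids), = clusters.values()
    # canonical row order: sorted by id
    perm = sorted(range(len(out_ids)), key=lambda i: out_ids[i])
    return SeqStructAlignment([out_ids[i] for i in perm], rows[perm])
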
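"""Alignment-free genome comparison by canonical k-mer presence/absence.

Reads are filtered on length and mononucleotide Shannon entropy, decomposed
into canonical 21-mers (strand-neutral: each window is stored as the
lexicographic minimum of itself and its reverse complement), and strains are
compared with binary-association distances that reward double presence
(Kulczynski, Ochiai, Chord/Hellinger).  Clusters are cut from an
average-linkage dendrogram and their robustness is scored by a bootstrap
Jaccard stability analysis.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .dist import DistanceMatrix

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

METRICS = ("kulczynski", "ochiai", "chord")


@dataclass(frozen=True)
class ReadFilterParams:
    min_len: int = 90
    min_entropy: float = 1.5  # bits
    k: int = 21

    def __post_init__(self) -> None:
        if self.k > self.min_len:
            raise ValueError("k must not exceed the minimum read length")
        if not (0.0 <= self.min_entropy <= 2.0):
            raise ValueError("mononucleotide entropy lies in [0, 2] bits")


@dataclass
class KmerProfile:
    strain_id: str
    kmers: frozenset[str]
    k: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "kmers", frozenset(self.kmers))
        for w in self.kmers:
            if len(w) != self.k or any(c not in "ACGT" for c in w):
                raise ValueError(f"{self.strain_id}: bad k-mer {w!r}")
            if w != canonical(w):
                raise ValueError(f"{self.strain_id}: {w!r} is not canonical")


@dataclass
class ClusterStabilityReport:
    assignment: dict[str, int]
    stability: dict[int, float]  # cluster label -> mean bootstrap Jaccard
    n_boot: int
    linkage_method: str = "average"
    labels_per_boot: np.ndarray | None = field(default=None, repr=False)

    def min_stability(self) -> float:
        return min(self.stability.values())


def shannon_entropy(read: str) -> float:
    """Mononucleotide Shannon entropy in bits (ambiguous bases ignored)."""
    counts = Counter(c for c in read.upper() if c in "ACGT")
    n = sum(counts.values())
    if n == 0:
        return 0.0
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def filter_reads(reads, p: ReadFilterParams | None = None) -> list[str]:
    """Retain reads with length >= min_len and entropy >= min_entropy.

    Low-complexity reads (entropy below the threshold) are discarded, as
    are short reads.
    """
    if p is None:
        p = ReadFilterParams()
    return [r for r in reads if len(r) >= p.min_len and shannon_entropy(r) >= p.min_entropy]


def reverse_complement(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def kmer_set(reads, k: int = 21, strain_id: str = "") -> KmerProfile:
    """Canonical k-mer set of a read collection; N-containing windows skipped."""
    kmers: set[str] = set()
    for read in reads:
        read = read.upper()
        for i in range(len(read) - k + 1):
            w = read[i : i + k]
            if "N" in w:
                continue
            kmers.add(canonical(w))
    return KmerProfile(strain_id, frozenset(kmers), k)


def binary_distance(a: KmerProfile, b: KmerProfile, metric: str = "kulczynski") -> float:
    """Binary-association distance between two presence/absence k-mer sets.

    With ``n11 = |A∩B|``, ``n10 = |A\\B|``, ``n01 = |B\\A|``:

    - kulczynski: ``1 - (n11/(n11+n10) + n11/(n11+n01)) / 2``
    - ochiai:     ``1 - n11 / sqrt((n11+n10) (n11+n01))``
    - chord:      ``sqrt(2 (1 - n11 / sqrt((n11+n10) (n11+n01))))``

    All reward shared presence; shared absence carries no signal.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if a.k != b.k:
        raise ValueError("profiles have different k")
    if not a.kmers or not b.kmers:
        raise ValueError("empty k-mer profile")
    n11 = len(a.kmers & b.kmers)
    na, nb = len(a.kmers), len(b.kmers)
    if metric == "kulczynski":
        return 1.0 - 0.5 * (n11 / na + n11 / nb)
    ochiai = 1.0 - n11 / math.sqrt(na * nb)
    if metric == "ochiai":
        return ochiai
    return math.sqrt(2.0 * ochiai)


def distance_matrix(profiles: list[KmerProfile], metric: str = "kulczynski") -> DistanceMatrix:
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    ks = {p.k for p in profiles}
    if len(ks) != 1:
        raise ValueError(f"mixed k values: {sorted(ks)}")
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = binary_distance(profiles[i], profiles[j], metric)
    return DistanceMatrix([p.strain_id for p in profiles], d)


def _cut(d_condensed: np.ndarray, k: int, method: str) -> np.ndarray:
    return fcluster(linkage(d_condensed, method=method), t=k, criterion="maxclust")


def cluster_with_stability(d: DistanceMatrix, k: int, n_boot: int = 100,
                           seed: int | None = None,
                           method: str = "average") -> ClusterStabilityReport:
    """Hierarchical clustering cut at ``k`` with bootstrap Jaccard stability.

    Per replicate, individuals are resampled with replacement, the
    resampled distance matrix is reclustered, and each original cluster is
    scored by its maximum Jaccard overlap with the replicate clusters
    (both restricted to the resampled multiset).  Stability of a cluster is
    the mean of that score over replicates; values near 1 indicate the
    cluster is rediscovered essentially intact.
    """
    n = len(d.ids)
    if k < 2:
        raise ValueError("need at least two clusters")
    if k > n:
        raise ValueError("more clusters than individuals")
    rng = np.random.default_rng(seed)
    base = _cut(d.condensed(), k, method)
    labels = np.unique(base)

    totals = {int(lab): 0.0 for lab in labels}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sub = d.values[np.ix_(idx, idx)]
        iu = np.triu_indices(n, k=1)
        rep = fcluster(linkage(sub[iu], method=method), t=k, criterion="maxclust")
        base_rep = base[idx]  # original labels carried onto the multiset
        for lab in labels:
            mask = base_rep == lab
            if not mask.any():
                continue  # cluster absent from this resample; contributes 0
            best = 0.0
            for rl in np.unique(rep):
                rmask = rep == rl
                inter = int(np.sum(mask & rmask))
                union = int(np.sum(mask | rmask))
                if union:
                    best = max(best, inter / union)
            totals[int(lab)] += best
    stability = {lab: tot / n_boot for lab, tot in totals.items()}
    assignment = {sid: int(lab) for sid, lab in zip(d.ids, base)}
    return ClusterStabilityReport(assignment, stability, n_boot, method)
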
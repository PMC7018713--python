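"""Cross-evidence consensus over independent species partitions.

Each line of evidence (CBC zero-connectivity, k-mer clusters, tree clades)
yields a partition of the same individuals.  The strict consensus is the
partition meet: two individuals are conspecific only when every line of
evidence agrees; pairwise disagreements are reported explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations


@dataclass
class ConsensusReport:
    partition: list[set[str]]
    #: (individual_a, individual_b, sources that split them) for pairs on
    #: which at least one but not every source agrees
    conflicts: list[tuple[str, str, tuple[str, ...]]] = field(default_factory=list)

    @property
    def n_species(self) -> int:
        return len(self.partition)

    def label_of(self) -> dict[str, int]:
        return {ind: i for i, grp in enumerate(sorted(
            (sorted(g) for g in self.partition))) for ind in grp}


def _normalize(partition) -> dict[str, int]:
    """Accept either a label mapping or an iterable of groups."""
    if isinstance(partition, dict):
        return {str(k): v for k, v in partition.items()}
    labels: dict[str, int] = {}
    for i, group in enumerate(partition):
        for ind in group:
            labels[str(ind)] = i
    return labels


def consensus_delineation(partitions: dict[str, object]) -> ConsensusReport:
    """Strict consensus (partition meet) of named partitions.

    ``partitions`` maps an evidence name to either a label mapping
    (individual -> cluster) or an iterable of groups.  All partitions must
    cover the same individuals.  The meet is idempotent, commutative and
    associative; pairs on which the sources disagree are listed with the
    dissenting sources.
    """
    if len(partitions) < 2:
        raise ValueError("need at least two partitions")
    named = {name: _normalize(p) for name, p in partitions.items()}
    id_sets = {name: frozenset(lbl) for name, lbl in named.items()}
    ref = next(iter(id_sets.values()))
    for name, ids in id_sets.items():
        if ids != ref:
            raise ValueError(f"partition {name!r} covers a different individual set")

    individuals = sorted(ref)
    keys = {ind: tuple(named[name][ind] for name in sorted(named)) for ind in individuals}
    groups: dict[tuple, set[str]] = {}
    for ind in individuals:
        groups.setdefault(keys[ind], set()).add(ind)

    conflicts = []
    for a, b in combinations(individuals, 2):
        together = [name for name in sorted(named) if named[name][a] == named[name][b]]
        apart = [name for name in sorted(named) if named[name][a] != named[name][b]]
        if together and apart:
            conflicts.append((a, b, tuple(apart)))
    partition = sorted(groups.values(), key=lambda g: sorted(g)[0])
    return ConsensusReport(partition, conflicts)
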
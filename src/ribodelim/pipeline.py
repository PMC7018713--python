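"""Stage orchestration and the end-to-end synthetic run.

Each stage function takes in-memory objects and returns in-memory results;
the command-line layer handles files.  ``end_to_end`` chains every stage on
one synthetic configuration and returns the consensus species call together
with the planted truth, which is how the pipeline is validated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cbc as cbc_mod
from . import kmer as kmer_mod
from . import synth
from .alignment import align_progressive
from .consensus import ConsensusReport, consensus_delineation
from .dist import DistanceMatrix
from .structures import encode12
from .trees import bootstrap_support, jc12_matrix, nj_tree


@dataclass
class ITS2Result:
    alignment: object
    tree: object
    cbc: cbc_mod.CBCMatrix
    partition: list[set[str]]
    conflicts: list


def run_its2(records, n_bootstrap: int = 100, seed: int | None = None) -> ITS2Result:
    """Alignment, bootstrapped NJ tree, CBC matrix and CBC species partition."""
    encoded = [encode12(r) for r in records]
    aln = align_progressive(encoded)
    tree = bootstrap_support(aln, n_replicates=n_bootstrap, seed=seed) \
        if len(records) >= 4 else None
    m = cbc_mod.cbc_matrix(aln)
    partition, conflicts = cbc_mod.delineate_species(m)
    return ITS2Result(aln, tree, m, partition, conflicts)


def tree_partition(tree, k: int) -> dict[str, int]:
    """Cut an NJ tree into ``k`` clades at its longest internal edges.

    Shared differences between clades accumulate on internal edges while
    strain-private substitutions sit on pendant edges, so removing the
    ``k - 1`` longest internal edges (pendant edges only as a fallback)
    yields the clade partition the tree supports.
    """
    nodes = list(tree.traverse(include_self=False))
    internal = [n for n in nodes if not n.is_tip()]
    tips_only = [n for n in nodes if n.is_tip()]
    ranked = sorted(internal, key=lambda n: -(n.length or 0.0))
    if len(ranked) < k - 1:
        ranked += sorted(tips_only, key=lambda n: -(n.length or 0.0))
    cut = set(id(n) for n in ranked[:k - 1])

    labels: dict[str, int] = {}
    next_label = 0

    def assign(node, label):
        nonlocal next_label
        for child in node.children:
            child_label = label
            if id(child) in cut:
                next_label += 1
                child_label = next_label
            if child.is_tip():
                labels[child.name] = child_label
            else:
                assign(child, child_label)

    assign(tree, 0)
    return labels


def partition_from_groups(groups: list[set[str]]) -> dict[str, int]:
    return {ind: i for i, g in enumerate(groups) for ind in g}


def end_to_end(config: synth.SynthConfig | None = None,
               n_bootstrap: int = 100) -> tuple[ConsensusReport, synth.PlantedTruth]:
    """Simulate every input, run all evidence lines, return the consensus.

    Evidence entering the consensus: the CBC zero-connectivity partition,
    the k-mer average-linkage clustering at the CBC-implied cluster count,
    and clades cut from the sequence-structure tree distances at the same
    count.
    """
    if config is None:
        config = synth.SynthConfig(strains_per_ribotype=4)
    records, truth = synth.gen_ribotype_sequences(config)
    its2 = run_its2(records, n_bootstrap=n_bootstrap, seed=config.seed)
    k = len(its2.partition)

    profiles, _ = synth.gen_kmer_profiles(config)
    d_kmer = kmer_mod.distance_matrix(profiles, "kulczynski")
    report = kmer_mod.cluster_with_stability(d_kmer, k, n_boot=n_bootstrap,
                                             seed=config.seed)

    tree = its2.tree if its2.tree is not None else nj_tree(jc12_matrix(its2.alignment))
    partitions = {
        "cbc": partition_from_groups(its2.partition),
        "kmer": report.assignment,
        "tree": tree_partition(tree, k),
    }
    return consensus_delineation(partitions), truth


def relative_contributions(community: pd.DataFrame,
                           parasite_taxa: list[str],
                           denominator: str = "parasite_reads") -> pd.DataFrame:
    """Per-sample relative read contribution of each parasite taxon."""
    if denominator == "parasite_reads":
        den = community[parasite_taxa].sum(axis=1)
    elif denominator == "total_reads":
        den = community.sum(axis=1)
    else:
        raise ValueError("denominator is 'total_reads' or 'parasite_reads'")
    den = den.replace(0, np.nan)
    return community[parasite_taxa].div(den, axis=0).fillna(0.0)
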
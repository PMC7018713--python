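# ribodelim

Polyphasic delineation of cryptic species among closely related rRNA
ribotypes, built for syndinian parasites of dinoflagellates (the
*Amoebophrya ceratii* species complex) but applicable to any protist group
whose taxonomy rests on molecular fingerprints rather than morphology.

Short metabarcodes lump distinct biological species into single operational
units; this package implements the complementary evidence lines that pull
them apart, together with a synthetic-data generator that plants known
ground truth so every stage is testable end to end:

- **ITS2 compensatory base changes (CBCs).** ITS2 sequences and their
  secondary structures are encoded jointly in a 12-letter alphabet
  ({A,C,G,U} × {unpaired, pair-opening, pair-closing}), globally aligned
  with affine gaps, and compared pair by pair. A CBC is a double
  substitution at a base pair that preserves canonical pairing
  (e.g. A-U → G-C); a hemi-CBC changes one partner (G-C → G-U). Taxa joined
  by zero-CBC paths form one candidate species. Trees are neighbor-joining
  on a 12-state Jukes-Cantor distance, d = −(11/12)·ln(1 − (12/11)·p),
  with bootstrap supports from column resampling.
- **Alignment-free genome comparison.** Reads filtered on length (≥90 bp)
  and mononucleotide Shannon entropy (≥1.5 bits) are decomposed into
  canonical 21-mers; strains are compared by presence/absence association
  distances that reward shared presence (Kulczynski, Ochiai,
  Chord/Hellinger) and clustered by average linkage, with per-cluster
  bootstrap Jaccard stability.
- **rDNA operon copy numbers.** Copies per genome = operon read coverage
  divided by the mean coverage of a curated single-copy gene panel; genome
  sizes from flow-cytometric fluorescence ratios to a 20.9 fg 1C standard
  (0.978 Mb/fg).
- **Phenotype and host-range ordination.** Pairwise Mann-Whitney tests on
  log(x+1) data with Holm adjustment; PCoA of Bray-Curtis distances over
  range-standardized phenotypes plus binary infection columns; descriptor
  fitting (envfit) with permutation significance.
- **Niche and fitness analysis.** OMI (Outlying Mean Index) ordination of
  Hellinger-transformed abundances against [0,1]-standardized environmental
  descriptors; abundance-weighted kernel densities on the first two niche
  axes; Schoener's D = 1 − ½Σ|p₁ − p₂| overlap; operon-normalized maximal
  abundances and persistence compared across host-range classes by
  Kruskal-Wallis with Dunn's post-hoc test.
- **Consensus.** The strict consensus (partition meet) of the CBC, k-mer
  and tree-clade partitions, with per-pair conflict reporting.

## Worked example

Generate a synthetic study — 8 ribotypes, 2 strains each, ≤3 strain-private
SNPs at unpaired sites, and a planted CBC matrix whose off-diagonal values
span 1–9 — then run the ITS2 stage and the k-mer stage:

```python
import numpy as np
from ribodelim import (SynthConfig, gen_ribotype_sequences, gen_kmer_profiles,
                       distance_matrix, cluster_with_stability)
from ribodelim.pipeline import run_its2

config = SynthConfig(strains_per_ribotype=2, seed=7)
records, truth = gen_ribotype_sequences(config)
result = run_its2(records, n_bootstrap=100, seed=7)

print("species found:", len(result.partition))
print("zero-CBC conflicts:", len(result.conflicts))
ribs = [f"R{r}S1" for r in range(1, 9)]
idx = [result.cbc.taxa.index(s) for s in ribs]
print("CBCs between ribotype representatives:")
print(result.cbc.counts[np.ix_(idx, idx)])

profiles, _ = gen_kmer_profiles(SynthConfig(seed=7))  # 8 x 8 strains
d = distance_matrix(profiles, "kulczynski")
report = cluster_with_stability(d, k=8, n_boot=100, seed=7)
print("min cluster bootstrap Jaccard stability:", report.min_stability())
```

prints

```
species found: 8
zero-CBC conflicts: 0
CBCs between ribotype representatives:
[[0 1 1 2 2 3 4 5]
 [1 0 2 3 3 4 5 6]
 [1 2 0 3 3 4 5 6]
 [2 3 3 0 4 5 6 7]
 [2 3 3 4 0 5 6 7]
 [3 4 4 5 5 0 7 8]
 [4 5 5 6 6 7 0 9]
 [5 6 6 7 7 8 9 0]]
min cluster bootstrap Jaccard stability: 1.0
```

The recovered CBC matrix equals the planted one exactly: strains of the
same ribotype show zero CBCs and collapse into one species, the eight
ribotypes separate, and every k-mer cluster is rediscovered intact in all
100 bootstrap replicates.

The same stages are available from a shell:

```sh
ribodelim simulate --seed 7 --out run/
ribodelim its2 --fasta run/its2.fasta --struct run/its2.db --out run/its2/
ribodelim kmer --profiles run/kmer_profiles.tsv --k-clusters 8 --out run/kmer/
ribodelim consensus --partition run/its2/species_partition.tsv \
                    --partition run/kmer/clusters.tsv --out run/consensus/
```

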
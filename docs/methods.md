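# Methods

## Sequence-structure model of the ITS2 region

The ITS2 transcript is modelled as a pseudoknot-free secondary structure
given in dot-bracket (Vienna) notation alongside the nucleotide string.
Each position carries a joint state from a 12-letter alphabet — nucleotide
{A, C, G, U} crossed with structural state {unpaired, pair-opening,
pair-closing} — so that alignment and distance computation see sequence and
structure simultaneously. `T` is mapped to `U` on input; pair tables are
derived by stack parsing and reject pseudoknot bracket types.

**Alignment.** Global pairwise alignment is affine-gap Gotoh dynamic
programming maximizing a symmetric 12×12 substitution score. The default
scheme is additive: +2 for a nucleotide match, −1 mismatch; +2 for a
structural-state match, −2 mismatch; gap opening −8 and extension −2, with
a gap of length L costing `open + (L−1)·extend`. The matrix is a behavioral
stand-in for published ITS2-specific scoring tables and can be replaced
from a file (`ScoringScheme.from_tsv`); the downstream conclusions depend
on jointly rewarding sequence and structure agreement, not on the exact
constants. Multiple alignment is progressive: a neighbor-joining guide tree
over pairwise alignment-score distances, profile-profile merging in
postorder under "once a gap, always a gap". Inputs are sorted by record id
before any computation, which makes the output invariant to input order.
Tie-breaking in the traceback prefers the diagonal, then the vertical move.

**Distances and trees.** With p the fraction of differing 12-letter states
over mutually ungapped columns, the Jukes-Cantor correction generalized to
12 states is d = −(11/12)·ln(1 − (12/11)·p), defined for p < 11/12
(saturation raises). Percent identity is reported on nucleotides only.
Neighbor joining follows the classical agglomeration; Q-criterion ties go
to the lowest-index pair, negative branch lengths are clamped to zero (the
clamp count is kept on the tree), and on additive inputs the tree's path
metric reproduces the input exactly — a property the test suite checks on
random additive matrices. Bootstrap supports come from resampling alignment
columns with replacement, rebuilding distance + NJ per replicate, and
mapping bipartition frequencies onto the point-estimate tree.

**CBC counting.** A column couple is comparable when *both* sequences pair
those two columns (each through its own structure lifted into alignment
coordinates); couples where only one sequence pairs are not comparable.
Among comparable couples with canonical pairing (Watson-Crick or G·U
wobble) on both sides: a change of both partners counts as one CBC, a
change of one partner as one hemi-CBC. Couples with a non-canonical side
are excluded from both counts and tallied separately as "disrupted".
Whether published CBC tables fold hemi-CBCs into the headline count is
ambiguous; both are therefore computed and reported separately, and the
species logic uses full CBCs only. Species are the connected components of
the zero-CBC graph; non-transitive zero patterns (a~b, b~c, but a–c > 0)
are reported as explicit conflicts rather than silently resolved.

## k-mer genome comparison

Reads shorter than 90 bp or with mononucleotide Shannon entropy below 1.5
bits are discarded (the entropy unit is bits and the filter is applied per
read; the upstream tools this emulates leave both choices ambiguous).
Windows containing N are skipped; each 21-mer is stored canonically as the
lexicographic minimum of itself and its reverse complement, making profiles
strand-neutral. With n11 = |A∩B|, n10 = |A∖B|, n01 = |B∖A|:

- Kulczynski D = 1 − ½(n11/(n11+n10) + n11/(n11+n01))
- Ochiai D = 1 − n11/√((n11+n10)(n11+n01))
- Chord D = √(2·Ochiai D)

All three weight shared presence and ignore shared absence, which is the
right behavior when coverage differs strongly between strains (cultures vs
amplified single cells). Kulczynski is the reported default; the other two
are always written alongside. Clustering is agglomerative on the distance
matrix (average linkage by default; single/complete exposed). Cluster
robustness follows the bootstrap Jaccard scheme: individuals are resampled
with replacement, the resampled matrix is reclustered at the same K, and
each original cluster is scored by its best Jaccard overlap with the
replicate clusters on the resampled multiset; a cluster absent from a
replicate contributes zero. Stability is the per-cluster mean over 100
replicates; values above ~0.9 indicate clusters that are essentially
always rediscovered.

## Operon copy number and genome size

Copies per genome = operon coverage / arithmetic mean of the retained
single-copy gene coverages ("mean of per-gene means"; a median-based
variant is emitted alongside as a robust alternative). Genes flagged
multi-copy or without a hit are excluded; flags are trusted input, since
the reciprocal-BLAST validation that produces them is upstream of this
package. Genome size in Mb = fluorescence ratio × 20.9 fg × 0.978 Mb/fg;
the reference mass is the *Micromonas pusilla* RCC299 1C standard and the
fg→Mb constant is the standard genome-size convention. The estimator is
scale-invariant in coverage and unbiased as depth grows, checked at 10×,
30× and 100× simulated depth.

## Ordination and descriptor fitting

Phenotype comparisons use two-sided Mann-Whitney tests on log(x+1) data
(tie-corrected normal approximation) with Holm adjustment — chosen as a
conservative default where the family-wise procedure is unspecified; the
rank test itself is invariant to the monotone transform. The strain
ordination is classical PCoA: Gower double-centering of −½D², symmetric
eigendecomposition, scores scaled by √eigenvalue. Negative eigenvalues are
dropped without Cailliez correction and their share of absolute inertia is
reported. The descriptor matrix combines range-standardized ([0,1])
continuous phenotypes with raw binary infection columns. envfit regresses
each centered descriptor on the first two axes; R² = 1 − RSS/TSS, the
direction is the unit coefficient vector, and significance is the
permutation fraction (hits+1)/(n_perm+1). Constant descriptors (e.g. a host
column every strain infects) carry no direction and are skipped with NaN.

## Niche analysis

Abundances are Hellinger-transformed (√ of within-sample relative
abundance); environmental descriptors are range-standardized to [0,1] —
following the source analyses' explicit choice over the more common
z-scoring — then centered on the uniform-weight sample mean, so the origin
is "average sampled conditions". For taxon s with normalized profile q_s
over samples and sample positions x_i:

- marginality m_s = Σᵢ q_s(i)·x_i, OMI_s = ‖m_s‖²
- tolerance = Σᵢ q_s(i)·(uᵀx_i − ‖m_s‖)² with u = m_s/‖m_s‖
- residual tolerance = inertia − OMI − tolerance, inertia = Σᵢ q_s(i)‖x_i‖²

so OMI + tolerance + residual = inertia holds identically (tested to
1e-8). Niche axes are eigenvectors of MᵀWM with W the diagonal of taxon
abundance shares; the eigenvalue sum equals Σ w_s·OMI_s. Realized niches on
the first two axes are Gaussian product-kernel densities over the sample
scores, weighted by the taxon's counts, with per-axis bandwidths from
Silverman's rule on the weighted samples (n_eff = (Σw)²/Σw²; h = σ·n_eff^(−1/6)
in two dimensions). One bandwidth per taxon is computed on a grid shared by
all taxa (100×100 cells spanning the sample cloud plus a 10% margin);
per-taxon versus global bandwidth is not specified by the analyses this
mirrors, and the weighted per-taxon choice is logged here. Overlap is
Schoener's D = 1 − ½Σ|p_a − p_b| over grid cells; the overlap heatmap rows
are ordered by average-linkage clustering of 1 − D.

## Fitness and host range

The relative read contribution of a ribotype is divided by its mean operon
copy number to correct the rDNA amplification bias ("normalized
abundance"). Persistence is the calendar-day span of the longest run of
consecutive samples whose (non-normalized) relative contribution exceeds
10%, where a present-but-below-threshold sample breaks the run and date
gaps between successive samples of up to 2 days are tolerated (sampling
every 1–2 days). The denominator of the contribution defaults to parasite
reads rather than total reads: parasite ribotypes rarely reach even a few
percent of total reads, so a 10% bar is only attainable within the parasite
fraction — the printed definition is internally inconsistent on this point
and both options are exposed. Host range is counted at the species level
(distinct host species infected, maximum over a ribotype's strains) and
grouped into the classes {1}, {3}, {4–5}; the grouping map is
configurable. Ribotype-year records are compared across classes by
tie-corrected Kruskal-Wallis on log(x+1) data, with Dunn's z post-hoc tests
(pooled-rank, tie-corrected, Holm-adjusted) when the omnibus test rejects
at α = 0.05. A year in which a ribotype is absent contributes a zero
record rather than being dropped, keeping the design balanced.

## Synthetic-data generator

The generator emulates the study design: 8 ribotypes, strain-level
replicates, ≤3 strain-private SNPs within a ribotype, 1–9 CBCs between
ribotypes, operon copies in 58–270, 48 samples across 3 survey years, and
7 environmental descriptors (temperature, salinity, precipitation, tide
coefficient, NO₃, PO₄, Si(OH)₄).

**CBC planting.** All ITS2 records live on one four-helix scaffold (48
pair columns, helices of 12 pairs). Planting uses the 4-clique of mutually
compensatory pair states {A-U, G-C, U-A, C-G}: a planted pair column
assigns every ribotype one of ≤4 states, contributing exactly one CBC to
each pair of ribotypes it separates. The requested matrix is decomposed
into such partition columns — additively "star-shaped" matrices
(D_ij = c_i + c_j) get a direct construction; others go through an
exhaustive ≤4-block search — and unreachable matrices raise with the
offending ribotype pair named. The shipped default is the star matrix with
c = (0, 1, 1, 2, 2, 3, 4, 5), whose off-diagonal values span 1–9. Strain
SNPs are restricted to unpaired positions, which forces the within-ribotype
CBC count to zero by construction; that placement is a generator choice
(where real SNPs fall is not constrained by the emulated study) and is
flagged in the truth file.

**k-mer profiles.** Each ribotype owns an ordered private core pool (6,000
k-mers); a strain takes the first `core_fraction` of its 4,000-k-mer
profile from that pool — so the core is shared exactly within a ribotype,
and at fraction 1.0 profiles are identical within ribotypes — and fills the
rest with a private draw from an 80,000-k-mer background pool. At fraction
0 no ribotype signal remains. These desk-scale set sizes preserve the
qualitative geometry (within-ribotype distances ≈ 1 − core fraction,
between ≈ 1) without genome-scale k-mer counting.

**Coverage, community, phenotypes.** Gene coverages are Poisson draws over
aligned-region lengths of 300–1500 bp at the configured depth (30× by
default); the operon row is depth × planted copies over a 4 kb region; a
configurable fraction of genes arrives flagged multi-copy or no-hit.
Community counts are Poisson realizations of Gaussian niche responses,
E[count] = A·exp(−‖x_i − μ_s‖²/(2σ_s²)), in range-standardized descriptor
space; planted optima sit on the realized seasonal trajectory at staggered
phases (σ = 0.5, A = 300 by default) so each taxon prefers a specific phase
of the gradient and well-sampled taxa are recoverable (Spearman ρ > 0.9
against planted axis-1 optima). Host-range classes default to the pattern
of the emulated study (four single-host ribotypes, one 3-host, two
broad-range, one 3-host known only from single cells); cytometry values
scatter log-normally around ribotype means with one brighter/larger group
and a bimodal genome-size split.

**What the generator does not emulate:** sequencing error profiles,
amplification (MDA) bias, chimeras, within-ribotype k-mer divergence
structure (cores are shared exactly), overdispersed counts (a Poisson noise
model is used; real metabarcoding counts are typically overdispersed), and
taxonomic misassignment. Passing tests therefore demonstrate correctness of
the algorithms under the planted model and the stated noise, not robustness
to every artifact of real survey data.

## Numerical and design notes

- Determinism: every generator and every stochastic routine takes an
  explicit seed; identical seed + configuration gives byte-identical
  outputs.
- The Gotoh row update uses a prefix-max formulation of the horizontal gap
  state, valid because gap opening is never cheaper than extension.
- Positions are 0-based in all error messages and pair tables.
- Distance matrices are validated (symmetry, zero diagonal, non-negativity)
  at construction; Chord = √(2·Ochiai) is an exact identity and is tested
  to 1e-12.
- Bootstrap cluster stability on very small clusters (2–3 members) is
  intrinsically pessimistic — resampling frequently misses half a cluster —
  so study-scale runs use 8 strains per ribotype.
- The end-to-end demonstration uses 4 strains per ribotype and reduced
  k-mer pools; these sizes preserve every qualitative behavior while
  keeping a full run in seconds.

## Known limitations

- The progressive aligner is heuristic; pairwise projections of the MSA are
  only guaranteed near-optimal on the synthetic sets tested (≥90% of the
  optimal pairwise score).
- Partition-cut CBC planting cannot realize every symmetric integer matrix
  (the error path is exercised in tests); the feasible family is ample for
  study-like designs.
- GTR-corrected distances and parsimony/likelihood sequence-structure trees
  are out of scope; the JC-corrected NJ path is the implemented route.
- OMI significance per taxon (permutation of profiles) is available but not
  part of the default reports.
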
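# Methods

This note documents the models behind each stage, the defaults and why
they are set where they are, the numerical choices, and the limits of what
the synthetic data can show.

## Similarity graph and Markov clustering

Hits are read from 12-column tabular output; only query, subject and
e-value are used. An edge exists when either direction scores at or below
the e-value threshold (default 1e-20); its weight is `min(−log10 E, 200)`
of the best direction, with E = 0 mapped to the cap. The cap bounds the
dynamic range of the column-stochastic matrix; symmetrisation by the best
direction is standard practice for asymmetric search output.

MCL runs independently on each connected component of the graph (clusters
cannot span components, and the dense iteration stays small). Within a
component: self-loops at each node's maximum incident weight, expansion by
matrix squaring, inflation by element-wise power with per-column pruning of
entries below 1e-6, renormalisation, and convergence when the largest
element change drops below 1e-8 (cap 1000 iterations, warning on
non-convergence). Clusters are read from attractor systems of the limit
matrix; a node attracted to several systems goes to the one holding the
largest share of its column mass, ties to the lexicographically smaller
cluster; a node whose column prunes to zero becomes a singleton. The
inflation default is 5.0, which produces fine-grained families.

Cluster retention: outgroup species present (required for rooting), at
least 4 species, all members at least 100 residues, mean sequences per
species strictly below 5 and median strictly below 2, with mean and median
taken over the species actually in the cluster.

## Alignments and the supermatrix

The amino-acid alignment step is deliberately external (any aligner can be
used); the package validates and consumes aligned proteins. Back-translation
replaces each residue by its source codon and each gap by `---`, checking
per row that the CDS has exactly three nucleotides per residue and that
every codon translates to its residue under the standard code. Rows
covering less than 70% of the alignment length are removed (exact-threshold
rows are kept; an epsilon guards float rounding). A simple optional column
filter (drop columns with more than 50% gaps) exists but is off by default
— heuristic trimming is treated as an upstream tool decision.

Concatenation pads absent species with `?`; `-` marks within-alignment
gaps; both count as missing in the statistics, and GC content is computed
over unambiguous cells only. Internal coordinates are 0-based half-open;
all written reports are 1-based inclusive. A parsimony-informative column
has at least two of A/C/G/T present in at least two rows each; gaps and
ambiguity codes never count as states.

## Gene trees, masking, pruning

The built-in engine is Jukes–Cantor distances (pairs compared only at
columns where both rows have an unambiguous nucleotide; p ≥ 3/4 raises a
saturation error rather than silently truncating) and canonical
Saitou–Nei neighbor joining. NJ ties are broken by the lexicographically
smallest pair of cluster labels (a cluster is labelled by its smallest tip
label), making results independent of input order; a negative branch
length at a join is clamped to zero with the deficit moved to the sister
edge. The engine exists so the pipeline is self-contained; the scientific
novelty of the chain is downstream of gene-tree estimation, and an
external ML program can be plugged in as a command template producing
Newick from FASTA.

Rooting places the root on the edge separating all outgroup tips from the
rest; when no single edge separates them the best-scoring edge (maximising
outgroup-minus-ingroup tips on a side, ties to the smallest preorder
index) is used with a warning. Monophyly masking collapses every maximal
same-species clade to the member with the longest underlying sequence
(ties to the smallest sequence id); the kept tip retains its own terminal
branch length. Masking precedes paralogue pruning — this order matters: a
recent duplicate forms a same-species cherry, and no clade containing that
cherry can be single-copy, so pruning alone would exclude the species
entirely.

Paralogue pruning repeatedly extracts the maximally inclusive subtree with
at most one sequence per species, scoring candidates by species count,
then tip count, then smallest preorder index (the tie-break hierarchy is a
package decision; the procedure's source is silent). Emitted pieces need
at least two tips; one-tip remainders are discarded. Retained subtrees
must span at least 7 species and at least 60% of the originating cluster's
species (real-valued comparison: 7 of 12 fails). Each emitted subtree is
re-rooted on the outgroup when it contains one; otherwise the induced
rooting is kept (midpoint rooting is used for gene trees lacking the
outgroup in the downstream estimators).

## STAR

A rooted gene tree with tips mapped to species induces distances
`d(i, j) = 2 · rank(MRCA(i, j))`. Ranks decrease by one from the root
toward the tips (polytomy children share a rank). The species tree is
neighbor joining on the per-pair mean across gene trees, rooted by the
outgroup. Two conventions matter only in edge cases:

- **Root rank normalisation.** With complete taxon sampling the root rank
  convention (n − 1 versus n) shifts every distance by a constant and
  cannot change the NJ topology (this invariance is tested). With per-gene
  missing species, however, tree-local ranks put trees with different tip
  counts on different scales, and pairs that co-occur mainly in sparsely
  sampled gene trees are pulled together; on one synthetic data set this
  produced a wrong cherry even though gene trees favoured the true one
  16:7. The default therefore ranks every root `N_total − 1`, where
  `N_total` is the species count across all gene trees, making distances
  comparable across trees; the tree-local convention remains available as
  `rank_normalization="local"`.
- No weighting by per-pair gene counts is applied (plain mean), matching
  the summary-statistic design of the method.

Gene trees reduced to fewer than two species are skipped with a warning; a
species pair that never co-occurs is a hard error naming the pairs.

## Multilocus bootstrap

Each replicate draws G gene indices with replacement (G = gene count),
then independently resamples columns with replacement within each drawn
gene. Site resampling is at single-nucleotide granularity by default
(replicates are then nucleotide-only); a codon-triplet mode preserves
reading frame behind a flag. Replicate r uses seed `master_seed + r`, with
the gene-index stream separated from the per-gene site streams so results
are reproducible under parallel evaluation. Support is mapped onto the
point estimate (not a consensus); failed replicates — including those
whose gene draw misses every gene containing some species — are dropped
with the denominator adjusted, and a warning fires past 5% drops.

## Rates and saturation

OV is the count of mismatching unordered sequence pairs at a site, with
any pair involving a gap or ambiguity skipped. Parsimony-informative sites
sorted by (OV, site index) split into two equal partitions, the odd site
going to the slow half. Because OV is an absolute pair count, sites
observed in fewer sequences (missing data) score lower, so the partitions
are an imperfect proxy for true rate — a property of the method itself,
not of this implementation.

The saturation index is `Iss = H / H_FSS`: H is the mean per-site entropy
(bits, over A/C/G/T cells; gaps and ambiguities excluded from the counts;
sites with no counted cells contribute zero), and H_FSS is the mean
entropy of 200 Monte-Carlo randomisations in which each site's counted
cells are redrawn iid from the global base composition — the
full-saturation expectation at the same coverage pattern. This Monte-Carlo
estimator carries the finite-cell entropy bias of its row count, so Iss is
comparable only between alignments with similar depth; critical values are
simulated at the data's own taxon count, keeping the comparison
consistent. Replicates for the t-test are Iss recomputed on 200 bootstrap
resamples of sites against the fixed H_FSS. If the composition is
single-state, H and H_FSS are both zero and the index is defined as 0 by
continuity.

Critical values `Iss.c` come from a reduced simulation: JC evolution on a
caterpillar (asymmetrical, `Iss.c1`) or balanced (symmetrical, `Iss.c2`)
topology with all edges equal, scaled to a grid of root-to-tip loads
(0.5–10 expected substitutions/site, 8 points, 20 simulations each,
alignment length capped at 800); at each load the mean Iss and the
proportion of simulations in which NJ on uncorrected p-distances (which
stay defined under saturation) recovers the true topology are recorded,
and `Iss.c` is the Iss linearly interpolated where recovery crosses 95%.
The taxon count is capped at 32, mirroring the published tabulation limit
of the original method. In this design the asymmetrical critical value
falls steeply with taxon count (more, shorter internal edges at fixed
height), while the symmetrical one stays nearly flat — balanced trees
remain recoverable until Iss plateaus — so the non-increasing-in-taxa
property is asserted for the asymmetrical shape and `Iss.c2 ≥ Iss.c1` as
the shape effect. Verdicts follow the asymmetrical convention by default:
"substantial saturation" iff Iss is not smaller than Iss.c (equality
included), otherwise "no evidence of saturation" when the two-tailed
one-sample t-test rejects at 0.001; zero-variance replicate vectors skip
the t-test and are flagged in the report.

## Synthetic data

The multispecies-coalescent simulator works branchwise on an arbitrary
(not necessarily ultrametric) species tree in coalescent units: the k
lineages in a branch coalesce at rate k(k−1)/2, survivors pass rootward,
everything merges above the root. Its calibration is tested against the
3-taxon closed form `P(concordance) = 1 − (2/3)e^{−t}` and against
msprime as an independent oracle. Sequence evolution uses the
eigendecomposition of a reversible rate matrix (JC or HKY, normalised to
one expected substitution per site per unit), root states from the
stationary distribution, optional Gamma or explicit per-site rate
multipliers. Paralogues are injected as recent tip-sister duplicates on
short branches; ancient duplications are out of scope.

`make_fixture_dataset` emulates the shape of a deep-phylogeny
transcriptome study: 14 species with a designated outgroup, 50 gene
families of 170 codons, each ingroup species missing from a gene with
probability 0.3 (at least four species kept), 10% recent paralogues, and
half of the nucleotide sites designated fast. Free parameters not fixed by
that shape are set once on biological grounds: ingroup internal and
terminal branches of 3 coalescent units (≈5% gene-tree discordance per
branch, terminal branches long as expected for ancient divergences), an
outgroup stem of 5 units, the coalescent-to-substitution scale 0.05
substitutions/site per coalescent unit, and site-rate multipliers 0.3×
(slow) and 4× (fast) — fast sites are then saturated over deep paths while
slow sites stay in the regime where the saturation test clears them.
Simulated codons that land on a stop are nudged to a near neighbour
(T→C at the first position), mirroring the upstream exclusion of
stop-containing CDS; proteins are the exact translations, so the
similarity hits, protein and CDS files are mutually consistent and the
hit table encodes the true families (strong within-family hits, self-hits
at E = 0, sparse above-threshold cross-family noise).

What passing on these data does and does not show: the generator produces
gapless alignments (no indels), missing species at random (not biased by
sequencing depth), a single recent duplication mode, no alignment error,
no compositional heterogeneity, and a clean two-class rate structure. The
end-to-end recovery results therefore validate the machinery — clustering,
pruning, STAR, bootstrap, saturation calls — under the model's own
assumptions; they do not certify performance under alignment error,
ancient paralogy, or systematic missingness.

## Reported problem sizes

Test and acceptance runs use desk-scale sizes chosen to keep Monte-Carlo
error well inside the asserted tolerances: 10,000 genes per point of the
concordance curve, 50 replicates × 200 gene trees for STAR consistency,
500 random trees for the pruning oracle, 1,000 bootstrap replicates for
the distinct-gene fraction, 100 multilocus replicates for the end-to-end
support check, and 12–20 simulations per grid point for critical values.
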
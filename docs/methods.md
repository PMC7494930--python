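# Methods

This note documents the models, conventions and numerical choices behind
phagepop, and what the synthetic validation does and does not establish.

## Distances and clustering

**Canonical k-mer profiles.** A genome's profile is the *set* of canonical
k-mers (presence/absence, no counts): each window of length k contributes
`min(window, revcomp(window))`; windows containing N are skipped. Profiles
are therefore strand-invariant — a genome and its reverse complement are at
distance zero, which matters because assembly orientation of phage contigs
is arbitrary. k = 10 and k = 21 are both supported: k = 21 is effectively
collision-free (shared 21-mers imply homology), while at k = 10 the
4^10-word space is small enough that unrelated 50–170 kb genomes share
many words by chance, compressing the distance range from above. Both
resolve cluster structure; figures and the CLI default use k = 10.

**Binary distance.** The asymmetric binary (Jaccard) distance
`|A △ B| / |A ∪ B|`: joint absences carry no signal when genomes sample a
tiny fraction of k-mer space. It is undefined (error) when both sets are
empty, 0 iff the sets are equal and 1 iff disjoint; it satisfies the
triangle inequality (tested on random triples).

**UPGMA.** Average-linkage agglomeration; ties broken by the lowest
(node-id, node-id) pair, so results are order-deterministic. **The merge
height is the average inter-cluster distance itself, not half of it.**
Published cut heights on Jaccard-distance dendrograms (0.82, 0.81, 0.58,
0.52, 0.39, 0.36 in the study this package reimplements) are read on that
scale, so they can be passed directly as `--cut`. Cut-height selection
itself is a user decision — the method provides no automatic rule. Cluster
letters (A, B, …; subclusters A1, A2, …) are assigned by decreasing cluster
size with ties broken by smallest member label; letters are presentation
only, and all tests compare partitions, never letters.

## Gene families and the pan genome

Genes are clustered greedily: sort by length descending (ties by gene id);
each gene joins the earliest-founded family whose representative it matches
at ≥ 90% identity, else founds a new family. Identity is global *nucleotide*
identity — matches / alignment length, gaps counting against identity —
under Needleman–Wunsch with match +1, mismatch −1, gap −2. (Roary-style
pan-genome tools cluster translated proteins; nucleotide space was chosen
because the simulator's divergence dial is calibrated in substitutions per
site, keeping the 90% threshold directly interpretable.)

Two performance fast paths, both conservative: (1) a CD-HIT-style
short-word prescreen — a representative is a candidate only if it shares at
least 5% of the query's canonical 15-mers (at 90% identity the expected
intact-15-mer fraction is 0.9^15 ≈ 0.21, four times the bar; at 75%
identity it is ≈ 1%, so cross-cluster alignments are skipped); (2) an
equal-length pair whose positional identity already clears the threshold is
accepted without the DP, since the optimal alignment cannot have lower
identity than the gapless one in that regime.

Pan-genome partition by family prevalence p: core p ≥ 0.99, softcore
0.95 ≤ p < 0.99, shell 0.15 ≤ p < 0.95, cloud p < 0.15. With fewer than 20
genomes "core" reduces to "present in all genomes" and softcore is empty —
the regime of all per-cluster comparisons here. Percentages are rounded
half-up (the convention that reproduces all eight printed per-cluster
percentages in the packaged table, including 72/187 → 39%).

## Marker phylogenies

**Alignment.** A deliberately simple, fully deterministic progressive
aligner replaces Clustal-class tools: guide tree = UPGMA on p-distances of
pairwise global alignments; profiles merged leaf-to-root by affine-gap
profile–profile alignment (match +1, mismatch −1, gap open −5, extend −1;
column score = expected pairwise score over base frequencies, gaps scoring
zero inside profiles). Good enough for intra-family marker genes, not for
twilight-zone homology.

**TN93 distance.** Closed-form Tamura–Nei distance from the purine- and
pyrimidine-transition proportions P1, P2, the transversion proportion Q,
and base frequencies pooled over the two sequences (symmetric estimator).
Sites where either sequence has a gap are excluded pairwise (not complete
deletion across the alignment — more robust on mosaic genes; MEGA's default
differs). A non-positive logarithm argument raises an explicit saturation
error rather than returning NaN; inside bootstrap replicates only,
saturated pairs are capped at distance 5.0 so a replicate is never lost to
a single resampled-column pathology. Under equal base frequencies the
formula reduces exactly to Kimura two-parameter (tested).

**Tree building.** Saitou–Nei neighbor joining with deterministic
tie-breaking by leaf label; negative branch lengths are clamped to zero
with the deficit moved to the sister branch, preserving path lengths. NJ is
exact on additive matrices (tested on random trees up to 8 taxa). This
distance-based route replaces maximum-likelihood inference deliberately:
it is deterministic, runs in seconds, and the downstream consumer is
cluster membership, which both routes resolve identically at the
divergences of interest; per-branch numerical agreement with an ML tree is
*not* claimed.

**Bootstrap.** Columns resampled with replacement; each replicate re-runs
TN93 + NJ; support = percentage of replicates containing each internal
bipartition of the point tree, written as integer internal node labels.
1000 replicates by default (the study's convention); the test suite and
acceptance script use 100, which is ample for edges at ~100% support.

**Multi-copy markers.** Genomes with 2–3 exonuclease copies contribute one
leaf per copy (`genomeid__copyN`), mirroring the observation that copy
choice can split clusters. For cluster-concordance the pipeline assigns
each genome its first copy's cluster; trees with unequal leaf sets are
excluded from RF/branch-score comparison rather than pruned.

## Tree agreement

Robinson–Foulds distance = bipartitions present in exactly one tree;
branch score = sqrt of summed squared branch-length differences over the
union of bipartitions plus pendant edges (Kuhner–Felsenfeld). Rooted
dendrograms are treated as unrooted by merging the two root edges'
lengths in bipartition space. The study named only the R packages it used
for "topological and branch length agreement"; RF and branch score are
those packages' standard measures.

## Synteny blocks

LCBs are detected at gene-order level (not nucleotide level): a block is a
maximal run of families appearing in ≥ 2 genomes in consistent relative
order and orientation (or exactly reversed with flipped strands). Phage
genomes are module-organised, so gene-order blocks capture what
whole-genome aligners report as LCBs while remaining checkable against
simulator truth: an inversion in an otherwise identical pair yields
exactly 3 blocks; re-inverting restores 1. Detection is greedy
seed-and-extend (genomes in input order, leftmost unused partner
occurrences, extension while *all* members agree), each gene occurrence in
at most one block; `min_block_genes = 2` by default, since a single shared
gene is not evidence of collinearity. Tandem-repeat copy-number differences
surface as extra blocks, the analogue of "variable repeat regions
comprising multiple LCBs". There is no analogue of Mauve's LCB weight, so
published LCB counts are emulation references, not numeric targets.

## Taxonomy

Genus similarity = Sørensen–Dice over canonical 21-mer sets,
`2|A∩B|/(|A|+|B|)`; assignment requires similarity strictly > 0.50
(threshold 0 disables demarcation and always assigns). This alignment-free
proxy is monotone in nucleotide identity at fixed length and equals 1 only
for identical k-mer sets. At 21-mer scale the 50% bar corresponds to
roughly ≥ 96.5% sequence identity between equal-length genomes
(0.965^21 ≈ 0.47) — a strict reading of the genus rule appropriate for the
within-cluster divergences simulated here; with more diverged real genera
a nucleotide-level ANI tool would be the natural substitute.

Population summaries round family percentages half-up to integers
(27/38 → 71%) and genus prevalence to one decimal (5/11 → 45.5%), matching
the printed values they are tested against. Subcluster labels collapse by
stripping trailing digits/underscores (A1, A_3 → A).

## The simulator

What it emulates: populations of linear dsDNA genomes in 3 (configurable)
clusters; per-cluster genome length spread over 45–170 kb and G+C over
35.5–46.4% (larger genomes more AT-rich, as in the study's data); a
conserved packaging module with fixed gene order (terminase small subunit →
terminase large subunit → portal → capsid → scaffold); 1–3 exonuclease
copies per cluster; generic conserved modules interleaved with
cluster-specific variable modules; genes 300–3000 bp in multiples of 3 with
2–200 bp spacers; per-genome events (module swap from another cluster,
inversion, loss, tandem repeat) at configurable probabilities, all zero by
default.

Key dials and defaults: within-cluster divergence 0.01 and between-cluster
0.15 substitutions/site (the study reports no divergence estimates; these
were set once for clean separability — between ≥ 10× within — and all
validation statements are conditional on them). Substitutions are uniform
over the three alternative bases; no indels inside genes unless
`indel_rate > 0` (codon-length blocks, for exercising the aligner's gap
machinery). Circular permutation is ignored: all downstream measures are
set- or order-based and assembled contigs are conventionally linear.

Mechanics worth knowing: cluster ancestors derive conserved-module genes
from common ancestral sequences mutated at the between-cluster rate; since
uniform substitution drifts G+C toward 0.5, the cluster-specific variable
modules and spacers are generated at a compensating G+C so each genome
lands within ±0.02 of its cluster target. Variable-module gene lengths are
solved against the cluster's target genome length, so realised lengths stay
inside the configured range. All randomness flows from a single seeded
generator in a fixed call order; identical configs give byte-identical
populations.

What passing tests do **not** show about real data: the simulator has no
intra-gene recombination, no promoters/tRNAs/regulatory structure, no
assembly artifacts, uniform substitution (no codon position or GC-skew
structure), and sharply separated clusters. Recovery statements (ARI 1.0,
bootstrap ≥ 95, 100% genus recovery) certify the *implementations* under
the stated conditions, not performance on borderline real populations.

## Pipeline and problem sizes

The pipeline writes every artifact with a SHA256 manifest; a rerun with the
same config and seed is bit-identical (tested). Marker-based cluster calls
cut a UPGMA dendrogram on the marker TN93 matrix at 0.15, the midpoint of
the expected within-/between-cluster distance gap under default
divergences. Reference exemplars for taxonomy are the first genome (by id)
of each whole-genome cluster.

The analysis scripts and acceptance run use 3 clusters × 5 genomes
(45–170 kb), 100 bootstrap replicates, and a 3 × 4 smoke population for
the determinism check; the unit suite uses 3 × 3 populations of 25–45 kb
genomes. These sizes resolve every tested effect deterministically while
keeping a full run in the minutes range on one CPU.

## Known limitations

- Greedy first-fit family clustering has no second-pass reassignment; a
  gene sitting between two families joins the earlier-founded one.
- The k-mer Dice similarity saturates for genomes < ~10 kb and is not a
  calibrated ANI; genus thresholds on real data deserve an alignment-based
  check.
- Gene-order LCBs cannot see rearrangement breakpoints inside intergenic
  DNA or partial-gene homology.
- The packaged study table is transcribed verbatim and carries that
  table's internal inconsistencies: one genome size (1,699,535 bp) is
  flagged `suspect_typo` (the running text gives 173,384 bp as the
  maximum, and range computations exclude the flagged row); the printed
  table minimum (44,539 bp) differs from the text's 44,324 bp; and the
  table's Hanrivervirus row count (14) disagrees with the text's count of
  ten. These are documented, not resolved, and nothing quantitative
  depends on them.
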
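# Methods

This note documents the models and procedures implemented in phagekit, the
parameters that matter, the synthetic data the claims are demonstrated on,
and the numerical and design choices made where more than one defensible
option existed.

## Homology engine

Pairwise protein comparison is affine-gap Smith–Waterman over BLOSUM62 with
BLAST-style penalties: a gap of length L costs 11 + L. The alignment itself
is computed by Biopython's `PairwiseAligner`; the test suite holds it to
exact score agreement with an independent brute-force Gotoh dynamic
program on hundreds of seeded peptide pairs.

Scores are normalised with Karlin–Altschul statistics using the published
gapped BLOSUM62 constants λ = 0.267, K = 0.041:

    bitscore = (λ·S − ln K) / ln 2,    E = m·n·2^(−bitscore)

with effective search space m·n = total query residues × total subject
residues, no length correction. E-values are therefore comparable to, but
not bit-identical with, BLAST/DIAMOND output. This is deliberate: every
threshold used downstream (30% identity, coverage 50%, E ≤ 1e−3; E ≤ 1e−5
with ≥ 50 bits; E ≤ 1e−3 with ≥ 40 bits; E ≤ 1e−10) is coarse, and the
package's claims are about behaviour at those thresholds, not about
reproducing any particular search engine's statistics. Coverage is measured
on the query (for translated reads, on the translated fragment); this is
the common tabular convention, but note that published "coverage ≥ 50%"
thresholds do not always say which side they refer to, so results can
differ from analyses that used subject coverage.

Translated search processes all six reading frames (NCBI table 11),
splitting peptides at stop codons and discarding fragments shorter than
10 aa — too short to clear a 40-bit threshold, so dropping them only saves
time. At most the best hit per (query, subject, frame) is reported.

A k-mer prefilter (k = 4) precedes full alignment: a pair is aligned only
when it shares at least `min_kmer_hits` distinct 4-mers. The default of 2
("two-hit") makes random pairs vanishingly rare while pairs above ~50%
identity always seed. Genome-vs-genome comparison uses single-hit seeding
because homologs near the 30%-identity threshold share few exact 4-mers;
`prefilter=False` disables seeding entirely (used by the oracle tests).

## Comparative genomics

Two genes are homologs when their best hit reaches identity ≥ 30%,
query coverage ≥ 50% and E ≤ 1e−3, all inclusive. Self-hits and
within-genome hits are excluded; one pair per unordered gene pair is kept
by bitscore. The shared-gene count A→B is the number of A's genes with at
least one homolog in B (directional, so A→B and B→A can differ when
paralogs collapse).

The percentage matrix needs one number per genome pair, and the literature
rarely states the denominator. The default here divides the smaller
proteome's shared-gene count by that proteome's size, which is symmetric by
construction and bounded by 100; `mean` and directional `query`
normalisations are available, and the choice is recorded on the result
object. Zero-gene genomes get zero rows with a logged warning rather than
an error.

## Gene-content network

The protein graph takes edges from all-vs-all hits at E ≤ 1e−5 and
bitscore ≥ 50, weighted by the maximum qualifying bitscore in either
direction.

MCL is implemented in full: self-loops at the node's maximum incident
weight (1.0 for isolated nodes), column-stochastic normalisation, then
alternating expansion (matrix power, e = 2) and inflation (elementwise
power r = 2.0 with renormalisation), pruning entries below 1e−5, until the
matrix changes by less than 1e−8 or 100 iterations (non-convergence returns
the current clustering with a warning — it has not been observed on any
tested input). Clusters are read off as connected components of the
converged flow's support, which assigns every node exactly once; node order
is fixed lexicographically, so the partition is invariant to input order.
The dense-matrix implementation is appropriate for the graph sizes this
package targets (up to a few thousand proteins).

Genome similarity is the plain −log10 hypergeometric tail probability of
sharing at least the observed number of protein clusters, capped at 300,
with the cluster universe defined dataset-locally as the number of protein
clusters containing at least one protein from the genomes under comparison.
No multiple-comparison correction is applied by default; network-analysis
tools differ on this, so a pair-count (Bonferroni) correction is available
as a flag. Edges with score ≥ 1 (inclusive) are retained, and viral
clusters come from MCL on the genome network (connected components are
available as a fallback). Clusters of size one are reported as unclustered
rather than as singleton clusters.

Environmental contigs are admitted when ≥ 20 kb long and when the fraction
of *contig* genes with a homolog in some single focal genome is ≥ 20%
(contig-relative, since the focal-relative reading would depend on focal
proteome size; both boundaries inclusive).

## Fragment recruitment

The reciprocal pipeline: (1) screen reads by translated search against the
focal proteins at E ≤ 1e−3 and ≥ 40 bits; (2) search survivors against
focal + background viral + bacterial decoy proteins; (3) keep a read only
when its single best hit (highest bitscore; ties by lower E-value, then
lexicographic subject id — determinism requires a total order) is on a
focal genome. Background and decoy entries exist only to veto: reads are
never assigned to them. (4) Per group, RPKM = recruited reads / mean group
genome size in kb / millions of virome reads, with the mean taken
arithmetically over the group's focal genomes and each read counting once
for its assigned group. The single-pass mode skips the combined database
and assigns each read to the highest-bitscore focal hit at E ≤ 1e−10.

## Integration-site detection

Reads are mapped to each replicon by exact 12-mer seeding followed by
local alignment (match +1, mismatch −2, gap open 2 + extend 1, minimum
score 18) in a window around the best seeded diagonals; a read sharing no
12-mer with a reference is unmapped, which at ≤ a few percent substitution
error is a negligible loss for segments of ≥ 20 bp. A read is a phage–host
hybrid when its phage- and host-aligned segments each have ≥ 20 bp
(`min_flank`) exclusive to their replicon and jointly cover ≥ 90% of the
read. The bases aligning to both replicons — the overlap — are the core
candidate: at a true att junction the duplicated core aligns to both
genomes.

Junctions are clustered per side (attL: host segment upstream of the phage
segment on the host forward strand; attR: the reverse) within ± 5 bp of
host position; a call requires ≥ 2 supporting reads per side. The
host-side coordinate of each junction is estimated as the mode over its
supporting reads — the attL host segments end where the core ends, the
attR host segments start where it starts, and a sequencing error moves
only its own read's endpoint — and the core is the host reference
sequence between the two junction coordinates, verified to occur in the
phage as well. Reading the core from the reference rather than from read
overlaps makes the call robust to per-read errors; when the verification
fails (e.g. a mis-clustered junction), the caller falls back to pairwise
longest-common-substring voting over the read overlaps, again admitting
only candidates present in both replicons. attL/attR are then assembled
from the genome sequences around the verified positions. None of these
thresholds comes from a published protocol; they were chosen so that
planted-truth recovery is exact at desk scale, and all are configurable.

## Synthetic data

The generators are pure functions of their parameters and a seed.

- **Genomes**: genes of ~200 aa (uniform ± 30%) on random strands with
  50-bp spacers, codons sampled iid at a base-level G+C solved numerically
  so that stop-free codons realise the target G+C (excluding AT-rich stop
  codons would otherwise bias it upward by ~0.01); realised G+C lands
  within ±0.02 of target on multi-kb genomes. Defaults emulate gene-dense
  podophage-like genomes (60 genes ≈ 40 kb, G+C 0.45).
- **Families**: children mutate each retained protein site at the stated
  per-site rate (every mutation changes the residue, so expected identity
  is 1 − rate), back-translate keeping parent codons at unmutated sites,
  drop genes independently, and append novel genes.
- **Viromes**: read source drawn from normalised weights, uniform start
  and strand, substitution-only errors (no indels — sufficient to stress
  identity thresholds without complicating translated search), genomes
  linear by default. Read length 150 bp and error 0–1% are the package's
  defaults; real virome protocols vary, and no specific instrument is
  being imitated.
- **Lysogens**: the core is read from the host at the chosen site,
  inserted into the phage to form the attP-bearing phage, and integration
  cuts both replicons within the core:
  `lysogen = host[:s+c] + phage[p:] + phage[:p] + core + host[s+c:]`.
  No host or phage base is deleted or mutated, the lysogen length is
  host + phage + core, and the core appears exactly twice (attL, attR).
  By default the insertion point is resampled until the bases flanking
  the two core copies disagree, so the planted core is the *maximal*
  duplicated sequence; without this, chance flank agreement would extend
  the true core beyond the planted one in a large fraction of plantings
  and "exact recovery" would be ill-posed. Both the host site and the
  phage insertion point stay at least 150 bp (capped at a quarter of the
  replicon) from the linear assembly ends: the replicons are circular in
  reality, rotations are equivalent, and a junction read that also spans
  an assembly wrap-around point cannot be interpreted against the linear
  reference by any method. Non-unique cores are recorded as a warning on
  the truth object rather than an error.
- **Decoy hosts** for recruitment benchmarks carry a few prophage-remnant
  genes (donor phage genes at 25% divergence); without them host reads
  never pass the screen and the reciprocal step has nothing to do.

What the generators do *not* model — realistic gene-content and
codon-usage structure, quality-score error profiles, indels, repeats,
strain microdiversity — bounds what passing tests show: they demonstrate
that the algorithms are correct and well-calibrated under their stated
assumptions, not that any particular real data set will behave as cleanly.

## Benchmark problem sizes

The end-to-end study conditions (in `phagekit.scenarios`) use genomes of
~15–20 kb with ~25–30 genes, 50,000-read viromes for the recruitment
benchmark, and ~17-kb lysogens at 20× coverage for integration recovery.
These sizes preserve the statistical structure the analyses respond to
(group divergence 0.15 within, unrelated between; mixture 5:3:2 with 30%
host reads at 1% error; cores of 10–50 bp) at desk scale. Read weights in
the mixture are proportional to target ratio × group mean genome size, so
the expected RPKM proportions equal the target ratios exactly.

## Known limitations

- E-values are engine-specific; only threshold behaviour, not exact
  E-values, transfers to BLAST/DIAMOND-derived hit tables.
- Genome-level clustering uses MCL rather than the ClusterONE algorithm
  found inside some network-analysis tools; on well-separated groups the
  partitions agree, but dense overlapping networks may differ.
- The att caller assumes one dominant integration site per (phage, host)
  pair in the read set; mixed lysogen populations with several sites will
  produce one call per junction-cluster pair and may need manual review.
- Very short cores (< 12 bp) below the seed k-mer size are recovered via
  junction flanks, but their genomic positions can be ambiguous when the
  core recurs by chance.
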
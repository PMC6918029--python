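# phagekit

Computational characterisation of newly isolated phages: shared-gene
comparative genomics, gene-content network clustering, reciprocal best-hit
viromic fragment recruitment with group-level RPKM normalisation, and
prophage integration-site (att) detection — each exercisable end to end on
synthetic data with known truth.

The package is aimed at phage genomicists and viral ecologists who have a
handful of annotated phage genomes (for example small marine podoviruses of
40–60 kb) and want to answer four questions about them:

1. **How much gene content do they share with known phages?** Homologs are
   called from pairwise protein alignments at amino-acid identity ≥ 30%,
   alignment coverage ≥ 50% and E ≤ 1e−3, and summarised as a symmetric
   genome-by-genome shared-gene percentage matrix.
2. **Which genus-level groups do they form?** All-vs-all protein hits
   (E ≤ 1e−5, bitscore ≥ 50) are clustered into protein families with the
   Markov clustering algorithm (MCL). Each genome is profiled by the
   families it carries, and two genomes A and B sharing `c` families out of
   a universe of `U` are scored by the hypergeometric tail

   ```
   P = Σ_{i≥c} C(|A|, i) · C(U−|A|, |B|−i) / C(U, |B|),   score = −log10 P
   ```

   Edges with score ≥ 1 form the gene-sharing network; MCL on that network
   yields viral clusters (approximately genus-level groups). An inclusion
   filter admits environmental contigs of ≥ 20 kb sharing ≥ 20% of their
   genes with a focal phage.
3. **How abundant are they in viromes?** Reads are screened by six-frame
   translated search against the focal phage proteins (E ≤ 1e−3,
   bitscore ≥ 40), then re-searched against a combined database of focal +
   background viral + bacterial decoy proteins; a read is recruited only if
   its single best hit lies on a focal genome (the reciprocal filter).
   Abundance per phage group is

   ```
   RPKM = recruited reads / mean group genome size (kb) / (virome reads / 10^6)
   ```

   A single-pass mode for very large viromes assigns each read to the
   highest-bitscore focal hit at E ≤ 1e−10.
4. **Where do temperate phages integrate?** Reads from a lysogen are mapped
   to the phage and the candidate host genome; reads splitting into a
   phage-aligned and a host-aligned segment mark the prophage boundaries.
   Clustered junctions reconstruct attL/attR and the core sequence that is
   duplicated at both boundaries.

A self-contained protein homology engine (affine-gap Smith–Waterman over
BLOSUM62 with Karlin–Altschul bit-score/E-value statistics and a k-mer
prefilter) backs all of the above, so no external search binary is needed;
12-column BLAST/DIAMOND tabular hit files are read and written for
interoperability. A first-class synthetic-data module generates annotated
genomes, diverged families, truth-labelled viromes and planted lysogens so
every claim above is testable against known truth.

## A worked example

`examples/04_fragment_recruitment.py` mixes three synthetic phage groups at
genome-copy proportions 5:3:2 with 30% of reads drawn from bacterial hosts
carrying prophage-remnant genes, then runs the reciprocal pipeline:

```
read fates: {'assigned': 2739, 'reciprocal_rejected': 143, 'screened_out': 1118}
group accuracy of assigned reads: 100.00%
virome group  count  mean_kb  total_reads         rpkm
virome  grpA   1327  15.0975         4000 21973.836728
virome  grpB    797  15.2780         4000 13041.628485
virome  grpC    615  16.5865         4000  9269.586712
recovered RPKM proportions: {'grpA': 0.496, 'grpB': 0.294, 'grpC': 0.209} (target 0.5 / 0.3 / 0.2)
```

Every assigned read lands in its true group — the 143 rejected reads are
mostly host reads whose best combined hit is a decoy protein, which is
exactly what the reciprocal step is for — and the RPKM proportions recover
the planted 5:3:2 mixture within ~2%. The other examples
(`examples/01`–`05`) walk through genome simulation, the shared-gene
matrix, network clustering and att-site detection the same way; each prints
the numbers it computes and says what they mean.

There is also a thin command line (`phagekit simulate|search|compare|
network|recruit|attcall`) over the same library functions.

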
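"""Shared-gene comparative genomics of a phage family.

Homologs are called from all-vs-all protein alignments at the standard
thresholds (identity >= 30%, coverage >= 50%, E <= 1e-3); the shared-gene
percentage matrix is the numeric backbone of a genome-similarity heatmap.
"""

from phagekit import (
    all_vs_all_hits,
    call_homologs,
    generate_family,
    generate_genome,
    shared_gene_count,
    shared_gene_matrix,
)

family = generate_family(2, n_genes=20, aa_divergence=0.25, seed=5, group="fam")
outsider = generate_genome(20, seed=99, genome_id="outsider")
genomes = family + [outsider]

hits = all_vs_all_hits(genomes)
pairs = call_homologs(hits)
print(f"{len(hits)} raw hits -> {len(pairs)} homolog pairs at 30%/50%/1e-3")

n = shared_gene_count(family[0], family[1], pairs)
print(f"{family[0].genome_id} shares {n}/{family[0].n_genes} genes with "
      f"{family[1].genome_id}")

matrix = shared_gene_matrix(genomes, pairs)
print(matrix.percent.round(1))
# related genomes score high (diagonal is 100 by definition); the
# unrelated genome shares nothing, so its off-diagonal entries are 0
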
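"""Homolog calling and shared-gene comparative genomics.

Two genes are homologs when a pairwise protein hit reaches amino-acid
identity >= 30%, query coverage >= 50% and E-value <= 1e-3 (all thresholds
inclusive and configurable). The genome-by-genome shared-gene percentage
matrix summarises how much of each proteome a pair of phages has in common.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .genomes import AnnotatedGenome
from .homology import ProteinHit, ScoringModel, search

logger = logging.getLogger(__name__)


def genome_of(qualified_id: str) -> str:
    """Genome part of a ``genomeID|geneID`` qualified protein id."""
    return qualified_id.split("|", 1)[0]


@dataclass(frozen=True)
class HomologPair:
    """An unordered pair of homologous genes and its best supporting hit."""

    gene_a: str
    gene_b: str
    hit: ProteinHit


def all_vs_all_hits(
    genomes: Sequence[AnnotatedGenome],
    model: Optional[ScoringModel] = None,
    max_evalue: float = 10.0,
    min_kmer_hits: int = 1,
) -> list[ProteinHit]:
    """All-versus-all protein search over a genome set.

    Protein ids are genome-qualified. The k-mer prefilter is run in
    single-hit mode by default so that pairs near the 30%-identity homolog
    threshold are not lost to seeding.
    """
    proteins: dict[str, str] = {}
    for g in genomes:
        proteins.update(g.proteins())
    return search(
        proteins,
        proteins,
        model=model,
        mode="protein",
        max_evalue=max_evalue,
        min_kmer_hits=min_kmer_hits,
    )


def call_homologs(
    hits: Iterable[ProteinHit],
    min_identity: float = 30.0,
    min_coverage: float = 50.0,
    max_evalue: float = 1e-3,
    query_lengths: Optional[dict[str, int]] = None,
) -> list[HomologPair]:
    """Filter hits to homolog pairs at the three inclusive thresholds.

    Self-hits (same gene) and within-genome hits are excluded. One pair is
    kept per unordered (gene_a, gene_b), by highest bitscore. For hits read
    from external tabular files (which carry no coverage column), pass
    ``query_lengths`` so coverage can be recomputed from the aligned span.
    """
    best: dict[tuple[str, str], ProteinHit] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if genome_of(h.query_id) == genome_of(h.subject_id):
            continue
        cov = h.query_coverage
        if cov == 0.0 and query_lengths is not None:
            qlen = query_lengths.get(h.query_id)
            if qlen:
                cov = 100.0 * (abs(h.qend - h.qstart) + 1) / qlen
        if h.percent_identity < min_identity:
            continue
        if cov < min_coverage:
            continue
        if h.evalue > max_evalue:
            continue
        key = tuple(sorted((h.query_id, h.subject_id)))
        if key not in best or h.bitscore > best[key].bitscore:
            best[key] = h
    return [HomologPair(a, b, h) for (a, b), h in sorted(best.items())]


def shared_gene_count(
    a: AnnotatedGenome, b: AnnotatedGenome, pairs: Iterable[HomologPair]
) -> int:
    """Number of genes of ``a`` with at least one homolog in ``b``."""
    a_genes = {g.qualified_id for g in a.genes}
    b_genes = {g.qualified_id for g in b.genes}
    shared = set()
    for p in pairs:
        if p.gene_a in a_genes and p.gene_b in b_genes:
            shared.add(p.gene_a)
        elif p.gene_b in a_genes and p.gene_a in b_genes:
            shared.add(p.gene_b)
    return len(shared)


@dataclass
class SharedGeneMatrix:
    """Symmetric shared-gene percentage matrix with directional counts."""

    genome_ids: list[str]
    percent: pd.DataFrame  # genome x genome, 0-100
    directional_counts: pd.DataFrame  # columns: genome_a, genome_b, shared
    denominator: str = "min"

    def to_tsv(self, path: str) -> None:
        self.percent.to_csv(path, sep="\t", float_format="%.2f")

    def counts_to_tsv(self, path: str) -> None:
        self.directional_counts.to_csv(path, sep="\t", index=False)


def shared_gene_matrix(
    genomes: Sequence[AnnotatedGenome],
    pairs: Iterable[HomologPair],
    denominator: str = "min",
) -> SharedGeneMatrix:
    """Shared-gene percentages for every genome pair.

    ``denominator`` sets the normalisation of the percentage:

    - ``min`` (default): shared genes of the smaller proteome over its gene
      count — symmetric by construction and bounded by 100;
    - ``mean``: mean of the two directional counts over the mean gene count;
    - ``query``: directional, row genome's shared genes over its gene count.

    Genomes with zero genes get zero rows/columns (logged). The diagonal is
    100 for genomes with at least one gene.
    """
    if denominator not in ("min", "mean", "query"):
        raise ValueError("denominator must be min|mean|query")
    pairs = list(pairs)
    ids = [g.genome_id for g in genomes]
    n = len(ids)
    mat = np.zeros((n, n))
    rows = []
    for i, ga in enumerate(genomes):
        if ga.n_genes == 0:
            logger.warning("genome %s has no genes; row set to 0", ga.genome_id)
            continue
        mat[i, i] = 100.0
    for i in range(n):
        for j in range(i + 1, n):
            ga, gb = genomes[i], genomes[j]
            if ga.n_genes == 0 or gb.n_genes == 0:
                continue
            ab = shared_gene_count(ga, gb, pairs)
            ba = shared_gene_count(gb, ga, pairs)
            rows.append((ga.genome_id, gb.genome_id, ab))
            rows.append((gb.genome_id, ga.genome_id, ba))
            if denominator == "min":
                small_count, denom = (
                    (ab, ga.n_genes) if ga.n_genes <= gb.n_genes else (ba, gb.n_genes)
                )
                pct = 100.0 * small_count / denom
                mat[i, j] = mat[j, i] = pct
            elif denominator == "mean":
                pct = 100.0 * (ab + ba) / (ga.n_genes + gb.n_genes)
                mat[i, j] = mat[j, i] = pct
            else:  # query (directional)
                mat[i, j] = 100.0 * ab / ga.n_genes
                mat[j, i] = 100.0 * ba / gb.n_genes
    percent = pd.DataFrame(mat, index=ids, columns=ids)
    counts = pd.DataFrame(rows, columns=["genome_a", "genome_b", "shared"])
    return SharedGeneMatrix(ids, percent, counts, denominator)
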
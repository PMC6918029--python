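"""Gene-content network analysis.

All-vs-all protein hits are thresholded (E <= 1e-5, bitscore >= 50) into a
weighted protein graph; Markov clustering (MCL) partitions it into protein
clusters (families); genomes are profiled by the clusters they carry; the
probability of two genomes sharing at least their observed number of
clusters under the hypergeometric null becomes an edge score
(-log10 P, cutoff >= 1); and MCL on that genome network yields viral
clusters, approximately genus-level groupings. An inclusion filter for
environmental contigs (>= 20 kb, >= 20% shared genes with a focal genome)
mirrors how assembled metagenomic contigs are admitted alongside isolate
genomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.stats import hypergeom

from .comparative import HomologPair, genome_of
from .genomes import AnnotatedGenome
from .homology import ProteinHit

logger = logging.getLogger(__name__)

SCORE_CAP = 300.0


def build_protein_graph(
    hits: Iterable[ProteinHit],
    max_evalue: float = 1e-5,
    min_bitscore: float = 50.0,
) -> nx.Graph:
    """Weighted undirected protein graph from all-vs-all hits.

    Edge weight is the maximum bitscore over qualifying hits in either
    direction; self-hits are dropped.
    """
    g = nx.Graph()
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if h.evalue > max_evalue or h.bitscore < min_bitscore:
            continue
        u, v = h.query_id, h.subject_id
        if g.has_edge(u, v):
            if h.bitscore > g[u][v]["weight"]:
                g[u][v]["weight"] = h.bitscore
        else:
            g.add_edge(u, v, weight=h.bitscore)
    return g


@dataclass(frozen=True)
class ProteinCluster:
    cluster_id: str
    members: tuple[str, ...]


def mcl(
    graph: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    prune_threshold: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> list[ProteinCluster]:
    """Markov clustering of a weighted graph.

    Self-loops are added with weight equal to the node's maximum incident
    edge weight (1.0 for isolated nodes), columns are normalised to
    stochastic, and expansion (matrix power) alternates with inflation
    (elementwise power + renormalisation), pruning entries below
    ``prune_threshold``, until the matrix changes by less than ``tol`` or
    ``max_iter`` sweeps. Clusters are the connected components of the
    converged flow's support, which assigns every node exactly once. Node
    order is fixed lexicographically, so the partition is independent of
    input order.
    """
    nodes = sorted(graph.nodes())
    n = len(nodes)
    if n == 0:
        return []
    pos = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w < 0:
            raise ValueError("MCL requires non-negative edge weights")
        M[pos[u], pos[v]] = w
        M[pos[v], pos[u]] = w
    loop = M.max(axis=0)
    loop[loop == 0] = 1.0
    M[np.diag_indices(n)] = loop
    M /= M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = np.power(M, inflation)
        M[M < prune_threshold] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        if np.abs(M - prev).max() < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations", max_iter)

    support = M > prune_threshold
    adj = support | support.T
    n_comp, labels = connected_components(adj, directed=False)
    clusters: list[list[str]] = [[] for _ in range(n_comp)]
    for i, lab in enumerate(labels):
        clusters[lab].append(nodes[i])
    clusters = sorted((sorted(c) for c in clusters), key=lambda c: (-len(c), c[0]))
    return [
        ProteinCluster(cluster_id=f"C{i + 1:05d}", members=tuple(c))
        for i, c in enumerate(clusters)
    ]


@dataclass(frozen=True)
class GenomeProfile:
    """The set of protein clusters a genome carries."""

    genome_id: str
    clusters: frozenset[str]


def genome_profiles(
    protein_clusters: Sequence[ProteinCluster],
    genome_ids: Optional[Iterable[str]] = None,
) -> list[GenomeProfile]:
    """Profiles from genome-qualified protein cluster membership."""
    by_genome: dict[str, set[str]] = {}
    for pc in protein_clusters:
        for member in pc.members:
            by_genome.setdefault(genome_of(member), set()).add(pc.cluster_id)
    if genome_ids is not None:
        for gid in genome_ids:
            by_genome.setdefault(gid, set())
    return [
        GenomeProfile(gid, frozenset(cl)) for gid, cl in sorted(by_genome.items())
    ]


def hypergeometric_similarity(
    a: GenomeProfile, b: GenomeProfile, universe: int
) -> float:
    """-log10 of the hypergeometric tail P(shared clusters >= observed).

    With ``c`` shared clusters out of profiles of sizes |A| and |B| drawn
    from ``universe`` clusters, P = sum_{i>=c} C(|A|,i) C(U-|A|, |B|-i) /
    C(U, |B|). The score is capped at 300; c = 0 gives score 0. No
    multiple-comparison correction is applied here (see
    :func:`build_genome_network`).
    """
    na, nb = len(a.clusters), len(b.clusters)
    if universe < len(a.clusters | b.clusters):
        raise ValueError("universe smaller than the union of the profiles")
    c = len(a.clusters & b.clusters)
    if c == 0:
        return 0.0
    p = float(hypergeom.sf(c - 1, universe, na, nb))
    if p <= 0:
        return SCORE_CAP
    return min(-np.log10(p), SCORE_CAP)


@dataclass(frozen=True)
class NetworkEdge:
    genome_a: str
    genome_b: str
    score: float


def build_genome_network(
    profiles: Sequence[GenomeProfile],
    universe: Optional[int] = None,
    cutoff: float = 1.0,
    bonferroni_pairs: bool = False,
) -> list[NetworkEdge]:
    """Similarity edges between genome profiles, keeping score >= cutoff.

    ``universe`` defaults to the number of distinct protein clusters across
    the profiles. With ``bonferroni_pairs`` the tail probability is
    multiplied by the number of genome pairs before the -log10, the
    correction some gene-sharing network tools apply.
    """
    if universe is None:
        universe = len(set().union(*(p.clusters for p in profiles)) if profiles else set())
    n = len(profiles)
    n_pairs = n * (n - 1) // 2
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            score = hypergeometric_similarity(profiles[i], profiles[j], universe)
            if bonferroni_pairs and score < SCORE_CAP and n_pairs > 0:
                score = max(score - np.log10(n_pairs), 0.0)
            if score >= cutoff:
                edges.append(
                    NetworkEdge(profiles[i].genome_id, profiles[j].genome_id, score)
                )
    return edges


@dataclass(frozen=True)
class ViralCluster:
    cluster_id: str
    members: tuple[str, ...]


def detect_viral_clusters(
    edges: Sequence[NetworkEdge],
    all_genomes: Optional[Iterable[str]] = None,
    inflation: float = 2.0,
    method: str = "mcl",
) -> tuple[list[ViralCluster], list[str]]:
    """Cluster the genome similarity network.

    Returns ``(clusters, unclustered)``; clusters have >= 2 members,
    singletons are reported as unclustered. ``method`` is ``mcl`` (default)
    or ``components`` (connected components fallback).
    """
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.genome_a, e.genome_b, weight=e.score)
    if method == "mcl":
        parts = mcl(g, inflation=inflation)
        groups = [list(p.members) for p in parts]
    elif method == "components":
        groups = [sorted(c) for c in nx.connected_components(g)]
        groups.sort(key=lambda c: (-len(c), c[0]))
    else:
        raise ValueError("method must be 'mcl' or 'components'")
    clusters = []
    unclustered = []
    i = 0
    for members in groups:
        if len(members) >= 2:
            i += 1
            clusters.append(ViralCluster(f"VC{i:04d}", tuple(sorted(members))))
        else:
            unclustered.extend(members)
    if all_genomes is not None:
        seen = set(g.nodes())
        unclustered.extend(gid for gid in all_genomes if gid not in seen)
    return clusters, sorted(set(unclustered))


def filter_env_contigs(
    contigs: Sequence[AnnotatedGenome],
    focal: Sequence[AnnotatedGenome],
    pairs: Iterable[HomologPair],
    min_length: int = 20_000,
    min_shared_fraction: float = 0.20,
) -> list[AnnotatedGenome]:
    """Environmental-contig inclusion filter.

    Keep contigs of length >= ``min_length`` whose shared-gene fraction
    (contig genes with a homolog in one focal genome, over the contig's
    gene count) reaches ``min_shared_fraction`` for at least one focal
    genome. Both boundaries are inclusive. Contigs without genes are
    excluded with a logged warning.
    """
    pairs = list(pairs)
    focal_ids = {g.genome_id for g in focal}
    # contig gene -> set of focal genomes in which it has a homolog
    gene_focal: dict[str, set[str]] = {}
    for p in pairs:
        for ga, gb in ((p.gene_a, p.gene_b), (p.gene_b, p.gene_a)):
            if genome_of(gb) in focal_ids:
                gene_focal.setdefault(ga, set()).add(genome_of(gb))
    kept = []
    for contig in contigs:
        if contig.n_genes == 0:
            logger.warning("contig %s has no genes; excluded", contig.genome_id)
            continue
        if len(contig) < min_length:
            continue
        per_focal: dict[str, int] = {}
        for gene in contig.genes:
            for fid in gene_focal.get(gene.qualified_id, ()):
                per_focal[fid] = per_focal.get(fid, 0) + 1
        if per_focal and max(per_focal.values()) / contig.n_genes >= min_shared_fraction:
            kept.append(contig)
    return kept


def write_edges_tsv(edges: Iterable[NetworkEdge], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("genome_a\tgenome_b\tscore\n")
        for e in edges:
            fh.write(f"{e.genome_a}\t{e.genome_b}\t{e.score:.4f}\n")


def write_clusters_tsv(
    clusters: Iterable[ViralCluster], unclustered: Iterable[str], path: str
) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tgenome_id\n")
        for c in clusters:
            for m in c.members:
                fh.write(f"{c.cluster_id}\t{m}\n")
        for m in unclustered:
            fh.write(f"unclustered\t{m}\n")


def write_graphml(edges: Iterable[NetworkEdge], path: str) -> None:
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.genome_a, e.genome_b, weight=float(e.score))
    nx.write_graphml(g, path)
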
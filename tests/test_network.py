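"""Protein graph, MCL, hypergeometric similarity, viral clusters, filters."""

import networkx as nx
import numpy as np
import pytest

from oracles import naive_mcl
from phagekit.genomes import AnnotatedGenome, GeneRecord
from phagekit.homology import ProteinHit
from phagekit.network import (
    GenomeProfile,
    NetworkEdge,
    build_genome_network,
    build_protein_graph,
    detect_viral_clusters,
    filter_env_contigs,
    hypergeometric_similarity,
    mcl,
)
from phagekit.comparative import HomologPair


def make_hit(q, s, evalue=1e-10, bits=100.0):
    return ProteinHit(
        query_id=q, subject_id=s, percent_identity=50.0, alignment_length=100,
        mismatches=0, gap_opens=0, qstart=1, qend=100, sstart=1, send=100,
        evalue=evalue, bitscore=bits,
    )


class TestProteinGraph:
    def test_evalue_threshold_exclusive_above(self):
        g = build_protein_graph([make_hit("a", "b", evalue=1e-4)])
        assert g.number_of_edges() == 0

    def test_bitscore_threshold(self):
        assert build_protein_graph([make_hit("a", "b", bits=49.0)]).number_of_edges() == 0
        assert build_protein_graph([make_hit("a", "b", bits=50.0)]).number_of_edges() == 1

    def test_reciprocal_hits_keep_max_weight(self):
        g = build_protein_graph([make_hit("a", "b", bits=55), make_hit("b", "a", bits=60)])
        assert g["a"]["b"]["weight"] == 60

    def test_self_hits_dropped(self):
        assert build_protein_graph([make_hit("a", "a")]).number_of_edges() == 0


class TestMCL:
    def test_disjoint_triangles_give_two_clusters(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                          ("x", "y"), ("y", "z"), ("x", "z")])
        members = sorted(c.members for c in mcl(g))
        assert members == [("a", "b", "c"), ("x", "y", "z")]

    def test_isolated_node_is_singleton(self):
        g = nx.Graph()
        g.add_node("solo")
        g.add_edge("a", "b")
        clusters = {c.members for c in mcl(g)}
        assert ("solo",) in clusters

    def test_partition_covers_every_node_once(self):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(20, 0.15, seed=7)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.integers(1, 50))
        clusters = mcl(g)
        members = [m for c in clusters for m in c.members]
        assert sorted(members) == sorted(g.nodes)

    def test_input_order_invariance(self):
        edges = [("a", "b", 3.0), ("b", "c", 2.0), ("d", "e", 5.0)]
        g1, g2 = nx.Graph(), nx.Graph()
        for u, v, w in edges:
            g1.add_edge(u, v, weight=w)
        for u, v, w in reversed(edges):
            g2.add_edge(v, u, weight=w)
        assert [c.members for c in mcl(g1)] == [c.members for c in mcl(g2)]

    def test_agrees_with_naive_reference(self):
        for seed in range(12):
            rng = np.random.default_rng(seed)
            n = 8
            A = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.35:
                        A[i, j] = A[j, i] = float(rng.integers(1, 100))
            g = nx.Graph()
            g.add_nodes_from(f"{i}" for i in range(n))
            for i in range(n):
                for j in range(i + 1, n):
                    if A[i, j] > 0:
                        g.add_edge(f"{i}", f"{j}", weight=A[i, j])
            mine = sorted(sorted(int(m) for m in c.members) for c in mcl(g))
            ref = sorted(sorted(c) for c in naive_mcl(A))
            assert mine == ref

    def test_negative_weights_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=-1.0)
        with pytest.raises(ValueError):
            mcl(g)


class TestHypergeometricSimilarity:
    def test_no_shared_clusters_scores_zero(self):
        a = GenomeProfile("A", frozenset({"c1"}))
        b = GenomeProfile("B", frozenset({"c2"}))
        assert hypergeometric_similarity(a, b, 10) == 0.0

    def test_exact_small_case(self):
        a = GenomeProfile("A", frozenset({"c1", "c2"}))
        b = GenomeProfile("B", frozenset({"c1", "c2"}))
        # P = 1 / C(4,2) = 1/6
        assert hypergeometric_similarity(a, b, 4) == pytest.approx(
            -np.log10(1 / 6), abs=1e-9
        )

    def test_score_nondecreasing_in_overlap(self):
        universe = 50
        scores = []
        for c in range(0, 6):
            shared = {f"s{i}" for i in range(c)}
            a = GenomeProfile("A", frozenset(shared | {f"a{i}" for i in range(5 - c)}))
            b = GenomeProfile("B", frozenset(shared | {f"b{i}" for i in range(5 - c)}))
            scores.append(hypergeometric_similarity(a, b, universe))
        assert all(x <= y for x, y in zip(scores, scores[1:]))

    def test_symmetry(self):
        a = GenomeProfile("A", frozenset({"c1", "c2", "c3"}))
        b = GenomeProfile("B", frozenset({"c2", "c3", "c4", "c5"}))
        assert hypergeometric_similarity(a, b, 20) == hypergeometric_similarity(
            b, a, 20
        )

    def test_universe_too_small_rejected(self):
        a = GenomeProfile("A", frozenset({"c1", "c2"}))
        b = GenomeProfile("B", frozenset({"c3"}))
        with pytest.raises(ValueError):
            hypergeometric_similarity(a, b, 2)


class TestGenomeNetwork:
    def _profiles(self):
        return [
            GenomeProfile("A", frozenset({"c1", "c2", "c3"})),
            GenomeProfile("B", frozenset({"c1", "c2", "c4"})),
            GenomeProfile("C", frozenset({"c9"})),
        ]

    def test_cutoff_inclusive(self):
        profiles = self._profiles()
        score_ab = hypergeometric_similarity(profiles[0], profiles[1], 5)
        edges = build_genome_network(profiles, universe=5, cutoff=score_ab)
        assert any({e.genome_a, e.genome_b} == {"A", "B"} for e in edges)
        edges_above = build_genome_network(
            profiles, universe=5, cutoff=score_ab + 1e-9
        )
        assert not any({e.genome_a, e.genome_b} == {"A", "B"} for e in edges_above)

    def test_disjoint_profiles_never_linked(self):
        edges = build_genome_network(self._profiles(), universe=6, cutoff=0.5)
        assert not any("C" in (e.genome_a, e.genome_b) for e in edges)


class TestViralClusters:
    def test_two_groups_and_singletons(self):
        edges = [
            NetworkEdge("a1", "a2", 5.0), NetworkEdge("a2", "a3", 5.0),
            NetworkEdge("a1", "a3", 5.0), NetworkEdge("b1", "b2", 4.0),
        ]
        clusters, unclustered = detect_viral_clusters(
            edges, all_genomes=["a1", "a2", "a3", "b1", "b2", "s1", "s2"]
        )
        assert [set(c.members) for c in clusters] == [
            {"a1", "a2", "a3"}, {"b1", "b2"},
        ]
        assert unclustered == ["s1", "s2"]

    def test_empty_edges_leave_all_unclustered(self):
        clusters, unclustered = detect_viral_clusters([], all_genomes=["x", "y"])
        assert clusters == [] and unclustered == ["x", "y"]

    def test_components_fallback(self):
        edges = [NetworkEdge("a", "b", 2.0), NetworkEdge("b", "c", 2.0)]
        clusters, _ = detect_viral_clusters(edges, method="components")
        assert [set(c.members) for c in clusters] == [{"a", "b", "c"}]


def _contig(cid, length, n_genes):
    genes = [
        GeneRecord(f"g{i}", cid, i * 30, i * 30 + 30, "+", "M" * 9)
        for i in range(n_genes)
    ]
    return AnnotatedGenome(
        genome_id=cid, sequence="A" * length, genes=genes, kind="env_contig"
    )


class TestEnvContigFilter:
    def _pairs(self, contig_id, n_shared, focal_id="F"):
        dummy = make_hit("x", "y")
        return [
            HomologPair(f"{contig_id}|g{i}", f"{focal_id}|g{i}", dummy)
            for i in range(n_shared)
        ]

    def test_short_contig_excluded(self):
        contig = _contig("c1", 19_900, 10)
        focal = [_contig("F", 40_000, 10)]
        kept = filter_env_contigs([contig], focal, self._pairs("c1", 5))
        assert kept == []

    def test_low_sharing_excluded(self):
        contig = _contig("c2", 25_000, 10)
        focal = [_contig("F", 40_000, 10)]
        kept = filter_env_contigs([contig], focal, self._pairs("c2", 1))
        assert kept == []

    def test_boundary_inclusive(self):
        contig = _contig("c3", 20_000, 10)
        focal = [_contig("F", 40_000, 10)]
        kept = filter_env_contigs([contig], focal, self._pairs("c3", 2))
        assert [c.genome_id for c in kept] == ["c3"]

    def test_zero_gene_contig_excluded(self):
        contig = AnnotatedGenome(genome_id="c4", sequence="A" * 30_000, genes=[])
        kept = filter_env_contigs([contig], [_contig("F", 40_000, 5)], [])
        assert kept == []
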
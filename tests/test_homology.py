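"""Protein homology engine: alignment, statistics, translated search, IO."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import gotoh_local_score
from phagekit.genomes import revcomp
from phagekit.homology import (
    ProteinHit,
    ScoringModel,
    align_local,
    bits_and_evalue,
    read_hits,
    search,
    six_frame_fragments,
    write_hits,
)
from phagekit.simulate import generate_genome, simulate_virome

AA = "ACDEFGHIKLMNPQRSTVWY"

peptides = st.text(alphabet=AA, min_size=1, max_size=25)


class TestAlignLocal:
    def test_identical_peptide_scores_sum_of_diagonal(self):
        aln = align_local("MKVLH", "MKVLH")
        # BLOSUM62 diagonal: M=5 K=5 V=4 L=4 H=8
        assert aln.raw_score == 26
        assert aln.identity_pct == 100.0
        assert aln.alignment_length == 5

    def test_no_positive_pair_gives_empty_alignment(self):
        aln = align_local("A", "T")  # BLOSUM62 A<->T is 0
        assert aln.raw_score == 0 and aln.is_empty

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_local("", "MKV")

    def test_matches_bruteforce_dp_on_random_pairs(self, rng):
        for _ in range(80):
            a = "".join(AA[i] for i in rng.integers(0, 20, rng.integers(1, 31)))
            b = "".join(AA[i] for i in rng.integers(0, 20, rng.integers(1, 31)))
            assert int(round(align_local(a, b).raw_score)) == gotoh_local_score(a, b)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(a=peptides, b=peptides)
    def test_score_symmetry(self, a, b):
        assert align_local(a, b).raw_score == align_local(b, a).raw_score


class TestKarlinAltschul:
    def test_zero_bitscore_gives_search_space_evalue(self):
        model = ScoringModel(search_space=(500, 2000))
        # raw score putting the bitscore exactly at 0
        s0 = math.log(model.k) / model.lam
        bits, evalue = bits_and_evalue(max(s0, 0), model)
        assert evalue == pytest.approx(500 * 2000 * 2 ** -bits)

    def test_published_constants_arithmetic(self):
        bits, _ = bits_and_evalue(40, ScoringModel(search_space=(1, 1)))
        assert bits == pytest.approx(20.02, abs=0.01)

    def test_evalue_linear_in_search_space(self):
        m1 = ScoringModel(search_space=(1000, 1000))
        m2 = ScoringModel(search_space=(2000, 1000))
        _, e1 = bits_and_evalue(50, m1)
        _, e2 = bits_and_evalue(50, m2)
        assert e2 == pytest.approx(2 * e1)

    def test_evalue_strictly_decreasing_in_score(self):
        model = ScoringModel(search_space=(1000, 1000))
        evs = [bits_and_evalue(s, model)[1] for s in range(0, 200, 10)]
        assert all(a > b for a, b in zip(evs, evs[1:]))

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            ScoringModel(lam=0.0)


class TestSixFrameTranslation:
    def test_all_six_frames_produced(self):
        g = generate_genome(3, mean_gene_len=60, seed=1)
        frags = six_frame_fragments(g.sequence[:600])
        assert {abs(f.frame) for f in frags} <= {1, 2, 3}
        assert any(f.frame > 0 for f in frags) and any(f.frame < 0 for f in frags)

    def test_short_fragments_discarded(self):
        # 45 bp with a central stop in frame +1 -> two ~7 aa pieces, dropped
        nt = "ATGGCTGCTGCTGCTGCTTAAGCTGCTGCTGCTGCTGCTGCTGCT"
        frags = six_frame_fragments(nt, min_fragment_len=10)
        assert all(f.frame != 1 for f in frags)


@pytest.fixture(scope="module")
def genome_and_reads():
    g = generate_genome(10, mean_gene_len=150, seed=77, genome_id="S")
    reads = simulate_virome([(g, 1.0)], 30, read_len=150, seed=3)
    return g, reads


class TestTranslatedSearch:

    def test_exact_reads_hit_source_at_full_identity(self, genome_and_reads):
        g, reads = genome_and_reads
        hits = search(reads, g.proteins(), mode="translated", min_bitscore=40)
        by_read = {}
        for h in hits:
            by_read.setdefault(h.query_id, h)  # hits sorted by bitscore
        assert len(by_read) == len(reads)
        # reads fully inside a CDS align at 100% identity
        full = [h for h in by_read.values() if h.alignment_length >= 45]
        assert full and all(h.percent_identity == 100.0 for h in full)

    def test_reverse_complement_finds_same_subject(self, genome_and_reads):
        g, reads = genome_and_reads
        r = reads[0]
        fwd = search([(r.read_id, r.sequence)], g.proteins(), mode="translated")
        rev = search([(r.read_id, revcomp(r.sequence))], g.proteins(), mode="translated")
        assert fwd[0].subject_id == rev[0].subject_id
        assert fwd[0].frame == -rev[0].frame
        assert fwd[0].bitscore == pytest.approx(rev[0].bitscore)

    def test_random_reads_rarely_reach_significance(self, rng):
        decoy = generate_genome(50, seed=99, genome_id="D")
        reads = [
            (f"r{i}", "".join("ACGT"[j] for j in rng.integers(0, 4, 150)))
            for i in range(400)
        ]
        hits = search(reads, decoy.proteins(), mode="translated", max_evalue=1e-3)
        assert len({h.query_id for h in hits}) / 400 < 0.01

    def test_prefilter_does_not_change_results_on_homologs(self, genome_and_reads):
        g, reads = genome_and_reads
        sub = reads[:5]
        fast = search(sub, g.proteins(), mode="translated", min_bitscore=40)
        slow = search(
            sub, g.proteins(), mode="translated", min_bitscore=40, prefilter=False
        )
        key = lambda h: (h.query_id, h.subject_id, h.frame, round(h.bitscore, 6))
        assert sorted(map(key, fast)) == sorted(map(key, slow))

    def test_empty_subject_set_gives_empty_result(self, genome_and_reads):
        _, reads = genome_and_reads
        assert search(reads, {}, mode="translated") == []


class TestTabularIO:
    def _hits(self):
        return [
            ProteinHit("q1", "s1", 98.5, 100, 1, 0, 1, 100, 5, 104, 1.2e-30, 200.1),
            ProteinHit("q2", "s2", 45.0, 80, 40, 2, 3, 240, 1, 78, 3.0e-5, 55.3),
            ProteinHit("q3", "s3", 100.0, 20, 0, 0, 60, 1, 10, 29, 2.0e-8, 44.0),
        ]

    def test_round_trip_identity(self, tmp_path):
        path = str(tmp_path / "hits.tsv")
        write_hits(self._hits(), path)
        back = read_hits(path)
        for a, b in zip(self._hits(), back):
            assert (a.query_id, a.subject_id) == (b.query_id, b.subject_id)
            assert b.percent_identity == pytest.approx(a.percent_identity, abs=0.01)
            assert (a.alignment_length, a.mismatches, a.gap_opens) == (
                b.alignment_length, b.mismatches, b.gap_opens,
            )
            assert (a.qstart, a.qend, a.sstart, a.send) == (
                b.qstart, b.qend, b.sstart, b.send,
            )
            assert b.evalue == pytest.approx(a.evalue, rel=1e-3)
            assert b.bitscore == pytest.approx(a.bitscore, abs=0.05)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert read_hits(str(path)) == []

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "q\ts\t99.0\t10\t0\t0\t1\t10\t1\t10\t1e-5\t50.0\n"
            "q\ts\t99.0\t10\t0\t0\t1\t10\t1\t10\t1e-5\tNOTANUMBER\n"
        )
        with pytest.raises(ValueError, match=":2"):
            read_hits(str(path))

    def test_extra_trailing_columns_tolerated(self, tmp_path):
        path = tmp_path / "extra.tsv"
        path.write_text("q\ts\t99.0\t10\t0\t0\t1\t10\t1\t10\t1e-5\t50.0\textra\tcols\n")
        assert len(read_hits(str(path))) == 1
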
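"""Reciprocal fragment recruitment, RPKM arithmetic, single-pass mode."""

import pytest

from phagekit.genomes import AnnotatedGenome, GeneRecord
from phagekit.recruitment import (
    ReadAssignment,
    ReferenceDB,
    _best_hit_per_read,
    gov_assign,
    recruit,
    recruitment_report,
    rpkm,
    screen_reads,
)
from phagekit.homology import ProteinHit
from phagekit.simulate import (
    evolve_genome,
    generate_family,
    generate_genome,
    simulate_virome,
)


def _db_genome(gid, kb, group=None, kind="phage"):
    return AnnotatedGenome(
        genome_id=gid, sequence="A" * int(kb * 1000), genes=[], group=group, kind=kind
    )


class TestRpkmArithmetic:
    def _assignments(self, n, group="grpA"):
        return [
            ReadAssignment(f"r{i}", "assigned", genome_id="g", group=group)
            for i in range(n)
        ]

    def test_printed_definition(self):
        db = ReferenceDB(focal=[_db_genome("g", 50.0, group="grpA")])
        (ab,) = rpkm(self._assignments(1000), db, virome_total_reads=1_000_000)
        assert ab.rpkm == 20.0

    def test_zero_reads_zero_rpkm(self):
        db = ReferenceDB(focal=[_db_genome("g", 50.0, group="grpA")])
        (ab,) = rpkm([], db, virome_total_reads=1_000_000)
        assert ab.rpkm == 0.0 and ab.recruited_read_count == 0

    def test_group_mean_genome_size(self):
        db = ReferenceDB(
            focal=[_db_genome("g1", 40.0, "grpA"), _db_genome("g2", 60.0, "grpA")]
        )
        (ab,) = rpkm(self._assignments(500), db, virome_total_reads=2_000_000)
        assert ab.mean_genome_kb == 50.0
        assert ab.rpkm == pytest.approx(5.0)

    def test_invalid_total_reads(self):
        db = ReferenceDB(focal=[_db_genome("g", 50.0, group="grpA")])
        with pytest.raises(ValueError):
            rpkm([], db, virome_total_reads=0)

    def test_focal_without_group_rejected(self):
        with pytest.raises(ValueError):
            ReferenceDB(focal=[_db_genome("g", 50.0, group=None)])


class TestBestHitTieBreaks:
    def _hit(self, s, bits, evalue=1e-10):
        return ProteinHit(
            query_id="r1", subject_id=s, percent_identity=90.0, alignment_length=40,
            mismatches=4, gap_opens=0, qstart=1, qend=120, sstart=1, send=40,
            evalue=evalue, bitscore=bits,
        )

    def test_highest_bitscore_wins(self):
        best = _best_hit_per_read([self._hit("A|g", 55.0), self._hit("B|g", 60.0)])
        assert best["r1"].subject_id == "B|g"

    def test_ties_broken_by_evalue_then_subject(self):
        best = _best_hit_per_read(
            [self._hit("B|g", 60.0, 1e-12), self._hit("A|g", 60.0, 1e-10)]
        )
        assert best["r1"].subject_id == "B|g"
        best = _best_hit_per_read(
            [self._hit("B|g", 60.0, 1e-10), self._hit("A|g", 60.0, 1e-10)]
        )
        assert best["r1"].subject_id == "A|g"


@pytest.fixture(scope="module")
def small_pipeline():
    """One focal group, one background genome carrying an identical gene,
    one unrelated decoy; reads from focal and background."""
    focal = generate_genome(
        12, mean_gene_len=150, seed=501, genome_id="F1", group="grpF"
    )
    # background genome = moderately diverged relative of the focal phage
    background = evolve_genome(focal, 0.25, seed=502, genome_id="BG")
    background.kind = "background_viral"
    background.group = None
    decoy = generate_genome(15, seed=503, genome_id="DEC", kind="bacterial_decoy")
    db = ReferenceDB(
        focal=[focal], background_viral=[background], bacterial_decoys=[decoy]
    )
    return focal, background, decoy, db


class TestReciprocalPipeline:
    def test_focal_reads_assigned_to_focal(self, small_pipeline):
        focal, _, _, db = small_pipeline
        reads = simulate_virome([(focal, 1.0)], 60, read_len=150, seed=1)
        assignments = recruit(reads, db)
        assigned = [a for a in assignments if a.stage == "assigned"]
        assert len(assigned) > 45
        assert all(a.genome_id == "F1" and a.group == "grpF" for a in assigned)

    def test_background_reads_vetoed_not_classified(self, small_pipeline):
        # reads truly from the background relative pass the screen but are
        # rejected at the reciprocal step; none may be assigned to it
        focal, background, _, db = small_pipeline
        reads = simulate_virome([(background, 1.0)], 60, read_len=150, seed=2)
        assignments = recruit(reads, db)
        stages = {a.stage for a in assignments}
        assert "reciprocal_rejected" in stages
        assert all(a.genome_id in (None, "F1") for a in assignments)
        frac_assigned = sum(a.stage == "assigned" for a in assignments) / 60
        assert frac_assigned < 0.2

    def test_unrelated_reads_screened_out(self, small_pipeline):
        _, _, decoy, db = small_pipeline
        reads = simulate_virome([(decoy, 1.0)], 40, read_len=150, seed=3)
        assignments = recruit(reads, db)
        assert sum(a.stage == "screened_out" for a in assignments) >= 39

    def test_stage_conservation(self, small_pipeline):
        focal, background, decoy, db = small_pipeline
        reads = simulate_virome(
            [(focal, 1.0), (background, 1.0), (decoy, 1.0)], 90, read_len=150, seed=4
        )
        assignments = recruit(reads, db)
        assert len(assignments) == 90
        stages = [a.stage for a in assignments]
        assert set(stages) <= {"screened_out", "reciprocal_rejected", "assigned"}

    def test_empty_virome(self, small_pipeline):
        *_, db = small_pipeline
        assert recruit([], db) == []


class TestGovMode:
    def test_reads_go_to_highest_bitscore_genome(self):
        fam = generate_family(2, n_genes=10, aa_divergence=0.2, seed=601, group="g")
        reads = simulate_virome([(fam[0], 1.0)], 40, read_len=150, seed=5)
        assignments = gov_assign(reads, fam)
        assigned = [a for a in assignments if a.stage == "assigned"]
        assert assigned
        correct = sum(a.genome_id == fam[0].genome_id for a in assigned)
        assert correct / len(assigned) > 0.9

    def test_stringent_cutoff_leaves_weak_reads_unassigned(self):
        focal = generate_genome(
            10, mean_gene_len=150, seed=602, genome_id="F", group="gF"
        )
        reads = simulate_virome([(focal, 1.0)], 30, read_len=150, seed=6)
        loose = gov_assign(reads, [focal], max_evalue=1e-10)
        strict = gov_assign(reads, [focal], max_evalue=1e-60)
        n_loose = sum(a.stage == "assigned" for a in loose)
        n_strict = sum(a.stage == "assigned" for a in strict)
        assert n_strict < n_loose

    def test_gov_and_reciprocal_concordant_without_decoys(self):
        fams = [
            generate_family(2, n_genes=10, aa_divergence=0.15, seed=700 + i, group=g)
            for i, g in enumerate(["gA", "gB"])
        ]
        focal = [g for f in fams for g in f]
        db = ReferenceDB(focal=focal)
        reads = simulate_virome([(g, 1.0) for g in focal], 120, read_len=150, seed=7)
        rec = {a.read_id: a.group for a in recruit(reads, db) if a.stage == "assigned"}
        gov = {
            a.read_id: a.group
            for a in gov_assign(reads, focal, max_evalue=1e-10)
            if a.stage == "assigned"
        }
        common = set(rec) & set(gov)
        assert common
        agree = sum(rec[r] == gov[r] for r in common) / len(common)
        assert agree >= 0.95


class TestReport:
    def _abundances(self):
        db = ReferenceDB(
            focal=[
                _db_genome("g1", 40.0, "grpA"),
                _db_genome("g2", 50.0, "grpB"),
                _db_genome("g3", 60.0, "grpC"),
            ]
        )
        out = []
        for virome in ("v1", "v2"):
            out.extend(rpkm([], db, virome_total_reads=1000, virome_id=virome))
        return out

    def test_long_format_shape(self):
        df = recruitment_report(self._abundances())
        assert len(df) == 6
        assert list(df.columns) == [
            "virome", "group", "count", "mean_kb", "total_reads", "rpkm",
        ]

    def test_empty_report(self):
        df = recruitment_report([])
        assert len(df) == 0 and list(df.columns)[0] == "virome"

    def test_rpkm_rederivable_from_columns(self):
        db = ReferenceDB(focal=[_db_genome("g1", 40.0, "grpA")])
        asg = [ReadAssignment(f"r{i}", "assigned", "g1", "grpA") for i in range(77)]
        df = recruitment_report(rpkm(asg, db, virome_total_reads=5000))
        row = df.iloc[0]
        assert row["rpkm"] == pytest.approx(
            row["count"] / row["mean_kb"] / (row["total_reads"] / 1e6)
        )
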
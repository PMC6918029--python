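"""Reciprocal best-hit viromic fragment recruitment and RPKM abundances.

The four-step procedure:

1. screen every virome read by translated search against the focal phage
   proteins (E <= 1e-3, bitscore >= 40, both inclusive);
2. re-search the surviving candidates against a combined protein database
   of focal phages + background viral genomes + bacterial decoy genomes;
3. keep a read only if its single best combined hit lies on a focal
   genome (the reciprocal filter — background and decoy entries exist to
   veto, never to receive reads);
4. per phage group, normalise recruited read counts as RPKM = reads /
   (group mean genome size in kb) / (virome reads in millions).

A single-pass mode for very large viromes assigns each read directly to
the qualifying (E <= 1e-10) focal hit with the highest bitscore.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .comparative import genome_of
from .genomes import AnnotatedGenome, ViromeRead
from .homology import ProteinHit, ScoringModel, search


@dataclass
class ReferenceDB:
    """Focal phage genomes (grouped), background viral genomes, and
    bacterial decoy genomes for the reciprocal step."""

    focal: list[AnnotatedGenome]
    background_viral: list[AnnotatedGenome] = field(default_factory=list)
    bacterial_decoys: list[AnnotatedGenome] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.focal:
            if not g.group:
                raise ValueError(f"focal genome {g.genome_id} has no group label")

    @property
    def groups(self) -> list[str]:
        return sorted({g.group for g in self.focal})

    def group_of(self, genome_id: str) -> Optional[str]:
        for g in self.focal:
            if g.genome_id == genome_id:
                return g.group
        return None

    @property
    def focal_ids(self) -> frozenset[str]:
        return frozenset(g.genome_id for g in self.focal)

    def focal_proteins(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for g in self.focal:
            out.update(g.proteins())
        return out

    def combined_proteins(self) -> dict[str, str]:
        out = self.focal_proteins()
        for g in self.background_viral + self.bacterial_decoys:
            out.update(g.proteins())
        return out

    def mean_genome_kb(self, group: str) -> float:
        sizes = [len(g) for g in self.focal if g.group == group]
        if not sizes:
            raise ValueError(f"no focal genomes in group {group!r}")
        return sum(sizes) / len(sizes) / 1000.0


@dataclass
class ReadAssignment:
    """Outcome of recruitment for one read."""

    read_id: str
    stage: str  # screened_out | reciprocal_rejected | assigned | unassigned
    genome_id: Optional[str] = None
    group: Optional[str] = None
    best_bitscore: float = 0.0
    best_subject: Optional[str] = None


def _best_hit_per_read(hits: Iterable[ProteinHit]) -> dict[str, ProteinHit]:
    """Best hit per read: highest bitscore, ties by lowest evalue then
    lexicographic subject id (determinism)."""
    best: dict[str, ProteinHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if (
            cur is None
            or h.bitscore > cur.bitscore
            or (
                h.bitscore == cur.bitscore
                and (h.evalue, h.subject_id) < (cur.evalue, cur.subject_id)
            )
        ):
            best[h.query_id] = h
    return best


def screen_reads(
    virome: Sequence[ViromeRead],
    db: ReferenceDB,
    model: Optional[ScoringModel] = None,
    max_evalue: float = 1e-3,
    min_bitscore: float = 40.0,
) -> tuple[list[ReadAssignment], list[ViromeRead]]:
    """Step 1: screen reads against the focal proteins.

    Returns assignments for every read (stage ``screened_out`` for misses)
    and the surviving candidate reads.
    """
    hits = search(
        virome,
        db.focal_proteins(),
        model=model,
        mode="translated",
        max_evalue=max_evalue,
        min_bitscore=min_bitscore,
    )
    best = _best_hit_per_read(hits)
    assignments = []
    candidates = []
    for read in virome:
        h = best.get(read.read_id)
        if h is None:
            assignments.append(ReadAssignment(read.read_id, "screened_out"))
        else:
            assignments.append(
                ReadAssignment(
                    read.read_id,
                    "candidate",
                    best_bitscore=h.bitscore,
                    best_subject=h.subject_id,
                )
            )
            candidates.append(read)
    return assignments, candidates


def reciprocal_assign(
    candidates: Sequence[ViromeRead],
    db: ReferenceDB,
    model: Optional[ScoringModel] = None,
    max_evalue: float = 1e-3,
) -> list[ReadAssignment]:
    """Steps 2-3: search candidates against the combined database and keep
    reads whose best hit is on a focal genome.

    Reads are never assigned to background or decoy genomes; a best hit on
    one of those vetoes the read (``reciprocal_rejected``).
    """
    hits = search(
        candidates,
        db.combined_proteins(),
        model=model,
        mode="translated",
        max_evalue=max_evalue,
    )
    best = _best_hit_per_read(hits)
    out = []
    for read in candidates:
        h = best.get(read.read_id)
        if h is None:
            out.append(ReadAssignment(read.read_id, "reciprocal_rejected"))
            continue
        gid = genome_of(h.subject_id)
        if gid in db.focal_ids:
            out.append(
                ReadAssignment(
                    read.read_id,
                    "assigned",
                    genome_id=gid,
                    group=db.group_of(gid),
                    best_bitscore=h.bitscore,
                    best_subject=h.subject_id,
                )
            )
        else:
            out.append(
                ReadAssignment(
                    read.read_id,
                    "reciprocal_rejected",
                    best_bitscore=h.bitscore,
                    best_subject=h.subject_id,
                )
            )
    return out


def recruit(
    virome: Sequence[ViromeRead],
    db: ReferenceDB,
    model: Optional[ScoringModel] = None,
    screen_max_evalue: float = 1e-3,
    screen_min_bitscore: float = 40.0,
) -> list[ReadAssignment]:
    """Full reciprocal pipeline: screen then reciprocal-assign.

    Returns one assignment per input read (stages ``screened_out``,
    ``reciprocal_rejected`` or ``assigned``).
    """
    screened, candidates = screen_reads(
        virome, db, model, max_evalue=screen_max_evalue, min_bitscore=screen_min_bitscore
    )
    final = {a.read_id: a for a in screened if a.stage == "screened_out"}
    for a in reciprocal_assign(candidates, db, model):
        final[a.read_id] = a
    return [final[r.read_id] for r in virome]


@dataclass(frozen=True)
class GroupAbundance:
    """Recruited-read count and RPKM for one phage group in one virome."""

    virome_id: str
    group: str
    recruited_read_count: int
    mean_genome_kb: float
    virome_total_reads: int
    rpkm: float


def rpkm(
    assignments: Iterable[ReadAssignment],
    db: ReferenceDB,
    virome_total_reads: int,
    virome_id: str = "virome",
) -> list[GroupAbundance]:
    """Step 4: per-group RPKM.

    RPKM = recruited reads / mean group genome size (kb) / (total virome
    reads / 1e6). Groups with zero recruited reads are reported with RPKM
    0. Each read counts once for its assigned group.
    """
    if virome_total_reads < 1:
        raise ValueError("virome_total_reads must be >= 1")
    counts: dict[str, int] = {g: 0 for g in db.groups}
    for a in assignments:
        if a.stage == "assigned" and a.group is not None:
            counts[a.group] = counts.get(a.group, 0) + 1
    out = []
    for group in db.groups:
        kb = db.mean_genome_kb(group)
        if kb <= 0:
            raise ValueError(f"group {group!r} has zero mean genome size")
        value = counts[group] / kb / (virome_total_reads / 1e6)
        out.append(
            GroupAbundance(
                virome_id=virome_id,
                group=group,
                recruited_read_count=counts[group],
                mean_genome_kb=kb,
                virome_total_reads=virome_total_reads,
                rpkm=value,
            )
        )
    return out


def gov_assign(
    virome: Sequence[ViromeRead],
    focal: Sequence[AnnotatedGenome],
    model: Optional[ScoringModel] = None,
    max_evalue: float = 1e-10,
) -> list[ReadAssignment]:
    """Single-pass mode for very large viromes.

    Each read is assigned to the focal genome providing the highest-bitscore
    qualifying hit (E <= ``max_evalue``); no background/decoy database is
    used. Reads without a qualifying hit are ``unassigned``.
    """
    db = ReferenceDB(focal=list(focal))
    hits = search(
        virome,
        db.focal_proteins(),
        model=model,
        mode="translated",
        max_evalue=max_evalue,
    )
    best = _best_hit_per_read(hits)
    out = []
    for read in virome:
        h = best.get(read.read_id)
        if h is None:
            out.append(ReadAssignment(read.read_id, "unassigned"))
        else:
            gid = genome_of(h.subject_id)
            out.append(
                ReadAssignment(
                    read.read_id,
                    "assigned",
                    genome_id=gid,
                    group=db.group_of(gid),
                    best_bitscore=h.bitscore,
                    best_subject=h.subject_id,
                )
            )
    return out


def recruitment_report(abundances: Iterable[GroupAbundance]) -> pd.DataFrame:
    """Long-format abundance table, deterministically ordered."""
    rows = [
        {
            "virome": a.virome_id,
            "group": a.group,
            "count": a.recruited_read_count,
            "mean_kb": a.mean_genome_kb,
            "total_reads": a.virome_total_reads,
            "rpkm": a.rpkm,
        }
        for a in abundances
    ]
    df = pd.DataFrame(
        rows, columns=["virome", "group", "count", "mean_kb", "total_reads", "rpkm"]
    )
    return df.sort_values(["virome", "group"], kind="stable").reset_index(drop=True)


def write_assignments_tsv(assignments: Iterable[ReadAssignment], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstage\tgenome_id\tgroup\tbest_bitscore\tbest_subject\n")
        for a in assignments:
            fh.write(
                f"{a.read_id}\t{a.stage}\t{a.genome_id or '.'}\t{a.group or '.'}\t"
                f"{a.best_bitscore:.1f}\t{a.best_subject or '.'}\n"
            )
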
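"""Prophage integration-site (att) detection from read evidence.

Reads from a lysogen are mapped to the phage genome and the candidate host
genome; reads that split into a phage-aligned and a host-aligned segment
(each with sufficient exclusive flank) are phage-host hybrids spanning a
prophage boundary. Junctions are clustered by host position and side, and
the attL/attR structure is reconstructed: the core is the sequence common
to the left- and right-junction overlaps, duplicated at both prophage
boundaries, and is verified to occur in both replicons.

Mapping uses exact 12-mer seeding into the reference followed by banded
affine local alignment around the seeded window; a read sharing no seed
k-mer with a reference is not aligned to it (reported as unmapped).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import Align

from .genomes import AnnotatedGenome, ViromeRead, revcomp

logger = logging.getLogger(__name__)

_NT_CODE = np.full(128, 0, dtype=np.int64)
for _i, _c in enumerate("ACGT"):
    _NT_CODE[ord(_c)] = _i


def _nt_kmers(seq: str, k: int) -> np.ndarray:
    if len(seq) < k:
        return np.empty(0, dtype=np.int64)
    arr = _NT_CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    powers = 4 ** np.arange(k, dtype=np.int64)
    return win @ powers


@dataclass(frozen=True)
class ReadAlignment:
    """Best local alignment of one read against one reference.

    ``read_start``/``read_end`` are 0-based half-open coordinates on the
    forward-oriented read regardless of strand; ``ref_start``/``ref_end``
    on the reference forward strand.
    """

    read_id: str
    strand: str  # "+" or "-"
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    score: float
    n_identical: int

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start


class ReferenceIndex:
    """Seed index of a reference sequence (both strands) for read mapping."""

    def __init__(self, reference: AnnotatedGenome | str, k: int = 12):
        self.sequence = (
            reference.sequence if isinstance(reference, AnnotatedGenome) else reference
        ).upper()
        self.k = k
        codes = _nt_kmers(self.sequence, k)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = order.astype(np.int64)
        self._code_set = np.unique(codes)

    def shares_kmer(self, read: str) -> bool:
        """Cheap screen: does the read (either strand) share any k-mer?"""
        q = _nt_kmers(read, self.k)
        if len(q) == 0:
            return False
        idx = np.searchsorted(self._code_set, q)
        idx[idx >= len(self._code_set)] = len(self._code_set) - 1
        if (self._code_set[idx] == q).any():
            return True
        qr = _nt_kmers(revcomp(read), self.k)
        idx = np.searchsorted(self._code_set, qr)
        idx[idx >= len(self._code_set)] = len(self._code_set) - 1
        return bool((self._code_set[idx] == qr).any())

    def seed_diagonals(self, read: str) -> list[tuple[int, int]]:
        """(diagonal, support) candidates: diagonal = ref_pos - read_pos."""
        q = _nt_kmers(read, self.k)
        if len(q) == 0:
            return []
        lo = np.searchsorted(self._codes, q, side="left")
        hi = np.searchsorted(self._codes, q, side="right")
        diags: Counter = Counter()
        for qi in np.nonzero(hi > lo)[0]:
            for p in self._pos[lo[qi] : hi[qi]]:
                diags[int(p) - int(qi)] += 1
        if not diags:
            return []
        # merge nearby diagonals (within 8 bp) into bands
        merged: list[tuple[int, int]] = []
        for d in sorted(diags):
            if merged and d - merged[-1][0] <= 8:
                merged[-1] = (merged[-1][0], merged[-1][1] + diags[d])
            else:
                merged.append((d, diags[d]))
        merged.sort(key=lambda t: -t[1])
        return merged[:4]


def _make_nt_aligner(
    match: int, mismatch: int, gap_open: int, gap_extend: int
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def map_read(
    read: ViromeRead | tuple[str, str],
    index: ReferenceIndex,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = 2,
    gap_extend: int = 1,
    min_score: int = 18,
) -> Optional[ReadAlignment]:
    """Best seeded local alignment of a read (both strands) to a reference.

    Returns ``None`` when no seed k-mer is shared or no alignment reaches
    ``min_score``. Soft-clipped ends are implicit in the read span.
    """
    rid, seq = (read.read_id, read.sequence) if isinstance(read, ViromeRead) else read
    seq = seq.upper()
    aligner = _make_nt_aligner(match, mismatch, gap_open, gap_extend)
    best: Optional[ReadAlignment] = None
    L = len(seq)
    ref = index.sequence
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        for diag, _support in index.seed_diagonals(oriented):
            w0 = max(0, diag - 20)
            w1 = min(len(ref), diag + L + 20)
            window = ref[w0:w1]
            score = aligner.score(oriented, window)
            if score < min_score or (best is not None and score <= best.score):
                continue
            aln = next(iter(aligner.align(oriented, window)))
            qb, sb = aln.aligned
            r0, r1 = int(qb[0][0]), int(qb[-1][1])
            n_id = sum(
                1
                for (q0, q1), (s0, s1) in zip(qb, sb)
                for i in range(q1 - q0)
                if oriented[q0 + i] == window[s0 + i]
            )
            if strand == "-":
                r0, r1 = L - r1, L - r0
            best = ReadAlignment(
                read_id=rid,
                strand=strand,
                read_start=r0,
                read_end=r1,
                ref_start=w0 + int(sb[0][0]),
                ref_end=w0 + int(sb[-1][1]),
                score=float(score),
                n_identical=n_id,
            )
    return best


def map_reads_nt(
    reads: Sequence[ViromeRead],
    reference: AnnotatedGenome | str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = 2,
    gap_extend: int = 1,
    min_score: int = 18,
    k: int = 12,
) -> dict[str, ReadAlignment]:
    """Map reads to a reference; returns best alignment per mapped read."""
    index = ReferenceIndex(reference, k=k)
    out: dict[str, ReadAlignment] = {}
    for read in reads:
        aln = map_read(
            read, index, match, mismatch, gap_open, gap_extend, min_score
        )
        if aln is not None:
            out[read.read_id] = aln
    return out


@dataclass(frozen=True)
class JunctionEvidence:
    """One hybrid read spanning a prophage boundary.

    ``side`` is ``left`` when, with the read oriented to the host forward
    strand, the host segment precedes the phage segment (attL), and
    ``right`` otherwise (attR). ``overlap`` is the read sequence aligning
    to both replicons (the core candidate), reported on the host forward
    strand; ``host_pos`` is the host coordinate of the junction.
    """

    read_id: str
    phage_alignment: ReadAlignment
    host_alignment: ReadAlignment
    side: str
    overlap: str
    host_pos: int


def find_hybrid_reads(
    reads: Sequence[ViromeRead],
    phage: AnnotatedGenome | str,
    host: AnnotatedGenome | str,
    min_flank: int = 20,
    min_coverage: float = 0.90,
    min_score: int = 18,
    k: int = 12,
) -> list[JunctionEvidence]:
    """Detect reads that split into a phage segment and a host segment.

    A read is hybrid when both segments have at least ``min_flank`` bases
    exclusive to their replicon and the two segments jointly cover at
    least ``min_coverage`` of the read. The inter-segment overlap (bases
    aligning to both) is recorded as a core candidate.
    """
    phage_index = ReferenceIndex(phage, k=k)
    host_index = ReferenceIndex(host, k=k)
    evidence: list[JunctionEvidence] = []
    for read in reads:
        # cheap both-replicon screen before any alignment
        if not (phage_index.shares_kmer(read.sequence) and host_index.shares_kmer(read.sequence)):
            continue
        pa = map_read(read, phage_index, min_score=min_score)
        ha = map_read(read, host_index, min_score=min_score)
        if pa is None or ha is None:
            continue
        L = len(read.sequence)
        p0, p1 = pa.read_start, pa.read_end
        h0, h1 = ha.read_start, ha.read_end
        inter0, inter1 = max(p0, h0), min(p1, h1)
        overlap_len = max(0, inter1 - inter0)
        phage_excl = (p1 - p0) - overlap_len
        host_excl = (h1 - h0) - overlap_len
        union = (p1 - p0) + (h1 - h0) - overlap_len
        if phage_excl < min_flank or host_excl < min_flank:
            continue
        if union < min_coverage * L:
            continue
        # orient the read to the host forward strand
        if ha.strand == "-":
            fh0, fh1 = L - h1, L - h0
            fp0, fp1 = L - p1, L - p0
            oriented = revcomp(read.sequence)
        else:
            fh0, fh1, fp0, fp1 = h0, h1, p0, p1
            oriented = read.sequence
        side = "left" if fh0 <= fp0 else "right"
        i0, i1 = max(fp0, fh0), min(fp1, fh1)
        overlap_seq = oriented[i0:i1] if i1 > i0 else ""
        host_pos = ha.ref_end if side == "left" else ha.ref_start
        evidence.append(
            JunctionEvidence(
                read_id=read.read_id,
                phage_alignment=pa,
                host_alignment=ha,
                side=side,
                overlap=overlap_seq,
                host_pos=host_pos,
            )
        )
    return evidence


@dataclass(frozen=True)
class AttCall:
    """A reconstructed integration site.

    ``host_core_position``/``phage_core_position`` are 0-based starts of
    the core in the host and phage references; ``attL``/``attR`` are the
    junction sequences assembled from the genomes (flank + core + flank).
    """

    core: str
    attL: str
    attR: str
    host_core_position: int
    phage_core_position: int
    support_left: int
    support_right: int


def _cluster_positions(
    items: list[JunctionEvidence], window: int
) -> list[list[JunctionEvidence]]:
    """Greedy 1-D chaining of junction positions within ``window`` bp."""
    items = sorted(items, key=lambda e: e.host_pos)
    clusters: list[list[JunctionEvidence]] = []
    for e in items:
        if clusters and e.host_pos - clusters[-1][-1].host_pos <= window:
            clusters[-1].append(e)
        else:
            clusters.append([e])
    return clusters


def _vote_core(
    left: list[JunctionEvidence],
    right: list[JunctionEvidence],
    phage_seq: str,
    host_seq: str,
    cap: int = 20,
) -> str:
    """Candidate core by pairwise voting over junction overlaps.

    Each (left overlap, right overlap) pair proposes its longest common
    substring; single-read artefacts — sequencing errors in one overlap,
    chance one-base extensions past the junction — differ between reads
    and between sides, so the true core dominates the vote. Only
    candidates present in both replicons are eligible.
    """
    l_ovs = [e.overlap for e in left if e.overlap][:cap]
    r_ovs = [e.overlap for e in right if e.overlap][:cap]
    votes: Counter = Counter()
    for l_ov in l_ovs:
        for r_ov in r_ovs:
            core = _longest_common_substring(l_ov, r_ov)
            if core and core in host_seq and core in phage_seq:
                votes[core] += 1
    if not votes:
        return ""
    return max(votes, key=lambda s: (votes[s], len(s), s))


def _longest_common_substring(a: str, b: str) -> str:
    if not a or not b:
        return ""
    if len(a) > len(b):
        a, b = b, a
    best = ""
    n = len(a)
    for i in range(n):
        for j in range(n, i + len(best), -1):
            if j - i <= len(best):
                break
            if a[i:j] in b:
                if j - i > len(best):
                    best = a[i:j]
                break
    return best


def call_att(
    evidence: Sequence[JunctionEvidence],
    phage: AnnotatedGenome | str,
    host: AnnotatedGenome | str,
    min_support: int = 2,
    cluster_window: int = 5,
    flank: int = 20,
) -> list[AttCall]:
    """Cluster junction evidence and reconstruct attL/attR with the core.

    Junctions are clustered by host position (within ``cluster_window`` bp)
    per side; a call needs >= ``min_support`` reads on each side. The
    host-side end of the left junction and start of the right junction are
    each taken as the mode over their supporting reads (a single read's
    sequencing errors move only its own endpoint), and the core is the
    host reference sequence between them — the maximal sequence common to
    the two junctions — verified to occur in the phage as well. When that
    verification fails, the core is inferred by pairwise voting over the
    read overlaps instead. Side pairs that yield no common sequence
    produce no call (logged).
    """
    phage_seq = (phage.sequence if isinstance(phage, AnnotatedGenome) else phage).upper()
    host_seq = (host.sequence if isinstance(host, AnnotatedGenome) else host).upper()
    left = [e for e in evidence if e.side == "left"]
    right = [e for e in evidence if e.side == "right"]
    left_clusters = [
        c for c in _cluster_positions(left, cluster_window) if len(c) >= min_support
    ]
    right_clusters = [
        c for c in _cluster_positions(right, cluster_window) if len(c) >= min_support
    ]
    def _mode(values: list[int], prefer_high: bool) -> int:
        counts = Counter(values)
        sign = 1 if prefer_high else -1
        return max(counts, key=lambda v: (counts[v], sign * v))

    calls: list[AttCall] = []
    for lc in left_clusters:
        for rc in right_clusters:
            left_end = _mode([e.host_alignment.ref_end for e in lc], True)
            right_start = _mode(
                [e.host_alignment.ref_start for e in rc], False
            )
            core = ""
            if 0 < left_end - right_start <= 1000:
                candidate = host_seq[right_start:left_end]
                if candidate in phage_seq:
                    core = candidate
            if not core:
                core = _vote_core(lc, rc, phage_seq, host_seq)
            if not core:
                logger.info(
                    "left/right junctions share no common sequence "
                    "present in both replicons; no call"
                )
                continue
            host_pos = host_seq.find(core)
            phage_pos = phage_seq.find(core)
            c = len(core)
            attl = (
                host_seq[max(0, host_pos - flank) : host_pos]
                + core
                + phage_seq[phage_pos + c : phage_pos + c + flank]
            )
            attr = (
                phage_seq[max(0, phage_pos - flank) : phage_pos]
                + core
                + host_seq[host_pos + c : host_pos + c + flank]
            )
            calls.append(
                AttCall(
                    core=core,
                    attL=attl,
                    attR=attr,
                    host_core_position=host_pos,
                    phage_core_position=phage_pos,
                    support_left=len(lc),
                    support_right=len(rc),
                )
            )
    calls.sort(key=lambda c: (-(c.support_left + c.support_right), c.core))
    return calls


def detect_integration(
    reads: Sequence[ViromeRead],
    phage: AnnotatedGenome | str,
    host: AnnotatedGenome | str,
    min_flank: int = 20,
    min_support: int = 2,
    cluster_window: int = 5,
) -> list[AttCall]:
    """End-to-end att detection: hybrid reads then att calling."""
    ev = find_hybrid_reads(reads, phage, host, min_flank=min_flank)
    return call_att(
        ev, phage, host, min_support=min_support, cluster_window=cluster_window
    )


def write_att_tsv(calls: Iterable[AttCall], path: str) -> None:
    """att calls as TSV (1-based core start positions)."""
    with open(path, "w") as fh:
        fh.write(
            "core\tcore_length\thost_core_start\tphage_core_start\t"
            "support_left\tsupport_right\n"
        )
        for c in calls:
            fh.write(
                f"{c.core}\t{len(c.core)}\t{c.host_core_position + 1}\t"
                f"{c.phage_core_position + 1}\t{c.support_left}\t{c.support_right}\n"
            )


def write_att_fasta(calls: Iterable[AttCall], path: str) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(calls, start=1):
            fh.write(f">att{i}_core\n{c.core}\n")
            fh.write(f">att{i}_attL\n{c.attL}\n")
            fh.write(f">att{i}_attR\n{c.attR}\n")
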
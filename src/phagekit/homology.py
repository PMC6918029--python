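"""Self-contained protein homology search.

Local alignment (affine-gap Smith-Waterman over BLOSUM62, via
Bio.Align.PairwiseAligner), Karlin-Altschul bit-score/E-value statistics,
six-frame translated search of nucleotide reads against protein databases,
and reading/writing of 12-column BLAST/DIAMOND tabular hit files — so every
downstream stage runs without an external search binary while staying
interoperable with externally produced hit tables.

The statistics use published gapped BLOSUM62 constants (lambda=0.267,
K=0.041) with effective search space = total query residues x total subject
residues; E-values are therefore comparable to, but not bit-identical with,
BLAST output. All downstream thresholds in this package are coarse enough
that this does not matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .genomes import ViromeRead, revcomp

PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX"

# anything outside the BLOSUM62 alphabet is treated as X
_SANITIZE = str.maketrans(
    {c: "X" for c in map(chr, range(65, 91)) if c not in PROTEIN_ALPHABET}
)


def sanitize_protein(seq: str) -> str:
    return seq.upper().translate(_SANITIZE)


@dataclass
class ScoringModel:
    """Substitution matrix, gap penalties and Karlin-Altschul constants.

    A gap of length L costs ``gap_open + L * gap_extend`` (BLAST 11/1
    convention). ``search_space`` is (m, n): total query and subject residue
    counts; when unset it is filled in by :func:`search` per database.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    k: float = 0.041
    search_space: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("lambda and K must be positive")
        self._matrix = substitution_matrices.load(self.matrix_name)

    @property
    def matrix(self):
        return self._matrix

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = self._matrix
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@dataclass(frozen=True)
class LocalAlignment:
    """An optimal local alignment; empty (score 0) when no positive pair."""

    raw_score: float
    query_start: int = 0
    query_end: int = 0
    subject_start: int = 0
    subject_end: int = 0
    n_identical: int = 0
    alignment_length: int = 0
    mismatches: int = 0
    gap_opens: int = 0

    @property
    def is_empty(self) -> bool:
        return self.alignment_length == 0

    @property
    def identity_pct(self) -> float:
        if self.alignment_length == 0:
            return 0.0
        return 100.0 * self.n_identical / self.alignment_length


def _parse_alignment(aln, a: str, b: str) -> LocalAlignment:
    qb, sb = aln.aligned
    n_id = 0
    aligned_cols = 0
    gap_opens = 0
    gap_cols = 0
    for (q0, q1), (s0, s1) in zip(qb, sb):
        aligned_cols += q1 - q0
        for i in range(q1 - q0):
            if a[q0 + i] == b[s0 + i]:
                n_id += 1
    for j in range(1, len(qb)):
        dq = qb[j][0] - qb[j - 1][1]
        ds = sb[j][0] - sb[j - 1][1]
        gap_cols += dq + ds
        gap_opens += (dq > 0) + (ds > 0)
    aln_len = aligned_cols + gap_cols
    return LocalAlignment(
        raw_score=float(aln.score),
        query_start=int(qb[0][0]),
        query_end=int(qb[-1][1]),
        subject_start=int(sb[0][0]),
        subject_end=int(sb[-1][1]),
        n_identical=n_id,
        alignment_length=aln_len,
        mismatches=aligned_cols - n_id,
        gap_opens=gap_opens,
    )


def align_local(
    a: str, b: str, model: Optional[ScoringModel] = None
) -> LocalAlignment:
    """Optimal affine-gap local alignment of two protein sequences.

    Returns an empty alignment (score 0) when no positive-scoring residue
    pair exists. Raises on empty input.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    model = model or ScoringModel()
    a = sanitize_protein(a)
    b = sanitize_protein(b)
    aligner = model.make_aligner()
    score = aligner.score(a, b)
    if score <= 0:
        return LocalAlignment(raw_score=0.0)
    return _parse_alignment(next(iter(aligner.align(a, b))), a, b)


def bits_and_evalue(
    raw_score: float, model: ScoringModel
) -> tuple[float, float]:
    """Karlin-Altschul normalised score and expectation.

    bitscore = (lambda * S - ln K) / ln 2 ; evalue = m * n * 2^-bitscore.
    """
    if raw_score < 0:
        raise ValueError("raw_score must be >= 0")
    bits = (model.lam * raw_score - math.log(model.k)) / math.log(2.0)
    m, n = model.search_space
    evalue = m * n * math.pow(2.0, -bits)
    return bits, evalue


@dataclass(frozen=True)
class ProteinHit:
    """One pairwise protein (or translated-read) homology result.

    Coordinates are 1-based inclusive as in BLAST tabular output; for
    translated queries they are nucleotide positions on the read, with
    ``qstart > qend`` on the reverse strand. ``frame`` is 0 for protein
    queries, +/-1..3 for translated reads. ``query_coverage`` is the
    aligned query span over the query length (the translated fragment, in
    translated mode), as a percentage.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    raw_score: float = 0.0
    query_coverage: float = 0.0
    frame: int = 0


# ---------------------------------------------------------------------------
# six-frame translation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranslatedFragment:
    """A stop-free peptide from one reading frame of a nucleotide read."""

    frame: int  # +1..+3 forward, -1..-3 reverse
    aa_offset: int  # offset of the fragment within the frame translation
    peptide: str


def six_frame_fragments(
    nt: str, min_fragment_len: int = 10, table: int = 11
) -> list[TranslatedFragment]:
    """Translate all six frames, splitting at stops.

    Fragments shorter than ``min_fragment_len`` amino acids are discarded:
    they cannot clear any threshold used downstream and only cost time.
    """
    out: list[TranslatedFragment] = []
    nt = nt.upper()
    rc = revcomp(nt)
    for strand, seq in ((1, nt), (-1, rc)):
        for off in range(3):
            sub = seq[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            if len(sub) < 3 * min_fragment_len:
                continue
            aa = str(Seq(sub).translate(table=table))
            pos = 0
            for piece in aa.split("*"):
                if len(piece) >= min_fragment_len:
                    out.append(
                        TranslatedFragment(
                            frame=strand * (off + 1),
                            aa_offset=pos,
                            peptide=sanitize_protein(piece),
                        )
                    )
                pos += len(piece) + 1
    return out


def _nt_coords(
    frame: int, aa_offset: int, a_start: int, a_end: int, read_len: int
) -> tuple[int, int]:
    """Map fragment-local aa span to 1-based nt coordinates on the read."""
    off = abs(frame) - 1
    nt0 = off + 3 * (aa_offset + a_start)  # 0-based on frame strand
    nt1 = off + 3 * (aa_offset + a_end)
    if frame > 0:
        return nt0 + 1, nt1
    return read_len - nt0, read_len - nt1 + 1


# ---------------------------------------------------------------------------
# k-mer prefilter
# ---------------------------------------------------------------------------

_AA_CODE = np.full(128, 23, dtype=np.int64)
for _i, _c in enumerate(PROTEIN_ALPHABET):
    _AA_CODE[ord(_c)] = _i
_KBASE = 24


def _encode_kmers(seq: str, k: int) -> np.ndarray:
    if len(seq) < k:
        return np.empty(0, dtype=np.int64)
    arr = _AA_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    powers = _KBASE ** np.arange(k, dtype=np.int64)
    return win @ powers


class KmerIndex:
    """Sorted k-mer index over a protein database for candidate pairing.

    A query/subject pair is a candidate when they share at least
    ``min_hits`` distinct k-mers; with the defaults (k=4, two hits) random
    pairs are almost never aligned while pairs above ~50% identity always
    are. Use ``min_hits=1`` when sensitivity down to the 30%-identity
    homolog threshold matters more than speed.
    """

    def __init__(self, subjects: Sequence[tuple[str, str]], k: int = 4):
        self.k = k
        codes = []
        sids = []
        for idx, (_, seq) in enumerate(subjects):
            c = np.unique(_encode_kmers(seq, k))
            codes.append(c)
            sids.append(np.full(len(c), idx, dtype=np.int64))
        if codes:
            allc = np.concatenate(codes)
            alls = np.concatenate(sids)
            order = np.argsort(allc, kind="stable")
            self.codes = allc[order]
            self.sids = alls[order]
        else:
            self.codes = np.empty(0, dtype=np.int64)
            self.sids = np.empty(0, dtype=np.int64)
        self.n_subjects = len(subjects)

    def candidates(self, seq: str, min_hits: int = 2) -> np.ndarray:
        q = np.unique(_encode_kmers(seq, self.k))
        if len(q) == 0 or len(self.codes) == 0:
            return np.empty(0, dtype=np.int64)
        lo = np.searchsorted(self.codes, q, side="left")
        hi = np.searchsorted(self.codes, q, side="right")
        mask = hi > lo
        if not mask.any():
            return np.empty(0, dtype=np.int64)
        pieces = [self.sids[l:h] for l, h in zip(lo[mask], hi[mask])]
        hits = np.concatenate(pieces)
        counts = np.bincount(hits, minlength=self.n_subjects)
        return np.nonzero(counts >= min_hits)[0]


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------

QueryLike = Union[dict, Sequence]


def _as_pairs(items: QueryLike) -> list[tuple[str, str]]:
    if isinstance(items, dict):
        return list(items.items())
    out = []
    for it in items:
        if isinstance(it, ViromeRead):
            out.append((it.read_id, it.sequence))
        else:
            name, seq = it
            out.append((name, seq))
    return out


def search(
    queries: QueryLike,
    subjects: QueryLike,
    model: Optional[ScoringModel] = None,
    mode: str = "protein",
    max_evalue: float = 10.0,
    min_bitscore: float = 0.0,
    prefilter: bool = True,
    min_kmer_hits: int = 2,
    kmer_size: int = 4,
    min_fragment_len: int = 10,
) -> list[ProteinHit]:
    """Search protein or nucleotide queries against a protein database.

    In ``translated`` mode each read is translated in all six frames,
    peptides are split at stop codons (fragments < ``min_fragment_len`` aa
    discarded) and at most the best hit per (query, subject, frame) is
    reported. Hits are sorted by descending bitscore (ties: query, subject).
    """
    if mode not in ("protein", "translated"):
        raise ValueError("mode must be 'protein' or 'translated'")
    qpairs = _as_pairs(queries)
    spairs = [(sid, sanitize_protein(seq)) for sid, seq in _as_pairs(subjects)]
    if not spairs or not qpairs:
        return []
    model = model or ScoringModel()

    if mode == "protein":
        frag_lists = [
            [TranslatedFragment(0, 0, sanitize_protein(seq))] for _, seq in qpairs
        ]
    else:
        frag_lists = [
            six_frame_fragments(seq, min_fragment_len=min_fragment_len)
            for _, seq in qpairs
        ]

    m = sum(len(f.peptide) for frags in frag_lists for f in frags)
    n = sum(len(s) for _, s in spairs)
    model = replace(model, search_space=(max(m, 1), max(n, 1)))
    aligner = model.make_aligner()

    index = KmerIndex(spairs, k=kmer_size) if prefilter else None
    all_sidx = np.arange(len(spairs))

    hits: list[ProteinHit] = []
    for (qid, qseq), frags in zip(qpairs, frag_lists):
        best: dict[tuple[str, int], tuple] = {}
        for frag in frags:
            cand = (
                index.candidates(frag.peptide, min_hits=min_kmer_hits)
                if index is not None
                else all_sidx
            )
            for si in cand:
                sid, sseq = spairs[si]
                score = aligner.score(frag.peptide, sseq)
                if score <= 0:
                    continue
                bits, evalue = bits_and_evalue(score, model)
                if bits < min_bitscore or evalue > max_evalue:
                    continue
                key = (sid, frag.frame)
                if key not in best or score > best[key][0]:
                    best[key] = (score, bits, evalue, frag, sseq)
        for (sid, frame), (score, bits, evalue, frag, sseq) in best.items():
            aln = _parse_alignment(
                next(iter(aligner.align(frag.peptide, sseq))), frag.peptide, sseq
            )
            cov = 100.0 * (aln.query_end - aln.query_start) / len(frag.peptide)
            if frame == 0:
                qs, qe = aln.query_start + 1, aln.query_end
            else:
                qs, qe = _nt_coords(
                    frame, frag.aa_offset, aln.query_start, aln.query_end, len(qseq)
                )
            hits.append(
                ProteinHit(
                    query_id=qid,
                    subject_id=sid,
                    percent_identity=aln.identity_pct,
                    alignment_length=aln.alignment_length,
                    mismatches=aln.mismatches,
                    gap_opens=aln.gap_opens,
                    qstart=qs,
                    qend=qe,
                    sstart=aln.subject_start + 1,
                    send=aln.subject_end,
                    evalue=evalue,
                    bitscore=bits,
                    raw_score=score,
                    query_coverage=cov,
                    frame=frame,
                )
            )
    hits.sort(key=lambda h: (-h.bitscore, h.query_id, h.subject_id))
    return hits


# ---------------------------------------------------------------------------
# tabular IO (BLAST/DIAMOND outfmt 6)
# ---------------------------------------------------------------------------

TABULAR_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def write_hits(hits: Iterable[ProteinHit], path: str) -> None:
    """Write hits in 12-column BLAST tabular (outfmt 6) order."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}\t"
                f"{h.alignment_length}\t{h.mismatches}\t{h.gap_opens}\t"
                f"{h.qstart}\t{h.qend}\t{h.sstart}\t{h.send}\t"
                f"{h.evalue:.3e}\t{h.bitscore:.1f}\n"
            )


def read_hits(path: str) -> list[ProteinHit]:
    """Read a 12-column tabular hit file; extra trailing columns tolerated.

    Raises ValueError naming the offending line on malformed rows.
    """
    hits: list[ProteinHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected >=12 tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                hits.append(
                    ProteinHit(
                        query_id=parts[0],
                        subject_id=parts[1],
                        percent_identity=float(parts[2]),
                        alignment_length=int(parts[3]),
                        mismatches=int(parts[4]),
                        gap_opens=int(parts[5]),
                        qstart=int(parts[6]),
                        qend=int(parts[7]),
                        sstart=int(parts[8]),
                        send=int(parts[9]),
                        evalue=float(parts[10]),
                        bitscore=float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from None
    return hits
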
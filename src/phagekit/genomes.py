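"""Core genome containers and plain-text readers/writers.

Coordinates are 0-based half-open internally; every human-readable export
(gene tables, att reports) uses 1-based inclusive coordinates.
"""

from __future__ import annotations


import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from Bio.Seq import Seq

#: NCBI translation table used throughout (bacteria/archaea/phage).
CODON_TABLE = 11

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G+C bases; 0.0 for an empty sequence."""
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def translate_cds(cds: str, table: int = CODON_TABLE) -> str:
    """Translate a CDS (must include the stop codon) and strip the stop."""
    aa = str(Seq(cds).translate(table=table))
    return aa[:-1] if aa.endswith("*") else aa


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene on a replicon.

    ``start``/``end`` are 0-based half-open nucleotide coordinates of the
    CDS including its stop codon; ``protein`` is the stop-stripped
    translation of the strand-adjusted CDS.
    """

    gene_id: str
    genome_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    protein: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad gene interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def cds(self, genome_sequence: str) -> str:
        """Strand-adjusted CDS extracted from the genome sequence."""
        sub = genome_sequence[self.start : self.end]
        return sub if self.strand == "+" else revcomp(sub)

    @property
    def qualified_id(self) -> str:
        """Genome-qualified protein id, ``genomeID|geneID``."""
        return f"{self.genome_id}|{self.gene_id}"


GENOME_KINDS = ("phage", "host", "background_viral", "bacterial_decoy", "env_contig")


@dataclass
class AnnotatedGenome:
    """A replicon with an ordered gene complement.

    ``group`` labels recruitment focal genomes (e.g. a genus-level phage
    group); ``kind`` records the role the genome plays in an analysis.
    """

    genome_id: str
    sequence: str
    genes: list[GeneRecord] = field(default_factory=list)
    group: Optional[str] = None
    kind: str = "phage"

    def __post_init__(self) -> None:
        if self.kind not in GENOME_KINDS:
            raise ValueError(f"unknown genome kind {self.kind!r}")
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        for g in self.genes:
            if g.end > len(self.sequence):
                raise ValueError(
                    f"gene {g.gene_id} extends past the end of {self.genome_id}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def gc(self) -> float:
        return gc_fraction(self.sequence)

    def proteins(self) -> dict[str, str]:
        """Mapping of genome-qualified protein id to amino-acid sequence."""
        return {g.qualified_id: g.protein for g in self.genes}


@dataclass(frozen=True)
class ViromeRead:
    """A simulated or real virome read, optionally truth-labelled."""

    read_id: str
    sequence: str
    truth_genome: Optional[str] = None
    truth_group: Optional[str] = None


# ---------------------------------------------------------------------------
# FASTA / FASTQ / table IO
# ---------------------------------------------------------------------------


def _wrap(seq: str, width: int = 70) -> Iterator[str]:
    for i in range(0, len(seq), width):
        yield seq[i : i + width]


def read_fasta(path_or_handle) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, sequence)`` tuples.

    Accepts wrapped and unwrapped records; the id is the first
    whitespace-delimited token of the header.
    """
    close = False
    if isinstance(path_or_handle, (str, os.PathLike)):
        handle = open(path_or_handle)
        close = True
    else:
        handle = path_or_handle
    try:
        records: list[tuple[str, str]] = []
        name = None
        chunks: list[str] = []
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name = line[1:].split()[0] if len(line) > 1 else ""
                chunks = []
            elif line:
                chunks.append(line)
        if name is not None:
            records.append((name, "".join(chunks)))
        return records
    finally:
        if close:
            handle.close()


def read_fastq(path_or_handle) -> list[tuple[str, str]]:
    """Read FASTQ records as ``(id, sequence)``; qualities are ignored."""
    close = False
    if isinstance(path_or_handle, (str, os.PathLike)):
        handle = open(path_or_handle)
        close = True
    else:
        handle = path_or_handle
    try:
        records = []
        lines = [ln.rstrip("\n") for ln in handle]
        if len(lines) % 4 not in (0,) and lines and lines[-1] == "":
            lines = lines[:-1]
        for i in range(0, len(lines) - 3, 4):
            header = lines[i]
            if not header.startswith("@"):
                raise ValueError(f"malformed FASTQ at line {i + 1}")
            records.append((header[1:].split()[0], lines[i + 1]))
        return records
    finally:
        if close:
            handle.close()


def write_genome_fasta(genomes: Iterable[AnnotatedGenome], path: str) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.genome_id}\n")
            for chunk in _wrap(g.sequence):
                fh.write(chunk + "\n")


def write_protein_fasta(genomes: Iterable[AnnotatedGenome], path: str) -> None:
    """Per-gene protein FASTA with ``genomeID|geneID`` headers."""
    with open(path, "w") as fh:
        for g in genomes:
            for gene in g.genes:
                fh.write(f">{gene.qualified_id}\n")
                for chunk in _wrap(gene.protein):
                    fh.write(chunk + "\n")


def write_gene_table(genomes: Iterable[AnnotatedGenome], path: str) -> None:
    """GFF3-like TSV of gene coordinates (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("genome_id\tgene_id\tstart\tend\tstrand\tprotein_length\n")
        for g in genomes:
            for gene in g.genes:
                fh.write(
                    f"{g.genome_id}\t{gene.gene_id}\t{gene.start + 1}\t"
                    f"{gene.end}\t{gene.strand}\t{len(gene.protein)}\n"
                )


def write_reads_fasta(reads: Iterable[ViromeRead], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.sequence}\n")


def write_reads_fastq(reads: Iterable[ViromeRead], path: str, quality: str = "I") -> None:
    """FASTQ with a uniform quality character (default Q40)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{quality * len(r.sequence)}\n")


def write_truth_table(reads: Iterable[ViromeRead], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttruth_genome\ttruth_group\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.truth_genome or '.'}\t{r.truth_group or '.'}\n"
            )


def read_reads(path: str) -> list[ViromeRead]:
    """Load reads from FASTA or FASTQ (sniffed from the first character)."""
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        recs = read_fastq(path)
    else:
        recs = read_fasta(path)
    return [ViromeRead(read_id=r, sequence=s) for r, s in recs]
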
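"""Synthetic phage/host genomes, diverged genome families, truth-labelled
viromes, and planted lysogens.

Every generator is a pure function of its arguments and a seed, so each
analysis stage of the package can be exercised end to end against known
truth. The models are deliberately minimal: gene-dense genomes with iid
codon sampling biased to a target G+C, per-site amino-acid divergence with
gene gain/loss for families, uniformly placed substitution-only reads for
viromes, and site-specific integration that duplicates a core sequence at
attL/attR for lysogens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .genomes import (
    AnnotatedGenome,
    GeneRecord,
    ViromeRead,
    revcomp,
    translate_cds,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")

_ALL_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]
_SENSE_CODONS = [c for c in _ALL_CODONS if c not in STOP_CODONS]
_SENSE_GC = np.array([c.count("G") + c.count("C") for c in _SENSE_CODONS])


def _base_probs(gc: float) -> np.ndarray:
    """iid base probabilities (A,C,G,T order) at a target G+C fraction."""
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _sense_codon_probs(gc: float) -> np.ndarray:
    p = _base_probs(gc)
    lookup = {b: p[i] for i, b in enumerate(BASES)}
    w = np.array([lookup[c[0]] * lookup[c[1]] * lookup[c[2]] for c in _SENSE_CODONS])
    return w / w.sum()


def _expected_coding_gc(gc_eff: float) -> float:
    """Expected G+C of stop-free codons sampled at iid base level gc_eff."""
    probs = _sense_codon_probs(gc_eff)
    return float((probs * _SENSE_GC).sum() / 3.0)


def _calibrated_gc(target: float) -> float:
    """Solve for the iid base-level G+C whose stop-free codons hit target.

    Excluding the AT-rich stop codons shifts coding G+C upward by ~0.01,
    enough to matter against a +/-0.02 realism check, so the sampling level
    is solved for numerically.
    """
    lo, hi = 1e-3, 1 - 1e-3
    f = lambda g: _expected_coding_gc(g) - target
    if f(lo) > 0 or f(hi) < 0:  # pragma: no cover - extreme targets
        return target
    return float(brentq(f, lo, hi, xtol=1e-9))


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    idx = rng.choice(4, size=n, p=_base_probs(gc))
    return "".join(BASES[i] for i in idx)


def _random_cds(rng: np.random.Generator, n_codons: int, gc_eff: float) -> str:
    """Stop-free codons + one terminal stop, sampled at calibrated G+C."""
    probs = _sense_codon_probs(gc_eff)
    idx = rng.choice(len(_SENSE_CODONS), size=n_codons, p=probs)
    stop = STOP_CODONS[rng.integers(3)]
    return "".join(_SENSE_CODONS[i] for i in idx) + stop


def _gc_weighted_codon(rng: np.random.Generator, aa: str, gc: float) -> str:
    """A codon for ``aa`` chosen with probability tilted toward target G+C."""
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[11].forward_table
    codons = [c for c, a in table.items() if a == aa]
    p = _base_probs(gc)
    lookup = {b: p[i] for i, b in enumerate(BASES)}
    w = np.array([lookup[c[0]] * lookup[c[1]] * lookup[c[2]] for c in codons])
    return codons[rng.choice(len(codons), p=w / w.sum())]


def generate_genome(
    n_genes: int,
    mean_gene_len: int = 200,
    gc: float = 0.45,
    intergenic_len: int = 50,
    seed: int = 0,
    genome_id: Optional[str] = None,
    group: Optional[str] = None,
    kind: str = "phage",
) -> AnnotatedGenome:
    """Generate a gene-dense annotated genome.

    Parameters
    ----------
    n_genes : number of protein-coding genes (>= 1).
    mean_gene_len : mean protein length in amino acids; individual genes
        are drawn uniformly within +/-30% of the mean.
    gc : target G+C fraction in (0, 1); realised G+C lands within ~0.02
        of the target for genomes of tens of kb.
    intergenic_len : spacer length between consecutive genes (and at both
        genome ends), in bp.
    seed : RNG seed; the result is a pure function of the arguments.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    if mean_gene_len < 10 or intergenic_len < 0:
        raise ValueError("non-positive or too-short length parameters")
    rng = np.random.default_rng(seed)
    gc_eff = _calibrated_gc(gc)
    gid = genome_id or f"G{seed:06d}"

    lo = max(10, int(mean_gene_len * 0.7))
    hi = max(lo + 1, int(mean_gene_len * 1.3))
    parts: list[str] = [_random_seq(rng, intergenic_len, gc)]
    pos = intergenic_len
    genes: list[GeneRecord] = []
    for i in range(n_genes):
        n_aa = int(rng.integers(lo, hi + 1))
        cds = _random_cds(rng, n_aa, gc_eff)
        strand = "+" if rng.random() < 0.5 else "-"
        oriented = cds if strand == "+" else revcomp(cds)
        genes.append(
            GeneRecord(
                gene_id=f"g{i + 1:04d}",
                genome_id=gid,
                start=pos,
                end=pos + len(cds),
                strand=strand,
                protein=translate_cds(cds),
            )
        )
        parts.append(oriented)
        pos += len(cds)
        parts.append(_random_seq(rng, intergenic_len, gc))
        pos += intergenic_len
    return AnnotatedGenome(
        genome_id=gid, sequence="".join(parts), genes=genes, group=group, kind=kind
    )


def evolve_genome(
    parent: AnnotatedGenome,
    aa_divergence: float,
    gene_loss: float = 0.0,
    gene_gain: int = 0,
    seed: int = 0,
    genome_id: Optional[str] = None,
    mean_gene_len: int = 200,
    intergenic_len: int = 50,
) -> AnnotatedGenome:
    """Derive a child genome at a controlled amino-acid divergence.

    Each retained protein is mutated at per-site rate ``aa_divergence``
    (every mutation changes the residue, so expected identity to the parent
    is ``1 - aa_divergence``) and back-translated, keeping the parent codon
    at unmutated sites. Genes are dropped independently with probability
    ``gene_loss``; ``gene_gain`` novel genes are appended. The genome is
    re-assembled with fresh intergenic spacers at the parent's G+C.
    """
    if not 0 <= aa_divergence < 1:
        raise ValueError("aa_divergence must be in [0, 1)")
    if not 0 <= gene_loss <= 1:
        raise ValueError("gene_loss must be in [0, 1]")
    rng = np.random.default_rng(seed)
    gid = genome_id or f"{parent.genome_id}.d{seed}"
    gc = parent.gc
    gc_eff = _calibrated_gc(gc)

    parts: list[str] = [_random_seq(rng, intergenic_len, gc)]
    pos = intergenic_len
    genes: list[GeneRecord] = []
    idx = 0
    for gene in parent.genes:
        if rng.random() < gene_loss:
            continue
        cds = gene.cds(parent.sequence)
        codons = [cds[i : i + 3] for i in range(0, len(cds) - 3, 3)]
        stop = cds[-3:]
        prot = gene.protein
        new_codons = []
        for aa, codon in zip(prot, codons):
            if rng.random() < aa_divergence:
                new_aa = AMINO_ACIDS[rng.integers(20)]
                while new_aa == aa:
                    new_aa = AMINO_ACIDS[rng.integers(20)]
                new_codons.append(_gc_weighted_codon(rng, new_aa, gc))
            else:
                new_codons.append(codon)
        new_cds = "".join(new_codons) + stop
        strand = gene.strand
        oriented = new_cds if strand == "+" else revcomp(new_cds)
        idx += 1
        genes.append(
            GeneRecord(
                gene_id=f"g{idx:04d}",
                genome_id=gid,
                start=pos,
                end=pos + len(new_cds),
                strand=strand,
                protein=translate_cds(new_cds),
            )
        )
        parts.append(oriented)
        pos += len(new_cds)
        parts.append(_random_seq(rng, intergenic_len, gc))
        pos += intergenic_len
    lo = max(10, int(mean_gene_len * 0.7))
    hi = max(lo + 1, int(mean_gene_len * 1.3))
    for _ in range(gene_gain):
        n_aa = int(rng.integers(lo, hi + 1))
        cds = _random_cds(rng, n_aa, gc_eff)
        strand = "+" if rng.random() < 0.5 else "-"
        idx += 1
        genes.append(
            GeneRecord(
                gene_id=f"g{idx:04d}",
                genome_id=gid,
                start=pos,
                end=pos + len(cds),
                strand=strand,
                protein=translate_cds(cds),
            )
        )
        parts.append(cds if strand == "+" else revcomp(cds))
        pos += len(cds)
        parts.append(_random_seq(rng, intergenic_len, gc))
        pos += intergenic_len
    return AnnotatedGenome(
        genome_id=gid,
        sequence="".join(parts),
        genes=genes,
        group=parent.group,
        kind=parent.kind,
    )


def generate_family(
    n_members: int,
    n_genes: int = 30,
    aa_divergence: float = 0.2,
    gene_loss: float = 0.05,
    gene_gain: int = 2,
    gc: float = 0.45,
    mean_gene_len: int = 200,
    seed: int = 0,
    group: str = "family",
) -> list[AnnotatedGenome]:
    """A phage 'group': an ancestor plus members diverged from it."""
    ancestor = generate_genome(
        n_genes,
        mean_gene_len=mean_gene_len,
        gc=gc,
        seed=seed,
        genome_id=f"{group}_anc",
        group=group,
    )
    members = [ancestor]
    for i in range(1, n_members):
        members.append(
            evolve_genome(
                ancestor,
                aa_divergence,
                gene_loss,
                gene_gain,
                seed=seed + 1000 + i,
                genome_id=f"{group}_m{i}",
                mean_gene_len=mean_gene_len,
            )
        )
    return members[:n_members]


def implant_genes(
    base: AnnotatedGenome,
    donor: AnnotatedGenome,
    n_genes: int,
    aa_divergence: float = 0.25,
    seed: int = 0,
) -> AnnotatedGenome:
    """Append diverged copies of donor genes to a genome.

    Emulates a bacterial host carrying prophage remnants or other
    phage-homologous genes: the implanted genes are donor genes mutated at
    per-site rate ``aa_divergence``, appended (with spacers) to the base
    sequence. This is what makes the reciprocal recruitment filter earn its
    keep — host reads from such regions pass a naive homology screen.
    """
    rng = np.random.default_rng(seed)
    if n_genes > donor.n_genes:
        raise ValueError("donor has too few genes")
    gc = base.gc
    picks = rng.choice(donor.n_genes, size=n_genes, replace=False)
    parts = [base.sequence]
    pos = len(base.sequence)
    genes = list(base.genes)
    idx = len(genes)
    for gi in sorted(picks):
        gene = donor.genes[gi]
        cds = gene.cds(donor.sequence)
        codons = [cds[i : i + 3] for i in range(0, len(cds) - 3, 3)]
        new_codons = []
        for aa, codon in zip(gene.protein, codons):
            if rng.random() < aa_divergence:
                new_aa = AMINO_ACIDS[rng.integers(20)]
                while new_aa == aa:
                    new_aa = AMINO_ACIDS[rng.integers(20)]
                new_codons.append(_gc_weighted_codon(rng, new_aa, gc))
            else:
                new_codons.append(codon)
        new_cds = "".join(new_codons) + cds[-3:]
        spacer = _random_seq(rng, 50, gc)
        parts.append(spacer)
        pos += len(spacer)
        idx += 1
        genes.append(
            GeneRecord(
                gene_id=f"g{idx:04d}",
                genome_id=base.genome_id,
                start=pos,
                end=pos + len(new_cds),
                strand="+",
                protein=translate_cds(new_cds),
            )
        )
        parts.append(new_cds)
        pos += len(new_cds)
    return AnnotatedGenome(
        genome_id=base.genome_id,
        sequence="".join(parts),
        genes=genes,
        group=base.group,
        kind=base.kind,
    )


def simulate_virome(
    sources: Sequence[tuple[AnnotatedGenome, float]],
    n_reads: int,
    read_len: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
    circular: bool = False,
    read_prefix: str = "read",
) -> list[ViromeRead]:
    """Draw truth-labelled reads from a weighted genome mixture.

    The source of each read is drawn from the normalised weights, its start
    is uniform over valid positions, its strand uniform, and each base is
    substituted (to a different base) independently at ``error_rate``.
    Genomes are treated as linear unless ``circular`` is set.
    """
    if not sources:
        raise ValueError("at least one source genome required")
    weights = np.array([w for _, w in sources], dtype=float)
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("weights must be >= 0 with at least one positive")
    for g, _ in sources:
        if len(g) < read_len:
            raise ValueError(f"read_len {read_len} exceeds genome {g.genome_id}")
    probs = weights / weights.sum()
    rng = np.random.default_rng(seed)
    src_idx = rng.choice(len(sources), size=n_reads, p=probs)
    reads: list[ViromeRead] = []
    for i, si in enumerate(src_idx):
        genome = sources[si][0]
        L = len(genome)
        if circular:
            start = int(rng.integers(0, L))
            frag = (genome.sequence + genome.sequence)[start : start + read_len]
        else:
            start = int(rng.integers(0, L - read_len + 1))
            frag = genome.sequence[start : start + read_len]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        if error_rate > 0:
            arr = list(frag)
            err = rng.random(read_len) < error_rate
            for j in np.nonzero(err)[0]:
                alt = BASES[rng.integers(4)]
                while alt == arr[j]:
                    alt = BASES[rng.integers(4)]
                arr[j] = alt
            frag = "".join(arr)
        reads.append(
            ViromeRead(
                read_id=f"{read_prefix}_{i:07d}",
                sequence=frag,
                truth_genome=genome.genome_id,
                truth_group=genome.group,
            )
        )
    return reads


@dataclass
class IntegrationTruth:
    """Ground truth for one planted site-specific integration.

    ``phage_attp`` is the attP-bearing phage (the input phage with the core
    inserted at ``phage_core_start``); it is the correct mapping reference
    for integration-site detection. ``core`` is maximal in the lysogen by
    construction unless ``ensure_maximal_core`` was disabled.
    """

    host_id: str
    phage_id: str
    core: str
    host_core_start: int
    phage_core_start: int
    lysogen: AnnotatedGenome
    host: AnnotatedGenome
    phage_attp: AnnotatedGenome
    attl_position: int  # lysogen coordinate of the attL core copy
    attr_position: int  # lysogen coordinate of the attR core copy
    warning: Optional[str] = None


def plant_integration(
    host: AnnotatedGenome,
    phage: AnnotatedGenome,
    core_len: int = 30,
    host_site: Optional[int] = None,
    seed: int = 0,
    ensure_maximal_core: bool = True,
    min_end_distance: int = 150,
) -> IntegrationTruth:
    """Integrate a phage into a host at a site-specific core sequence.

    The core is read from the host at ``host_site`` and inserted into the
    phage at a random position to form the attP-bearing phage. Integration
    cuts both replicons within the core, producing::

        lysogen = host[:s+c] + phage[p:] + phage[:p] + core + host[s+c:]

    so the core flanks the prophage at attL and attR (duplicated), no host
    or phage base is deleted or mutated, and ``len(lysogen) == len(host) +
    len(phage) + core_len``.

    With ``ensure_maximal_core`` (default) the phage insertion point is
    resampled until the bases flanking the two core copies disagree, making
    the planted core the maximal duplicated sequence — without this, chance
    flank agreement would silently extend the true core.

    The insertion point (and a randomly drawn host site) is kept at least
    ``min_end_distance`` bp (capped at a quarter of the replicon length)
    from the ends of the linear assemblies. Rotations of the circular
    replicons are equivalent, so this loses no generality, but it keeps
    prophage-boundary reads from spanning an assembly's wrap-around point
    or falling off a truncated flank, either of which would make the
    planted site unrecoverable against the linear references by any
    method.
    """
    if core_len < 1:
        raise ValueError("core_len must be >= 1")
    rng = np.random.default_rng(seed)
    host_margin = max(1, min(min_end_distance, len(host) // 4))
    if host_site is None:
        host_site = int(
            rng.integers(host_margin, len(host) - core_len - host_margin + 1)
        )
    if host_site + core_len > len(host) or host_site < 0:
        raise ValueError("host_site + core_len exceeds host length")
    s, c = host_site, core_len
    core = host.sequence[s : s + c]

    warning = None
    if host.sequence.count(core) != 1:
        warning = "core is not unique in the host; recovery may be ambiguous"
    if core in phage.sequence:
        warning = "core already occurs in the phage; recovery may be ambiguous"

    hseq, pseq = host.sequence, phage.sequence
    margin = max(1, min(min_end_distance, len(phage) // 4))
    for _ in range(200):
        p = int(rng.integers(margin, len(phage) - margin + 1))
        if not ensure_maximal_core:
            break
        # maximality: attL left flank (host) vs attR left flank (phage), and
        # attL right flank (phage) vs attR right flank (host) must differ
        left_ok = s == 0 or hseq[s - 1] != pseq[p - 1]
        right_ok = s + c == len(hseq) or hseq[s + c] != pseq[p % len(pseq)]
        if left_ok and right_ok:
            break
    else:  # pragma: no cover - pathological sequences
        warning = warning or "could not place a maximal core in the phage"

    attp_seq = pseq[:p] + core + pseq[p:]
    attp_genes = [
        g if g.end <= p else (
            GeneRecord(g.gene_id, g.genome_id, g.start + c, g.end + c, g.strand, g.protein)
            if g.start >= p
            else None
        )
        for g in phage.genes
    ]
    phage_attp = AnnotatedGenome(
        genome_id=f"{phage.genome_id}.attP",
        sequence=attp_seq,
        genes=[g for g in attp_genes if g is not None],
        group=phage.group,
        kind=phage.kind,
    )

    lys_seq = hseq[: s + c] + pseq[p:] + pseq[:p] + core + hseq[s + c :]
    lysogen = AnnotatedGenome(
        genome_id=f"{host.genome_id}.lys.{phage.genome_id}",
        sequence=lys_seq,
        genes=[],
        group=host.group,
        kind="host",
    )
    assert len(lysogen) == len(host) + len(phage) + c
    return IntegrationTruth(
        host_id=host.genome_id,
        phage_id=phage.genome_id,
        core=core,
        host_core_start=s,
        phage_core_start=p,
        lysogen=lysogen,
        host=host,
        phage_attp=phage_attp,
        attl_position=s,
        attr_position=s + c + len(pseq),
        warning=warning,
    )
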
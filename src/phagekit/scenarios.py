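"""Benchmark study conditions built from the synthetic-data generators.

These functions define, in one place, the synthetic data sets on which the
package's end-to-end claims are demonstrated: a three-group virome mixture
with bacterial-host contamination for recruitment, a multi-family genome
set for gene-sharing network clustering, and batches of planted lysogens
for integration-site recovery. Problem sizes are desk-scale by design
(genomes of ~15-20 kb rather than the 40-60 kb of real podophage isolates);
the statistical structure — group divergences, mixture weights, error
rates — is what the analyses are sensitive to, not the absolute sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomes import AnnotatedGenome, ViromeRead
from .recruitment import ReferenceDB
from .simulate import (
    IntegrationTruth,
    generate_family,
    generate_genome,
    implant_genes,
    plant_integration,
    simulate_virome,
)

#: target mixture proportions of the three phage groups (genome-copy scale)
RECRUITMENT_MIX = {"grpA": 5, "grpB": 3, "grpC": 2}
#: fraction of virome reads drawn from bacterial hosts
HOST_READ_FRACTION = 0.30


@dataclass
class RecruitmentScenario:
    db: ReferenceDB
    reads: list[ViromeRead]
    truth_genome: dict[str, str]
    truth_group: dict[str, str | None]
    expected_proportions: dict[str, float]  # expected RPKM proportions


def recruitment_scenario(
    seed: int,
    n_reads: int = 50_000,
    n_genes: int = 25,
    read_len: int = 150,
    error_rate: float = 0.01,
) -> RecruitmentScenario:
    """Three phage groups mixed 5:3:2 plus 30% bacterial-host reads.

    Each group is two genomes diverged 0.15 from an independent ancestor
    (between-group proteins are unrelated, so well below 40% identity).
    Two decoy host genomes each carry five prophage-remnant genes diverged
    0.25 from a focal ancestor — the reads that make the reciprocal step
    necessary. Read weights are proportional to mixture ratio x group mean
    genome size, so the expected RPKM proportions are exactly 5:3:2.
    """
    rng_base = seed * 101
    fams = {
        grp: generate_family(
            2, n_genes=n_genes, aa_divergence=0.15, gene_loss=0.05, gene_gain=1,
            seed=rng_base + i, group=grp,
        )
        for i, grp in enumerate(RECRUITMENT_MIX)
    }
    focal = [g for fam in fams.values() for g in fam]
    background = [
        generate_genome(
            n_genes, seed=rng_base + 50 + i, genome_id=f"bgv{i}",
            kind="background_viral",
        )
        for i in range(3)
    ]
    decoys = []
    for i, grp in enumerate(list(RECRUITMENT_MIX)[:2]):
        base = generate_genome(
            30, gc=0.52, seed=rng_base + 70 + i, genome_id=f"host{i}", kind="host"
        )
        decoy = implant_genes(
            base, fams[grp][0], n_genes=5, aa_divergence=0.25, seed=rng_base + 90 + i
        )
        decoy.kind = "bacterial_decoy"
        decoys.append(decoy)
    db = ReferenceDB(
        focal=focal, background_viral=background, bacterial_decoys=decoys
    )

    group_kb = {grp: db.mean_genome_kb(grp) for grp in RECRUITMENT_MIX}
    total = sum(RECRUITMENT_MIX[g] * group_kb[g] for g in RECRUITMENT_MIX)
    sources: list[tuple[AnnotatedGenome, float]] = []
    for grp, fam in fams.items():
        w = (1 - HOST_READ_FRACTION) * RECRUITMENT_MIX[grp] * group_kb[grp] / total
        for g in fam:
            sources.append((g, w / len(fam)))
    for d in decoys:
        sources.append((d, HOST_READ_FRACTION / len(decoys)))

    reads = simulate_virome(
        sources, n_reads, read_len=read_len, error_rate=error_rate, seed=seed
    )
    mix_sum = sum(RECRUITMENT_MIX.values())
    return RecruitmentScenario(
        db=db,
        reads=reads,
        truth_genome={r.read_id: r.truth_genome for r in reads},
        truth_group={r.read_id: r.truth_group for r in reads},
        expected_proportions={g: v / mix_sum for g, v in RECRUITMENT_MIX.items()},
    )


def family_scenario(
    seed: int,
    n_families: int = 4,
    members_per_family: int = 3,
    n_singletons: int = 5,
    n_genes: int = 30,
    aa_divergence: float = 0.2,
) -> tuple[list[AnnotatedGenome], dict[str, str]]:
    """Genome families plus unrelated singletons for viral-cluster recovery.

    Returns the genomes and the truth partition label of every family
    member (singletons are absent from the truth map: they should remain
    unclustered).
    """
    genomes: list[AnnotatedGenome] = []
    truth: dict[str, str] = {}
    for i in range(n_families):
        fam = generate_family(
            members_per_family, n_genes=n_genes, aa_divergence=aa_divergence,
            gene_loss=0.05, gene_gain=2, seed=seed * 31 + i, group=f"fam{i}",
        )
        genomes.extend(fam)
        for g in fam:
            truth[g.genome_id] = f"fam{i}"
    for i in range(n_singletons):
        genomes.append(
            generate_genome(
                n_genes, seed=seed * 31 + 500 + i, genome_id=f"solo{i}"
            )
        )
    return genomes, truth


def integration_scenarios(
    seed: int,
    n: int,
    core_min: int = 10,
    core_max: int = 50,
    coverage: float = 20.0,
    read_len: int = 150,
    error_rate: float = 0.0,
    host_genes: int = 16,
    phage_genes: int = 10,
) -> list[tuple[IntegrationTruth, list[ViromeRead]]]:
    """Batches of planted lysogens with reads at the stated coverage.

    A handful of distinct host/phage pairs is reused across plantings (the
    integration site, core length and reads differ every time).
    """
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(min(4, n)):
        host = generate_genome(
            host_genes, gc=0.5, seed=seed * 7 + i, genome_id=f"host{i}", kind="host"
        )
        phage = generate_genome(
            phage_genes, gc=0.45, seed=seed * 7 + 100 + i, genome_id=f"phage{i}"
        )
        pairs.append((host, phage))
    out = []
    for i in range(n):
        host, phage = pairs[i % len(pairs)]
        core_len = int(rng.integers(core_min, core_max + 1))
        truth = plant_integration(
            host, phage, core_len=core_len, seed=int(rng.integers(2**31))
        )
        n_reads = int(len(truth.lysogen) * coverage / read_len)
        reads = simulate_virome(
            [(truth.lysogen, 1.0)], n_reads, read_len=read_len,
            error_rate=error_rate, seed=int(rng.integers(2**31)),
        )
        out.append((truth, reads))
    return out
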
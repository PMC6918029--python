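"""Prophage integration-site detection from hybrid reads.

A phage is integrated into a host at a site-specific core sequence, which
ends up duplicated at the attL and attR prophage boundaries. Reads from
the lysogen that span a boundary align partly to the phage and partly to
the host; clustering those junctions and intersecting their overlap
sequences reconstructs the core and both att sites.
"""

from phagekit import detect_integration, find_hybrid_reads, generate_genome
from phagekit.simulate import plant_integration, simulate_virome

host = generate_genome(16, gc=0.50, seed=21, genome_id="host", kind="host")
phage = generate_genome(10, gc=0.45, seed=22, genome_id="phage")
truth = plant_integration(host, phage, core_len=30, seed=3)
print(f"planted a {len(truth.core)}-bp core at host position "
      f"{truth.host_core_start + 1} (1-based)")

reads = simulate_virome([(truth.lysogen, 1.0)],
                        n_reads=int(len(truth.lysogen) * 20 / 150),
                        read_len=150, error_rate=0.01, seed=4)
evidence = find_hybrid_reads(reads, truth.phage_attp, truth.host)
print(f"{len(reads)} reads -> {len(evidence)} phage-host hybrid reads "
      f"({sum(e.side == 'left' for e in evidence)} attL, "
      f"{sum(e.side == 'right' for e in evidence)} attR)")

calls = detect_integration(reads, truth.phage_attp, truth.host)
call = calls[0]
print(f"called core: {call.core}")
print(f"exact match to planted core: {call.core == truth.core}")
print(f"host position {call.host_core_position + 1}, support "
      f"{call.support_left}+{call.support_right} reads")
print(f"attL: {call.attL}")
print(f"attR: {call.attR}")
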
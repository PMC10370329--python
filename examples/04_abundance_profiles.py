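"""Map reads to genomes and profile per-sample abundance as RPKM.

RPKM = mapped reads / (genome length in kb) / (sample reads in millions):
a length- and depth-normalized abundance that makes phage presence/absence
comparable across unevenly sequenced samples.
"""

from berrylink import abundance_table, default_config, map_reads, simulate_community

genomes, truth, reads = simulate_community(default_config(rng_seed=1))

alignments = {s: map_reads(reads[s], genomes, rng_seed=1) for s in sorted(reads)}
table = abundance_table(
    alignments, genomes, {s: len(reads[s]) for s in reads}
)
wide = table.pivot(index="ref_id", columns="sample_id", values="rpkm").round(1)
print(wide.to_string())
# phage5 was simulated absent from sample s3: its RPKM there is ~0, the
# hallmark of sample-to-sample phage abundance variability.
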
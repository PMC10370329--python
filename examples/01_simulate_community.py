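"""Build the reference synthetic phage-host community and inspect its truth.

The community mimics a small sulfur-cycling aggregate: 3 bacterial hosts,
each with two CRISPR arrays, 5 phages with sample-to-sample abundance
variation, half of all spacers copied from phage genomes with 2
substitutions, and a planted transposon-mediated HGT event.
"""

from berrylink import default_config, simulate_community

genomes, truth, reads = simulate_community(default_config(rng_seed=1))

print(f"{len(genomes)} genomes:")
for g in genomes:
    print(f"  {g.id:8s} {len(g):>7,} bp")
print(f"{len(truth.arrays)} CRISPR arrays planted "
      f"({sum(len(a.spacer_intervals) for a in truth.arrays)} spacers, "
      f"{sum(1 for s in truth.planted_spacers if s.source)} phage-derived)")
for sample in sorted(reads):
    print(f"sample {sample}: {len(reads[sample]):,} reads of "
          f"{len(reads[sample][0])} bp")
hr = truth.hgt_record
print(f"HGT: {len(hr.donor_interval)} bp phage gene copied into "
      f"{hr.host_interval.ref_id} at {hr.host_interval.start:,}, "
      f"insertion at gene offset {hr.insertion_offset} -> premature stop at "
      f"codon {hr.premature_stop_codon} (donor stops at {hr.donor_stop_codon})")
# Every feature above is recorded in `truth`, so downstream stages can be
# scored exactly against what was planted.
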
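"""Match mined spacers to phage genomes and call each phage's host.

A spacer-protospacer match requires >= 80% identity over the full spacer
length (ungapped, either strand).  Each phage is assigned the taxon with the
most matching spacers; ties are left unassigned, single-hit calls are
flagged weak.
"""

from berrylink import (
    default_config,
    dereplicate_repeats,
    detect_arrays,
    export_network,
    extract_spacers,
    match_spacers,
    predict_hosts,
    simulate_community,
)

genomes, truth, reads = simulate_community(default_config(rng_seed=1))
hosts = [g for g in genomes if g.id.startswith("host")]
phages = [g for g in genomes if g.id.startswith("phage")]

repeat_set = dereplicate_repeats([a for h in hosts for a in detect_arrays(h)])
merged = [r for s in sorted(reads) for r in reads[s]]
catalog = extract_spacers(merged, repeat_set)

hits = match_spacers(catalog, phages, min_identity=0.80)
print(f"{len(hits)} spacer-protospacer alignments")
for pred in predict_hosts(hits, [p.id for p in phages]):
    true = truth.true_host_of_phage[pred.phage_id]
    flags = ("weak" if pred.weak_flag else "") + (
        " ambiguous" if pred.ambiguous_flag else "")
    print(f"  {pred.phage_id}: called {pred.taxon_call} (true {true}) "
          f"hits {pred.hits_per_taxon} {flags}")

nodes, edges = export_network(hits, predict_hosts(hits))
print(f"network: {len(nodes)} nodes, {len(edges)} edges "
      f"(edge weight = alignment identity)")
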
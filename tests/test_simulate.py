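import numpy as np
import pytest

from berrylink.hgt import frame_shift_report
from berrylink.seqcore import revcomp
from berrylink.simulate import (
    STOP_CODONS,
    build_community,
    hgt_config,
    simulate_community,
    translate_to_first_stop,
)

from conftest import small_config


class TestBuildCommunity:
    def test_arrays_planted_at_recorded_intervals(self, small_community):
        genomes, truth, _ = small_community
        by_id = {g.id: g for g in genomes}
        for arr in truth.arrays:
            g = by_id[arr.host_id].residues
            for iv in arr.repeat_intervals:
                assert g[iv.start : iv.end] == arr.repeat_sequence
        for sp in truth.planted_spacers:
            g = by_id[sp.host_id].residues
            assert g[sp.host_interval.start : sp.host_interval.end] == sp.spacer_seq

    def test_phage_derived_spacers_match_source_up_to_mutations(
        self, small_community
    ):
        genomes, truth, _ = small_community
        by_id = {g.id: g for g in genomes}
        n_mut = 2  # per_protospacer_mutations in the fixture config
        planted = [s for s in truth.planted_spacers if s.source is not None]
        assert planted
        for sp in planted:
            src = sp.source
            proto = by_id[src.ref_id].residues[src.start : src.end]
            if src.strand == "-":
                proto = revcomp(proto)
            diffs = sum(a != b for a, b in zip(proto, sp.spacer_seq))
            assert diffs == n_mut

    def test_all_spacers_exact_substrings_when_no_mutations(self):
        cfg = small_config(seed=21)
        cfg.protospacer_plan.fraction_of_spacers_from_phages = 1.0
        cfg.protospacer_plan.per_protospacer_mutations = 0
        genomes, truth = build_community(cfg)
        phage_seqs = [g.residues for g in genomes if g.id.startswith("phage")]
        for sp in truth.planted_spacers:
            assert sp.source is not None
            assert any(
                sp.spacer_seq in s or revcomp(sp.spacer_seq) in s
                for s in phage_seqs
            )

    def test_deterministic_given_seed(self):
        a = simulate_community(small_config(seed=4))
        b = simulate_community(small_config(seed=4))
        assert [g.residues for g in a[0]] == [g.residues for g in b[0]]
        for s in a[2]:
            assert [r.residues for r in a[2][s]] == [r.residues for r in b[2][s]]

    def test_oversized_array_raises(self):
        cfg = small_config()
        cfg.hosts[0].arrays[0].n_spacers = 500
        cfg.hosts[0].genome_length = 5_000
        with pytest.raises(ValueError):
            build_community(cfg)


class TestReadSimulation:
    def test_error_free_reads_are_genome_substrings(self, small_community):
        genomes, truth, reads = small_community
        by_id = {g.id: g for g in genomes}
        for sample in reads:
            for read in reads[sample][:300]:
                iv = truth.read_origins[sample][read.id]
                frag = by_id[iv.ref_id].residues[iv.start : iv.end]
                if iv.strand == "-":
                    frag = revcomp(frag)
                assert read.residues == frag

    def test_zero_abundance_means_zero_reads(self):
        cfg = small_config(seed=9)
        cfg.phages[1].per_sample_abundance = [0.5, 0.0]
        _, truth, reads = simulate_community(cfg)
        origins = truth.read_origins["s2"]
        assert not any(iv.ref_id == "phageB" for iv in origins.values())
        assert any(iv.ref_id == "phageB" for iv in truth.read_origins["s1"].values())

    def test_read_fractions_match_abundance_expectation(self):
        # binomial oracle: per-genome read fractions within 3 SE of
        # abundance x length weights
        cfg = small_config(seed=17)
        cfg.read_plan.n_reads_per_sample = [30_000, 100]
        genomes, truth, reads = simulate_community(cfg)
        weights = {
            "hostA": 1.0 * 12_000, "hostB": 1.0 * 12_000,
            "phageA": 1.0 * 8_000, "phageB": 0.5 * 8_000,
        }
        total_w = sum(weights.values())
        n = 30_000
        counts = {k: 0 for k in weights}
        for iv in truth.read_origins["s1"].values():
            counts[iv.ref_id] += 1
        for ref, w in weights.items():
            p = w / total_w
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts[ref] / n - p) < 3 * se, ref


class TestHgtPlanting:
    def test_host_insert_structure_and_truth(self):
        genomes, truth, _ = simulate_community(hgt_config(3))
        host, phage = genomes
        hr = truth.hgt_record
        # direct repeats flank the host copy and are identical
        d0, d1 = hr.host_dr_intervals
        dr_a = host.residues[d0.start : d0.end]
        dr_b = host.residues[d1.start : d1.end]
        assert dr_a == dr_b == hr.dr_sequence
        # the phage-side copy differs by exactly the configured mismatches
        pdr = phage.residues[hr.phage_dr_interval.start : hr.phage_dr_interval.end]
        assert sum(a != b for a, b in zip(pdr, hr.dr_sequence)) == 1
        # host gene copy = donor gene with one inserted base at the offset
        gene = phage.residues[hr.donor_interval.start : hr.donor_interval.end]
        copy = host.residues[hr.host_gene_interval.start : hr.host_gene_interval.end]
        p = hr.insertion_offset
        assert copy == gene[:p] + hr.inserted_base + gene[p:]

    def test_host_copy_stops_before_donor(self):
        genomes, truth, _ = simulate_community(hgt_config(8))
        host, phage = genomes
        hr = truth.hgt_record
        copy = host.residues[hr.host_gene_interval.start : hr.host_gene_interval.end]
        assert translate_to_first_stop(copy) == hr.premature_stop_codon
        assert hr.premature_stop_codon < hr.donor_stop_codon

    def test_frame_shift_report_recovers_planted_insertion(self):
        genomes, truth, _ = simulate_community(hgt_config(15))
        host, phage = genomes
        hr = truth.hgt_record
        gene = phage.residues[hr.donor_interval.start : hr.donor_interval.end]
        copy = host.residues[hr.host_gene_interval.start : hr.host_gene_interval.end]
        rep = frame_shift_report(gene, copy)
        assert rep.indel_type == "insertion"
        assert rep.indel_position == hr.insertion_offset
        assert rep.premature_stop_position == hr.premature_stop_codon

    def test_donor_gene_is_valid_orf(self):
        genomes, truth, _ = simulate_community(hgt_config(2))
        _, phage = genomes
        hr = truth.hgt_record
        gene = phage.residues[hr.donor_interval.start : hr.donor_interval.end]
        assert gene.startswith("ATG")
        assert len(gene) % 3 == 0 and len(gene) >= 300
        assert gene[-3:] in STOP_CODONS
        assert translate_to_first_stop(gene) == len(gene) // 3 - 1


class TestVariantPlanting:
    def test_rates_elevated_in_protospacers(self):
        from berrylink.simulate import enrichment_config

        cfg = enrichment_config(33, 3.0)
        genomes, truth = build_community(cfg)
        phage = [g for g in genomes if g.id == "phageA"][0]
        mask = np.zeros(len(phage), dtype=bool)
        for iv in truth.protospacer_intervals:
            mask[iv.start : iv.end] = True
        in_proto = sum(1 for _, pos, _, _ in truth.planted_variants if mask[pos])
        out_proto = len(truth.planted_variants) - in_proto
        rate_in = in_proto / mask.sum()
        rate_out = out_proto / (len(phage) - mask.sum())
        assert 2.0 < rate_in / rate_out < 4.5

    def test_invalid_rate_ordering_rejected(self):
        cfg = small_config()
        cfg.variant_plan.background_substitution_rate = 0.1
        cfg.variant_plan.protospacer_substitution_rate = 0.01
        with pytest.raises(ValueError):
            build_community(cfg)
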
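import numpy as np
import pytest

from berrylink.seqcore import AlignmentRecord, Interval, SeqRecord
from berrylink.variants import (
    call_variants,
    per_bp_enrichment,
    pileup,
    protospacer_enrichment,
    protospacer_logo,
    window_variant_counts,
)

from conftest import random_seq


def _aln(read_id, pos, seq, ref="ref"):
    return AlignmentRecord(read_id, ref, pos, "+", 0, len(seq), seq)


class TestPileup:
    def test_single_read_columns_match_bases(self):
        ref = SeqRecord("ref", "ACGT" * 25)
        read_seq = ref.residues[10:40]
        pile = pileup([_aln("r", 10, read_seq)], ref)
        base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for offset, base in enumerate(read_seq):
            assert pile.counts[base_idx[base], 10 + offset] == 1
        assert pile.counts[:, :10].sum() == 0

    def test_column_sums_equal_depth(self):
        rng = np.random.default_rng(0)
        ref = SeqRecord("ref", random_seq(rng, 300))
        alns = [
            _aln(f"r{i}", int(rng.integers(0, 200)), random_seq(rng, 100))
            for i in range(40)
        ]
        pile = pileup(alns, ref)
        from berrylink.coverage import coverage

        track = coverage(alns, ref, 40)
        assert (pile.depth == track.depth).all()

    def test_n_bases_excluded(self):
        ref = SeqRecord("ref", "ACGTACGTACGT")
        pile = pileup([_aln("r", 0, "ACGTNNGTACGT")], ref)
        assert pile.counts[:, 4].sum() == 0 and pile.counts[:, 5].sum() == 0

    def test_agrees_with_brute_force_tally(self):
        rng = np.random.default_rng(1)
        ref = SeqRecord("ref", random_seq(rng, 150))
        alns = [
            _aln(f"r{i}", int(rng.integers(0, 100)), random_seq(rng, 50))
            for i in range(25)
        ]
        pile = pileup(alns, ref)
        expected = np.zeros((4, 150), dtype=int)
        for a in alns:
            for off, base in enumerate(a.seq):
                if base in "ACGT":
                    expected["ACGT".index(base), a.pos + off] += 1
        assert (pile.counts == expected).all()


class TestCallVariants:
    def test_monomorphic_pileup_no_calls(self):
        rng = np.random.default_rng(2)
        ref = SeqRecord("ref", random_seq(rng, 200))
        alns = [_aln(f"r{i}", 0, ref.residues) for i in range(10)]
        assert call_variants(pileup(alns, ref), ref) == []

    def test_planted_polymorphism_called(self):
        rng = np.random.default_rng(3)
        ref = SeqRecord("ref", random_seq(rng, 200))
        alt = list(ref.residues)
        alt[57] = "A" if alt[57] != "A" else "C"
        alns = [_aln("wt", 0, ref.residues), _aln("mut", 0, "".join(alt))]
        calls = call_variants(pileup(alns, ref), ref, min_alt_reads=1)
        assert [c.pos for c in calls] == [57]
        assert calls[0].alt_bases == [alt[57]]
        assert calls[0].alt_read_count == 1 and calls[0].total_count == 2

    def test_raising_min_alt_reads_monotone(self):
        rng = np.random.default_rng(4)
        ref = SeqRecord("ref", random_seq(rng, 300))
        alns = []
        for i in range(30):
            seq = list(ref.residues)
            for p in rng.integers(0, 300, size=3):
                seq[p] = "ACGT"[rng.integers(0, 4)]
            alns.append(_aln(f"r{i}", 0, "".join(seq)))
        pile = pileup(alns, ref)
        prev = None
        for threshold in (1, 2, 3, 5):
            pos = {c.pos for c in call_variants(pile, ref, threshold)}
            if prev is not None:
                assert pos <= prev
            prev = pos


class TestWindowCounts:
    def _call(self, pos):
        from berrylink.variants import VariantCall

        return VariantCall("ref", pos, "A", ["C"], 1, 10)

    def test_boundary_assignment(self):
        wins = window_variant_counts(
            [self._call(0), self._call(99), self._call(100)], 250, 100
        )
        assert [w.n_variants for w in wins] == [2, 1, 0]
        assert (wins[0].start, wins[0].end) == (0, 100)
        assert (wins[2].start, wins[2].end) == (200, 250)  # short terminal

    def test_no_calls_all_zero(self):
        wins = window_variant_counts([], 500, 100)
        assert len(wins) == 5 and all(w.n_variants == 0 for w in wins)

    def test_total_conserved(self):
        rng = np.random.default_rng(5)
        calls = [self._call(int(p)) for p in rng.integers(0, 5_000, size=200)]
        wins = window_variant_counts(calls, 5_000, 100)
        assert sum(w.n_variants for w in wins) == 200


class TestEnrichment:
    def test_uniform_rates_give_ratio_near_one(self):
        rng = np.random.default_rng(6)
        calls = [
            TestWindowCounts._call(None, int(p))
            for p in np.nonzero(rng.random(50_000) < 0.02)[0]
        ]
        wins = window_variant_counts(calls, 50_000, 100)
        protos = [Interval("ref", s, s + 100) for s in range(1_000, 9_000, 800)]
        enr = protospacer_enrichment(wins, protos)
        assert 0.7 < enr.ratio < 1.3

    def test_window_overlap_by_one_bp_counts_as_targeted(self):
        wins = window_variant_counts([], 300, 100)
        enr = protospacer_enrichment(wins, [Interval("ref", 99, 101)])
        assert enr.n_targeted_windows == 2  # windows [0,100) and [100,200)

    def test_zero_background_flagged_undefined(self):
        calls = [TestWindowCounts._call(None, 10)]
        wins = window_variant_counts(calls, 300, 100)
        enr = protospacer_enrichment(wins, [Interval("ref", 0, 100)])
        assert enr.ratio is None

    def test_per_bp_mode_recovers_planted_ratio(self):
        rng = np.random.default_rng(7)
        proto = [Interval("ref", s, s + 100) for s in range(2_000, 42_000, 2_000)]
        mask = np.zeros(50_000, dtype=bool)
        for iv in proto:
            mask[iv.start : iv.end] = True
        rates = np.where(mask, 0.06, 0.02)
        positions = np.nonzero(rng.random(50_000) < rates)[0]
        calls = [TestWindowCounts._call(None, int(p)) for p in positions]
        enr = per_bp_enrichment(calls, proto, 50_000)
        assert abs(enr.ratio - 3.0) / 3.0 < 0.25


class TestLogo:
    def test_identical_reads_give_two_bits(self):
        rng = np.random.default_rng(8)
        seq = random_seq(rng, 60)
        alns = [_aln(f"r{i}", 0, seq) for i in range(10)]
        pfm = protospacer_logo(alns, Interval("ref", 10, 40))
        assert np.allclose(pfm.information(), 2.0)

    def test_equal_four_way_column_zero_bits(self):
        alns = [_aln(f"r{i}", 0, b * 30) for i, b in enumerate("ACGT")]
        pfm = protospacer_logo(alns, Interval("ref", 0, 30))
        assert np.allclose(pfm.information(), 0.0)

    def test_fifty_fifty_column_one_bit(self):
        rng = np.random.default_rng(9)
        seq = random_seq(rng, 50)
        alt = list(seq)
        alt[25] = "A" if alt[25] != "A" else "C"
        alns = [_aln(f"a{i}", 0, seq) for i in range(50)] + [
            _aln(f"b{i}", 0, "".join(alt)) for i in range(50)
        ]
        pfm = protospacer_logo(alns, Interval("ref", 20, 30))
        info = pfm.information()
        assert abs(info[5] - 1.0) < 1e-9
        assert np.allclose(np.delete(info, 5), 2.0)

    def test_only_spanning_reads_counted(self):
        rng = np.random.default_rng(10)
        seq = random_seq(rng, 100)
        alns = [
            _aln("span", 0, seq),
            _aln("partial", 30, seq[30:45]),  # ends inside the interval
        ]
        pfm = protospacer_logo(alns, Interval("ref", 20, 60))
        assert pfm.counts.sum() == 40  # one spanning read only

    def test_no_spanning_read_rejected(self):
        with pytest.raises(ValueError):
            protospacer_logo([_aln("r", 0, "ACGT")], Interval("ref", 100, 140))
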
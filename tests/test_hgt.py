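import numpy as np
import pytest

from berrylink.coverage import CoverageTrack
from berrylink.hgt import (
    align_region_to_host,
    compute_ani,
    detect_high_coverage,
    find_short_repeats,
    find_tirs,
    frame_shift_report,
)
from berrylink.seqcore import Interval, SeqRecord, revcomp
from berrylink.simulate import _mutate

from conftest import random_seq


def _track(depth):
    return CoverageTrack("ref", np.asarray(depth, dtype=np.int64), 1_000)


class TestDetectHighCoverage:
    def test_uniform_coverage_empty(self):
        assert detect_high_coverage(_track([30] * 10_000)) == []

    def test_planted_step_region_found_with_tight_boundaries(self):
        depth = np.full(20_000, 25)
        depth[8_000:9_500] = 100  # 4x step of 1.5 kb
        regions = detect_high_coverage(_track(depth))
        assert len(regions) == 1
        r = regions[0]
        assert abs(r.start - 8_000) <= 100 and abs(r.end - 9_500) <= 100
        assert r.fold_change == pytest.approx(4.0)
        assert not r.origin_artifact_flag

    def test_two_fold_not_detected_at_three(self):
        depth = np.full(20_000, 30)
        depth[5_000:6_000] = 60
        assert detect_high_coverage(_track(depth), fold=3) == []
        found = detect_high_coverage(_track(depth), fold=1.5)
        assert len(found) == 1 and found[0].fold_change == pytest.approx(2.0)

    def test_short_runs_dropped(self):
        depth = np.full(20_000, 30)
        depth[5_000:5_100] = 200  # 100 bp < min_len=200
        assert detect_high_coverage(_track(depth)) == []

    def test_region_near_origin_flagged_as_artifact(self):
        depth = np.full(20_000, 30)
        depth[:600] = 150
        regions = detect_high_coverage(_track(depth))
        assert len(regions) == 1 and regions[0].origin_artifact_flag

    def test_all_zero_track_empty(self):
        assert detect_high_coverage(_track([0] * 10_000)) == []


class TestAlignRegionToHost:
    def test_verbatim_copy_found_at_truth_coordinates(self):
        rng = np.random.default_rng(0)
        region = random_seq(rng, 800)
        host_seq = random_seq(rng, 10_000)
        host = SeqRecord("h", host_seq[:4_000] + region + host_seq[4_800:])
        alns = align_region_to_host(region, host)
        assert any(
            a.ref_start == 4_000 and a.ref_end == 4_800 and a.identity == 1.0
            for a in alns
        )

    def test_absent_region_gives_empty(self):
        rng = np.random.default_rng(1)
        region = random_seq(rng, 600)
        host = SeqRecord("h", random_seq(rng, 10_000))
        assert align_region_to_host(region, host) == []

    def test_reverse_complement_insert_found_on_minus(self):
        rng = np.random.default_rng(2)
        region = random_seq(rng, 500)
        host_seq = list(random_seq(rng, 8_000))
        host_seq[3_000:3_500] = list(revcomp(region))
        alns = align_region_to_host(region, SeqRecord("h", "".join(host_seq)))
        assert any(a.strand == "-" and a.ref_start == 3_000 for a in alns)

    def test_five_percent_divergence_identity(self):
        rng = np.random.default_rng(3)
        region = random_seq(rng, 1_000)
        diverged = _mutate(np.random.default_rng(4), region, 50)
        host_seq = list(random_seq(rng, 12_000))
        host_seq[5_000:6_000] = list(diverged)
        alns = align_region_to_host(region, SeqRecord("h", "".join(host_seq)))
        best = max(alns, key=lambda a: a.query_end - a.query_start)
        assert abs(best.identity - 0.95) <= 0.02


def _brute_force_exact_pairs(a, b, min_len, inverted=False):
    """Oracle: O(n*m) DP enumeration of maximal exact match runs."""
    bb = revcomp(b) if inverted else b
    n, m = len(a), len(bb)
    run = [[0] * (m + 1) for _ in range(n + 1)]
    out = []
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if a[i] == bb[j]:
                run[i][j] = run[i + 1][j + 1] + 1
    for i in range(n):
        for j in range(m):
            if run[i][j] >= min_len and (
                i == 0 or j == 0 or a[i - 1] != bb[j - 1]
            ):
                L = run[i][j]
                if inverted:
                    out.append((i, len(b) - j - L, L))
                else:
                    out.append((i, j, L))
    return sorted(out)


class TestFindShortRepeats:
    def test_planted_direct_repeat_one_mismatch(self):
        rng = np.random.default_rng(5)
        dr = random_seq(rng, 17)
        seq_a = random_seq(rng, 400) + dr + random_seq(rng, 400)
        dr_b = _mutate(np.random.default_rng(6), dr, 1)
        seq_b = random_seq(rng, 300) + dr_b + random_seq(rng, 300)
        pairs = find_short_repeats(seq_a, seq_b, min_len=15, max_mismatch=1)
        hit = [
            p for p in pairs
            if p.kind == "direct" and p.mismatches == 1
            and p.a_start <= 400 and p.a_start + p.length >= 417
        ]
        assert len(hit) == 1

    def test_planted_perfect_inverted_pair(self):
        rng = np.random.default_rng(7)
        arm = random_seq(rng, 20)
        seq_a = random_seq(rng, 200) + arm + random_seq(rng, 200)
        seq_b = random_seq(rng, 150) + revcomp(arm) + random_seq(rng, 150)
        pairs = find_short_repeats(seq_a, seq_b, min_len=15, max_mismatch=0,
                                  kinds=("inverted",))
        hit = [p for p in pairs if p.a_start <= 200 and p.a_start + p.length >= 220]
        assert hit and hit[0].mismatches == 0
        assert hit[0].sequence_a[
            200 - hit[0].a_start : 220 - hit[0].a_start
        ] == arm

    @pytest.mark.parametrize("inverted", [False, True])
    def test_exact_pairs_match_brute_force(self, inverted):
        rng = np.random.default_rng(8 + inverted)
        a, b = random_seq(rng, 900), random_seq(rng, 900)
        # plant a few shared words so matches exist
        for k, L in enumerate((9, 12, 16)):
            word = random_seq(rng, L)
            ai, bi = 100 + 250 * k, 80 + 260 * k
            a = a[:ai] + word + a[ai + L :]
            ins = revcomp(word) if inverted else word
            b = b[:bi] + ins + b[bi + L :]
        kinds = ("inverted",) if inverted else ("direct",)
        got = sorted(
            (p.a_start, p.b_start, p.length)
            for p in find_short_repeats(a, b, min_len=8, max_len=900,
                                        max_mismatch=0, kinds=kinds)
        )
        assert got == _brute_force_exact_pairs(a, b, 8, inverted=inverted)

    def test_self_comparison_excludes_trivial_identity(self):
        rng = np.random.default_rng(10)
        word = random_seq(rng, 14)
        seq = random_seq(rng, 300) + word + random_seq(rng, 300) + word
        pairs = find_short_repeats(seq, seq, min_len=12, max_mismatch=0)
        direct = [p for p in pairs if p.kind == "direct"]
        assert all(p.a_start != p.b_start for p in direct)
        assert any(
            p.a_start <= 300 and p.b_start >= 600 for p in direct
        )


class TestFindTirs:
    def test_planted_transposon_top_ranked(self):
        rng = np.random.default_rng(11)
        tir = random_seq(rng, 25)
        element = tir + random_seq(rng, 700) + revcomp(tir)
        g = list(random_seq(rng, 5_000))
        g[2_000 : 2_000 + len(element)] = list(element)
        genome = SeqRecord("g", "".join(g))
        tirs = find_tirs(genome, Interval("g", 1_800, 3_000))
        assert tirs
        top = tirs[0]
        left_truth = (2_000, 2_025)
        right_truth = (2_000 + len(element) - 25, 2_000 + len(element))
        assert top.a_start <= left_truth[0] and top.a_start + top.length >= left_truth[1]
        assert top.b_start <= right_truth[0] and top.b_start + top.length >= right_truth[1]

    def test_window_without_tirs_empty(self):
        rng = np.random.default_rng(12)
        genome = SeqRecord("g", random_seq(rng, 5_000))
        assert find_tirs(genome, Interval("g", 1_000, 3_000), max_mismatch=0) == []

    def test_arms_reported_on_plus_strand(self):
        rng = np.random.default_rng(13)
        tir = random_seq(rng, 30)
        element = tir + random_seq(rng, 600) + revcomp(tir)
        g = list(random_seq(rng, 4_000))
        g[1_500 : 1_500 + len(element)] = list(element)
        genome = SeqRecord("g", "".join(g))
        top = find_tirs(genome, Interval("g", 1_300, 2_500))[0]
        assert genome.residues[top.a_start : top.a_start + top.length] == top.sequence_a
        assert genome.residues[top.b_start : top.b_start + top.length] == top.sequence_b
        assert top.a_start < top.b_start


class TestFrameShiftReport:
    def _gene(self, rng, length=600):
        from berrylink.simulate import _random_gene

        return _random_gene(rng, length)

    def test_identical_orfs_no_indel_no_stop(self):
        gene = self._gene(np.random.default_rng(14))
        rep = frame_shift_report(gene, gene)
        assert rep.indel_position is None
        assert rep.premature_stop_position is None

    def test_single_deletion_reported(self):
        gene = self._gene(np.random.default_rng(15))
        p = 303
        while gene[p] == gene[p - 1]:  # unambiguous gap placement
            p += 1
        rep = frame_shift_report(gene, gene[:p] + gene[p + 1 :])
        assert rep.indel_type == "deletion"
        assert abs(rep.indel_position - p) <= 1

    def test_invalid_orf_rejected(self):
        with pytest.raises(ValueError):
            frame_shift_report("ACGT" * 100, "ACGT" * 100)  # no ATG/stop


class TestComputeAni:
    def test_self_ani_exactly_100(self):
        rng = np.random.default_rng(16)
        g = SeqRecord("g", random_seq(rng, 20_000))
        res = compute_ani(g, g)
        assert res.ani_percent == 100.0
        assert res.n_fragments_used == res.n_fragments_total

    def test_one_percent_divergence(self):
        rng = np.random.default_rng(17)
        g = SeqRecord("g", random_seq(rng, 40_000))
        mutated = SeqRecord("m", _mutate(np.random.default_rng(18), g.residues, 400))
        res = compute_ani(g, mutated)
        assert abs(res.ani_percent - 99.0) <= 0.3

    def test_unrelated_genomes_undefined_or_low(self):
        rng = np.random.default_rng(19)
        a = SeqRecord("a", random_seq(rng, 30_000))
        b = SeqRecord("b", random_seq(rng, 30_000))
        res = compute_ani(a, b)
        assert res.n_fragments_used <= 1
        if res.ani_percent is not None:
            assert res.ani_percent < 50
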
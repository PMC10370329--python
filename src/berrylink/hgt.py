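"""Phage-host horizontal gene transfer evidence: coverage anomalies, host
alignment, short direct/inverted repeats, IS-style terminal inverted
repeats, frameshift pseudogene reports, and fragment-based average
nucleotide identity (ANI).

The evidence chain mirrors how transposon-mediated HGT is recognized in
practice: a discretely over-covered region of a phage genome aligns to the
predicted host chromosome, the junctions carry short direct repeats
(transposase footprints), an IS element with terminal inverted repeats sits
nearby, and the transferred gene copy is a pseudogene inactivated by a
single-base frameshift producing a premature stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from Bio import Align

from .coverage import CoverageTrack
from .seqcore import (
    Interval,
    SeqRecord,
    encode,
    encode_revcomp,
    mismatch_profile,
    revcomp,
)
from .simulate import STOP_CODONS, translate_to_first_stop


@dataclass
class HighCoverageRegion:
    ref_id: str
    start: int
    end: int
    region_median_depth: float
    flank_median_depth: float
    fold_change: float
    origin_artifact_flag: bool = False  # near assembly origin: possible
    # circular-permutation artifact rather than HGT


@dataclass
class RepeatPair:
    sequence_a: str
    sequence_b: str
    a_start: int
    b_start: int
    length: int
    kind: str  # "direct" | "inverted"
    mismatches: int


@dataclass
class LocalAlignment:
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    strand: str
    identity: float


@dataclass
class FrameReport:
    indel_position: Optional[int]  # 0-based offset in orf_a coordinates
    indel_type: Optional[str]  # "insertion" (extra base in orf_b) | "deletion"
    n_single_base_gaps: int
    premature_stop_position: Optional[int]  # codon index in orf_b, if earlier
    orf_stop_position: int  # codon index of orf_a's own stop


@dataclass
class ANIResult:
    ani_percent: Optional[float]  # None when no fragment passes the filters
    n_fragments_used: int
    n_fragments_total: int


# ---------------------------------------------------------------------------
# coverage anomalies


def detect_high_coverage(
    track: CoverageTrack,
    fold: float = 3.0,
    min_len: int = 200,
    flank: int = 1000,
    merge_gap: int = 50,
) -> List[HighCoverageRegion]:
    """Maximal runs of positions with depth >= fold x the surrounding depth.

    The genome is treated as circular; "surrounding" is the median depth of
    the two ``flank``-sized windows adjacent to the run.  Candidate runs
    separated by sub-threshold gaps shorter than ``merge_gap`` (sampling
    noise at finite depth) are merged; runs shorter than ``min_len`` are
    dropped.  Regions within ``flank`` of the assembly origin are flagged as
    possible circular-permutation artifacts.
    """
    d = track.depth
    n = len(d)
    if n <= 2 * flank:
        raise ValueError("genome shorter than twice the flank size")
    if d.max() == 0:
        return []
    baseline = float(np.median(d))
    if baseline == 0:
        baseline = float(d.mean())
    mask = d >= fold * baseline
    regions: List[HighCoverageRegion] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    runs = list(zip(edges[::2], edges[1::2]))
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    for s, e in merged:
        if e - s < min_len:
            continue
        left = d[(np.arange(s - flank, s)) % n]
        right = d[(np.arange(e, e + flank)) % n]
        flank_med = float(np.median(np.concatenate([left, right])))
        region_med = float(np.median(d[s:e]))
        if region_med == 0:
            continue
        if flank_med > 0 and region_med < fold * flank_med:
            continue
        regions.append(
            HighCoverageRegion(
                ref_id=track.ref_id,
                start=int(s),
                end=int(e),
                region_median_depth=region_med,
                flank_median_depth=flank_med,
                fold_change=(region_med / flank_med) if flank_med > 0 else float("inf"),
                origin_artifact_flag=(s < flank or n - e < flank),
            )
        )
    return regions


# ---------------------------------------------------------------------------
# seeded local alignment (region -> host)


def align_region_to_host(
    region_seq: str,
    host: SeqRecord,
    min_len: int = 100,
    min_identity: float = 0.80,
    seed_k: int = 12,
    xdrop: int = 12,
) -> List[LocalAlignment]:
    """Seeded ungapped local alignments of ``region_seq`` against ``host``
    (both strands): exact ``seed_k``-mer seeds, X-drop extension, all
    alignments of length >= ``min_len`` and identity >= ``min_identity``.
    Empty list when the region has no host counterpart."""
    q = encode(region_seq)
    results: Dict[Tuple[str, int], LocalAlignment] = {}
    for strand in "+-":
        t = encode(host.residues) if strand == "+" else encode_revcomp(
            encode(host.residues)
        )
        index: Dict[bytes, List[int]] = {}
        raw = t.tobytes()
        for i in range(0, len(raw) - seed_k + 1):
            index.setdefault(raw[i : i + seed_k], []).append(i)
        qraw = q.tobytes()
        diagonals: Set[int] = set()
        for off in range(0, len(q) - seed_k + 1, seed_k):
            for tpos in index.get(qraw[off : off + seed_k], ()):
                diagonals.add(tpos - off)
        for diag in diagonals:
            q0 = max(0, -diag)
            q1 = min(len(q), len(t) - diag)
            if q1 - q0 < min_len:
                continue
            seg_mm = mismatch_profile(q[q0:q1], t[q0 + diag : q1 + diag])
            aln = _best_xdrop_segment(seg_mm, xdrop)
            if aln is None:
                continue
            s, e = aln
            if e - s < min_len:
                continue
            ident = 1.0 - seg_mm[s:e].mean()
            if ident < min_identity:
                continue
            qs, qe = q0 + s, q0 + e
            ts, te = qs + diag, qe + diag
            if strand == "-":
                ts, te = len(t) - te, len(t) - ts
            key = (strand, diag)
            cur = results.get(key)
            if cur is None or (qe - qs) > (cur.query_end - cur.query_start):
                results[key] = LocalAlignment(qs, qe, ts, te, strand, float(ident))
    out = list(results.values())
    # drop alignments nested inside a longer one on another diagonal
    out.sort(key=lambda a: (a.query_start - a.query_end, a.query_start, a.ref_start))
    kept: List[LocalAlignment] = []
    for a in out:
        if any(
            k.query_start <= a.query_start and a.query_end <= k.query_end
            and k.strand == a.strand
            for k in kept
        ):
            continue
        kept.append(a)
    kept.sort(key=lambda a: (a.query_start, a.ref_start))
    return kept


def _best_xdrop_segment(mm: np.ndarray, xdrop: int) -> Optional[Tuple[int, int]]:
    """Best-scoring segment (match +1 / mismatch -1) of a diagonal, found by
    Kadane-style scanning with an X-drop cutoff; returns (start, end)."""
    score = np.where(mm, -1, 1)
    best, best_range = 0, None
    cur, cur_start = 0, 0
    cur_best, cur_best_end = 0, 0
    for i, s in enumerate(score):
        cur += s
        if cur > cur_best:
            cur_best, cur_best_end = cur, i + 1
        if cur_best - cur > xdrop or cur < 0:
            if cur_best > best:
                best, best_range = cur_best, (cur_start, cur_best_end)
            cur, cur_start = 0, i + 1
            cur_best, cur_best_end = 0, i + 1
    if cur_best > best:
        best, best_range = cur_best, (cur_start, cur_best_end)
    return best_range


# ---------------------------------------------------------------------------
# short repeats and TIRs


def find_short_repeats(
    seq_a: str,
    seq_b: str,
    min_len: int = 12,
    max_len: int = 40,
    max_mismatch: int = 1,
    kinds: Iterable[str] = ("direct", "inverted"),
) -> List[RepeatPair]:
    """All maximal length-matched pairs between ``seq_a`` and ``seq_b``
    within the length bounds and mismatch budget, for the requested kinds.

    A pair is maximal when it cannot be extended in either direction without
    exceeding ``max_mismatch``.  Self-comparison (``seq_b is seq_a`` or equal
    strings) is permitted; trivial self-identity pairs are excluded and
    symmetric duplicates reported once.
    """
    self_cmp = seq_a == seq_b
    a = encode(seq_a)
    pairs: List[RepeatPair] = []
    for kind in kinds:
        if kind == "direct":
            b = encode(seq_b)
        elif kind == "inverted":
            b = encode_revcomp(encode(seq_b))
        else:
            raise ValueError(f"unknown repeat kind {kind!r}")
        for diag in range(-(len(b) - 1), len(a)):
            if self_cmp and kind == "direct" and diag == 0:
                continue  # trivial identity
            a0 = max(0, diag)
            a1 = min(len(a), len(b) + diag)
            if a1 - a0 < min_len:
                continue
            mm = mismatch_profile(a[a0:a1], b[a0 - diag : a1 - diag])
            for s, e, n_mm in _maximal_windows(mm, max_mismatch):
                if not (min_len <= e - s <= max_len):
                    continue
                a_start = a0 + s
                b_idx = a_start - diag  # position in the (possibly rc) b text
                if kind == "inverted":
                    b_start = len(seq_b) - (b_idx + (e - s))
                else:
                    b_start = b_idx
                if self_cmp:
                    if kind == "direct" and a_start > b_start:
                        continue  # symmetric duplicate
                    if kind == "inverted" and a_start > b_start:
                        continue
                pairs.append(
                    RepeatPair(
                        sequence_a=seq_a[a_start : a_start + (e - s)],
                        sequence_b=seq_b[b_start : b_start + (e - s)],
                        a_start=a_start,
                        b_start=b_start,
                        length=e - s,
                        kind=kind,
                        mismatches=n_mm,
                    )
                )
    pairs.sort(key=lambda p: (p.a_start, p.b_start, p.kind, -p.length))
    return pairs


def _maximal_windows(mm: np.ndarray, k: int):
    """Maximal (start, end, n_mismatch) windows of a boolean mismatch mask
    containing at most ``k`` mismatches."""
    idx = np.flatnonzero(mm)
    L = len(mm)
    if len(idx) <= k:
        yield 0, L, int(len(idx))
        return
    bounds = np.concatenate(([-1], idx, [L]))
    # window s covers mismatches idx[s .. s+k-1]
    for s in range(0, len(idx) - k + 1):
        start = int(bounds[s] + 1)
        end = int(bounds[s + k + 1])
        yield start, end, k


def find_tirs(
    genome: SeqRecord,
    window: Interval,
    tir_len: Tuple[int, int] = (10, 40),
    max_mismatch: int = 2,
    min_internal: int = 500,
) -> List[RepeatPair]:
    """Terminal-inverted-repeat candidates inside ``window``: inverted repeat
    pairs whose arms face inward and bracket at least ``min_internal`` bp.
    Coordinates are on the genome; arms are reported 5'->3' on the + strand.
    Ranked by arm length (desc), then mismatches (asc)."""
    wseq = genome.residues[window.start : window.end]
    pairs = find_short_repeats(
        wseq, wseq, min_len=tir_len[0], max_len=tir_len[1],
        max_mismatch=max_mismatch, kinds=("inverted",),
    )
    out = []
    for p in pairs:
        left, right = sorted((p.a_start, p.b_start))
        if right - (left + p.length) < min_internal:
            continue
        out.append(
            RepeatPair(
                sequence_a=wseq[left : left + p.length],
                sequence_b=wseq[right : right + p.length],
                a_start=window.start + left,
                b_start=window.start + right,
                length=p.length,
                kind="inverted",
                mismatches=p.mismatches,
            )
        )
    out.sort(key=lambda p: (-p.length, p.mismatches, p.a_start))
    return out


# ---------------------------------------------------------------------------
# frameshift pseudogene report


def _affine_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    return aligner


def frame_shift_report(orf_a: str, orf_b: str) -> FrameReport:
    """Compare an intact ORF (``orf_a``) with a putative pseudogene copy
    (``orf_b``): locate single-base gaps in a global affine-gap alignment and
    the first in-frame stop codon of ``orf_b`` (in ``orf_a``'s reading frame)
    occurring before ``orf_a``'s own stop."""
    if len(orf_a) < 300 or len(orf_b) < 300:
        raise ValueError("both sequences must be >= 300 bp")
    if len(orf_a) % 3 or not orf_a.startswith("ATG") or orf_a[-3:] not in STOP_CODONS:
        raise ValueError("orf_a must be a valid ORF (ATG ... stop, length % 3 == 0)")

    aln = _affine_aligner().align(orf_a, orf_b)[0]
    blocks_a, blocks_b = aln.aligned
    indel_position = None
    indel_type = None
    n_single = 0
    for i in range(1, len(blocks_a)):
        gap_a = blocks_a[i][0] - blocks_a[i - 1][1]
        gap_b = blocks_b[i][0] - blocks_b[i - 1][1]
        if gap_a == 1 and gap_b == 0:
            n_single += 1
            if indel_position is None:
                indel_position = int(blocks_a[i - 1][1])
                indel_type = "deletion"  # base missing from orf_b
        elif gap_b == 1 and gap_a == 0:
            n_single += 1
            if indel_position is None:
                indel_position = int(blocks_a[i - 1][1])
                indel_type = "insertion"  # extra base in orf_b
    orf_stop = len(orf_a) // 3 - 1
    stop_b = translate_to_first_stop(orf_b)
    premature = stop_b if (0 <= stop_b < orf_stop) else None
    return FrameReport(
        indel_position=indel_position,
        indel_type=indel_type,
        n_single_base_gaps=n_single,
        premature_stop_position=premature,
        orf_stop_position=orf_stop,
    )


# ---------------------------------------------------------------------------
# fragment ANI (Goris-style)


def compute_ani(
    genome_a: SeqRecord,
    genome_b: SeqRecord,
    frag_len: int = 1020,
    min_id: float = 0.30,
    min_cov: float = 0.70,
    seed_k: int = 16,
) -> ANIResult:
    """One-way fragment ANI: ``genome_a`` is cut into consecutive
    ``frag_len`` pieces, each placed on ``genome_b`` (best ungapped seeded
    placement, either strand); fragments are kept when identity >= ``min_id``
    over >= ``min_cov`` of the fragment, and ANI is the mean identity (%) of
    kept fragments.  Undefined (``ani_percent=None``) when none pass."""
    texts = {}
    b_code = encode(genome_b.residues)
    texts["+"] = b_code
    texts["-"] = encode_revcomp(b_code)
    index: Dict[bytes, List[Tuple[str, int]]] = {}
    for strand, t in texts.items():
        raw = t.tobytes()
        for i in range(0, len(raw) - seed_k + 1):
            index.setdefault(raw[i : i + seed_k], []).append((strand, i))

    a_code = encode(genome_a.residues)
    n_total = 0
    identities = []
    for f0 in range(0, len(a_code), frag_len):
        frag = a_code[f0 : f0 + frag_len]
        if len(frag) < seed_k:
            break
        n_total += 1
        fraw = frag.tobytes()
        candidates: Set[Tuple[str, int]] = set()
        for off in range(0, len(frag) - seed_k + 1, seed_k):
            for strand, tpos in index.get(fraw[off : off + seed_k], ()):
                candidates.add((strand, tpos - off))
        best_identity = None
        for strand, diag in candidates:
            t = texts[strand]
            q0 = max(0, -diag)
            q1 = min(len(frag), len(t) - diag)
            aligned = q1 - q0
            if aligned < min_cov * len(frag):
                continue
            ident = 1.0 - mismatch_profile(
                frag[q0:q1], t[q0 + diag : q1 + diag]
            ).mean()
            if best_identity is None or ident > best_identity:
                best_identity = float(ident)
        if best_identity is not None and best_identity >= min_id:
            identities.append(best_identity)
    if not identities:
        return ANIResult(None, 0, n_total)
    return ANIResult(100.0 * float(np.mean(identities)), len(identities), n_total)
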
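"""Pileup-based variant calling, windowed variant density, protospacer
enrichment, and protospacer position-frequency matrices.

Variant calls are deliberately unfiltered by default (any non-reference base
seen in at least ``min_alt_reads`` reads): the goal is to maximize the number
of recovered allelic variants, with the alt-read threshold exposed for
noisier data.  Variant density is summarized in fixed, non-overlapping
100 bp windows anchored at position 0 (the short terminal window is kept),
and CRISPR-targeted enrichment is the ratio of mean per-window variant
counts between windows overlapping a protospacer and all remaining windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .seqcore import AlignmentRecord, Interval, SeqRecord, encode

_BASE_ORDER = "ACGT"


@dataclass
class Pileup:
    ref_id: str
    counts: np.ndarray  # shape (4, ref_len), rows A/C/G/T; N excluded

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass
class VariantCall:
    ref_id: str
    pos: int
    ref_base: str
    alt_bases: List[str]
    alt_read_count: int  # count of the best-supported alt
    total_count: int


@dataclass
class WindowStat:
    ref_id: str
    start: int
    end: int
    n_variants: int


@dataclass
class EnrichmentResult:
    mean_variants_targeted: float
    mean_variants_background: float
    ratio: Optional[float]  # None when the background mean is 0 (undefined)
    n_targeted_windows: int
    n_background_windows: int


@dataclass
class PFM:
    """Position frequency matrix over a reference interval with per-column
    information content in bits (2 - Shannon entropy of the column)."""

    interval: Interval
    counts: np.ndarray  # shape (4, L)

    def information(self) -> np.ndarray:
        totals = self.counts.sum(axis=0)
        info = np.zeros(self.counts.shape[1])
        nz = totals > 0
        p = self.counts[:, nz] / totals[nz]
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(p > 0, -p * np.log2(p), 0.0).sum(axis=0)
        info[nz] = 2.0 - h
        return info


def pileup(alignments: Iterable[AlignmentRecord], ref: SeqRecord) -> Pileup:
    """Per-position A/C/G/T counts among aligned (reference-oriented) reads;
    N bases are excluded from the counts."""
    counts = np.zeros((4, len(ref)), dtype=np.int64)
    for a in alignments:
        if a.ref_id != ref.id or not a.seq:
            continue
        codes = encode(a.seq)
        pos = np.arange(a.pos, a.pos + len(codes))
        keep = codes < 4
        np.add.at(counts, (codes[keep], pos[keep]), 1)
    return Pileup(ref.id, counts)


def call_variants(
    pile: Pileup, ref: SeqRecord, min_alt_reads: int = 1
) -> List[VariantCall]:
    """A position is a variant iff any non-reference base is supported by at
    least ``min_alt_reads`` reads; all qualifying alts are listed."""
    ref_codes = encode(ref.residues)
    calls: List[VariantCall] = []
    counts = pile.counts
    nonref = counts.copy()
    valid = ref_codes < 4
    cols = np.arange(len(ref))
    nonref[ref_codes[valid], cols[valid]] = 0
    hit_cols = np.nonzero((nonref >= min_alt_reads).any(axis=0))[0]
    for pos in hit_cols:
        if ref_codes[pos] >= 4:
            continue
        alts = [
            _BASE_ORDER[b]
            for b in range(4)
            if b != ref_codes[pos] and counts[b, pos] >= min_alt_reads
        ]
        if not alts:
            continue
        best_alt = max(alts, key=lambda b: counts[_BASE_ORDER.index(b), pos])
        calls.append(
            VariantCall(
                ref_id=pile.ref_id,
                pos=int(pos),
                ref_base=_BASE_ORDER[ref_codes[pos]],
                alt_bases=alts,
                alt_read_count=int(counts[_BASE_ORDER.index(best_alt), pos]),
                total_count=int(counts[:, pos].sum()),
            )
        )
    return calls


def window_variant_counts(
    calls: Sequence[VariantCall], ref_length: int, window: int = 100
) -> List[WindowStat]:
    """Non-overlapping windows tiling the genome from position 0; each call
    lands in exactly one window, so counts conserve the total."""
    if window < 1:
        raise ValueError("window must be >= 1")
    n_win = (ref_length + window - 1) // window
    tallies = np.zeros(n_win, dtype=np.int64)
    ref_id = calls[0].ref_id if calls else ""
    for c in calls:
        tallies[c.pos // window] += 1
        ref_id = c.ref_id
    return [
        WindowStat(ref_id, w * window, min((w + 1) * window, ref_length), int(t))
        for w, t in enumerate(tallies)
    ]


def protospacer_enrichment(
    windows: Sequence[WindowStat],
    protospacers: Sequence[Interval],
    ref_id: Optional[str] = None,
) -> EnrichmentResult:
    """Mean variant count in CRISPR-targeted windows (>= 1 bp overlap with a
    protospacer) versus all other windows, and their ratio."""
    if not windows:
        raise ValueError("no windows")
    proto = [
        iv for iv in protospacers if ref_id is None or iv.ref_id == ref_id
    ]
    targeted, background = [], []
    for w in windows:
        overlapping = any(
            iv.start < w.end and w.start < iv.end for iv in proto
        )
        (targeted if overlapping else background).append(w.n_variants)
    if not targeted or not background:
        raise ValueError("need >= 1 targeted and >= 1 background window")
    mean_t = float(np.mean(targeted))
    mean_b = float(np.mean(background))
    return EnrichmentResult(
        mean_variants_targeted=mean_t,
        mean_variants_background=mean_b,
        ratio=(mean_t / mean_b) if mean_b > 0 else None,
        n_targeted_windows=len(targeted),
        n_background_windows=len(background),
    )


def per_bp_enrichment(
    calls: Sequence[VariantCall],
    protospacers: Sequence[Interval],
    ref_length: int,
    ref_id: Optional[str] = None,
) -> EnrichmentResult:
    """Per-base-pair variant-rate enrichment: variants per bp inside
    protospacer intervals versus variants per bp outside them.

    Unlike the fixed-window classification, this estimator is insensitive to
    how much of a window the targeted interval happens to cover, so it
    recovers the underlying substitution-rate ratio directly.  Means are
    per-bp rates here; ``n_*_windows`` report the base counts of each class.
    """
    proto = [iv for iv in protospacers if ref_id is None or iv.ref_id == ref_id]
    if not proto:
        raise ValueError("no protospacer intervals on this reference")
    targeted_mask = np.zeros(ref_length, dtype=bool)
    for iv in proto:
        targeted_mask[iv.start : iv.end] = True
    n_t = int(targeted_mask.sum())
    n_b = ref_length - n_t
    if n_t == 0 or n_b == 0:
        raise ValueError("need >= 1 targeted and >= 1 background base")
    t_calls = sum(1 for c in calls if targeted_mask[c.pos])
    b_calls = len(calls) - t_calls
    rate_t = t_calls / n_t
    rate_b = b_calls / n_b
    return EnrichmentResult(
        mean_variants_targeted=rate_t,
        mean_variants_background=rate_b,
        ratio=(rate_t / rate_b) if rate_b > 0 else None,
        n_targeted_windows=n_t,
        n_background_windows=n_b,
    )


def protospacer_logo(
    alignments: Iterable[AlignmentRecord], interval: Interval
) -> PFM:
    """Position frequency matrix over ``interval`` from reads that fully span
    it (spanning-reads-only rule); requires at least one spanning read."""
    L = len(interval)
    counts = np.zeros((4, L), dtype=np.int64)
    n_span = 0
    for a in alignments:
        if a.ref_id != interval.ref_id or not a.seq:
            continue
        if a.pos <= interval.start and a.pos + a.aligned_length >= interval.end:
            n_span += 1
            sub = encode(a.seq[interval.start - a.pos : interval.end - a.pos])
            keep = sub < 4
            np.add.at(counts, (sub[keep], np.arange(L)[keep]), 1)
    if n_span == 0:
        raise ValueError("no read fully spans the interval")
    return PFM(interval, counts)
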
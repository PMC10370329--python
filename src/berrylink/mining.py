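"""Repeat-anchored CRISPR spacer mining from unassembled reads.

Given a dereplicated repeat set, each read is scanned for approximate repeat
matches on both strands; the subsequence strictly between two consecutive
same-strand repeat hits of spacer-compatible length is a full spacer
candidate.  Candidates are canonicalized to the repeat's array orientation,
pooled across samples, and retained when observed in at least
``min_neighbor_support`` distinct reads.  Spacers inherit the taxon of the
repeat they were anchored on.  Reverse-complement spacer pairs arising from
different repeats are deliberately kept as distinct records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .arrays import RepeatSet
from .seqcore import QualRead, encode, encode_revcomp, revcomp, scan_pattern

logger = logging.getLogger(__name__)


@dataclass
class SpacerRecord:
    spacer_id: str  # "<repeat_id>-<serial>", e.g. "01-3"
    sequence: str
    repeat_id: str
    taxon_label: str
    support: int
    samples: Dict[str, int] = field(default_factory=dict)


@dataclass
class SpacerCatalog:
    records: List[SpacerRecord] = field(default_factory=list)
    partials: List[Tuple[str, str]] = field(default_factory=list)  # (repeat_id, seq)
    provenance: Dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def sequences(self) -> Dict[str, str]:
        return {r.spacer_id: r.sequence for r in self.records}


def find_repeat_hits(
    read_seq: str, repeat: str, max_mismatch: int = 2
) -> List[Tuple[int, str]]:
    """All (position, strand) where ``repeat`` matches the read with at most
    ``max_mismatch`` substitutions (ungapped, both strands), sorted."""
    if len(repeat) > len(read_seq):
        return []
    code = encode(read_seq)
    hits: List[Tuple[int, str]] = []
    fwd = encode(repeat)
    for pat, strand in ((fwd, "+"), (encode_revcomp(fwd), "-")):
        pos, _ = scan_pattern(code, pat, max_mismatch)
        hits.extend((int(p), strand) for p in pos)
    hits.sort()
    return hits


def _exact_chunks(repeat: str, max_mismatch: int) -> List[str]:
    """Pigeonhole pre-filter: with <= max_mismatch substitutions, at least one
    of max_mismatch+1 chunks of the repeat occurs exactly."""
    k = max_mismatch + 1
    size = len(repeat) // k
    return [repeat[i * size : (i + 1) * size] for i in range(k)]


def extract_spacers(
    reads: Iterable[QualRead],
    repeat_set: RepeatSet,
    approx_repeat_size: int = 36,
    min_neighbor_support: int = 2,
    spacer_len: Tuple[int, int] = (18, 60),
    max_repeat_mismatch: int = 2,
) -> SpacerCatalog:
    """Mine spacers from reads anchored on known repeats.

    Only candidates flanked by a repeat on both sides enter the catalog;
    one-sided (partial) candidates are kept in ``catalog.partials`` for
    diagnostics.  Support is the number of distinct reads yielding the same
    (repeat, sequence) candidate; records below ``min_neighbor_support`` are
    dropped.  Serial numbers are assigned per repeat by descending support,
    then lexicographic sequence.
    """
    if not len(repeat_set):
        raise ValueError("empty repeat set")
    taxon_of = repeat_set.taxon_of()
    usable = []
    for rid, repeat, taxa, _ in repeat_set.entries:
        if abs(len(repeat) - approx_repeat_size) > 12:
            logger.warning(
                "repeat %s length %d outside %d +/- 12 window; skipped",
                rid, len(repeat), approx_repeat_size,
            )
            continue
        chunks = _exact_chunks(repeat, max_repeat_mismatch)
        rc_chunks = _exact_chunks(revcomp(repeat), max_repeat_mismatch)
        usable.append((rid, repeat, chunks + rc_chunks))

    # (repeat_id, spacer_seq) -> {read ids}, and per-sample counters
    seen: Dict[Tuple[str, str], set] = {}
    sample_counts: Dict[Tuple[str, str], Dict[str, int]] = {}
    partials: Dict[Tuple[str, str], None] = {}

    for read in reads:
        seq = read.residues
        for rid, repeat, chunks in usable:
            if not any(c in seq for c in chunks):
                continue
            hits = find_repeat_hits(seq, repeat, max_repeat_mismatch)
            if not hits:
                continue
            by_strand: Dict[str, List[int]] = {"+": [], "-": []}
            for p, s in hits:
                by_strand[s].append(p)
            for strand, positions in by_strand.items():
                if not positions:
                    continue
                full_pairs = []
                for a, b in zip(positions, positions[1:]):
                    gap = b - (a + len(repeat))
                    if spacer_len[0] <= gap <= spacer_len[1]:
                        full_pairs.append((a, b))
                for a, b in full_pairs:
                    spacer = seq[a + len(repeat) : b]
                    if strand == "-":
                        spacer = revcomp(spacer)
                    key = (rid, spacer)
                    seen.setdefault(key, set()).add(read.id)
                    sc = sample_counts.setdefault(key, {})
                    sc[read.sample_id] = sc.get(read.sample_id, 0) + 1
                # one-sided fragments at the read edges are partial candidates
                if positions and not full_pairs:
                    left = seq[: positions[0]]
                    right = seq[positions[-1] + len(repeat) :]
                    for frag in (left, right):
                        if len(frag) >= spacer_len[0]:
                            frag_c = frag if strand == "+" else revcomp(frag)
                            partials.setdefault((rid, frag_c))

    records: List[SpacerRecord] = []
    per_repeat: Dict[str, List[Tuple[str, set]]] = {}
    for (rid, spacer), read_ids in seen.items():
        if len(read_ids) >= min_neighbor_support:
            per_repeat.setdefault(rid, []).append((spacer, read_ids))
    for rid in sorted(per_repeat):
        entries = sorted(per_repeat[rid], key=lambda e: (-len(e[1]), e[0]))
        for serial, (spacer, read_ids) in enumerate(entries, start=1):
            records.append(
                SpacerRecord(
                    spacer_id=f"{rid}-{serial}",
                    sequence=spacer,
                    repeat_id=rid,
                    taxon_label=taxon_of[rid],
                    support=len(read_ids),
                    samples=dict(sorted(sample_counts[(rid, spacer)].items())),
                )
            )
    return SpacerCatalog(
        records=records,
        partials=sorted(partials),
        provenance={"n_repeats": str(len(usable))},
    )


def spacer_read_coverage(
    catalog: SpacerCatalog,
    reads: Iterable[QualRead],
    max_mismatch: int = 0,
) -> Dict[str, int]:
    """Per spacer, the number of reads containing its sequence (either
    strand) with at most ``max_mismatch`` substitutions."""
    if not len(catalog):
        raise ValueError("empty spacer catalog")
    counts = {r.spacer_id: 0 for r in catalog.records}
    if max_mismatch == 0:
        pairs = [
            (r.spacer_id, r.sequence, revcomp(r.sequence)) for r in catalog.records
        ]
        for read in reads:
            seq = read.residues
            for sid, fwd, rc in pairs:
                if fwd in seq or rc in seq:
                    counts[sid] += 1
    else:
        enc = [
            (r.spacer_id, encode(r.sequence), encode_revcomp(encode(r.sequence)))
            for r in catalog.records
        ]
        for read in reads:
            code = encode(read.residues)
            for sid, fwd, rc in enc:
                hit = False
                for pat in (fwd, rc):
                    pos, _ = scan_pattern(code, pat, max_mismatch)
                    if len(pos):
                        hit = True
                        break
                if hit:
                    counts[sid] += 1
    return counts
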
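"""Read mapping, per-position coverage tracks and RPKM abundance tables.

The internal mapper is deliberately simple: exact k-mer seeding on both
strands, full-read ungapped scoring, best placement kept when the mismatch
count stays below ``max_mismatch_rate x read_length``, ties broken uniformly
at random under a recorded seed.  Any external mapper can be substituted via
the SAM import path; everything downstream consumes AlignmentRecords.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .seqcore import (
    AlignmentRecord,
    QualRead,
    SeqRecord,
    encode,
    encode_revcomp,
    decode,
    mismatch_profile,
)


@dataclass
class CoverageTrack:
    """Per-position read depth on one reference.

    ``normalized`` is depth divided by the total number of trimmed/filtered
    reads in the sample, the normalization used for cross-sample coverage
    comparisons.
    """

    ref_id: str
    depth: np.ndarray
    total_sample_reads: int

    @property
    def normalized(self) -> np.ndarray:
        return self.depth / float(self.total_sample_reads)


class _RefIndex:
    """Exact k-mer index over both strands of a reference set."""

    def __init__(self, refs: Sequence[SeqRecord], k: int):
        self.k = k
        self.refs = list(refs)
        self.codes = {r.id: encode(r.residues) for r in refs}
        self.rc_codes = {r.id: encode_revcomp(self.codes[r.id]) for r in refs}
        self.index: Dict[bytes, List[Tuple[int, int, int]]] = {}
        # (ref_idx, strand_idx, pos); strand 0 = forward, 1 = revcomp text
        for ri, r in enumerate(self.refs):
            for si, code in enumerate((self.codes[r.id], self.rc_codes[r.id])):
                raw = code.tobytes()
                for i in range(0, len(raw) - k + 1):
                    self.index.setdefault(raw[i : i + k], []).append((ri, si, i))


def map_reads(
    reads: Iterable[QualRead],
    refs: Sequence[SeqRecord],
    seed_k: int = 15,
    max_mismatch_rate: float = 0.05,
    rng_seed: int = 0,
) -> List[AlignmentRecord]:
    """Best ungapped end-to-end placement per read; unmapped reads omitted."""
    idx = _RefIndex(refs, seed_k)
    rng = np.random.default_rng(rng_seed)
    out: List[AlignmentRecord] = []
    for read in reads:
        code = encode(read.residues)
        L = len(code)
        if L < seed_k:
            continue
        max_mm = int(np.floor(max_mismatch_rate * L))
        raw = code.tobytes()
        candidates = set()
        offsets = list(range(0, L - seed_k + 1, seed_k))
        if offsets[-1] != L - seed_k:
            offsets.append(L - seed_k)
        for off in offsets:
            for ri, si, pos in idx.index.get(raw[off : off + seed_k], ()):
                start = pos - off
                text = idx.codes[idx.refs[ri].id] if si == 0 else idx.rc_codes[
                    idx.refs[ri].id
                ]
                if 0 <= start <= len(text) - L:
                    candidates.add((ri, si, start))
        best: List[Tuple[int, int, int]] = []
        best_mm = max_mm + 1
        for ri, si, start in candidates:
            ref_id = idx.refs[ri].id
            text = idx.codes[ref_id] if si == 0 else idx.rc_codes[ref_id]
            mm = int(mismatch_profile(text[start : start + L], code).sum())
            if mm < best_mm:
                best, best_mm = [(ri, si, start)], mm
            elif mm == best_mm:
                best.append((ri, si, start))
        if not best or best_mm > max_mm:
            continue
        best.sort()
        ri, si, start = best[rng.integers(0, len(best))] if len(best) > 1 else best[0]
        ref = idx.refs[ri]
        if si == 0:
            pos, strand, oriented = start, "+", read.residues
        else:
            # placement on the reverse-complement text; convert to + coords
            pos = len(ref) - (start + L)
            strand = "-"
            oriented = decode(encode_revcomp(code))
        out.append(
            AlignmentRecord(
                read_id=read.id,
                ref_id=ref.id,
                pos=pos,
                strand=strand,
                mismatches=best_mm,
                aligned_length=L,
                seq=oriented,
            )
        )
    return out


def coverage(
    alignments: Iterable[AlignmentRecord],
    ref: SeqRecord,
    total_sample_reads: int,
) -> CoverageTrack:
    """Per-position depth on ``ref``; sum(depth) equals the summed aligned
    length of the records on this reference."""
    depth = np.zeros(len(ref), dtype=np.int64)
    for a in alignments:
        if a.ref_id != ref.id:
            continue
        if a.pos + a.aligned_length > len(ref):
            raise ValueError(f"alignment {a.read_id} overruns {ref.id}")
        depth[a.pos : a.pos + a.aligned_length] += 1
    return CoverageTrack(ref.id, depth, total_sample_reads)


def rpkm(mapped_reads: int, length_bp: int, total_reads: int) -> float:
    """Reads per kilobase of reference per million sample reads."""
    if length_bp <= 0 or total_reads <= 0:
        raise ValueError("length_bp and total_reads must be positive")
    return mapped_reads / (length_bp / 1000.0) / (total_reads / 1e6)


def abundance_table(
    alignments_per_sample: Dict[str, Sequence[AlignmentRecord]],
    refs: Sequence[SeqRecord],
    total_reads_per_sample: Dict[str, int],
    bins: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """Per-genome (or per-MAG) RPKM rows across samples.

    ``bins`` maps contig id -> bin (MAG) id; binned contigs are pooled:
    mapped reads summed over member contigs and length the summed contig
    length.  "Mapped reads" counts primary placements only (the mapper emits
    one record per read).
    """
    bins = bins or {}
    length_of: Dict[str, int] = {}
    members: Dict[str, List[str]] = {}
    for r in refs:
        unit = bins.get(r.id, r.id)
        length_of[unit] = length_of.get(unit, 0) + len(r)
        members.setdefault(unit, []).append(r.id)
    rows = []
    for sample in sorted(alignments_per_sample):
        total = total_reads_per_sample[sample]
        mapped: Dict[str, int] = {u: 0 for u in length_of}
        for a in alignments_per_sample[sample]:
            unit = bins.get(a.ref_id, a.ref_id)
            if unit in mapped:
                mapped[unit] += 1
        for unit in sorted(length_of):
            rows.append(
                {
                    "ref_id": unit,
                    "sample_id": sample,
                    "mapped_reads": mapped[unit],
                    "length_bp": length_of[unit],
                    "total_reads": total,
                    "rpkm": rpkm(mapped[unit], length_of[unit], total),
                }
            )
    return pd.DataFrame(rows)
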
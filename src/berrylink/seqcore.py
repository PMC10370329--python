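"""Shared sequence types, coordinate conventions and quality trimming.

Conventions used throughout the package:

* alphabet ``{A, C, G, T, N}``; other IUPAC codes are mapped to ``N`` on
  ingest with a logged warning,
* all internal coordinates are 0-based half-open; 1-based coordinates appear
  only at GFF3/SAM serialization boundaries,
* ``N`` counts as a mismatch in every comparison (conservative and
  deterministic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)

ALPHABET = "ACGTN"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# base -> code: A=0 C=1 G=2 T=3, everything else (incl. N) = 4
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of ``seq`` (involution; ``N`` maps to ``N``)."""
    return seq.translate(_COMPLEMENT)[::-1]


def clean_residues(seq: str, record_id: str = "?") -> str:
    """Uppercase ``seq`` and map non-ACGTN IUPAC codes to ``N``."""
    seq = seq.upper()
    if not set(seq) <= set(ALPHABET):
        n_bad = sum(c not in ALPHABET for c in seq)
        logger.warning(
            "record %s: %d non-ACGTN residues mapped to N", record_id, n_bad
        )
        seq = "".join(c if c in ALPHABET else "N" for c in seq)
    return seq


def encode(seq: str) -> np.ndarray:
    """Encode residues as uint8 codes (A=0 C=1 G=2 T=3 N/other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def encode_revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space (N stays N)."""
    out = (3 - codes[::-1]).astype(np.int16)
    out[codes[::-1] == 4] = 4
    return out.astype(np.uint8)


def mismatch_profile(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Boolean mismatch mask; ``N`` (code 4) always mismatches."""
    return (a != b) | (a == 4) | (b == 4)


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    if len(a) != len(b):
        raise ValueError("hamming: length mismatch")
    return int(mismatch_profile(a, b).sum())


def scan_pattern(text: np.ndarray, pattern: np.ndarray, max_mismatch: int):
    """All start positions where ``pattern`` matches ``text`` with at most
    ``max_mismatch`` substitutions (ungapped).

    Returns ``(positions, mismatch_counts)`` as int arrays, positions sorted.
    """
    n = len(text) - len(pattern) + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    windows = sliding_window_view(text, len(pattern))
    mm = ((windows != pattern) | (windows == 4) | (pattern == 4)).sum(axis=1)
    pos = np.nonzero(mm <= max_mismatch)[0]
    return pos.astype(np.int64), mm[pos].astype(np.int64)


@dataclass
class SeqRecord:
    """A named nucleotide sequence (genome, contig or region)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        self.residues = clean_residues(self.residues, self.id)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class QualRead:
    """A short read with per-base Phred scores and a sample label."""

    id: str
    residues: str
    quals: Sequence[int]
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.residues):
            raise ValueError(
                f"read {self.id}: {len(self.quals)} qualities for "
                f"{len(self.residues)} residues"
            )
        if len(self.quals) and (min(self.quals) < 0 or max(self.quals) > 60):
            raise ValueError(f"read {self.id}: Phred scores outside [0, 60]")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a named reference."""

    ref_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.ref_id == other.ref_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class AlignmentRecord:
    """Ungapped placement of a read on a reference (SAM-compatible).

    ``seq`` is reference-oriented, as in SAM: for ``-`` strand placements it
    is the reverse complement of the original read.
    """

    read_id: str
    ref_id: str
    pos: int
    strand: str
    mismatches: int
    aligned_length: int
    seq: str = ""


def quality_trim(
    read: QualRead,
    window: int = 4,
    min_avg_q: float = 15,
    end_q: float = 2,
    min_len: int = 100,
    adapters: Iterable[str] = (),
) -> Optional[QualRead]:
    """Trimmomatic-style trim: adapter clip, end trim, sliding window, length.

    Stage order is fixed: (1) exact-match adapter clip from the leftmost
    adapter start; (2) removal of leading/trailing bases with quality below
    ``end_q``; (3) 5'->3' scan cutting the read at the start of the first
    ``window``-sized window whose mean quality falls below ``min_avg_q``;
    (4) reads shorter than ``min_len`` are discarded (``None`` returned).

    The operation is idempotent: trimming a trimmed read changes nothing.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    seq = read.residues
    quals = list(read.quals)

    cut = len(seq)
    for adapter in adapters:
        i = seq.find(adapter.upper())
        if i >= 0:
            cut = min(cut, i)
    seq, quals = seq[:cut], quals[:cut]

    lo = 0
    while lo < len(seq) and quals[lo] < end_q:
        lo += 1
    hi = len(seq)
    while hi > lo and quals[hi - 1] < end_q:
        hi -= 1
    seq, quals = seq[lo:hi], quals[lo:hi]

    for i in range(0, len(seq) - window + 1):
        if sum(quals[i : i + window]) / window < min_avg_q:
            seq, quals = seq[:i], quals[:i]
            break

    if len(seq) < min_len:
        return None
    return QualRead(read.id, seq, quals, read.sample_id)
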
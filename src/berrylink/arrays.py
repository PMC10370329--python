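"""CRISPR array detection in assembled genomes and repeat dereplication.

The detector is CRT-style: exact k-mer seeds recurring at an array-like
spacing nominate a candidate repeat, the seed is extended while the two
copies agree, all approximate occurrences of the candidate repeat are then
located genome-wide, and chains of occurrences separated by spacer-sized
gaps with at least ``min_repeats`` units are reported as arrays.  The repeat
consensus is the per-column majority over copies (ties broken
alphabetically).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .seqcore import (
    SeqRecord,
    decode,
    encode,
    revcomp,
    scan_pattern,
)


@dataclass
class CRISPRArray:
    """A detected repeat-spacer-repeat locus on one genome."""

    genome_id: str
    repeat_consensus: str
    repeat_starts: List[int]
    repeat_length: int
    spacers: List[str]

    @property
    def n_units(self) -> int:
        return len(self.repeat_starts)

    @property
    def repeat_intervals(self) -> List[Tuple[int, int]]:
        return [(s, s + self.repeat_length) for s in self.repeat_starts]


@dataclass
class RepeatSet:
    """Dereplicated repeats with taxon provenance.

    No two entries share a sequence or are reverse complements of each other;
    ids are zero-padded serials assigned in sorted (taxon, genome) order.
    """

    entries: List[Tuple[str, str, Tuple[str, ...], Tuple[str, ...]]] = field(
        default_factory=list
    )  # (repeat_id, sequence, taxa, source_genomes)

    def __len__(self) -> int:
        return len(self.entries)

    def sequences(self) -> Dict[str, str]:
        return {rid: seq for rid, seq, _, _ in self.entries}

    def taxon_of(self) -> Dict[str, str]:
        # first (alphabetical) taxon is the representative label
        return {rid: taxa[0] for rid, _, taxa, _ in self.entries}


def _consensus(copies: Sequence[str]) -> str:
    arr = np.stack([encode(c) for c in copies])
    cons = []
    for col in arr.T:
        counts = np.bincount(col[col < 4], minlength=4)
        if counts.sum() == 0:
            cons.append(4)
        else:
            cons.append(int(np.argmax(counts)))  # argmax tie -> lowest = alphabetical
    return decode(np.array(cons, dtype=np.uint8))


def detect_arrays(
    genome: SeqRecord,
    min_repeats: int = 3,
    repeat_len: Tuple[int, int] = (19, 48),
    spacer_len: Tuple[int, int] = (18, 60),
    seed_k: int = 8,
    max_repeat_mismatch: int = 2,
) -> List[CRISPRArray]:
    """Detect CRISPR arrays on the forward strand of ``genome``.

    Arrays are reported in genome order with 0-based coordinates; calls that
    share a repeat interval are merged (the call with most units wins).
    """
    seq = genome.residues
    code = encode(seq)
    n = len(code)
    if n <= 2 * repeat_len[1]:
        return []
    min_period = repeat_len[0] + spacer_len[0]
    max_period = repeat_len[1] + spacer_len[1]

    # seed pairs: identical k-mers recurring at array-like spacing
    kmer_pos: Dict[bytes, List[int]] = {}
    raw = code.tobytes()
    for i in range(n - seed_k + 1):
        kmer_pos.setdefault(raw[i : i + seed_k], []).append(i)

    candidate_repeats: Dict[str, None] = {}
    for positions in kmer_pos.values():
        if len(positions) < 2:
            continue
        for a, b in zip(positions, positions[1:]):
            d = b - a
            if not (min_period <= d <= max_period):
                continue
            # extend while the two copies agree, up to the max repeat length
            left = 0
            while (
                a - left - 1 >= 0
                and code[a - left - 1] == code[b - left - 1]
                and code[a - left - 1] != 4
                and (seed_k + left + 1) <= repeat_len[1]
                and left + 1 < d - spacer_len[0] - seed_k  # keep copies disjoint-ish
            ):
                left += 1
            right = 0
            while (
                b + seed_k + right < n
                and code[a + seed_k + right] == code[b + seed_k + right]
                and code[a + seed_k + right] != 4
                and (seed_k + left + right + 1) <= repeat_len[1]
            ):
                right += 1
            length = seed_k + left + right
            if length < repeat_len[0]:
                continue
            candidate_repeats.setdefault(seq[a - left : a - left + length])

    arrays: List[CRISPRArray] = []
    seen_chains = set()
    for repeat in candidate_repeats:
        pat = encode(repeat)
        pos, _ = scan_pattern(code, pat, max_repeat_mismatch)
        if len(pos) < min_repeats:
            continue
        # drop overlapping occurrences, keep the leftmost of each clump
        kept = []
        for p in pos:
            if not kept or p >= kept[-1] + len(repeat):
                kept.append(int(p))
        # group into chains with spacer-sized gaps
        chain = [kept[0]]
        chains = []
        for p in kept[1:]:
            gap = p - (chain[-1] + len(repeat))
            if spacer_len[0] <= gap <= spacer_len[1]:
                chain.append(p)
            else:
                chains.append(chain)
                chain = [p]
        chains.append(chain)
        for chain in chains:
            if len(chain) < min_repeats:
                continue
            key = (len(repeat), tuple(chain))
            if key in seen_chains:
                continue
            seen_chains.add(key)
            copies = [seq[p : p + len(repeat)] for p in chain]
            spacers = [
                seq[chain[i] + len(repeat) : chain[i + 1]]
                for i in range(len(chain) - 1)
            ]
            arrays.append(
                CRISPRArray(
                    genome.id, _consensus(copies), chain, len(repeat), spacers
                )
            )

    # merge overlapping calls of the same locus: keep the call with most
    # units, breaking ties by total copy-to-consensus disagreement (the true
    # repeat phase has agreeing copies; shifted candidates accumulate
    # mismatches in the chance-matching flank columns)
    def _copy_disagreement(a: CRISPRArray) -> int:
        cons = encode(a.repeat_consensus)
        total = 0
        for s in a.repeat_starts:
            total += int(
                (encode(seq[s : s + a.repeat_length]) != cons).sum()
            )
        return total

    arrays.sort(
        key=lambda a: (-a.n_units, _copy_disagreement(a), a.repeat_starts[0])
    )
    kept_arrays: List[CRISPRArray] = []
    spans: List[Tuple[int, int]] = []
    for arr in arrays:
        lo = arr.repeat_starts[0]
        hi = arr.repeat_starts[-1] + arr.repeat_length
        if any(lo < e and s < hi for s, e in spans):
            continue
        kept_arrays.append(arr)
        spans.append((lo, hi))
    kept_arrays.sort(key=lambda a: a.repeat_starts[0])
    return kept_arrays


def dereplicate_repeats(
    arrays: Iterable[CRISPRArray],
    taxon_of_genome: Optional[Dict[str, str]] = None,
) -> RepeatSet:
    """Collapse exact and reverse-complement duplicate repeats across genomes.

    Every entry keeps all taxon labels it was seen in; repeat ids are
    zero-padded serials assigned deterministically (sorted by taxon, then
    source genome, then sequence).
    """
    taxon_of_genome = taxon_of_genome or {}
    groups: Dict[str, dict] = {}
    items = []
    for arr in arrays:
        taxon = taxon_of_genome.get(arr.genome_id, arr.genome_id)
        items.append((taxon, arr.genome_id, arr.repeat_consensus))
    items.sort()
    for taxon, genome_id, repeat in items:
        canon = min(repeat, revcomp(repeat))
        g = groups.setdefault(
            canon, {"sequence": repeat, "taxa": [], "genomes": []}
        )
        if taxon not in g["taxa"]:
            g["taxa"].append(taxon)
        if genome_id not in g["genomes"]:
            g["genomes"].append(genome_id)

    ordered = sorted(
        groups.values(), key=lambda g: (g["taxa"][0], g["genomes"][0], g["sequence"])
    )
    width = max(2, len(str(len(ordered))))
    entries = [
        (str(i + 1).zfill(width), g["sequence"], tuple(g["taxa"]), tuple(g["genomes"]))
        for i, g in enumerate(ordered)
    ]
    return RepeatSet(entries)
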
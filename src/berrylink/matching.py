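"""Spacer-to-phage (protospacer) matching and CRISPR-based host prediction.

A spacer matches a phage when an ungapped full-length placement on either
strand has identity >= ``min_identity`` over the entire spacer length
(equivalently, at most ``floor((1 - min_identity) * L)`` substitutions).
Host calls are per-phage majority votes over the taxa of matching spacers:
argmax wins, ties are left unassigned and flagged ambiguous, and calls
resting on a single hit are flagged weak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .mining import SpacerCatalog
from .seqcore import Interval, SeqRecord, encode, encode_revcomp, scan_pattern


@dataclass
class ProtospacerHit:
    spacer_id: str
    taxon: str
    phage_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    identity: float


@dataclass
class HostPrediction:
    phage_id: str
    taxon_call: str  # taxon label or "unassigned"
    hits_per_taxon: Dict[str, int] = field(default_factory=dict)
    weak_flag: bool = False
    ambiguous_flag: bool = False


def match_spacers(
    catalog: SpacerCatalog,
    phages: Sequence[SeqRecord],
    min_identity: float = 0.80,
) -> List[ProtospacerHit]:
    """Every ungapped full-length placement of every spacer on every phage
    (both strands) with identity >= ``min_identity``.

    Overlapping placements of one spacer are reported separately.  Output is
    deterministically ordered by (spacer_id, phage_id, start).
    """
    taxon = {r.spacer_id: r.taxon_label for r in catalog.records}
    hits: List[ProtospacerHit] = []
    phage_codes = [(ph.id, encode(ph.residues)) for ph in phages]
    for rec in catalog.records:
        L = len(rec.sequence)
        # small epsilon so e.g. (1 - 0.8) * 30 floors to 6, not 5
        max_mm = int(np.floor((1.0 - min_identity) * L + 1e-9))
        fwd = encode(rec.sequence)
        rc = encode_revcomp(fwd)
        for phage_id, code in phage_codes:
            for pat, strand in ((fwd, "+"), (rc, "-")):
                pos, mm = scan_pattern(code, pat, max_mm)
                for p, m in zip(pos, mm):
                    hits.append(
                        ProtospacerHit(
                            spacer_id=rec.spacer_id,
                            taxon=taxon[rec.spacer_id],
                            phage_id=phage_id,
                            start=int(p),
                            end=int(p) + L,
                            strand=strand,
                            mismatches=int(m),
                            identity=(L - int(m)) / L,
                        )
                    )
    hits.sort(key=lambda h: (h.spacer_id, h.phage_id, h.start, h.strand))
    return hits


def predict_hosts(
    hits: Iterable[ProtospacerHit],
    phage_ids: Optional[Sequence[str]] = None,
) -> List[HostPrediction]:
    """Per-phage majority host call from protospacer hit taxa.

    Phages with zero hits (when listed in ``phage_ids``) are "unassigned".
    A tie for the best taxon yields "unassigned" with the ambiguous flag; a
    runner-up with at least half the best taxon's hits also sets the
    ambiguous flag; a winning taxon with exactly one hit is flagged weak.
    """
    by_phage: Dict[str, Dict[str, int]] = {}
    for h in hits:
        by_phage.setdefault(h.phage_id, {}).setdefault(h.taxon, 0)
        by_phage[h.phage_id][h.taxon] += 1
    all_ids = list(phage_ids) if phage_ids is not None else sorted(by_phage)
    for pid in by_phage:
        if pid not in all_ids:
            all_ids.append(pid)

    predictions = []
    for pid in all_ids:
        counts = by_phage.get(pid, {})
        if not counts:
            predictions.append(HostPrediction(pid, "unassigned", {}))
            continue
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        best_taxon, best_n = ranked[0]
        runner_n = ranked[1][1] if len(ranked) > 1 else 0
        tie = runner_n == best_n
        predictions.append(
            HostPrediction(
                phage_id=pid,
                taxon_call="unassigned" if tie else best_taxon,
                hits_per_taxon=dict(ranked),
                weak_flag=(not tie) and best_n == 1,
                ambiguous_flag=tie or (runner_n * 2 >= best_n and runner_n > 0),
            )
        )
    return predictions


def export_network(
    hits: Sequence[ProtospacerHit],
    predictions: Sequence[HostPrediction],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables of the spacer-phage match network.

    Nodes: spacers with >= 1 hit (typed by taxon) and phages.  Edges: one per
    hit, weighted by identity.  Deterministic, stably ordered.
    """
    spacer_nodes = sorted({(h.spacer_id, h.taxon) for h in hits})
    phage_nodes = sorted(
        {h.phage_id for h in hits} | {p.phage_id for p in predictions}
    )
    host_call = {p.phage_id: p.taxon_call for p in predictions}
    nodes = pd.DataFrame(
        [
            {"node": sid, "type": "spacer", "taxon": tx}
            for sid, tx in spacer_nodes
        ]
        + [
            {"node": pid, "type": "phage", "taxon": host_call.get(pid, "unassigned")}
            for pid in phage_nodes
        ]
    )
    edges = pd.DataFrame(
        [
            {
                "spacer": h.spacer_id,
                "phage": h.phage_id,
                "weight": h.identity,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
            }
            for h in sorted(hits, key=lambda h: (h.spacer_id, h.phage_id, h.start))
        ]
    )
    return nodes, edges


def hits_table(hits: Sequence[ProtospacerHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "spacer_id": h.spacer_id,
                "taxon": h.taxon,
                "phage_id": h.phage_id,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "mismatches": h.mismatches,
                "identity_percent": round(100.0 * h.identity, 2),
            }
            for h in hits
        ]
    )
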
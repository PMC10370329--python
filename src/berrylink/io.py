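"""Readers and writers for FASTA, FASTQ, SAM, GFF3 and BED6.

FASTA/FASTQ go through Biopython's SeqIO and SAM through pysam; thin wrappers
enforce this package's round-trip contract (``parse(serialize(x)) == x``) and
report malformed records with a line number.  All writers emit 1-based
coordinates for GFF3/SAM and 0-based for BED, per the package-wide coordinate
convention.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Sequence, Tuple

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .seqcore import AlignmentRecord, Interval, QualRead, SeqRecord


def read_fasta(path: str | os.PathLike) -> List[SeqRecord]:
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id) :].strip()
            records.append(SeqRecord(rec.id, str(rec.seq), desc))
    except ValueError as exc:  # pragma: no cover - malformed input path
        raise ValueError(f"{path}: malformed FASTA record #{len(records) + 1}: {exc}")
    return records


def write_fasta(path: str | os.PathLike, records: Iterable[SeqRecord]) -> None:
    bio = [
        BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_fastq(path: str | os.PathLike, sample_id: str = "") -> List[QualRead]:
    reads: List[QualRead] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            reads.append(
                QualRead(
                    rec.id,
                    str(rec.seq),
                    list(rec.letter_annotations["phred_quality"]),
                    sample_id,
                )
            )
    except ValueError as exc:
        # Sanger FASTQ records are 4 lines each.
        raise ValueError(
            f"{path}: malformed FASTQ record near line {4 * len(reads) + 1}: {exc}"
        )
    return reads


def write_fastq(path: str | os.PathLike, reads: Iterable[QualRead]) -> None:
    bio = []
    for r in reads:
        rec = BioSeqRecord(Seq(r.residues), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quals)
        bio.append(rec)
    SeqIO.write(bio, str(path), "fastq")


def write_sam(
    path: str | os.PathLike,
    alignments: Iterable[AlignmentRecord],
    ref_lengths: Dict[str, int],
) -> None:
    """Write ungapped alignments (CIGAR ``<len>M``) as SAM with NM tags."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in ref_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for a in alignments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = a.read_id
            seg.query_sequence = a.seq or None
            seg.flag = 16 if a.strand == "-" else 0
            seg.reference_id = out.header.get_tid(a.ref_id)
            seg.reference_start = a.pos
            seg.mapping_quality = 255
            seg.cigartuples = [(0, a.aligned_length)]
            seg.set_tag("NM", int(a.mismatches))
            out.write(seg)


def read_sam(path: str | os.PathLike) -> List[AlignmentRecord]:
    records: List[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as f:
        for seg in f:
            if seg.is_unmapped:
                continue
            records.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    ref_id=seg.reference_name,
                    pos=seg.reference_start,
                    strand="-" if seg.is_reverse else "+",
                    mismatches=int(seg.get_tag("NM")) if seg.has_tag("NM") else 0,
                    aligned_length=seg.infer_query_length() or 0,
                    seq=seg.query_sequence or "",
                )
            )
    return records


def write_gff3(
    path: str | os.PathLike,
    features: Sequence[Tuple[Interval, str, Dict[str, str]]],
    source: str = "berrylink",
) -> None:
    """Write features as GFF3 (coordinates converted to 1-based inclusive)."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for iv, ftype, attrs in features:
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            out.write(
                f"{iv.ref_id}\t{source}\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attr_s}\n"
            )


def write_bed(
    path: str | os.PathLike,
    intervals: Sequence[Tuple[Interval, str, float]],
) -> None:
    """Write BED6 rows ``(interval, name, score)`` (0-based half-open)."""
    with open(path, "w") as out:
        for iv, name, score in intervals:
            out.write(
                f"{iv.ref_id}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )
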
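"""Read data model, FASTQ/SAM input and output, and per-stage filter metrics.

The pipeline tracks every read from ingestion to a single terminal
disposition (a drop bucket, host subtraction, classified, or unclassified).
``ReadStatus`` encodes the stages in pipeline order; transitions are
monotone — a record never moves backwards.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ReadStatus",
    "ReadRecord",
    "FilterMetrics",
    "AlignmentHit",
    "read_fastq",
    "read_alignments",
    "write_fastq",
    "write_metrics",
    "pair_stem",
    "check_conservation",
]

# Phred+33 qualities up to Q41 cover modern short-read platforms; characters
# above 'J' are the signature of Phred+64 input, which is rejected rather
# than auto-detected (silent mis-decoding would corrupt the quality filters).
_MIN_QUAL_CHAR = 33
_MAX_QUAL_CHAR = 33 + 41


class ReadStatus(enum.IntEnum):
    """Pipeline dispositions, in stage order (monotone transitions only)."""

    RAW = 0
    TRIMMED = 1
    FILTERED_QUALITY = 2
    FILTERED_COMPLEXITY = 3
    FILTERED_DUPLICATE = 4
    SUBTRACTED_KMER = 5
    SUBTRACTED_ALIGNMENT = 6
    NONHOST = 7
    CLASSIFIED = 8
    UNCLASSIFIED = 9


#: Statuses that are terminal: the read takes no further part in the run.
TERMINAL_STATUSES = frozenset(
    {
        ReadStatus.FILTERED_QUALITY,
        ReadStatus.FILTERED_COMPLEXITY,
        ReadStatus.FILTERED_DUPLICATE,
        ReadStatus.SUBTRACTED_KMER,
        ReadStatus.SUBTRACTED_ALIGNMENT,
        ReadStatus.CLASSIFIED,
        ReadStatus.UNCLASSIFIED,
    }
)


@dataclass
class ReadRecord:
    """One sequencing read with bases, qualities and a filter-status trail."""

    read_id: str
    bases: str
    quals: list[int]
    mate_of: Optional[str] = None
    is_first_of_pair: bool = True
    status: ReadStatus = ReadStatus.RAW
    status_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def advance_status(self, new: ReadStatus, reason: Optional[str] = None) -> None:
        """Move to a later pipeline status; reverting raises ``ValueError``."""
        if new < self.status:
            raise ValueError(
                f"read {self.read_id!r}: illegal status transition "
                f"{self.status.name} -> {new.name}"
            )
        self.status = new
        if reason is not None:
            self.status_reason = reason

    @property
    def is_dropped(self) -> bool:
        return self.status in (
            ReadStatus.FILTERED_QUALITY,
            ReadStatus.FILTERED_COMPLEXITY,
            ReadStatus.FILTERED_DUPLICATE,
        )


@dataclass
class FilterMetrics:
    """Bookkeeping for one pipeline stage; reads_in == reads_out + dropped."""

    stage_name: str
    reads_in: int = 0
    reads_out: int = 0
    reads_dropped: int = 0
    bases_trimmed: int = 0

    def validate(self) -> None:
        if self.reads_in != self.reads_out + self.reads_dropped:
            raise ValueError(
                f"stage {self.stage_name}: {self.reads_in} in != "
                f"{self.reads_out} out + {self.reads_dropped} dropped"
            )


@dataclass(frozen=True)
class AlignmentHit:
    """One candidate placement of a read on a reference sequence.

    Coordinates are 0-based, half-open on the reference; ``nm`` is the edit
    distance (mismatches plus inserted/deleted bases), per the SAM NM tag.
    """

    read_id: str
    ref_name: str
    ref_start: int
    cigar: str
    nm: int
    mapq: int = 0
    is_secondary: bool = False
    strand: str = "+"


def pair_stem(read_id: str) -> str:
    """Strip a trailing /1 or /2 mate suffix from a read identifier."""
    if len(read_id) > 2 and read_id[-2] == "/" and read_id[-1] in "12":
        return read_id[:-2]
    return read_id


def _decode_quals(qual_str: str, read_id: str, record_number: int) -> list[int]:
    quals = []
    for ch in qual_str:
        o = ord(ch)
        if o < _MIN_QUAL_CHAR or o > _MAX_QUAL_CHAR:
            raise ValueError(
                f"record {record_number} ({read_id!r}): quality character "
                f"{ch!r} outside the Phred+33 range '!'..'J' "
                "(Phred+64 input is not supported)"
            )
        quals.append(o - 33)
    return quals


def _fastq_records(path: str, is_first: bool) -> Iterator[ReadRecord]:
    with open(path) as handle:
        for number, (title, seq, qual) in enumerate(FastqGeneralIterator(handle), 1):
            read_id = title.split()[0] if title.split() else title
            seq = seq.upper()
            if len(seq) != len(qual):
                raise ValueError(
                    f"record {number} ({read_id!r}) in {path}: sequence and "
                    "quality strings differ in length"
                )
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(
                    f"record {number} ({read_id!r}) in {path}: "
                    f"invalid base characters {sorted(bad)}"
                )
            yield ReadRecord(
                read_id=read_id,
                bases=seq,
                quals=_decode_quals(qual, read_id, number),
                is_first_of_pair=is_first,
            )


def read_fastq(path: str, paired_path: Optional[str] = None) -> Iterator[ReadRecord]:
    """Stream ``ReadRecord``s from a FASTQ file, optionally with mate file.

    Paired files must have equal record counts in matching order; mates are
    linked through ``mate_of`` and opposite ``is_first_of_pair`` flags.
    Qualities are decoded from Phred+33 only.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if paired_path is None:
        yield from _fastq_records(path, is_first=True)
        return
    if not os.path.exists(paired_path):
        raise FileNotFoundError(paired_path)
    it1 = _fastq_records(path, is_first=True)
    it2 = _fastq_records(paired_path, is_first=False)
    n = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            break
        if r1 is None or r2 is None:
            raise ValueError(
                f"paired FASTQ files {path} and {paired_path} have unequal "
                f"record counts (mismatch after {n} pairs)"
            )
        n += 1
        if pair_stem(r1.read_id) != pair_stem(r2.read_id):
            raise ValueError(
                f"pair {n}: read ids {r1.read_id!r} and {r2.read_id!r} "
                "do not share a stem"
            )
        r1.mate_of = r2.read_id
        r2.mate_of = r1.read_id
        yield r1
        yield r2


def _cigar_query_length(cigar: str) -> int:
    import re

    length = 0
    for num, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        if op in "MIS=X":
            length += int(num)
    return length


def read_alignments(path: str) -> Iterator[tuple[ReadRecord, list[AlignmentHit]]]:
    """Stream ``(ReadRecord, hits)`` per query from a SAM/BAM file.

    All primary and secondary/supplementary placements are collected per
    query name; unmapped queries yield an empty hit list. Requires a header
    sequence dictionary. Queries must be grouped (e.g. name-collated or
    unsorted aligner output); records of one query must be adjacent.
    """
    import pysam

    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        if not fh.header.get("SQ"):
            raise ValueError(f"{path}: SAM header has no sequence dictionary (@SQ)")
        current: Optional[str] = None
        record: Optional[ReadRecord] = None
        hits: list[AlignmentHit] = []
        for aln in fh:
            if aln.is_paired:
                key = aln.query_name + ("/1" if aln.is_read1 else "/2")
            else:
                key = aln.query_name
            if key != current:
                if record is not None:
                    yield record, hits
                current = key
                record = None
                hits = []
            if not aln.is_secondary and not aln.is_supplementary:
                seq = aln.query_sequence or ""
                quals = list(aln.query_qualities) if aln.query_qualities is not None else [30] * len(seq)
                if aln.is_reverse and seq:
                    seq = reverse_complement(seq)
                    quals = quals[::-1]
                record = ReadRecord(
                    read_id=key,
                    bases=seq,
                    quals=quals,
                    is_first_of_pair=aln.is_read1 or not aln.is_paired,
                )
            if not aln.is_unmapped:
                hits.append(
                    AlignmentHit(
                        read_id=key,
                        ref_name=aln.reference_name,
                        ref_start=aln.reference_start,
                        cigar=aln.cigarstring or "",
                        nm=int(aln.get_tag("NM")) if aln.has_tag("NM") else 0,
                        mapq=aln.mapping_quality,
                        is_secondary=aln.is_secondary or aln.is_supplementary,
                        strand="-" if aln.is_reverse else "+",
                    )
                )
        if record is not None:
            yield record, hits


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def write_fastq(records: Iterable[ReadRecord], path: str) -> int:
    """Write records as Phred+33 FASTQ; returns the number written."""
    n = 0
    with open(path, "w") as out:
        for rec in records:
            qual = "".join(chr(q + 33) for q in rec.quals)
            out.write(f"@{rec.read_id}\n{rec.bases}\n+\n{qual}\n")
            n += 1
    return n


def write_metrics(metrics: Iterable[FilterMetrics], path: str) -> None:
    """Write per-stage metrics as TSV, one row per stage."""
    with open(path, "w") as out:
        out.write("stage_name\treads_in\treads_out\treads_dropped\tbases_trimmed\n")
        for m in metrics:
            m.validate()
            out.write(
                f"{m.stage_name}\t{m.reads_in}\t{m.reads_out}\t"
                f"{m.reads_dropped}\t{m.bases_trimmed}\n"
            )


def check_conservation(records: Iterable[ReadRecord]) -> dict[str, int]:
    """Count terminal dispositions and verify every read has exactly one.

    Returns a status-name → count mapping. Raises ``ValueError`` if any
    record is still in a non-terminal state.
    """
    counts: dict[str, int] = {}
    for rec in records:
        if rec.status not in TERMINAL_STATUSES:
            raise ValueError(
                f"read {rec.read_id!r} finished in non-terminal state "
                f"{rec.status.name}"
            )
        counts[rec.status.name] = counts.get(rec.status.name, 0) + 1
    return counts
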
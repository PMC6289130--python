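"""Alignment-based host subtraction and microbial alignment.

The production path consumes externally produced SAM/BAM ("bring your own
aligner"); ``MinimalAligner`` is a small exact-seed, ungapped-extension
aligner sufficient for desk-scale references, so the whole pipeline runs
without third-party executables.

Sequence identity is computed against the full (unclipped) read length:
identity = (query bases in M/=/X operations - NM) / read_length, floored at
zero. Soft-clipped and inserted bases therefore count against identity, the
strictest defensible definition.
"""

from __future__ import annotations

import re
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
from Bio import SeqIO

from .core_io import AlignmentHit, ReadRecord, ReadStatus, reverse_complement

__all__ = [
    "compute_identity",
    "subtract_by_alignment",
    "MinimalAligner",
    "write_sam",
]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def compute_identity(hit: AlignmentHit, read_length: int) -> float:
    """Fraction of the read matching the reference in this placement."""
    ops = _CIGAR_RE.findall(hit.cigar)
    if not ops or "".join(f"{n}{o}" for n, o in ops) != hit.cigar:
        raise ValueError(f"unparseable CIGAR {hit.cigar!r}")
    query_len = sum(int(n) for n, o in ops if o in "MIS=X")
    if query_len != read_length:
        raise ValueError(
            f"CIGAR {hit.cigar!r} consumes {query_len} query bases but the "
            f"read has {read_length}"
        )
    matched = sum(int(n) for n, o in ops if o in "M=X")
    return max(0.0, (matched - hit.nm) / read_length)


def best_identity(hits: Sequence[AlignmentHit], read_length: int) -> float:
    return max((compute_identity(h, read_length) for h in hits), default=0.0)


def subtract_by_alignment(
    records: Iterable[ReadRecord],
    hits_by_read: Dict[str, List[AlignmentHit]],
    min_identity: float = 0.70,
    reference_names: Optional[set[str]] = None,
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Split reads into (non-host survivors, alignment-subtracted).

    A read whose best host hit reaches ``min_identity`` is subtracted;
    pairs are removed jointly, as in k-mer subtraction. Survivors are
    marked NONHOST.
    """
    records = list(records)
    if reference_names is not None:
        for hits in hits_by_read.values():
            for h in hits:
                if h.ref_name not in reference_names:
                    raise ValueError(
                        f"alignment hit references unknown sequence {h.ref_name!r}"
                    )
    flagged: set[str] = set()
    for rec in records:
        hits = hits_by_read.get(rec.read_id, [])
        if hits and best_identity(hits, len(rec.bases)) >= min_identity:
            flagged.add(rec.read_id)
    nonhost: list[ReadRecord] = []
    subtracted: list[ReadRecord] = []
    for rec in records:
        mate_flagged = rec.mate_of is not None and rec.mate_of in flagged
        if rec.read_id in flagged or mate_flagged:
            reason = (
                "host alignment" if rec.read_id in flagged else "mate aligned to host"
            )
            rec.advance_status(ReadStatus.SUBTRACTED_ALIGNMENT, reason)
            subtracted.append(rec)
        else:
            rec.advance_status(ReadStatus.NONHOST)
            nonhost.append(rec)
    return nonhost, subtracted


class MinimalAligner:
    """Exact-seed, ungapped-extension aligner for desk-scale references.

    Seeds of ``seed_length`` bases are indexed over the reference; a read is
    probed with non-overlapping seeds on both strands, every seed hit is
    extended ungapped over the full read, and all placements within one
    mismatch of the best are reported (deterministic order: by mismatch
    count, reference name, position, strand). Placements extending past a
    reference end are not reported; indels only enter the pipeline through
    consumed SAM.
    """

    def __init__(self, references: Dict[str, str], seed_length: int = 21):
        if seed_length < 4:
            raise ValueError("seed_length must be >= 4")
        self.seed_length = seed_length
        self.references = {name: seq.upper() for name, seq in references.items()}
        self._seed_index: Dict[str, list[tuple[str, int]]] = {}
        s = seed_length
        for name, seq in self.references.items():
            for pos in range(0, len(seq) - s + 1):
                seed = seq[pos : pos + s]
                if "N" in seed:
                    continue
                self._seed_index.setdefault(seed, []).append((name, pos))
        self._ref_arrays = {
            name: np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            for name, seq in self.references.items()
        }

    @classmethod
    def from_fasta(cls, path: str, seed_length: int = 21) -> "MinimalAligner":
        refs = {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
        if not refs:
            raise ValueError(f"{path}: empty or unparseable FASTA")
        return cls(refs, seed_length=seed_length)

    def _seed_offsets(self, read_length: int) -> list[int]:
        s = self.seed_length
        offsets = list(range(0, max(1, read_length - s + 1), s))
        last = read_length - s
        if last >= 0 and last not in offsets:
            offsets.append(last)
        return offsets

    def _candidates(self, bases: str) -> set[tuple[str, int]]:
        cands: set[tuple[str, int]] = set()
        s = self.seed_length
        for off in self._seed_offsets(len(bases)):
            seed = bases[off : off + s]
            if "N" in seed:
                continue
            for name, pos in self._seed_index.get(seed, ()):
                start = pos - off
                if start >= 0 and start + len(bases) <= len(self.references[name]):
                    cands.add((name, start))
        return cands

    def align(self, read_id: str, bases: str) -> list[AlignmentHit]:
        """All placements of the read within 1 mismatch of the best."""
        if len(bases) < self.seed_length:
            return []
        read_arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
        rc = reverse_complement(bases)
        rc_arr = np.frombuffer(rc.encode("ascii"), dtype=np.uint8)
        scored: list[tuple[int, str, int, str]] = []
        for strand, seq, arr in (("+", bases, read_arr), ("-", rc, rc_arr)):
            for name, start in self._candidates(seq):
                ref = self._ref_arrays[name]
                window = ref[start : start + len(bases)]
                # N in read or reference counts as a mismatch
                nm = int((window != arr).sum())
                nm += int((window[window == arr] == ord("N")).sum())
                scored.append((nm, name, start, strand))
        if not scored:
            return []
        scored.sort()
        best_nm = scored[0][0]
        hits = []
        for i, (nm, name, start, strand) in enumerate(scored):
            if nm > best_nm + 1:
                break
            hits.append(
                AlignmentHit(
                    read_id=read_id,
                    ref_name=name,
                    ref_start=start,
                    cigar=f"{len(bases)}M",
                    nm=nm,
                    mapq=60 if i == 0 else 0,
                    is_secondary=i > 0,
                    strand=strand,
                )
            )
        return hits

    def align_records(
        self, records: Iterable[ReadRecord]
    ) -> Dict[str, List[AlignmentHit]]:
        return {rec.read_id: self.align(rec.read_id, rec.bases) for rec in records}


def write_sam(
    records: Sequence[ReadRecord],
    hits_by_read: Dict[str, List[AlignmentHit]],
    references: Dict[str, str],
    path: str,
) -> None:
    """Emit records and their hits as a valid SAM file (pysam)."""
    import pysam

    names = sorted(references)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(references[n])} for n in names],
    }
    name_to_tid = {n: i for i, n in enumerate(names)}

    def _name_and_pair_flag(read_id: str) -> tuple[str, int]:
        # mate suffixes are carried in SAM flag bits, not the query name
        if read_id.endswith("/1"):
            return read_id[:-2], 0x1 | 0x40
        if read_id.endswith("/2"):
            return read_id[:-2], 0x1 | 0x80
        return read_id, 0

    with pysam.AlignmentFile(path, "w", header=header) as out:
        for rec in records:
            hits = hits_by_read.get(rec.read_id, [])
            qname, pair_flag = _name_and_pair_flag(rec.read_id)
            if not hits:
                a = pysam.AlignedSegment(out.header)
                a.query_name = qname
                a.query_sequence = rec.bases
                a.query_qualities = rec.quals
                a.flag = 4 | pair_flag
                out.write(a)
                continue
            for hit in hits:
                a = pysam.AlignedSegment(out.header)
                a.query_name = qname
                seq = rec.bases
                quals = rec.quals
                if hit.strand == "-":
                    seq = reverse_complement(seq)
                    quals = quals[::-1]
                a.query_sequence = seq
                a.query_qualities = quals
                a.reference_id = name_to_tid[hit.ref_name]
                a.reference_start = hit.ref_start
                a.cigarstring = hit.cigar
                a.mapping_quality = hit.mapq
                flag = pair_flag
                if hit.strand == "-":
                    flag |= 16
                if hit.is_secondary:
                    flag |= 256
                a.flag = flag
                a.set_tag("NM", hit.nm)
                out.write(a)
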
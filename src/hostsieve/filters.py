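"""Quality, adapter, complexity and duplicate filtering of read libraries.

The chain rescues partially informative reads by trimming (low-quality
ends, adapter read-through, low-complexity masking) before dropping reads
that remain uninformative (too short, too ambiguous, or duplicated).

Stage order: quality trim -> adapter trim -> DUST mask ->
ambiguity/length filter -> duplicate removal. When one mate of a pair is
dropped the survivor is demoted to single-end and continues alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from . import dust
from .core_io import FilterMetrics, ReadRecord, ReadStatus, pair_stem

__all__ = [
    "FilterConfig",
    "trim_low_quality",
    "trim_adapters",
    "dust_mask",
    "filter_ambiguous_and_short",
    "remove_duplicates",
    "run_filter_chain",
]


@dataclass
class FilterConfig:
    """Tunable parameters of the pre-subtraction filter chain.

    ``min_read_length`` should not be below the host index k (31 by
    default): a shorter read cannot be k-mer screened. ``dust_window`` 64
    and ``dust_score_threshold`` 2.0 are the published symmetric-DUST
    defaults. ``duplicate_key_length`` of ``None`` keys duplicates on the
    full read.
    """

    min_base_quality: int = 15
    quality_window: int = 1
    min_read_length: int = 31
    max_ambiguous_fraction: float = 0.05
    adapter_sequences: Sequence[str] = field(default_factory=list)
    min_adapter_overlap: int = 6
    dust_window: int = 64
    dust_score_threshold: float = 2.0
    duplicate_key_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.quality_window < 1:
            raise ValueError("quality_window must be >= 1")
        if self.dust_window < 3:
            raise ValueError("dust_window must be >= 3 (triplets must exist)")
        if not 0.0 <= self.max_ambiguous_fraction <= 1.0:
            raise ValueError("max_ambiguous_fraction must lie in [0, 1]")
        for a in self.adapter_sequences:
            if set(a) - set("ACGT"):
                raise ValueError(f"adapter {a!r} must be uppercase ACGT")


def trim_low_quality(record: ReadRecord, cfg: FilterConfig) -> int:
    """Trim low-quality ends in place; returns the number of bases removed.

    Greedy end trimming: a terminal base is removed while it is below
    ``min_base_quality`` or the terminal window of ``quality_window`` bases
    has mean quality below it. With the default window of 1 this is plain
    per-base end trimming. A fully trimmed read becomes length 0 and is
    dropped downstream by the length check.
    """
    q = record.quals
    t = cfg.min_base_quality
    w = cfg.quality_window
    lo, hi = 0, len(q)

    def _bad(window: Sequence[int], terminal: int) -> bool:
        return terminal < t or (sum(window) / len(window)) < t

    while hi > lo and _bad(q[max(lo, hi - w) : hi], q[hi - 1]):
        hi -= 1
    while hi > lo and _bad(q[lo : min(hi, lo + w)], q[lo]):
        lo += 1
    trimmed = len(q) - (hi - lo)
    if trimmed:
        record.bases = record.bases[lo:hi]
        record.quals = q[lo:hi]
        record.advance_status(ReadStatus.TRIMMED)
    return trimmed


def trim_adapters(record: ReadRecord, cfg: FilterConfig) -> int:
    """Remove adapter read-through from the 3' end; returns bases removed.

    A read suffix equal (exactly, no mismatches) to a prefix of any adapter,
    with at least ``min_adapter_overlap`` bases of overlap, is trimmed; the
    longest qualifying trim across adapters wins.
    """
    bases = record.bases
    best = 0
    for adapter in cfg.adapter_sequences:
        max_l = min(len(bases), len(adapter))
        for length in range(max_l, max(cfg.min_adapter_overlap, best + 1) - 1, -1):
            if length <= best:
                break
            if bases.endswith(adapter[:length]):
                best = length
                break
    if best:
        record.bases = bases[: len(bases) - best]
        record.quals = record.quals[: len(record.quals) - best]
        record.advance_status(ReadStatus.TRIMMED)
    return best


def dust_mask(record: ReadRecord, cfg: FilterConfig) -> int:
    """Mask low-complexity stretches with N in place; returns bases masked."""
    masked = dust.mask_sequence(
        record.bases, window=cfg.dust_window, threshold=cfg.dust_score_threshold
    )
    if masked is record.bases:
        return 0
    n_masked = masked.count("N") - record.bases.count("N")
    record.bases = masked
    record.advance_status(ReadStatus.TRIMMED)
    return n_masked


def filter_ambiguous_and_short(record: ReadRecord, cfg: FilterConfig) -> bool:
    """Drop reads that are too short or too ambiguous post-trim/mask.

    Returns True when the read survives. Over-masked reads are dropped as
    FILTERED_COMPLEXITY; short reads as FILTERED_QUALITY.
    """
    n = len(record.bases)
    if n > 0:
        n_frac = record.bases.count("N") / n
        if n_frac > cfg.max_ambiguous_fraction:
            record.advance_status(
                ReadStatus.FILTERED_COMPLEXITY,
                f"ambiguous fraction {n_frac:.3f} > {cfg.max_ambiguous_fraction}",
            )
            return False
    if n < cfg.min_read_length:
        record.advance_status(
            ReadStatus.FILTERED_QUALITY,
            f"length {n} < {cfg.min_read_length} after trimming",
        )
        return False
    return True


def _dup_key(record: ReadRecord, key_length: Optional[int]) -> str:
    return record.bases if key_length is None else record.bases[:key_length]


def remove_duplicates(
    records: Iterable[ReadRecord], cfg: Optional[FilterConfig] = None
) -> list[ReadRecord]:
    """Keep the first read (or pair, keyed jointly) per duplicate key.

    Pairs are keyed on both mates' leading ``duplicate_key_length`` bases in
    forward orientation; later records with an identical key are dropped as
    FILTERED_DUPLICATE. Input order decides the survivor.
    """
    cfg = cfg or FilterConfig()
    records = list(records)
    by_id = {r.read_id: r for r in records}
    seen_pair: set[tuple[str, str]] = set()
    seen_single: set[str] = set()
    done: set[str] = set()
    out: list[ReadRecord] = []
    for rec in records:
        if rec.read_id in done:
            continue
        mate = by_id.get(rec.mate_of) if rec.mate_of else None
        if mate is not None:
            first, second = (rec, mate) if rec.is_first_of_pair else (mate, rec)
            key = (
                _dup_key(first, cfg.duplicate_key_length),
                _dup_key(second, cfg.duplicate_key_length),
            )
            done.update((rec.read_id, mate.read_id))
            if key in seen_pair:
                first.advance_status(ReadStatus.FILTERED_DUPLICATE, "duplicate pair")
                second.advance_status(ReadStatus.FILTERED_DUPLICATE, "duplicate pair")
            else:
                seen_pair.add(key)
                out.extend([first, second] if rec.is_first_of_pair else [rec, mate])
        else:
            done.add(rec.read_id)
            key1 = _dup_key(rec, cfg.duplicate_key_length)
            if key1 in seen_single:
                rec.advance_status(ReadStatus.FILTERED_DUPLICATE, "duplicate read")
            else:
                seen_single.add(key1)
                out.append(rec)
    return out


def run_filter_chain(
    records: Iterable[ReadRecord],
    cfg: Optional[FilterConfig] = None,
    skip_duplicates: bool = False,
) -> tuple[list[ReadRecord], list[FilterMetrics]]:
    """Apply the full pre-subtraction filter chain.

    Returns surviving records (pairs kept adjacent; widowed mates demoted to
    single-end) and one ``FilterMetrics`` row per stage. Read counts are
    conserved: every input read either survives or carries a terminal
    dropped status.
    """
    cfg = cfg or FilterConfig()
    records = list(records)
    n_in = len(records)

    m_qual = FilterMetrics("quality_trim", reads_in=n_in, reads_out=n_in)
    for rec in records:
        m_qual.bases_trimmed += trim_low_quality(rec, cfg)

    m_adapt = FilterMetrics("adapter_trim", reads_in=n_in, reads_out=n_in)
    for rec in records:
        m_adapt.bases_trimmed += trim_adapters(rec, cfg)

    m_dust = FilterMetrics("dust_mask", reads_in=n_in, reads_out=n_in)
    for rec in records:
        m_dust.bases_trimmed += dust_mask(rec, cfg)

    m_ambig = FilterMetrics("ambiguity_length_filter", reads_in=n_in)
    survivors: list[ReadRecord] = []
    for rec in records:
        if filter_ambiguous_and_short(rec, cfg):
            survivors.append(rec)
        else:
            m_ambig.reads_dropped += 1
    m_ambig.reads_out = len(survivors)

    # widow mates whose partner was dropped: demote to single-end
    alive = {r.read_id for r in survivors}
    for rec in survivors:
        if rec.mate_of and rec.mate_of not in alive:
            rec.mate_of = None

    m_dup = FilterMetrics("duplicate_removal", reads_in=len(survivors))
    if skip_duplicates:
        m_dup.reads_out = len(survivors)
        out = survivors
    else:
        out = remove_duplicates(survivors, cfg)
        m_dup.reads_out = len(out)
        m_dup.reads_dropped = m_dup.reads_in - m_dup.reads_out

    metrics = [m_qual, m_adapt, m_dust, m_ambig, m_dup]
    for m in metrics:
        m.validate()
    return out, metrics
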
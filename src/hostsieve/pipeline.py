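"""End-to-end orchestration: filter -> host subtraction -> classification.

Stage order mirrors the standard computational-subtraction design:

1. quality/adapter/complexity/duplicate filter chain;
2. host k-mer subtraction (Bloom or exact-set index) — cheap removal of
   the bulk of host reads before any alignment;
3. alignment-based host subtraction of the k-mer survivors;
4. microbial alignment of non-host reads and taxonomic classification
   with the paired-end consistency rule and identity cutoff;
5. abundance report, unclassified-read FASTQ, per-stage metrics.

Every input read ends in exactly one terminal disposition; the metrics
reconcile exactly (checked, not assumed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

from Bio import SeqIO

from . import alignment, classify, filters, kmer_index
from .core_io import (
    AlignmentHit,
    FilterMetrics,
    ReadRecord,
    ReadStatus,
    check_conservation,
    read_fastq,
    write_fastq,
    write_metrics,
)
from .taxonomy import TaxonomyTree, build_taxonomy

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    filter_config: filters.FilterConfig = field(default_factory=filters.FilterConfig)
    kmer_k: int = 31
    index_kind: str = "EXACT_SET"
    bloom_fp_rate: float = 0.001
    min_host_kmers: int = 1
    host_min_identity: float = 0.70
    min_identity: float = 0.70
    paired_consistency: bool = True
    length_normalize: bool = False
    seed_length: int = 21
    skip_duplicates: bool = False


@dataclass
class PipelineResult:
    records: List[ReadRecord]
    metrics: List[FilterMetrics]
    classifications: Dict[str, classify.ReadClassification]
    score_table: classify.TaxonScoreTable
    tree: TaxonomyTree
    dispositions: Dict[str, int]
    report_path: Optional[str] = None
    unclassified_path: Optional[str] = None
    metrics_path: Optional[str] = None


def _classify_all(
    records: List[ReadRecord],
    hits_by_read: Dict[str, List[AlignmentHit]],
    tree: TaxonomyTree,
    cfg: PipelineConfig,
) -> Dict[str, classify.ReadClassification]:
    """Classify surviving non-host reads, pairing mates when both exist."""
    by_id = {r.read_id: r for r in records}
    done: set[str] = set()
    out: Dict[str, classify.ReadClassification] = {}
    for rec in records:
        if rec.read_id in done:
            continue
        mate = by_id.get(rec.mate_of) if rec.mate_of else None
        if mate is not None and cfg.paired_consistency:
            first, second = (rec, mate) if rec.is_first_of_pair else (mate, rec)
            cls = classify.classify_read_or_pair(
                hits_by_read.get(first.read_id, []),
                len(first.bases),
                tree,
                min_identity=cfg.min_identity,
                hits_mate2=hits_by_read.get(second.read_id, []),
                read_length2=len(second.bases),
                read_id=first.read_id,
            )
            done.update((rec.read_id, mate.read_id))
            out[first.read_id] = cls
            out[second.read_id] = cls
            status = ReadStatus.CLASSIFIED if cls.is_classified else ReadStatus.UNCLASSIFIED
            first.advance_status(status)
            second.advance_status(status)
        else:
            cls = classify.classify_read_or_pair(
                hits_by_read.get(rec.read_id, []),
                len(rec.bases),
                tree,
                min_identity=cfg.min_identity,
                read_id=rec.read_id,
            )
            done.add(rec.read_id)
            out[rec.read_id] = cls
            rec.advance_status(
                ReadStatus.CLASSIFIED if cls.is_classified else ReadStatus.UNCLASSIFIED
            )
    return out


def run_pipeline(
    fastq_1: str,
    host_fasta: str,
    microbe_fasta: str,
    taxonomy_nodes: str,
    seq_map: str,
    fastq_2: Optional[str] = None,
    taxonomy_names: Optional[str] = None,
    out_dir: Optional[str] = None,
    cfg: Optional[PipelineConfig] = None,
    host_index: Optional[kmer_index.KmerHostIndex] = None,
    host_hits: Optional[Dict[str, List[AlignmentHit]]] = None,
    microbe_hits: Optional[Dict[str, List[AlignmentHit]]] = None,
) -> PipelineResult:
    """Run the full pipeline from files; returns all stage outputs.

    ``host_hits`` / ``microbe_hits`` allow pre-aligned (bring-your-own-SAM)
    input, consumed via :func:`hostsieve.core_io.read_alignments`; when
    absent, the built-in minimal aligner is used.
    """
    cfg = cfg or PipelineConfig()
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        # fail fast on unwritable output before any stage runs
        probe = os.path.join(out_dir, ".write_probe")
        with open(probe, "w"):
            pass
        os.remove(probe)

    records = list(read_fastq(fastq_1, fastq_2))
    n_input = len(records)

    survivors, metrics = filters.run_filter_chain(
        records, cfg.filter_config, skip_duplicates=cfg.skip_duplicates
    )

    if host_index is None:
        host_index = kmer_index.build_index(
            host_fasta,
            k=cfg.kmer_k,
            structure_kind=cfg.index_kind,
            target_fp_rate=cfg.bloom_fp_rate,
        )
    survivors, kmer_subtracted = kmer_index.subtract_host_reads(
        survivors, host_index, min_host_kmers=cfg.min_host_kmers
    )
    m_kmer = FilterMetrics(
        "kmer_subtraction",
        reads_in=len(survivors) + len(kmer_subtracted),
        reads_out=len(survivors),
        reads_dropped=len(kmer_subtracted),
    )

    host_refs = {r.id: str(r.seq) for r in SeqIO.parse(host_fasta, "fasta")}
    if host_hits is None:
        host_aligner = alignment.MinimalAligner(host_refs, seed_length=cfg.seed_length)
        host_hits = host_aligner.align_records(survivors)
    nonhost, align_subtracted = alignment.subtract_by_alignment(
        survivors,
        host_hits,
        min_identity=cfg.host_min_identity,
        reference_names=set(host_refs),
    )
    m_align = FilterMetrics(
        "host_alignment_subtraction",
        reads_in=len(nonhost) + len(align_subtracted),
        reads_out=len(nonhost),
        reads_dropped=len(align_subtracted),
    )

    microbe_refs = {r.id: str(r.seq) for r in SeqIO.parse(microbe_fasta, "fasta")}
    tree = build_taxonomy(
        taxonomy_nodes,
        names_file=taxonomy_names,
        seq_map_file=seq_map,
        genome_lengths={n: len(s) for n, s in microbe_refs.items()},
    )
    if microbe_hits is None:
        microbe_aligner = alignment.MinimalAligner(
            microbe_refs, seed_length=cfg.seed_length
        )
        microbe_hits = microbe_aligner.align_records(nonhost)

    classifications = _classify_all(nonhost, microbe_hits, tree, cfg)
    n_classified_reads = sum(
        1 for r in nonhost if r.status == ReadStatus.CLASSIFIED
    )
    m_classify = FilterMetrics(
        "classification",
        reads_in=len(nonhost),
        reads_out=n_classified_reads,
        reads_dropped=len(nonhost) - n_classified_reads,
    )
    metrics.extend([m_kmer, m_align, m_classify])

    pair_level = {
        cls.read_id: cls for cls in classifications.values() if cls.is_classified
    }
    score_table = classify.accumulate_scores(pair_level.values(), tree)

    dispositions = check_conservation(records)
    total = sum(dispositions.values())
    if total != n_input:
        raise AssertionError(
            f"conservation violated: {total} terminal reads != {n_input} input"
        )

    result = PipelineResult(
        records=records,
        metrics=metrics,
        classifications=classifications,
        score_table=score_table,
        tree=tree,
        dispositions=dispositions,
    )
    if out_dir is not None:
        result.report_path = os.path.join(out_dir, "abundance_report.tsv")
        classify.write_abundance_report(
            score_table, tree, result.report_path, length_normalize=cfg.length_normalize
        )
        result.unclassified_path = os.path.join(out_dir, "unclassified.fastq")
        classify.emit_unclassified(nonhost, classifications, result.unclassified_path)
        result.metrics_path = os.path.join(out_dir, "metrics.tsv")
        write_metrics(metrics, result.metrics_path)
        write_fastq(nonhost, os.path.join(out_dir, "nonhost.fastq"))
    return result
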
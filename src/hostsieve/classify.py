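"""Taxonomic read classification and per-taxon abundance scoring.

A read (or pair) is classified from its microbial alignment hits:

1. hits below the identity cutoff (default 70%, user-settable) are
   discarded;
2. for a pair, only organisms (species-level ancestors) hit by BOTH mates
   survive — the paired-end consistency rule that raises specificity;
3. among surviving organisms, those tied at the best summed identity are
   kept; each receives weight 1/|tied|, and the read is assigned to the
   lowest common ancestor of the tied set;
4. a read with no surviving organism is UNCLASSIFIED.

Weights are exact rationals, so abundance conservation holds exactly: the
total weight at species level plus any weight at supra-species assignments
equals the number of classified reads/pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Optional, Sequence

from .alignment import compute_identity
from .core_io import AlignmentHit, ReadRecord, ReadStatus
from .taxonomy import TaxonomyTree, rank_sort_key

__all__ = [
    "UNCLASSIFIED",
    "ReadClassification",
    "TaxonScore",
    "TaxonScoreTable",
    "classify_read_or_pair",
    "accumulate_scores",
    "write_abundance_report",
    "emit_unclassified",
]

UNCLASSIFIED = -1


@dataclass
class ReadClassification:
    """Outcome of classifying one read or pair."""

    read_id: str
    assigned_taxon: int = UNCLASSIFIED
    candidate_taxa: frozenset[int] = frozenset()
    weight: Fraction = Fraction(0)
    identity_best: float = 0.0

    @property
    def is_classified(self) -> bool:
        return self.assigned_taxon != UNCLASSIFIED


def _organism_identities(
    hits: Sequence[AlignmentHit],
    read_length: int,
    tree: TaxonomyTree,
    min_identity: float,
) -> Dict[int, float]:
    """Best per-organism identity among hits passing the cutoff."""
    best: Dict[int, float] = {}
    for hit in hits:
        ident = compute_identity(hit, read_length)
        if ident < min_identity:
            continue
        organism = tree.organism_of(tree.taxon_of_sequence(hit.ref_name))
        if ident > best.get(organism, -1.0):
            best[organism] = ident
    return best


def classify_read_or_pair(
    hits_mate1: Sequence[AlignmentHit],
    read_length1: int,
    tree: TaxonomyTree,
    min_identity: float = 0.70,
    hits_mate2: Optional[Sequence[AlignmentHit]] = None,
    read_length2: Optional[int] = None,
    read_id: str = "",
) -> ReadClassification:
    """Classify one read, or one pair under the same-organism rule."""
    org1 = _organism_identities(hits_mate1, read_length1, tree, min_identity)
    if hits_mate2 is not None:
        if read_length2 is None:
            raise ValueError("read_length2 required when hits_mate2 is given")
        org2 = _organism_identities(hits_mate2, read_length2, tree, min_identity)
        shared = set(org1) & set(org2)
        summed = {o: org1[o] + org2[o] for o in shared}
    else:
        summed = dict(org1)
    if not summed:
        return ReadClassification(read_id=read_id)
    best_score = max(summed.values())
    # keep every organism tied at the best summed identity
    tied = frozenset(o for o, s in summed.items() if s == best_score)
    return ReadClassification(
        read_id=read_id,
        assigned_taxon=tree.lowest_common_ancestor(tied),
        candidate_taxa=tied,
        weight=Fraction(1, len(tied)),
        identity_best=max(org1.get(o, 0.0) for o in tied),
    )


@dataclass
class TaxonScore:
    score: Fraction = field(default_factory=lambda: Fraction(0))
    reads: int = 0
    unambiguous: int = 0


@dataclass
class TaxonScoreTable:
    """Per-taxon accumulated abundance; internal nodes hold subtree sums."""

    entries: Dict[int, TaxonScore] = field(default_factory=dict)
    n_classified: int = 0

    def entry(self, taxon: int) -> TaxonScore:
        if taxon not in self.entries:
            self.entries[taxon] = TaxonScore()
        return self.entries[taxon]

    def score_normalized(self, taxon: int) -> float:
        """Score as a percentage of total classified weight."""
        if self.n_classified == 0:
            return 0.0
        return float(self.entries[taxon].score / self.n_classified * 100)


def accumulate_scores(
    classifications: Iterable[ReadClassification], tree: TaxonomyTree
) -> TaxonScoreTable:
    """Distribute classification weights over the taxonomy.

    Each candidate taxon receives its 1/|candidates| weight, and weights
    propagate by summation to every ancestor. The ``reads`` counter of a
    node counts distinct reads/pairs contributing anywhere in its subtree;
    ``unambiguous`` counts those with a single candidate.
    """
    table = TaxonScoreTable()
    for cls in classifications:
        if not cls.is_classified:
            continue
        table.n_classified += 1
        touched: set[int] = set()
        for candidate in cls.candidate_taxa:
            w = cls.weight
            for node in tree.path_to_root(candidate):
                table.entry(node).score += w
                touched.add(node)
        for node in touched:
            e = table.entry(node)
            e.reads += 1
            if len(cls.candidate_taxa) == 1:
                e.unambiguous += 1
    return table


def _rolled_genome_length(
    tree: TaxonomyTree,
    taxon: int,
    kids: Dict[int, list[int]],
    cache: Dict[int, int],
) -> int:
    if taxon in cache:
        return cache[taxon]
    total = tree.genome_length.get(taxon, 0)
    for child in kids.get(taxon, []):
        total += _rolled_genome_length(tree, child, kids, cache)
    cache[taxon] = total
    return total


def write_abundance_report(
    table: TaxonScoreTable,
    tree: TaxonomyTree,
    path: str,
    length_normalize: bool = False,
) -> None:
    """Write the per-taxon abundance report as TSV.

    Rows are sorted by rank (root-first canonical order) then descending
    score then taxon id, which makes the byte output deterministic for a
    fixed table. ``length_normalize`` adds score per reference megabase.
    """
    header = [
        "taxon_id",
        "rank",
        "name",
        "path",
        "score",
        "score_normalized",
        "reads",
        "unambiguous",
        "genome_length",
    ]
    if length_normalize:
        header.append("score_per_mb")
    length_cache: Dict[int, int] = {}
    kids = tree.children()
    rows = []
    for taxon, entry in table.entries.items():
        rank = tree.rank.get(taxon, "no rank")
        path_names = [
            tree.name.get(t, str(t)) for t in reversed(tree.path_to_root(taxon))
        ]
        glen = _rolled_genome_length(tree, taxon, kids, length_cache)
        row = [
            taxon,
            rank,
            tree.name.get(taxon, ""),
            "|".join(path_names),
            float(entry.score),
            table.score_normalized(taxon),
            entry.reads,
            entry.unambiguous,
            glen,
        ]
        if length_normalize:
            row.append(float(entry.score) / glen * 1e6 if glen else 0.0)
        rows.append(row)
    rows.sort(key=lambda r: (rank_sort_key(r[1]), -r[4], r[0]))
    with open(path, "w") as out:
        out.write("\t".join(header) + "\n")
        for row in rows:
            out.write(
                "\t".join(
                    f"{v:.6f}" if isinstance(v, float) else str(v) for v in row
                )
                + "\n"
            )


def emit_unclassified(
    records: Sequence[ReadRecord],
    classifications: Dict[str, ReadClassification],
    path: str,
) -> int:
    """Write non-host unclassified reads as FASTQ, mates kept adjacent."""
    from .core_io import write_fastq

    out: List[ReadRecord] = []
    for rec in records:
        if rec.status == ReadStatus.UNCLASSIFIED:
            out.append(rec)
    return write_fastq(out, path)
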
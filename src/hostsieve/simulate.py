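"""Synthetic host/microbe communities with exhaustive ground truth.

Generates a random host genome, a set of microbial reference genomes with
no shared 31-mers (so k-mer subtraction truth is exact), an optional
"novel" organism absent from the reference (exercising the
unclassified-read discovery path), a taxonomy, and a paired-end read
library with planted artifacts (sequencing errors, adapter read-through,
low-complexity inserts, PCR duplicates). Every emitted read is labelled
exactly once in the ground-truth table.

Category read counts are exact-partitioned by largest-remainder rounding,
not sampled, so fixture assertions can be exact. All randomness flows from
one seeded ``numpy`` generator; outputs are byte-identical for a fixed
seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import ReadRecord, reverse_complement
from .kmer_index import canonical_kmers
from .taxonomy import TaxonomyTree

__all__ = [
    "ILLUMINA_ADAPTER",
    "CommunitySpec",
    "CommunityFixture",
    "generate_community",
    "generate_low_abundance_pathogen",
    "generate_discordant_fixture",
]

#: TruSeq-style adapter planted as 3' read-through contamination.
ILLUMINA_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class CommunitySpec:
    """Study conditions of one synthetic community."""

    host_length: int = 100_000
    n_microbe_species: int = 5
    microbe_lengths: Optional[Sequence[int]] = None  # default 20 kb each
    proportions: Optional[Sequence[float]] = None  # default (.4,.3,.15,.1,.05)
    host_fraction: float = 0.9
    read_length: int = 100
    n_reads: int = 10_000
    per_base_error_rate: float = 0.0
    duplicate_rate: float = 0.0
    adapter_contamination_rate: float = 0.0
    low_complexity_insert_rate: float = 0.0
    novel_organism_fraction: float = 0.0
    novel_length: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.microbe_lengths is None:
            self.microbe_lengths = [20_000] * self.n_microbe_species
        if self.proportions is None:
            if self.n_microbe_species == 5:
                self.proportions = (0.4, 0.3, 0.15, 0.1, 0.05)
            else:
                self.proportions = tuple(
                    [1.0 / self.n_microbe_species] * self.n_microbe_species
                )
        if len(self.microbe_lengths) != self.n_microbe_species:
            raise ValueError("one genome length per microbe species required")
        if len(self.proportions) != self.n_microbe_species:
            raise ValueError("one proportion per microbe species required")
        if abs(sum(self.proportions) - 1.0) > 1e-12:
            raise ValueError("microbe proportions must sum to 1 within 1e-12")
        for name in (
            "host_fraction",
            "per_base_error_rate",
            "duplicate_rate",
            "adapter_contamination_rate",
            "low_complexity_insert_rate",
            "novel_organism_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.host_fraction + self.novel_organism_fraction > 1.0 + 1e-12:
            raise ValueError("host + novel fractions exceed 1")
        if self.n_reads % 2:
            raise ValueError("n_reads must be even (reads are generated in pairs)")
        min_genome = min([self.host_length, self.novel_length, *self.microbe_lengths])
        if self.read_length > min_genome:
            raise ValueError("read_length exceeds the shortest genome")


@dataclass
class CommunityFixture:
    """On-disk and in-memory handles to one generated community."""

    spec: CommunitySpec
    out_dir: str
    host_fasta: str
    microbe_fasta: str
    seq_map: str
    taxonomy_nodes: str
    fastq_1: str
    fastq_2: str
    truth_path: str
    truth: pd.DataFrame
    genomes: Dict[str, str] = field(default_factory=dict)
    tree: Optional[TaxonomyTree] = None
    species_taxa: Dict[str, int] = field(default_factory=dict)


def _random_genome(rng: np.random.Generator, length: int) -> str:
    """Uniform random genome, resampled free of low-complexity stretches.

    Plain i.i.d. sequence contains occasional short homopolymers that the
    complexity filter would mask, so fixture reads would not be cleanly
    recoverable; maskable positions are resampled until none remain. Planted
    artifacts are the only low-complexity content of a fixture.
    """
    from . import dust

    arr = rng.integers(0, 4, size=length)
    for _ in range(50):
        genome = _BASES[arr].tobytes().decode("ascii")
        mask = dust.mask_intervals(genome)
        if not mask.any():
            return genome
        arr[mask] = rng.integers(0, 4, size=int(mask.sum()))
    raise RuntimeError("could not generate a complexity-clean genome")


def _disjoint_genome(
    rng: np.random.Generator, length: int, forbidden: set[int], k: int = 31
) -> str:
    """Random genome sharing no canonical k-mer with ``forbidden``."""
    for _ in range(20):
        genome = _random_genome(rng, length)
        kmers = set(canonical_kmers(genome, k).tolist())
        if not kmers & forbidden:
            forbidden |= kmers
            return genome
    raise RuntimeError("could not generate a k-mer-disjoint genome")


def largest_remainder(weights: Sequence[float], total: int) -> List[int]:
    """Integer partition of ``total`` proportional to ``weights`` (exact)."""
    raw = [w * total for w in weights]
    counts = [int(x) for x in raw]
    remainder = total - sum(counts)
    order = sorted(
        range(len(weights)), key=lambda i: (raw[i] - counts[i], -i), reverse=True
    )
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _default_taxonomy(n_species: int) -> tuple[TaxonomyTree, Dict[str, int]]:
    """Fixed small taxonomy: root > superkingdom > phylum > family > genus > species."""
    parent = {1: 1, 2: 1, 3: 2}
    rank = {1: "root", 2: "superkingdom", 3: "phylum"}
    name = {1: "root", 2: "Bacteria", 3: "Simulibacterota"}
    species_taxa: Dict[str, int] = {}
    for i in range(n_species):
        genus = 20 + i // 2
        family = 10 + (i // 2) // 2
        if family not in parent:
            parent[family] = 3
            rank[family] = "family"
            name[family] = f"Simulaceae_{family - 10}"
        if genus not in parent:
            parent[genus] = family
            rank[genus] = "genus"
            name[genus] = f"Simulomonas_{genus - 20}"
        sp = 100 + i
        parent[sp] = genus
        rank[sp] = "species"
        name[sp] = f"Simulomonas specii_{i}"
        species_taxa[f"species_{i}"] = sp
    tree = TaxonomyTree(parent=parent, rank=rank, name=name, root=1)
    tree.validate()
    return tree, species_taxa


def _apply_errors(
    rng: np.random.Generator, bases: str, rate: float
) -> tuple[str, List[int]]:
    if rate <= 0.0:
        return bases, []
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode("ascii"), [int(i) for i in hits]


def _draw_pair(
    rng: np.random.Generator, genome: str, read_length: int
) -> tuple[str, str, int, int]:
    """Fragment-based pair: mate1 forward prefix, mate2 RC of the suffix."""
    max_frag = min(2 * read_length + 60, len(genome))
    frag_len = int(rng.integers(read_length, max_frag + 1))
    start = int(rng.integers(0, len(genome) - frag_len + 1))
    frag = genome[start : start + frag_len]
    mate1 = frag[:read_length]
    mate2 = reverse_complement(frag[-read_length:])
    return mate1, mate2, start, start + frag_len - read_length


def generate_community(spec: CommunitySpec, out_dir: str) -> CommunityFixture:
    """Generate genomes, taxonomy, paired FASTQ and ground truth on disk."""
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.Generator(np.random.PCG64(spec.seed))

    forbidden: set[int] = set()
    host = _random_genome(rng, spec.host_length)
    forbidden |= set(canonical_kmers(host, 31).tolist())
    microbes = {
        f"species_{i}": _disjoint_genome(rng, spec.microbe_lengths[i], forbidden)
        for i in range(spec.n_microbe_species)
    }
    novel = _disjoint_genome(rng, spec.novel_length, forbidden)
    genomes = {"host_chr1": host, **microbes, "novel_org": novel}

    tree, species_taxa = _default_taxonomy(spec.n_microbe_species)

    n_pairs = spec.n_reads // 2
    n_dup = int(round(spec.duplicate_rate * n_pairs))
    n_fresh_total = n_pairs - n_dup
    microbe_weight = 1.0 - spec.host_fraction - spec.novel_organism_fraction
    weights = [spec.host_fraction, spec.novel_organism_fraction] + [
        microbe_weight * p for p in spec.proportions
    ]
    # composition is exact-partitioned over the distinct (non-duplicate)
    # pairs; duplicates inherit the origin of the pair they copy
    counts = largest_remainder(weights, n_fresh_total)
    origins: List[str] = (
        ["host"] * counts[0]
        + ["novel"] * counts[1]
        + [f"species_{i}" for i in range(spec.n_microbe_species) for _ in range(counts[2 + i])]
    )
    origins = [origins[i] for i in rng.permutation(len(origins))]

    n_adapter = int(round(spec.adapter_contamination_rate * n_pairs))
    n_lowc = int(round(spec.low_complexity_insert_rate * n_pairs))

    rows = []
    reads: List[tuple[str, str, str, str]] = []  # (id1, bases1, id2, bases2)
    pair_store: List[tuple[str, str, str]] = []  # (origin, bases1, bases2)
    n_fresh = n_pairs - n_dup
    for p in range(n_pairs):
        rid = f"r{p:07d}"
        if p < n_fresh:
            origin = origins[p]
            source = "host_chr1" if origin == "host" else (
                "novel_org" if origin == "novel" else origin
            )
            genome = genomes[source]
            m1, m2, pos1, pos2 = _draw_pair(rng, genome, spec.read_length)
            m1, err1 = _apply_errors(rng, m1, spec.per_base_error_rate)
            m2, err2 = _apply_errors(rng, m2, spec.per_base_error_rate)
            has_adapter = p < n_adapter
            has_lowc = n_adapter <= p < n_adapter + n_lowc
            if has_adapter:
                keep = spec.read_length - len(ILLUMINA_ADAPTER)
                m1 = m1[:keep] + ILLUMINA_ADAPTER
            if has_lowc:
                span = min(40, spec.read_length // 2)
                mid = (spec.read_length - span) // 2
                m1 = m1[:mid] + ("AT" * span)[:span] + m1[mid + span :]
            dup_of = ""
            pair_store.append((origin, m1, m2))
        else:
            src = int(rng.integers(0, n_fresh))
            origin, m1, m2 = pair_store[src]
            pos1 = pos2 = -1
            err1 = err2 = []
            has_adapter = has_lowc = False
            dup_of = f"r{src:07d}"
            source = "host_chr1" if origin == "host" else (
                "novel_org" if origin == "novel" else origin
            )
        reads.append((f"{rid}/1", m1, f"{rid}/2", m2))
        for mate, bases, pos, errs in ((1, m1, pos1, err1), (2, m2, pos2, err2)):
            rows.append(
                {
                    "read_id": f"{rid}/{mate}",
                    "mate": mate,
                    "origin": origin,
                    "ref_name": source,
                    "pos": pos,
                    "n_errors": len(errs),
                    "error_positions": ";".join(map(str, errs)),
                    "has_adapter": has_adapter and mate == 1,
                    "has_low_complexity": has_lowc and mate == 1,
                    "duplicate_of": dup_of,
                }
            )

    truth = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "mate",
            "origin",
            "ref_name",
            "pos",
            "n_errors",
            "error_positions",
            "has_adapter",
            "has_low_complexity",
            "duplicate_of",
        ],
    )

    paths = _write_fixture_files(out_dir, spec, host, microbes, species_taxa, tree, reads, truth)
    return CommunityFixture(
        spec=spec,
        out_dir=out_dir,
        genomes=genomes,
        tree=tree,
        species_taxa=species_taxa,
        truth=truth,
        **paths,
    )


def _write_fixture_files(
    out_dir: str,
    spec: CommunitySpec,
    host: str,
    microbes: Dict[str, str],
    species_taxa: Dict[str, int],
    tree: TaxonomyTree,
    reads: Sequence[tuple[str, str, str, str]],
    truth: pd.DataFrame,
) -> Dict[str, str]:
    def _p(name: str) -> str:
        return os.path.join(out_dir, name)

    with open(_p("host.fasta"), "w") as out:
        out.write(">host_chr1\n")
        for i in range(0, len(host), 80):
            out.write(host[i : i + 80] + "\n")
    with open(_p("microbes.fasta"), "w") as out:
        for name, seq in microbes.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                out.write(seq[i : i + 80] + "\n")
    with open(_p("seq_map.tsv"), "w") as out:
        for name, taxon in species_taxa.items():
            out.write(f"{name}\t{taxon}\n")
    with open(_p("taxonomy.tsv"), "w") as out:
        for taxon in sorted(tree.parent):
            rank = tree.rank.get(taxon, "no rank")
            name = tree.name.get(taxon, "")
            out.write(f"{taxon}\t{tree.parent[taxon]}\t{rank}|{name}\n")
    qual = "I" * spec.read_length
    with open(_p("reads_1.fastq"), "w") as o1, open(_p("reads_2.fastq"), "w") as o2:
        for id1, m1, id2, m2 in reads:
            o1.write(f"@{id1}\n{m1}\n+\n{'I' * len(m1)}\n")
            o2.write(f"@{id2}\n{m2}\n+\n{'I' * len(m2)}\n")
    truth.to_csv(_p("truth.tsv"), sep="\t", index=False)
    return {
        "host_fasta": _p("host.fasta"),
        "microbe_fasta": _p("microbes.fasta"),
        "seq_map": _p("seq_map.tsv"),
        "taxonomy_nodes": _p("taxonomy.tsv"),
        "fastq_1": _p("reads_1.fastq"),
        "fastq_2": _p("reads_2.fastq"),
        "truth_path": _p("truth.tsv"),
    }


def generate_low_abundance_pathogen(
    out_dir: str,
    n_reads: int = 100_000,
    abundance: float = 1e-4,
    per_base_error_rate: float = 0.005,
    host_fraction: float = 0.9,
    seed: int = 0,
) -> CommunityFixture:
    """Community with one pathogen species planted at trace abundance.

    ``species_0`` is the pathogen, present at ``abundance`` of all reads;
    the remaining microbial reads are split evenly over four background
    species. Mirrors the trace-organism detection scenario: the pipeline
    should still classify the planted reads at the default identity cutoff.
    """
    if n_reads * abundance < 2 and abundance > 0:
        raise ValueError("too few reads to plant the pathogen at this abundance")
    microbe_fraction = 1.0 - host_fraction
    pathogen_prop = abundance / microbe_fraction
    rest = (1.0 - pathogen_prop) / 4.0
    spec = CommunitySpec(
        n_microbe_species=5,
        proportions=(pathogen_prop, rest, rest, rest, rest),
        host_fraction=host_fraction,
        n_reads=n_reads,
        per_base_error_rate=per_base_error_rate,
        seed=seed,
    )
    return generate_community(spec, out_dir)


def generate_discordant_fixture(
    out_dir: str,
    n_pairs: int = 200,
    discordant_fraction: float = 0.5,
    read_length: int = 100,
    seed: int = 0,
) -> CommunityFixture:
    """Microbe-only fixture with deliberately discordant mate placements.

    Concordant pairs draw both mates from one fragment of one species;
    discordant pairs draw mate 1 from ``species_0`` and mate 2 from
    ``species_1``, so the paired-end same-organism rule must leave them
    unclassified. The truth table carries a ``concordant`` column.
    """
    spec = CommunitySpec(
        n_microbe_species=2,
        proportions=(0.5, 0.5),
        host_fraction=0.0,
        n_reads=2 * n_pairs,
        seed=seed,
    )
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.Generator(np.random.PCG64(seed))
    forbidden: set[int] = set()
    host = _random_genome(rng, 1000)  # placeholder host, unused by reads
    forbidden |= set(canonical_kmers(host, 31).tolist())
    microbes = {
        "species_0": _disjoint_genome(rng, 20_000, forbidden),
        "species_1": _disjoint_genome(rng, 20_000, forbidden),
    }
    tree, species_taxa = _default_taxonomy(2)
    n_disc = int(round(discordant_fraction * n_pairs))
    reads = []
    rows = []
    for p in range(n_pairs):
        rid = f"r{p:07d}"
        discordant = p < n_disc
        if discordant:
            m1, _, pos1, _ = _draw_pair(rng, microbes["species_0"], read_length)
            _, m2, _, pos2 = _draw_pair(rng, microbes["species_1"], read_length)
            origin = "discordant"
        else:
            m1, m2, pos1, pos2 = _draw_pair(rng, microbes["species_0"], read_length)
            origin = "species_0"
        reads.append((f"{rid}/1", m1, f"{rid}/2", m2))
        for mate, bases, pos in ((1, m1, pos1), (2, m2, pos2)):
            rows.append(
                {
                    "read_id": f"{rid}/{mate}",
                    "mate": mate,
                    "origin": origin,
                    "ref_name": "species_0" if (mate == 1 or not discordant) else "species_1",
                    "pos": pos,
                    "n_errors": 0,
                    "error_positions": "",
                    "has_adapter": False,
                    "has_low_complexity": False,
                    "duplicate_of": "",
                    "concordant": not discordant,
                }
            )
    truth = pd.DataFrame(rows)
    paths = _write_fixture_files(out_dir, spec, host, microbes, species_taxa, tree, reads, truth)
    return CommunityFixture(
        spec=spec,
        out_dir=out_dir,
        genomes={"host_chr1": host, **microbes},
        tree=tree,
        species_taxa=species_taxa,
        truth=truth,
        **paths,
    )
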
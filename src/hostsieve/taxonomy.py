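"""Taxonomic tree, sequence-to-taxon mapping, and ancestor queries.

Accepts either the NCBI-dump dialect (pipe-delimited ``nodes.dmp`` /
``names.dmp``) or a simplified 3-column TSV (taxon_id, parent_id,
"rank|name"). The tree is validated on construction: exactly one root,
no cycles, every node reachable from the root by parent traversal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Set

__all__ = ["TaxonomyTree", "build_taxonomy", "RANK_ORDER"]

#: Canonical rank ordering, root-first, used for report sorting.
RANK_ORDER = [
    "root",
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "strain",
    "no rank",
]
_RANK_INDEX = {r: i for i, r in enumerate(RANK_ORDER)}


@dataclass
class TaxonomyTree:
    """Rooted taxonomy with ranks, names and reference-sequence mapping."""

    parent: Dict[int, int]
    rank: Dict[int, str]
    name: Dict[int, str]
    root: int
    seq_to_taxon: Dict[str, int] = field(default_factory=dict)
    genome_length: Dict[int, int] = field(default_factory=dict)
    _path_cache: Dict[int, tuple[int, ...]] = field(default_factory=dict, repr=False)

    def __contains__(self, taxon_id: int) -> bool:
        return taxon_id in self.parent

    def path_to_root(self, taxon_id: int) -> tuple[int, ...]:
        """Ancestors from the taxon up to (and including) the root."""
        cached = self._path_cache.get(taxon_id)
        if cached is not None:
            return cached
        if taxon_id not in self.parent:
            raise KeyError(f"unknown taxon {taxon_id}")
        path = [taxon_id]
        node = taxon_id
        while node != self.root:
            node = self.parent[node]
            path.append(node)
        result = tuple(path)
        self._path_cache[taxon_id] = result
        return result

    def depth(self, taxon_id: int) -> int:
        return len(self.path_to_root(taxon_id)) - 1

    def lowest_common_ancestor(self, taxa: Iterable[int]) -> int:
        """Deepest node ancestral to (or equal to) every input taxon."""
        taxa = list(taxa)
        if not taxa:
            raise ValueError("LCA of an empty taxon set is undefined")
        common: Optional[Set[int]] = None
        for t in taxa:
            path = set(self.path_to_root(t))
            common = path if common is None else common & path
        assert common  # root is always shared
        return max(common, key=self.depth)

    def ancestor_at_rank(self, taxon_id: int, rank: str) -> Optional[int]:
        for node in self.path_to_root(taxon_id):
            if self.rank.get(node) == rank:
                return node
        return None

    def organism_of(self, taxon_id: int) -> int:
        """Species-level ancestor, or the taxon itself if none exists.

        This is the granularity of the paired-end "same organism" rule:
        strain-level hits agree when they share a species.
        """
        species = self.ancestor_at_rank(taxon_id, "species")
        return species if species is not None else taxon_id

    def taxon_of_sequence(self, seq_name: str) -> int:
        try:
            return self.seq_to_taxon[seq_name]
        except KeyError:
            raise KeyError(f"reference sequence {seq_name!r} is not mapped to a taxon")

    def children(self) -> Dict[int, list[int]]:
        kids: Dict[int, list[int]] = {t: [] for t in self.parent}
        for t, p in self.parent.items():
            if t != self.root:
                kids[p].append(t)
        return kids

    def validate(self) -> None:
        roots = [t for t, p in self.parent.items() if t == p]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {roots}")
        # cycle check via iterative traversal with visited marking
        state: Dict[int, int] = {}  # 0 in-progress, 1 done
        for start in self.parent:
            chain = []
            node = start
            while state.get(node) is None and node != self.root:
                if node in chain:
                    cycle = chain[chain.index(node) :] + [node]
                    raise ValueError(f"cycle detected in taxonomy: {cycle}")
                chain.append(node)
                node = self.parent[node]
            for n in chain:
                state[n] = 1
        for seq, taxon in self.seq_to_taxon.items():
            if taxon not in self.parent:
                raise ValueError(f"sequence {seq!r} maps to unknown taxon {taxon}")
        for taxon, length in self.genome_length.items():
            if length <= 0:
                raise ValueError(f"taxon {taxon} has non-positive genome length")

    # -- serialization ------------------------------------------------------

    def save(self, path: str) -> None:
        data = {
            "root": self.root,
            "nodes": {
                str(t): [self.parent[t], self.rank.get(t, "no rank"), self.name.get(t, "")]
                for t in self.parent
            },
            "seq_to_taxon": self.seq_to_taxon,
            "genome_length": {str(t): n for t, n in self.genome_length.items()},
        }
        with open(path, "w") as out:
            json.dump(data, out)

    @classmethod
    def load(cls, path: str) -> "TaxonomyTree":
        with open(path) as fh:
            data = json.load(fh)
        parent = {int(t): v[0] for t, v in data["nodes"].items()}
        tree = cls(
            parent=parent,
            rank={int(t): v[1] for t, v in data["nodes"].items()},
            name={int(t): v[2] for t, v in data["nodes"].items()},
            root=data["root"],
            seq_to_taxon=dict(data["seq_to_taxon"]),
            genome_length={int(t): n for t, n in data["genome_length"].items()},
        )
        tree.validate()
        return tree


def _parse_ncbi_dmp_line(line: str) -> list[str]:
    return [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]


def _read_nodes(nodes_file: str) -> tuple[Dict[int, int], Dict[int, str]]:
    parent: Dict[int, int] = {}
    rank: Dict[int, str] = {}
    with open(nodes_file) as fh:
        first = fh.readline()
        fh.seek(0)
        if "\t|\t" in first or first.rstrip("\n").endswith("|"):
            for line in fh:
                fields = _parse_ncbi_dmp_line(line)
                taxon, par, rk = int(fields[0]), int(fields[1]), fields[2]
                parent[taxon] = par
                rank[taxon] = rk
        else:  # simplified TSV: taxon_id, parent_id, rank|name
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                taxon_s, par_s, rank_name = line.split("\t")
                rk = rank_name.split("|")[0]
                parent[int(taxon_s)] = int(par_s)
                rank[int(taxon_s)] = rk
    return parent, rank


def _read_names(names_file: Optional[str], parent: Dict[int, int]) -> Dict[int, str]:
    names: Dict[int, str] = {}
    if names_file is None:
        return names
    with open(names_file) as fh:
        first = fh.readline()
        fh.seek(0)
        if "\t|\t" in first or first.rstrip("\n").endswith("|"):
            for line in fh:
                fields = _parse_ncbi_dmp_line(line)
                taxon = int(fields[0])
                if len(fields) >= 4 and fields[3] != "scientific name":
                    continue
                names[taxon] = fields[1]
        else:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                taxon_s, name = line.split("\t")[:2]
                names[int(taxon_s)] = name
    return names


def build_taxonomy(
    nodes_file: str,
    names_file: Optional[str] = None,
    seq_map_file: Optional[str] = None,
    genome_lengths: Optional[Dict[str, int]] = None,
) -> TaxonomyTree:
    """Build and validate a ``TaxonomyTree`` from on-disk tables.

    ``nodes_file`` may be NCBI ``nodes.dmp`` or the simplified TSV whose
    third column is ``rank|name`` (in which case names come from there and
    ``names_file`` may be omitted). ``seq_map_file`` is a 2-column TSV
    (sequence_name, taxon_id); orphan sequence names are warned about and
    excluded. ``genome_lengths`` maps sequence names to base counts and is
    accumulated per taxon.
    """
    parent, rank = _read_nodes(nodes_file)
    names = _read_names(names_file, parent)
    if names_file is None:
        # simplified dialect carries the name inline after the pipe
        with open(nodes_file) as fh:
            first = fh.readline()
            fh.seek(0)
            if "\t|\t" not in first:
                for line in fh:
                    line = line.rstrip("\n")
                    if not line or line.startswith("#"):
                        continue
                    taxon_s, _, rank_name = line.split("\t")
                    if "|" in rank_name:
                        names[int(taxon_s)] = rank_name.split("|", 1)[1]
    roots = [t for t, p in parent.items() if t == p]
    if len(roots) != 1:
        raise ValueError(f"taxonomy must have exactly one root, found {roots}")
    seq_to_taxon: Dict[str, int] = {}
    if seq_map_file is not None:
        with open(seq_map_file) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                seq_name, taxon_s = line.split("\t")[:2]
                taxon = int(taxon_s)
                if taxon not in parent:
                    warnings.warn(
                        f"sequence {seq_name!r} maps to unknown taxon {taxon}; excluded"
                    )
                    continue
                seq_to_taxon[seq_name] = taxon
    genome_length: Dict[int, int] = {}
    if genome_lengths:
        for seq_name, length in genome_lengths.items():
            taxon = seq_to_taxon.get(seq_name)
            if taxon is not None:
                genome_length[taxon] = genome_length.get(taxon, 0) + int(length)
    tree = TaxonomyTree(
        parent=parent,
        rank=rank,
        name=names,
        root=roots[0],
        seq_to_taxon=seq_to_taxon,
        genome_length=genome_length,
    )
    tree.validate()
    return tree


def rank_sort_key(rank: str) -> int:
    return _RANK_INDEX.get(rank, len(RANK_ORDER))
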
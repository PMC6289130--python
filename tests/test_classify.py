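"""Classification rules, abundance accumulation and report output."""

from fractions import Fraction

import pytest

from hostsieve import classify
from hostsieve.classify import (
    UNCLASSIFIED,
    accumulate_scores,
    classify_read_or_pair,
    write_abundance_report,
)
from hostsieve.core_io import AlignmentHit
from hostsieve.taxonomy import TaxonomyTree


@pytest.fixture()
def tree():
    # root > superkingdom > two genera > four species; sequences seqA..seqD
    parent = {1: 1, 2: 1, 20: 2, 21: 2, 100: 20, 101: 20, 102: 21, 103: 21}
    rank = {
        1: "root", 2: "superkingdom", 20: "genus", 21: "genus",
        100: "species", 101: "species", 102: "species", 103: "species",
    }
    name = {t: f"t{t}" for t in parent}
    t = TaxonomyTree(
        parent=parent,
        rank=rank,
        name=name,
        root=1,
        seq_to_taxon={"seqA": 100, "seqB": 101, "seqC": 102, "seqD": 103},
        genome_length={100: 1000, 101: 1000, 102: 2000, 103: 500},
    )
    t.validate()
    return t


def hit(ref, nm, length=100, read_id="r"):
    return AlignmentHit(read_id, ref, 0, f"{length}M", nm)


class TestClassifyReadOrPair:
    def test_single_end_single_hit(self, tree):
        cls = classify_read_or_pair([hit("seqA", 5)], 100, tree, min_identity=0.7)
        assert cls.assigned_taxon == 100
        assert cls.candidate_taxa == frozenset({100})
        assert cls.weight == Fraction(1)
        assert cls.identity_best == pytest.approx(0.95)

    def test_hits_below_cutoff_discarded(self, tree):
        cls = classify_read_or_pair([hit("seqA", 40)], 100, tree, min_identity=0.7)
        assert cls.assigned_taxon == UNCLASSIFIED

    def test_discordant_pair_unclassified(self, tree):
        cls = classify_read_or_pair(
            [hit("seqA", 0)], 100, tree,
            hits_mate2=[hit("seqB", 0)], read_length2=100,
        )
        assert cls.assigned_taxon == UNCLASSIFIED

    def test_concordant_pair_classified(self, tree):
        cls = classify_read_or_pair(
            [hit("seqA", 0), hit("seqB", 20)], 100, tree,
            hits_mate2=[hit("seqA", 1)], read_length2=100,
        )
        assert cls.assigned_taxon == 100
        assert cls.weight == Fraction(1)

    def test_tied_organisms_split_weight_and_assign_lca(self, tree):
        cls = classify_read_or_pair(
            [hit("seqA", 10), hit("seqB", 10)], 100, tree,
            hits_mate2=[hit("seqA", 10), hit("seqB", 10)], read_length2=100,
        )
        assert cls.candidate_taxa == frozenset({100, 101})
        assert cls.weight == Fraction(1, 2)
        assert cls.assigned_taxon == 20  # LCA = shared genus

    def test_best_summed_identity_wins(self, tree):
        # seqA sums 1.9, seqC sums 1.8 -> only A kept
        cls = classify_read_or_pair(
            [hit("seqA", 0), hit("seqC", 10)], 100, tree,
            hits_mate2=[hit("seqA", 10), hit("seqC", 10)], read_length2=100,
        )
        assert cls.candidate_taxa == frozenset({100})

    def test_pair_rule_strictly_refines_single_end(self, tree):
        """Pairs classified under the same-organism rule are a subset of
        reads classified when each mate is judged independently."""
        m1 = [hit("seqA", 0)]
        m2 = [hit("seqB", 0)]
        pair = classify_read_or_pair([*m1], 100, tree, hits_mate2=[*m2], read_length2=100)
        single1 = classify_read_or_pair([*m1], 100, tree)
        single2 = classify_read_or_pair([*m2], 100, tree)
        assert single1.is_classified and single2.is_classified
        assert not pair.is_classified  # refinement removed the discordant pair

    def test_cutoff_monotonicity(self, tree):
        hits1 = [hit("seqA", 25)]  # identity 0.75
        hits2 = [hit("seqA", 15)]  # identity 0.85
        counts = []
        for cutoff in (0.6, 0.7, 0.8, 0.9):
            n = sum(
                classify_read_or_pair(h, 100, tree, min_identity=cutoff).is_classified
                for h in (hits1, hits2)
            )
            counts.append(n)
        assert counts == sorted(counts, reverse=True)


class TestAccumulateScores:
    def test_single_read_scores_whole_path(self, tree):
        cls = classify_read_or_pair([hit("seqA", 0)], 100, tree)
        table = accumulate_scores([cls], tree)
        for node in (100, 20, 2, 1):
            assert table.entries[node].score == Fraction(1)
            assert table.entries[node].unambiguous == 1
        assert 101 not in table.entries

    def test_empty_input_gives_empty_table(self, tree):
        table = accumulate_scores([], tree)
        assert table.entries == {} and table.n_classified == 0

    def test_tie_weights_conserved_exactly(self, tree):
        classifications = [
            classify_read_or_pair([hit("seqA", 10), hit("seqB", 10)], 100, tree),
            classify_read_or_pair([hit("seqC", 0)], 100, tree),
            classify_read_or_pair([hit("seqD", 40)], 100, tree),  # unclassified
        ]
        table = accumulate_scores(classifications, tree)
        species_total = sum(
            table.entries[t].score for t in (100, 101, 102, 103) if t in table.entries
        )
        assert species_total == table.n_classified == 2
        assert table.entries[1].score == Fraction(2)
        assert table.entries[20].reads == 1
        assert table.entries[20].unambiguous == 0

    def test_internal_node_score_is_sum_of_children(self, tree):
        classifications = [
            classify_read_or_pair([hit("seqA", 0)], 100, tree),
            classify_read_or_pair([hit("seqB", 0)], 100, tree),
            classify_read_or_pair([hit("seqC", 0)], 100, tree),
        ]
        table = accumulate_scores(classifications, tree)
        assert (
            table.entries[20].score
            == table.entries[100].score + table.entries[101].score
        )
        assert table.entries[2].score == table.entries[20].score + table.entries[21].score


class TestReport:
    def test_empty_table_is_header_only(self, tree, tmp_path):
        p = tmp_path / "report.tsv"
        write_abundance_report(accumulate_scores([], tree), tree, str(p))
        lines = p.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("taxon_id\t")

    def test_single_species_rows(self, tree, tmp_path):
        cls = classify_read_or_pair([hit("seqA", 0)], 100, tree)
        p = tmp_path / "report.tsv"
        write_abundance_report(accumulate_scores([cls], tree), tree, str(p))
        lines = p.read_text().splitlines()
        assert len(lines) == 1 + 4  # root, superkingdom, genus, species
        ranks = [l.split("\t")[1] for l in lines[1:]]
        assert ranks == ["root", "superkingdom", "genus", "species"]

    def test_normalized_scores_sum_to_100_per_rank(self, tree, tmp_path):
        classifications = [
            classify_read_or_pair([hit("seqA", 0)], 100, tree),
            classify_read_or_pair([hit("seqC", 0)], 100, tree),
            classify_read_or_pair([hit("seqC", 1)], 100, tree),
        ]
        table = accumulate_scores(classifications, tree)
        by_rank = {}
        for taxon in table.entries:
            by_rank.setdefault(tree.rank[taxon], []).append(
                table.score_normalized(taxon)
            )
        for rank, vals in by_rank.items():
            assert sum(vals) <= 100.0 + 1e-9
            if rank in ("species", "genus", "superkingdom", "root"):
                assert sum(vals) == pytest.approx(100.0)

    def test_deterministic_bytes(self, tree, tmp_path):
        classifications = [
            classify_read_or_pair([hit("seqA", 10), hit("seqB", 10)], 100, tree),
            classify_read_or_pair([hit("seqD", 2)], 100, tree),
        ]
        table = accumulate_scores(classifications, tree)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_abundance_report(table, tree, str(p1))
        write_abundance_report(table, tree, str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_genome_length_rolls_up(self, tree, tmp_path):
        cls = classify_read_or_pair([hit("seqA", 0)], 100, tree)
        p = tmp_path / "report.tsv"
        write_abundance_report(accumulate_scores([cls], tree), tree, str(p))
        rows = {l.split("\t")[0]: l.split("\t") for l in p.read_text().splitlines()[1:]}
        assert rows["100"][8] == "1000"
        assert rows["20"][8] == "2000"  # genus 20 spans species 100+101
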
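"""Filter chain: quality/adapter trimming, masking, drops, duplicates."""

import pytest
from hypothesis import given, settings, strategies as st

from hostsieve import core_io, filters
from hostsieve.core_io import ReadRecord, ReadStatus
from hostsieve.filters import FilterConfig
from hostsieve.simulate import ILLUMINA_ADAPTER


def make_read(bases, quals=None, read_id="r1", **kw):
    quals = quals if quals is not None else [40] * len(bases)
    return ReadRecord(read_id, bases, list(quals), **kw)


class TestQualityTrim:
    def test_high_quality_read_unchanged(self):
        rec = make_read("ACGTACGT")
        assert filters.trim_low_quality(rec, FilterConfig()) == 0
        assert rec.bases == "ACGTACGT"
        assert rec.status is ReadStatus.RAW

    def test_uniformly_bad_read_fully_trimmed(self):
        rec = make_read("ACGTAC", quals=[2] * 6)
        trimmed = filters.trim_low_quality(rec, FilterConfig(min_base_quality=15))
        assert trimmed == 6
        assert rec.bases == ""

    def test_windowed_tail_trim(self):
        # windows ending in the low tail fail the mean test until only the
        # three Q40 bases remain
        rec = make_read("ACGTAC", quals=[40, 40, 40, 2, 2, 2])
        cfg = FilterConfig(min_base_quality=15, quality_window=3)
        assert filters.trim_low_quality(rec, cfg) == 3
        assert rec.bases == "ACG"
        assert rec.quals == [40, 40, 40]

    def test_five_prime_trim(self):
        rec = make_read("ACGTAC", quals=[2, 2, 40, 40, 40, 40])
        assert filters.trim_low_quality(rec, FilterConfig()) == 2
        assert rec.bases == "GTAC"

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.integers(0, 41), min_size=0, max_size=50))
    def test_never_lengthens_and_keeps_bases_aligned(self, quals):
        rec = make_read("A" * len(quals), quals=quals)
        filters.trim_low_quality(rec, FilterConfig())
        assert len(rec.bases) == len(rec.quals) <= len(quals)


class TestAdapterTrim:
    ADAPTER = "AGATCGGAAGAGC"

    def cfg(self, min_overlap=3):
        return FilterConfig(
            adapter_sequences=[self.ADAPTER], min_adapter_overlap=min_overlap
        )

    def test_no_adapter_unchanged(self):
        rec = make_read("ACGTACGTACGT")
        assert filters.trim_adapters(rec, self.cfg()) == 0
        assert rec.bases == "ACGTACGTACGT"

    def test_full_adapter_suffix_removed(self):
        insert = "TTGACCAGTCAGT"
        rec = make_read(insert + self.ADAPTER)
        filters.trim_adapters(rec, self.cfg())
        assert rec.bases == insert

    def test_partial_overlap_matches_brute_force(self):
        # brute-force oracle: longest suffix of the read equal to a prefix
        # of the adapter with >= min_overlap bases
        read = "CCGTGACTTAGATC"  # ends in first 5 adapter bases
        expected = max(
            (
                L
                for L in range(3, min(len(read), len(self.ADAPTER)) + 1)
                if read.endswith(self.ADAPTER[:L])
            ),
            default=0,
        )
        assert expected == 5
        rec = make_read(read)
        assert filters.trim_adapters(rec, self.cfg(min_overlap=3)) == expected
        assert rec.bases == read[:-5]

    def test_short_overlap_below_minimum_kept(self):
        rec = make_read("CCGTGACTTCCAG" + "AGA")
        assert filters.trim_adapters(rec, self.cfg(min_overlap=6)) == 0


class TestAmbiguityLengthFilter:
    def test_long_clean_read_passes(self):
        rec = make_read("ACGT" * 25)
        assert filters.filter_ambiguous_and_short(rec, FilterConfig())

    def test_fully_masked_read_dropped_as_complexity(self):
        rec = make_read("N" * 50)
        assert not filters.filter_ambiguous_and_short(rec, FilterConfig())
        assert rec.status is ReadStatus.FILTERED_COMPLEXITY

    def test_ambiguous_fraction_boundary(self):
        rec = make_read("N" * 30 + "ACGTA" * 4)
        cfg = FilterConfig(max_ambiguous_fraction=0.5)
        assert not filters.filter_ambiguous_and_short(rec, cfg)  # 0.6 > 0.5

    def test_short_read_dropped_as_quality(self):
        rec = make_read("ACGTACGT")
        assert not filters.filter_ambiguous_and_short(rec, FilterConfig())
        assert rec.status is ReadStatus.FILTERED_QUALITY


class TestRemoveDuplicates:
    def test_identical_reads_keep_first(self):
        a, b = make_read("ACGT" * 10, read_id="a"), make_read("ACGT" * 10, read_id="b")
        out = filters.remove_duplicates([a, b])
        assert [r.read_id for r in out] == ["a"]
        assert b.status is ReadStatus.FILTERED_DUPLICATE

    def test_distinct_stream_unchanged(self):
        recs = [make_read("ACGT" * i, read_id=f"r{i}") for i in range(8, 12)]
        assert filters.remove_duplicates(list(recs)) == recs

    def test_pairs_keyed_jointly(self):
        p1a = make_read("AAAA", read_id="p1/1", mate_of="p1/2")
        p1b = make_read("CCCC", read_id="p1/2", mate_of="p1/1", is_first_of_pair=False)
        p2a = make_read("AAAA", read_id="p2/1", mate_of="p2/2")
        p2b = make_read("GGGG", read_id="p2/2", mate_of="p2/1", is_first_of_pair=False)
        out = filters.remove_duplicates([p1a, p1b, p2a, p2b])
        # mate-2 differs, so the pairs are not duplicates
        assert len(out) == 4

    def test_planted_duplicate_rate_recovered_exactly(self, artifact_community):
        """Survivor count equals the generator's distinct-pair count."""
        fx = artifact_community
        records = list(core_io.read_fastq(fx.fastq_1, fx.fastq_2))
        out = filters.remove_duplicates(records)
        truth = fx.truth
        n_dup_pairs = (truth.loc[truth.mate == 1, "duplicate_of"] != "").sum()
        expected = len(records) - 2 * n_dup_pairs
        assert len(out) == expected


class TestFilterChain:
    def test_empty_input(self):
        out, metrics = filters.run_filter_chain([])
        assert out == []
        for m in metrics:
            assert (m.reads_in, m.reads_out, m.reads_dropped) == (0, 0, 0)

    def test_clean_reads_all_survive(self, clean_community):
        fx = clean_community
        records = list(core_io.read_fastq(fx.fastq_1, fx.fastq_2))
        out, _ = filters.run_filter_chain(records)
        assert len(out) == len(records)

    def test_planted_artifact_counts_match_truth(self, artifact_community):
        fx = artifact_community
        records = list(core_io.read_fastq(fx.fastq_1, fx.fastq_2))
        cfg = FilterConfig(adapter_sequences=[ILLUMINA_ADAPTER])
        out, metrics = filters.run_filter_chain(records, cfg)
        by_stage = {m.stage_name: m for m in metrics}
        truth = fx.truth
        # adapter trimming removes at least the planted read-through bases
        # (chance suffix overlaps can add a few more)
        n_adapter = int(truth.has_adapter.sum())
        assert by_stage["adapter_trim"].bases_trimmed >= n_adapter * len(ILLUMINA_ADAPTER)
        # every planted low-complexity read is dropped by the ambiguity rule
        lowc_ids = set(truth.loc[truth.has_low_complexity, "read_id"])
        dropped = {
            r.read_id for r in records if r.status is ReadStatus.FILTERED_COMPLEXITY
        }
        assert lowc_ids <= dropped
        # conservation across the chain
        assert len(out) + sum(m.reads_dropped for m in metrics) == len(records)

    def test_widowed_mates_demoted_to_single_end(self):
        lowc = make_read("AT" * 30, read_id="p/1", mate_of="p/2")
        ok = make_read("AACAGATACTTGCCTGAGTGCGTGGATCGAACAGT", read_id="p/2",
                       mate_of="p/1", is_first_of_pair=False)
        out, _ = filters.run_filter_chain([lowc, ok], FilterConfig(min_read_length=20))
        assert [r.read_id for r in out] == ["p/2"]
        assert out[0].mate_of is None

    def test_chain_conserves_and_never_grows(self, artifact_community):
        fx = artifact_community
        records = list(core_io.read_fastq(fx.fastq_1, fx.fastq_2))
        out, metrics = filters.run_filter_chain(records)
        assert len(out) <= len(records)
        for m in metrics:
            m.validate()
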
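# Methods

This note documents the models and procedures implemented in `hostsieve`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that make runs exact
and reproducible.

## Pipeline model

A read enters as `RAW` and ends in exactly one terminal disposition:
dropped by a filter (`FILTERED_QUALITY`, `FILTERED_COMPLEXITY`,
`FILTERED_DUPLICATE`), removed as host (`SUBTRACTED_KMER`,
`SUBTRACTED_ALIGNMENT`), or resolved against the microbial reference
(`CLASSIFIED`, `UNCLASSIFIED`). Status transitions are monotone in stage
order and conservation (`input = Σ terminal buckets`) is asserted, not
assumed, on every run. Stage order: quality trim → adapter trim → DUST
mask → ambiguity/length filter → duplicate removal → k-mer host
subtraction → alignment host subtraction → microbial classification.
Duplicate marking runs after trimming so that reads differing only in
trimmed artifact bases collapse to the same key.

## Read filtering

**Quality trimming.** Ends are trimmed greedily: a terminal base is
removed while its own quality is below `min_base_quality` (default 15) or
the terminal window of `quality_window` bases (default 1) has mean quality
below it. With the default window this is plain per-base end trimming; a
larger window additionally removes high-quality bases stranded inside a
low-quality tail (e.g. quals `40,40,40,2,2,2` at window 3 leave the three
Q40 bases). Requiring both the terminal-base and the window-mean
condition was a deliberate design choice: a pure window-mean rule can
retain a terminal base of quality 2 behind two Q40 neighbours, which
defeats the purpose of end trimming. A fully trimmed read becomes length
0 and is dropped by the length check rather than raising.

**Adapter trimming.** A read suffix equal — exactly, no mismatches — to a
prefix of a configured adapter with at least `min_adapter_overlap`
(default 6) bases of overlap is removed; the longest qualifying trim
wins. Mismatch-tolerant adapter matching is out of scope; at the short
overlaps involved it buys little and costs specificity.

**Low-complexity masking (symmetric DUST).** For an interval containing
`l` overlapping nucleotide triplets with counts `c_t`, the score is
`S = Σ c_t(c_t−1)/2 ÷ (l−1)` (defined 0 for `l < 2`). An interval is
*perfect* when `S` exceeds `dust_score_threshold` (default 2.0) and no
subinterval scores strictly higher; the union of perfect intervals no
longer than `dust_window` (default 64) is masked to N. Because the score
depends only on the triplet count multiset, the mask is independent of
scan direction and invariant under complementation. Defaults are the
published symmetric-DUST defaults. Triplets touching an ambiguous base do
not exist: masking operates on maximal ACGT runs independently, which
makes it idempotent (masking a masked read is a no-op, verified by
property test). Masked bases contribute no k-mers downstream and count as
mismatches in alignment identity — the conservative treatment of
uninformative bases.

The implementation runs an O(n·window) banded dynamic program per ACGT
run (JIT-compiled with numba): scanning starts right-to-left, the maximum
subinterval score of `(i+1, j)` is carried from the previous outer
iteration and of `(i, j−1)` as a running value, so perfectness is decided
with two comparisons. All score comparisons are exact integer
cross-multiplications; the threshold is converted to a rational with
denominator ≤ 10⁶ so every product stays far below the int64 range
(maximum pair-sum at window 64 is 1891).

**Ambiguity/length filter.** After masking, reads with an N fraction
above `max_ambiguous_fraction` (default 0.05) are dropped as
low-complexity; reads shorter than `min_read_length` (default 31) as
low-quality. The length default is forced by k = 31: a shorter read
cannot be k-mer-screened.

**Duplicate removal.** Reads — or pairs, keyed jointly on both mates —
sharing the leading `duplicate_key_length` bases (default: the full read)
in forward orientation keep only the first occurrence. PCR duplicates
share orientation, so no reverse-complement canonicalization of keys is
performed. When one mate of a pair is dropped by an earlier stage, the
widowed mate proceeds as single-end and is exempt from the paired-end
consistency rule (which presumes both mates exist).

## Host k-mer subtraction

Every ACGT k-window of the host reference is inserted in canonical form:
the lexicographic minimum of the k-mer and its reverse complement, which
under A<C<G<T 2-bit packing equals the numeric minimum of the two packed
62-bit values. k must be odd (no k-mer is its own reverse complement) and
≤ 31 (fits a uint64); default 31.

Two membership structures share one interface. The **exact set** is a
sorted uint64 array queried by binary search — exact answers, used as the
oracle. The **Bloom filter** is dimensioned from the standard formulas
`m = ⌈−n·ln p / (ln 2)²⌉` bits and `h = round((m/n)·ln 2)` hashes for `n`
distinct k-mers at target false-positive rate `p` (default 0.001: a false
positive costs a wrongly subtracted read, so the default errs low; the
cost is ~14.4 bits per k-mer). The `h` probe positions come from two
splitmix64-style mixes of the packed k-mer with fixed seeds, combined by
double hashing (`h1 + i·h2 mod m`, `h2` forced odd). No false negatives
are possible by construction; answers are identical across platforms and
serialize/reload byte-identically.

A read is subtracted when ≥ `min_host_kmers` (default 1) of its canonical
k-mers — N-containing windows skipped — are in the index. If either mate
of a surviving pair is flagged, the pair is removed jointly: both mates
come from one host fragment. Reads shorter than k pass unscreened and
rely on the alignment stage; silently dropping them would violate read
conservation.

## Alignment and identity

The production contract is "bring your own SAM": pre-aligned host or
microbe hits are consumed from SAM/BAM (flags, CIGAR, NM). For fully
self-contained runs, `MinimalAligner` provides exact-seed (default 21 bp,
non-overlapping offsets plus the final window, both strands), ungapped
extension over the full read, reporting every placement within one
mismatch of the best in a deterministic order. It is intentionally not a
production aligner: no indels (those enter only via consumed SAM), no
chimeric alignment, placements must lie fully inside a reference
sequence.

Identity of a placement is `(query bases in M/=/X − NM) / read length`,
floored at 0. The denominator is the full, unclipped read length, so
soft-clipping cannot inflate identity — the strictest defensible
definition. Host-alignment subtraction uses the same 0.70 default cutoff
as microbial classification unless overridden (one fewer unexplained
constant).

## Classification and abundance

Per read (or pair): hits below the identity cutoff are discarded; each
remaining hit is attributed to an *organism*, defined as the
species-level ancestor of the hit sequence's taxon (strain-level hits
agree when they share a species; a hit mapped above species level is its
own organism). For pairs, only organisms present in both mates' surviving
hit sets are kept — the paired-end consistency rule. Among survivors,
organisms tied at the best summed (over mates) identity are all kept:
each receives weight `1/|tied|`, the read is assigned to their lowest
common ancestor, and ambiguity is surfaced in the report's `unambiguous`
column rather than resolved by arbitrary choice. A read with no surviving
organism is `UNCLASSIFIED` and is written to the unclassified FASTQ for
downstream assembly.

Weights are exact `Fraction`s. Each candidate's weight is added to the
candidate and every ancestor, so an internal node's score is exactly the
sum of its children's scores plus weight assigned directly to it, and the
species-level total plus supra-species assignments equals the number of
classified reads/pairs — conservation holds to equality, not tolerance.
`score_normalized` is the score as a percentage of total classified
weight (not of input reads; input-relative fractions are derivable from
the stage metrics). A genome-length-normalized column (score per
reference megabase) is available behind `--length-normalize`; it is not
on by default because no single normalization is canonical. Report rows
are sorted by canonical rank order, then descending score, then taxon id,
making the byte output deterministic.

Taxonomies are read either from NCBI-style pipe-delimited `nodes.dmp` /
`names.dmp` or from a simplified 3-column TSV (`taxon_id`, `parent_id`,
`rank|name`). Validation requires exactly one root and no cycles; orphan
sequence mappings are warned about and excluded. Unranked intermediate
nodes are retained in the tree and in roll-ups but carry rank `no rank`
in the report.

## Synthetic communities

The generator emulates the essential structure of a host-dominated
short-read library: a host genome, several microbial reference genomes,
an optional novel organism excluded from the reference (exercising the
discovery path), paired-end reads with substitution errors, adapter
read-through, planted low-complexity inserts, and PCR duplicates —
each read labelled exactly once with origin, mutated positions, artifact
flags and duplicate group.

Design choices that make fixture assertions exact rather than
statistical:

* Category counts (host / novel / each species) are exact-partitioned by
  largest-remainder rounding over the distinct pairs, not sampled;
  duplicates inherit the origin of the pair they copy.
* Genomes are uniform random ACGT with two rejection rules: no canonical
  31-mer shared between any two genomes (k-mer subtraction truth is
  exact), and no maskable low-complexity interval (positions the
  complexity filter would mask are resampled until none remain), so the
  only low-complexity content is what the generator plants deliberately.
* All randomness flows from one seeded PCG64 generator; outputs are
  byte-identical for a fixed seed.

Default study conditions: 100 kb host, five 20 kb microbes at proportions
(0.40, 0.30, 0.15, 0.10, 0.05), 100 bp paired reads at 90% host fraction.
The trace-pathogen fixture plants one species at 10⁻⁴ of reads with 0.5%
per-base error over 10⁵ reads; the discordant fixture draws mate 1 and
mate 2 from different species for half its pairs.

What the generator does **not** emulate — and therefore what passing
tests do not establish about real data: quality-by-cycle error profiles
(fixture qualities are constant Q40; the quality trimmer is exercised by
unit tests instead), indels, GC bias and coverage non-uniformity,
transcript splicing, real genome repeat structure and homology between
host and microbes, and contamination chimeras. Real libraries also
violate the no-shared-k-mer idealization: a real host index will subtract
some genuinely microbial reads sharing 31-mers with the host.

## Problem sizes and runtime choices

The test suite and the acceptance script use desk-scale inputs chosen as
the smallest sizes at which each property is sharp: 10⁵ random 64-mers
for DUST-oracle agreement, ~10⁵ k-mers and 10⁵ probes for Bloom
behaviour, 2 000 host 100-mers for subtraction completeness, 5 000
error-free pairs for abundance recovery (exact partitioning makes the
recovery error essentially zero; the 3-point check bounds residual
filter losses), 10⁵ reads for trace-pathogen detection, and 2 000-4 000
reads for conservation, monotonicity, and determinism runs. Multi-core
parallelization is out of scope; `--threads` is accepted for interface
compatibility but execution is single-threaded.

## Known limitations

* The built-in aligner is ungapped and exact-seeded; reads with indels or
  dense mismatches in every seed window are only handled via externally
  supplied SAM.
* BAM is read through pysam when available; SAM text is the tested
  contract surface. CRAM is unsupported.
* Phred+64 FASTQ is rejected outright (quality characters above 'J'),
  never auto-detected: silent mis-decoding would corrupt the quality
  filter.
* The Bloom path can subtract a non-host read with probability near the
  target false-positive rate; runs that must be exact should use the
  exact-set index, which is also the default.
* Classification granularity below species (strain deconvolution) and
  mapping-quality- or E-value-based scoring are out of scope.
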
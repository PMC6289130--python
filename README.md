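# hostsieve

Computational subtraction of host reads and taxonomic classification of the
microbial residue in short-read sequencing libraries.

## The problem

Deep DNA or RNA sequencing of a tissue, blood or cell-line sample from a
eukaryotic host yields a library that is overwhelmingly host-derived, with
microbial (viral, bacterial, fungal) reads present at fractions that can be
below 10⁻⁴. Detecting those organisms — including ones with no close
reference genome — is done by *computational subtraction*: remove every
read attributable to the host, align what is left against a microbial
reference, and keep the still-unidentified residue as the substrate for
novel-organism discovery.

`hostsieve` implements this as a configurable library plus CLI:

1. **Filter chain** — quality trimming of read ends, adapter read-through
   trimming, low-complexity masking with the symmetric DUST algorithm, an
   ambiguity/length filter, and duplicate removal. Trimming rescues
   partially informative reads instead of discarding them.
2. **k-mer host subtraction** — every canonical 31-mer of the host genome
   is stored in a membership structure (a Bloom filter, or an exact set
   used as its testing oracle); a read containing at least one host k-mer
   is removed. This cheap screen removes the large majority of host reads
   before any alignment is attempted.
3. **Alignment host subtraction** — surviving reads are aligned to the
   host reference (external SAM/BAM is consumed, or the built-in
   seed-and-extend aligner is used at desk scale); reads at ≥ 70% identity
   are removed.
4. **Classification** — non-host reads are aligned to the microbial
   reference and assigned taxonomically. Hits below the identity cutoff
   (default 0.70, user-settable) are ignored; both mates of a pair must
   map to the same organism (species) for the pair to count; organisms
   tied at the best summed identity share the read's unit weight, and the
   read is assigned to their lowest common ancestor.
5. **Report** — per-taxon abundance scores rolled up the taxonomy, with
   exact weight conservation, plus the unclassified-read FASTQ and
   per-stage filter metrics.

For a read of length *L* with alignment edit distance *NM* and *M* bases in
match operations, identity is `(M − NM) / L` — soft-clipped and inserted
bases count against the read. The DUST score of an interval with triplet
counts *c_t* over *l* triplets is `Σ c_t(c_t−1)/2 ÷ (l−1)`; intervals whose
score exceeds the threshold and is not beaten by any subinterval
("perfect" intervals, window-bounded) are masked.

A synthetic-community generator (`hostsieve.simulate`) produces host and
microbial genomes, taxonomies and paired-end libraries with exhaustive
per-read ground truth (origin, mutations, planted adapters, planted
low-complexity inserts, duplicate groups), so the whole pipeline is
testable without downloading anything.

## Worked example

```bash
hostsieve fixtures --out fx --seed 3
hostsieve run \
    --fastq-1 fx/reads_1.fastq --fastq-2 fx/reads_2.fastq \
    --host-fasta fx/host.fasta --microbe-fasta fx/microbes.fasta \
    --taxonomy fx/taxonomy.tsv --seq-map fx/seq_map.tsv \
    --out-dir out
```

prints the terminal disposition of every read:

```
{
  "CLASSIFIED": 1000,
  "FILTERED_DUPLICATE": 2,
  "SUBTRACTED_KMER": 8998
}
```

The fixture plants 10 000 reads at 90% host fraction: the k-mer stage
subtracts all 9 000 host reads (two chance duplicate pairs are removed
first), and the 1 000 microbial reads classify. `out/abundance_report.tsv`
begins:

```
taxon_id  rank          name             path                            score       score_normalized  reads  unambiguous  genome_length
1         root          root             root                            500.000000  100.000000        500    500          100000
2         superkingdom  Bacteria         root|Bacteria                   500.000000  100.000000        500    500          100000
3         phylum        Simulibacterota  root|Bacteria|Simulibacterota   500.000000  100.000000        500    500          100000
```

500 classified pairs distribute their weight down to the five species rows
(40/30/15/10/5% of classified weight), and every internal node holds
exactly the sum of its children. `out/metrics.tsv` reconciles per stage:
`reads_in == reads_out + reads_dropped`, and summed over the chain every
input read appears in exactly one terminal bucket.

The same operations are available as a library — see
`hostsieve.run_pipeline`, and `docs/methods.md` for the full model
description and parameter defaults.

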
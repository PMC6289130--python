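"""Canonical k-mer membership index of the host genome.

Every ACGT k-window of the host reference is inserted in canonical form
(the lexicographic minimum of the k-mer and its reverse complement, which
with A<C<G<T 2-bit packing equals the numeric minimum of the two packed
values). Reads containing at least one host k-mer are then subtracted
before any alignment, which removes the large majority of host reads
cheaply.

Two interchangeable structures implement membership:

* ``EXACT_SET`` — a sorted uint64 array; exact answers, used as the oracle.
* ``BLOOM`` — a Bloom filter dimensioned from the standard formulas
  m = ceil(-n ln p / (ln 2)^2), h = round((m/n) ln 2); zero false negatives
  by construction, false positives near the target rate. Hashes come from a
  splitmix64-style mixer with two fixed seeds combined by double hashing,
  so answers are reproducible across platforms.

k must be odd (a canonical k-mer can then never equal its own reverse
complement) and at most 31 so a k-mer packs into 62 bits.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from Bio import SeqIO

from .core_io import ReadRecord, ReadStatus, pair_stem

__all__ = [
    "KmerHostIndex",
    "build_index",
    "build_index_from_sequences",
    "canonical_kmers",
    "encode_kmer",
    "subtract_host_reads",
]

_MAGIC = b"HKIX"
_VERSION = 1

_SEED1 = np.uint64(0x51_7CC1B727220A95 & 0xFFFFFFFFFFFFFFFF)
_SEED2 = np.uint64(0x2545F4914F6CDD1D)

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def _mix64(x: np.ndarray, seed: np.uint64) -> np.ndarray:
    """splitmix64 finalizer over a uint64 array (vectorized, wrap-around)."""
    z = x ^ seed
    z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def _pack_windows(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed forward and reverse-complement values of every valid k-window.

    Windows containing a non-ACGT base are skipped.
    """
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = codes.size
    if n < k:
        return np.empty(0, np.uint64), np.empty(0, np.uint64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win < 4).all(axis=1)
    win = win[valid].astype(np.uint64)
    if win.size == 0:
        return np.empty(0, np.uint64), np.empty(0, np.uint64)
    pw_desc = np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64)
    pw_asc = np.uint64(4) ** np.arange(k, dtype=np.uint64)
    fwd = (win * pw_desc).sum(axis=1, dtype=np.uint64)
    rc = ((np.uint64(3) - win) * pw_asc).sum(axis=1, dtype=np.uint64)
    return fwd, rc


def canonical_kmers(seq: str, k: int) -> np.ndarray:
    """Canonical packed values of every ACGT k-window of ``seq``."""
    fwd, rc = _pack_windows(seq, k)
    return np.minimum(fwd, rc)


def encode_kmer(kmer: str, k: int) -> int:
    """Canonical packed value of a single k-mer (hard error on bad input)."""
    if len(kmer) != k:
        raise ValueError(f"k-mer {kmer!r} is not length {k}")
    if set(kmer) - set("ACGT"):
        raise ValueError(f"k-mer {kmer!r} contains non-ACGT characters")
    can = canonical_kmers(kmer, k)
    return int(can[0])


@dataclass
class KmerHostIndex:
    """Host-genome canonical k-mer membership structure."""

    k: int
    structure_kind: str  # "BLOOM" | "EXACT_SET"
    n_kmers: int
    bloom_bits: int = 0
    n_hash_functions: int = 0
    target_fp_rate: float = 0.0
    serialized_version: int = _VERSION
    _bits: Optional[np.ndarray] = None  # uint8 buffer (BLOOM)
    _sorted: Optional[np.ndarray] = None  # sorted uint64 array (EXACT_SET)

    def __post_init__(self) -> None:
        if self.k % 2 == 0 or not 1 <= self.k <= 31:
            raise ValueError("k must be odd and <= 31")

    # -- membership ---------------------------------------------------------

    def contains_packed(self, kmers: np.ndarray) -> np.ndarray:
        """Vectorized membership of canonical packed k-mers."""
        kmers = np.asarray(kmers, dtype=np.uint64)
        if self.structure_kind == "EXACT_SET":
            idx = np.searchsorted(self._sorted, kmers)
            idx = np.minimum(idx, self._sorted.size - 1)
            return self._sorted[idx] == kmers
        m = np.uint64(self.bloom_bits)
        h1 = _mix64(kmers, _SEED1) % m
        h2 = (_mix64(kmers, _SEED2) | np.uint64(1)) % m
        hit = np.ones(kmers.shape, dtype=bool)
        idx = h1.copy()
        for _ in range(self.n_hash_functions):
            hit &= (self._bits[idx >> np.uint64(3)] >> (idx & np.uint64(7))) & 1 == 1
            idx = (idx + h2) % m
        return hit

    def contains(self, kmer: str) -> bool:
        """Membership of one k-mer string (canonicalized internally)."""
        packed = encode_kmer(kmer, self.k)
        return bool(self.contains_packed(np.array([packed], dtype=np.uint64))[0])

    def _insert_packed(self, kmers: np.ndarray) -> None:
        m = np.uint64(self.bloom_bits)
        h1 = _mix64(kmers, _SEED1) % m
        h2 = (_mix64(kmers, _SEED2) | np.uint64(1)) % m
        idx = h1.copy()
        for _ in range(self.n_hash_functions):
            np.bitwise_or.at(
                self._bits,
                (idx >> np.uint64(3)).astype(np.int64),
                (np.uint64(1) << (idx & np.uint64(7))).astype(np.uint8),
            )
            idx = (idx + h2) % m
    # -- serialization ------------------------------------------------------

    def save(self, path: str) -> None:
        """Serialize; reloading reproduces answers byte-identically."""
        kind_code = 0 if self.structure_kind == "EXACT_SET" else 1
        payload = (
            self._sorted.tobytes() if kind_code == 0 else self._bits.tobytes()
        )
        with open(path, "wb") as out:
            out.write(_MAGIC)
            out.write(
                struct.pack(
                    "<BBqqqd",
                    self.serialized_version,
                    kind_code,
                    self.k,
                    self.n_kmers,
                    self.bloom_bits,
                    self.target_fp_rate,
                )
            )
            out.write(struct.pack("<q", self.n_hash_functions))
            out.write(payload)

    @classmethod
    def load(cls, path: str) -> "KmerHostIndex":
        with open(path, "rb") as fh:
            if fh.read(4) != _MAGIC:
                raise ValueError(f"{path}: not a host k-mer index file")
            version, kind_code, k, n_kmers, bloom_bits, fp = struct.unpack(
                "<BBqqqd", fh.read(struct.calcsize("<BBqqqd"))
            )
            (n_hash,) = struct.unpack("<q", fh.read(8))
            payload = fh.read()
        if version != _VERSION:
            raise ValueError(f"{path}: unsupported index version {version}")
        idx = cls(
            k=k,
            structure_kind="EXACT_SET" if kind_code == 0 else "BLOOM",
            n_kmers=n_kmers,
            bloom_bits=bloom_bits,
            n_hash_functions=n_hash,
            target_fp_rate=fp,
        )
        if kind_code == 0:
            idx._sorted = np.frombuffer(payload, dtype=np.uint64)
        else:
            idx._bits = np.frombuffer(payload, dtype=np.uint8).copy()
        return idx


def bloom_dimensions(n: int, target_fp_rate: float) -> tuple[int, int]:
    """Standard Bloom sizing: bit count m and hash count h for n items."""
    if not 0.0 < target_fp_rate < 0.5:
        raise ValueError("target_fp_rate must lie in (0, 0.5)")
    m = math.ceil(-n * math.log(target_fp_rate) / (math.log(2) ** 2))
    h = max(1, round((m / n) * math.log(2)))
    return m, h


def build_index_from_sequences(
    sequences: Iterable[str],
    k: int = 31,
    structure_kind: str = "EXACT_SET",
    target_fp_rate: float = 0.001,
) -> KmerHostIndex:
    """Build the index from in-memory host sequences."""
    if structure_kind not in ("EXACT_SET", "BLOOM"):
        raise ValueError(f"unknown structure kind {structure_kind!r}")
    parts = [canonical_kmers(seq, k) for seq in sequences]
    parts = [p for p in parts if p.size]
    if not parts:
        raise ValueError("host reference contains no ACGT k-windows (0 k-mers)")
    distinct = np.unique(np.concatenate(parts))
    n = int(distinct.size)
    if structure_kind == "EXACT_SET":
        return KmerHostIndex(
            k=k, structure_kind="EXACT_SET", n_kmers=n, _sorted=distinct
        )
    m, h = bloom_dimensions(n, target_fp_rate)
    idx = KmerHostIndex(
        k=k,
        structure_kind="BLOOM",
        n_kmers=n,
        bloom_bits=m,
        n_hash_functions=h,
        target_fp_rate=target_fp_rate,
        _bits=np.zeros((m + 7) // 8, dtype=np.uint8),
    )
    idx._insert_packed(distinct)
    return idx


def build_index(
    host_fasta: str,
    k: int = 31,
    structure_kind: str = "EXACT_SET",
    target_fp_rate: float = 0.001,
) -> KmerHostIndex:
    """Build the host index from a FASTA file of reference sequences."""
    seqs = [str(rec.seq) for rec in SeqIO.parse(host_fasta, "fasta")]
    if not seqs:
        raise ValueError(f"{host_fasta}: empty or unparseable FASTA")
    return build_index_from_sequences(
        seqs, k=k, structure_kind=structure_kind, target_fp_rate=target_fp_rate
    )


def count_host_kmers(record: ReadRecord, index: KmerHostIndex) -> int:
    """Number of the read's canonical k-mers present in the host index."""
    kmers = canonical_kmers(record.bases, index.k)
    if kmers.size == 0:
        return 0
    return int(index.contains_packed(kmers).sum())


def subtract_host_reads(
    records: Iterable[ReadRecord],
    index: KmerHostIndex,
    min_host_kmers: int = 1,
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Split reads into (survivors, host-subtracted) by k-mer membership.

    A read is host-flagged when at least ``min_host_kmers`` of its canonical
    k-mers (N-containing windows skipped) are in the index; reads shorter
    than k pass through unscreened. If either mate of a surviving pair is
    flagged, the whole pair is removed — a host fragment implicates both
    mates.
    """
    records = list(records)
    flagged: set[str] = set()
    for rec in records:
        if len(rec.bases) >= index.k and count_host_kmers(rec, index) >= min_host_kmers:
            flagged.add(rec.read_id)
    survivors: list[ReadRecord] = []
    subtracted: list[ReadRecord] = []
    by_id = {r.read_id: r for r in records}
    for rec in records:
        mate_flagged = rec.mate_of is not None and rec.mate_of in flagged
        if rec.read_id in flagged or mate_flagged:
            reason = (
                "host k-mer hit" if rec.read_id in flagged else "mate hit host k-mer"
            )
            rec.advance_status(ReadStatus.SUBTRACTED_KMER, reason)
            subtracted.append(rec)
        else:
            survivors.append(rec)
    return survivors, subtracted
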
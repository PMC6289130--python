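"""Independent brute-force oracles used to validate the implementation.

These deliberately use the dumbest correct formulation (explicit
enumeration, Counter-based counting, full-scan alignment) and share no
code with the package internals they check.
"""

from collections import Counter
from fractions import Fraction

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def dust_score_oracle(seq: str) -> Fraction:
    """Whole-sequence DUST score by explicit triplet counting."""
    triplets = [
        seq[i : i + 3]
        for i in range(len(seq) - 2)
        if set(seq[i : i + 3]) <= set("ACGT")
    ]
    l = len(triplets)
    if l < 2:
        return Fraction(0)
    counts = Counter(triplets)
    pairs = sum(c * (c - 1) // 2 for c in counts.values())
    return Fraction(pairs, l - 1)


def dust_window_scores_oracle(seq: str, window: int) -> list[float]:
    if len(seq) <= window:
        return [float(dust_score_oracle(seq))]
    return [
        float(dust_score_oracle(seq[i : i + window]))
        for i in range(len(seq) - window + 1)
    ]


def dust_mask_oracle(seq: str, window: int, threshold: float) -> np.ndarray:
    """Union of perfect intervals by exhaustive enumeration.

    An interval (span <= window, at least two triplets) is perfect when its
    score exceeds the threshold and no subinterval scores strictly higher.
    """
    n = len(seq)
    thr = Fraction(threshold).limit_denominator(10**6)
    scores: dict[tuple[int, int], Fraction] = {}
    for i in range(n):
        for j in range(i + 4, min(n, i + window) + 1):
            scores[(i, j)] = dust_score_oracle(seq[i:j])
    mask = np.zeros(n, dtype=bool)
    for (i, j), s in scores.items():
        if s <= thr:
            continue
        perfect = True
        for i2 in range(i, j):
            for j2 in range(i2 + 4, j + 1):
                if (i2, j2) != (i, j) and scores[(i2, j2)] > s:
                    perfect = False
                    break
            if not perfect:
                break
        if perfect:
            mask[i:j] = True
    return mask


def canonical_kmers_oracle(seq: str, k: int) -> list[str]:
    """Canonical k-mers of all ACGT windows, as strings."""
    out = []
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if set(kmer) <= set("ACGT"):
            out.append(min(kmer, revcomp(kmer)))
    return out


def brute_best_placements(
    read: str, references: dict[str, str]
) -> tuple[int, set[tuple[str, int, str]]]:
    """Minimum-Hamming placements of the read over every position/strand."""
    best = len(read) + 1
    placements: set[tuple[str, int, str]] = set()
    read_arrs = {
        "+": np.frombuffer(read.encode(), dtype=np.uint8),
        "-": np.frombuffer(revcomp(read).encode(), dtype=np.uint8),
    }
    for name, ref in references.items():
        if len(ref) < len(read):
            continue
        ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(ref_arr, len(read))
        for strand, arr in read_arrs.items():
            nm = (windows != arr).sum(axis=1)
            m = int(nm.min())
            if m < best:
                best = m
                placements = set()
            if m == best:
                for pos in np.nonzero(nm == m)[0]:
                    placements.add((name, int(pos), strand))
    return best, placements


def lca_oracle(parent: dict[int, int], root: int, taxa: set[int]) -> int:
    """LCA by explicit root-path intersection."""

    def path(t: int) -> list[int]:
        out = [t]
        while t != root:
            t = parent[t]
            out.append(t)
        return out

    common = None
    for t in taxa:
        p = set(path(t))
        common = p if common is None else common & p
    depth = {t: len(path(t)) for t in common}
    return max(common, key=lambda t: depth[t])
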
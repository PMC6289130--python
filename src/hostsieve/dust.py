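"""Symmetric DUST low-complexity scoring and masking.

The DUST score of an interval is S = sum_t c_t(c_t-1)/2 / (l-1), where c_t
are the counts of the 64 overlapping nucleotide triplets in the interval and
l is the number of triplets. An interval is *perfect* when S exceeds the
threshold and no subinterval scores strictly higher; the union of all
perfect intervals no longer than the window is masked (bases replaced by N).
Because the score depends only on the triplet count multiset, the result is
independent of scan direction (the "symmetric" property) and invariant
under complementation.

Triplets containing an ambiguous base do not exist: masking operates on
maximal ACGT runs independently, which also makes masking idempotent.

Scores are compared exactly as rationals (integer cross-multiplication);
the threshold is converted to a rational with denominator <= 1e6 so all
int64 products stay far from overflow. The inner dynamic program is
JIT-compiled with numba.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from numba import njit

__all__ = ["dust_score", "window_scores", "mask_intervals", "mask_sequence"]

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def _codes(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _triplet_codes(codes: np.ndarray) -> np.ndarray:
    """Triplet codes 0..63; 64 marks triplets touching a non-ACGT base."""
    if codes.size < 3:
        return np.empty(0, dtype=np.int64)
    a = codes[:-2].astype(np.int64)
    b = codes[1:-1].astype(np.int64)
    c = codes[2:].astype(np.int64)
    tri = a * 16 + b * 4 + c
    tri[(a > 3) | (b > 3) | (c > 3)] = 64
    return tri


def dust_score(seq: str) -> float:
    """DUST score of a whole sequence (0.0 when fewer than 2 valid triplets)."""
    tri = _triplet_codes(_codes(seq))
    tri = tri[tri < 64]
    l = tri.size
    if l < 2:
        return 0.0
    counts = np.bincount(tri, minlength=64)
    pairs = int((counts * (counts - 1) // 2).sum())
    return pairs / (l - 1)


def window_scores(seq: str, window: int) -> np.ndarray:
    """DUST scores of every full-length window (sliding by one base).

    A sequence shorter than the window yields its single whole-sequence
    score. Invalid triplets (touching N) are excluded from the counts.
    """
    n = len(seq)
    if n <= window:
        return np.array([dust_score(seq)])
    tri = _triplet_codes(_codes(seq))
    out = np.empty(n - window + 1, dtype=np.float64)
    counts = np.zeros(65, dtype=np.int64)
    ntri = window - 2
    pairs = 0
    valid = 0
    for t in tri[:ntri]:
        pairs += counts[t]
        counts[t] += 1
    valid = ntri - counts[64]
    vp = pairs - counts[64] * (counts[64] - 1) // 2
    out[0] = vp / (valid - 1) if valid >= 2 else 0.0
    for w in range(1, n - window + 1):
        t_out = tri[w - 1]
        counts[t_out] -= 1
        pairs -= counts[t_out]
        t_in = tri[w + ntri - 1]
        pairs += counts[t_in]
        counts[t_in] += 1
        valid = ntri - counts[64]
        # pairs only counts valid-triplet collisions: code 64 never collides
        # with itself meaningfully, so subtract its pair contribution
        vp = pairs - counts[64] * (counts[64] - 1) // 2
        out[w] = vp / (valid - 1) if valid >= 2 else 0.0
    return out


@njit(cache=True)
def _perfect_mask_run(tri, n_bases, window, t_num, t_den, mask, offset):  # pragma: no cover
    """Mark every perfect interval (span <= window) of one ACGT run.

    For start i (descending) and end j (ascending), maintains the triplet
    counts and pair sum of [i, j) incrementally. maxsub(i+1, j) comes from
    the previous outer iteration (ms_num/ms_den over j); maxsub(i, j-1) is
    the running maximum within the inner loop. An interval is perfect iff
    its score is > threshold and >= both of those maxima. All rationals are
    compared by int64 cross-multiplication.
    """
    n = n_bases
    ms_num = np.zeros(n + 1, dtype=np.int64)
    ms_den = np.ones(n + 1, dtype=np.int64)
    cur_num = np.zeros(n + 1, dtype=np.int64)
    cur_den = np.ones(n + 1, dtype=np.int64)
    counts = np.zeros(64, dtype=np.int64)
    for i in range(n - 1, -1, -1):
        for t in range(64):
            counts[t] = 0
        psum = 0
        run_num = 0
        run_den = 1
        jmax = min(n, i + window)
        for j in range(i + 3, jmax + 1):
            t = tri[j - 3]
            psum += counts[t]
            counts[t] += 1
            l = j - i - 2
            s_num = psum
            s_den = l - 1
            if l >= 2:
                if (
                    s_num * t_den > t_num * s_den
                    and s_num * ms_den[j] >= ms_num[j] * s_den
                    and s_num * run_den >= run_num * s_den
                ):
                    for b in range(i, j):
                        mask[offset + b] = True
                # maxsub(i, j) = max(S(i,j), maxsub(i+1,j), maxsub(i,j-1))
                m_num, m_den = s_num, s_den
                if ms_num[j] * m_den > m_num * ms_den[j]:
                    m_num, m_den = ms_num[j], ms_den[j]
                if run_num * m_den > m_num * run_den:
                    m_num, m_den = run_num, run_den
                run_num, run_den = m_num, m_den
                cur_num[j] = m_num
                cur_den[j] = m_den
            else:
                cur_num[j] = ms_num[j]
                cur_den[j] = ms_den[j]
                if ms_num[j] * run_den > run_num * ms_den[j]:
                    run_num, run_den = ms_num[j], ms_den[j]
        # hand the band [i+2, i+window] to the next outer iteration; values
        # outside it are never read again (subintervals stay within the window)
        if i + 2 <= n:
            cur_num[i + 2] = 0
            cur_den[i + 2] = 1
        for j in range(i + 2, jmax + 1):
            ms_num[j] = cur_num[j]
            ms_den[j] = cur_den[j]
            cur_num[j] = 0
            cur_den[j] = 1


def _threshold_rational(threshold: float) -> tuple[int, int]:
    if threshold < 0:
        raise ValueError("dust threshold must be non-negative")
    frac = Fraction(threshold).limit_denominator(10**6)
    return frac.numerator, frac.denominator


def mask_intervals(seq: str, window: int = 64, threshold: float = 2.0) -> np.ndarray:
    """Boolean mask of low-complexity positions (perfect-interval union)."""
    if window < 3:
        raise ValueError("dust window must be >= 3")
    t_num, t_den = _threshold_rational(threshold)
    codes = _codes(seq)
    mask = np.zeros(len(seq), dtype=np.bool_)
    # process maximal ACGT runs independently
    valid = codes < 4
    n = len(seq)
    start = 0
    while start < n:
        if not valid[start]:
            start += 1
            continue
        end = start
        while end < n and valid[end]:
            end += 1
        if end - start >= 5:  # shortest scoreable interval has 2 triplets + 1
            sub = codes[start:end].astype(np.int64)
            tri = sub[:-2] * 16 + sub[1:-1] * 4 + sub[2:]
            _perfect_mask_run(tri, end - start, window, t_num, t_den, mask, start)
        start = end
    return mask


def mask_sequence(seq: str, window: int = 64, threshold: float = 2.0) -> str:
    """Replace low-complexity bases with N (idempotent)."""
    mask = mask_intervals(seq, window, threshold)
    if not mask.any():
        return seq
    chars = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    chars[mask] = ord("N")
    return chars.tobytes().decode("ascii")
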
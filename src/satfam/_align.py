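"""Low-level alignment and sequence helpers.

The wraparound verification aligns an array candidate locally against tandem
copies of its consensus monomer under TRF-style weights (match +m, mismatch
-mm, indel -d, linear gaps).  Implemented as a Smith-Waterman scan compiled
with numba; start-row tracking recovers the array boundaries without a full
traceback matrix.
"""
from __future__ import annotations

import numpy as np
from numba import njit

_CODE = np.full(256, 4, dtype=np.uint8)   # N and anything else -> 4
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i

_COMP = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; N/other -> 4 (matches nothing)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def gc_percent(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return 100.0 * (seq.count("G") + seq.count("C")) / acgt


@njit(cache=True)
def _local_dp(text, ref, match, mismatch, indel):  # pragma: no cover - numba
    """Local alignment of text vs ref (linear gap penalty).

    Returns (best_score, text_start, text_end) of the maximum-scoring local
    alignment, with text coordinates half-open.  N (code 4) never matches.
    """
    n, m = len(text), len(ref)
    H = np.zeros(m + 1, dtype=np.int64)
    S = np.zeros(m + 1, dtype=np.int64)       # start row of each cell's path
    best, bi, bstart = 0, 0, 0
    for i in range(1, n + 1):
        diag_h = H[0]
        diag_s = S[0]
        H[0] = 0
        S[0] = i
        for j in range(1, m + 1):
            up_h = H[j]
            up_s = S[j]
            if text[i - 1] == ref[j - 1] and text[i - 1] != 4:
                sub = diag_h + match
            else:
                sub = diag_h - mismatch
            sub_s = diag_s
            left = H[j - 1] - indel
            left_s = S[j - 1]
            upv = up_h - indel
            # choose max(0, sub, upv, left); ties prefer substitution
            v = sub
            vs = sub_s
            if upv > v:
                v = upv
                vs = up_s
            if left > v:
                v = left
                vs = left_s
            if v <= 0:
                v = 0
                vs = i
            H[j] = v
            S[j] = vs
            diag_h = up_h
            diag_s = up_s
            if v > best:
                best = v
                bi = i
                bstart = vs
    return best, bstart, bi


def local_align_score(text: str, ref: str, match: int, mismatch: int,
                      indel: int) -> tuple[int, int, int]:
    """Best local-alignment score of ``text`` against ``ref`` plus the
    aligned interval on ``text`` (0-based half-open)."""
    score, s, e = _local_dp(encode(text), encode(ref), match, mismatch, indel)
    return int(score), int(s), int(e)


def wraparound_score(text: str, monomer: str, match: int, mismatch: int,
                     indel: int) -> tuple[int, int, int]:
    """Score ``text`` against tandem copies of ``monomer`` (wraparound
    alignment), free in phase and extent.  Returns (score, start, end) on
    ``text``."""
    p = len(monomer)
    if p == 0:
        return 0, 0, 0
    reps = len(text) // p + 2
    return local_align_score(text, monomer * reps, match, mismatch, indel)


def max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if seq else 0


def self_complementarity(seq: str) -> int:
    """Max ungapped antiparallel self-annealing score, +1 match / -1 mismatch.

    Slides the oligo against its own reverse complement over every offset and
    returns the best contiguous-window score (best suffix-max over each
    diagonal's running sum).
    """
    rc = revcomp(seq)
    n = len(seq)
    best = 0
    for offset in range(-(n - 1), n):
        running = 0
        for i in range(max(0, -offset), min(n, n - offset)):
            running += 1 if seq[i] == rc[i + offset] else -1
            if running < 0:
                running = 0
            elif running > best:
                best = running
    return best


def mismatch_hits(text: str, probe: str, max_mismatches: int = 2) -> int:
    """Number of ungapped occurrences of ``probe`` in ``text`` (given strand)
    with at most ``max_mismatches`` substitutions."""
    n, m = len(text), len(probe)
    if n < m:
        return 0
    t = encode(text)
    p = encode(probe)
    windows = np.lib.stride_tricks.sliding_window_view(t, m)
    mism = (windows != p).sum(axis=1)
    return int((mism <= max_mismatches).sum())


def has_hit_either_strand(text: str, probe: str, max_mismatches: int = 2) -> bool:
    return (mismatch_hits(text, probe, max_mismatches) > 0
            or mismatch_hits(text, revcomp(probe), max_mismatches) > 0)
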
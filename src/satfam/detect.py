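"""Native tandem-array detection.

A simplified Tandem-Repeats-Finder-style detector: exact k-mer re-occurrence
distances propose candidate monomer periods (k=5 for periods <= 29, k=7
above), and a wraparound local alignment of the candidate region against
tandem copies of its phased majority-vote consensus verifies period, extent
and score under the weights match +2 / mismatch -5 / indel -7.  Periods that
are near-multiples of a smaller unit collapse to the smallest period whose
verified score stays within 95% of the best, so a 21-mer array is reported
with period 21, not 42.  Detection is strand-symmetric in what it reports;
arrays carry no strand.
"""
from __future__ import annotations

from collections import defaultdict

import edlib

from ._align import wraparound_score
from .model import DetectorParams, SequenceRecord, TRArray

# minimum aligned span, in copies, for a verified array; a stretch that does
# not wrap at least most of twice around its monomer is not a tandem repeat
_MIN_COPIES = 1.9
_DIVISOR_TOL = 0.95


def consensus_of(array_sequence: str, period: int) -> str:
    """Column-wise majority vote over period-phased slices of the array.

    Ties break by fixed base order A<C<G<T; N casts no vote.  Raises if the
    array is shorter than one period.
    """
    if period < 1:
        raise ValueError("period must be >= 1")
    if len(array_sequence) < period:
        raise ValueError("array shorter than one period")
    counts = [[0, 0, 0, 0] for _ in range(period)]
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i, base in enumerate(array_sequence):
        j = idx.get(base)
        if j is not None:
            counts[i % period][j] += 1
    out = []
    for col in counts:
        best = max(col)
        out.append("N" if best == 0 else "ACGT"[col.index(best)])
    return "".join(out)


def _divisors(n: int) -> list[int]:
    divs = [d for d in range(1, n) if n % d == 0]
    return divs


def _propose_candidates(seq: str, maxperiod: int) -> list[tuple[int, int, int, int]]:
    """Yield (start, end, period, support) candidate regions from k-mer
    re-occurrence distances."""
    n = len(seq)
    hits: dict[int, list[int]] = defaultdict(list)
    for k, lo, hi in ((5, 1, 29), (7, 30, maxperiod)):
        if n < 2 * k:
            continue
        last: dict[str, int] = {}
        for i in range(n - k + 1):
            km = seq[i:i + k]
            if "N" in km:
                continue
            prev = last.get(km)
            if prev is not None:
                d = i - prev
                if lo <= d <= min(hi, maxperiod):
                    hits[d].append(i)
            last[km] = i

    raw: list[tuple[int, int, int, int]] = []
    for d, positions in hits.items():
        max_gap = max(2 * d, 40)
        run_start = positions[0]
        prev = positions[0]
        count = 1
        for pos in positions[1:] + [None]:
            if pos is not None and pos - prev <= max_gap:
                prev = pos
                count += 1
                continue
            span = prev - run_start
            if count >= 4 and span >= d:
                s = max(0, run_start - d - 4)
                e = min(n, prev + d + 12)
                raw.append((s, e, d, count))
            if pos is not None:
                run_start = prev = pos
                count = 1

    # merge candidates with overlapping extent and similar period; keep the
    # better-supported one so each array is verified once
    raw.sort(key=lambda c: (c[0], c[1]))
    merged: list[tuple[int, int, int, int]] = []
    for cand in raw:
        s, e, d, cnt = cand
        absorbed = False
        for i, (ms, me, md, mc) in enumerate(merged):
            overlap = min(e, me) - max(s, ms)
            if overlap > 0.5 * min(e - s, me - ms) and \
                    abs(d - md) <= 0.2 * max(d, md):
                if cnt > mc:
                    merged[i] = (min(s, ms), max(e, me), d, cnt)
                else:
                    merged[i] = (min(s, ms), max(e, me), md, mc)
                absorbed = True
                break
        if not absorbed:
            merged.append(cand)
    return merged


def _copy_stats(array_seq: str, consensus: str) -> tuple[float, float]:
    """Percent match / percent indel of full monomer copies vs the consensus
    (edit-distance alignment per phased copy)."""
    p = len(consensus)
    eq = sub = ind = 0
    for c0 in range(0, len(array_seq) - p + 1, p):
        copy = array_seq[c0:c0 + p]
        res = edlib.align(copy, consensus, mode="NW", task="path")
        for length, op in _iter_cigar(res["cigar"]):
            if op == "=":
                eq += length
            elif op == "X":
                sub += length
            else:
                ind += length
    total = eq + sub + ind
    if total == 0:
        return 0.0, 0.0
    return 100.0 * eq / total, 100.0 * ind / total


def _iter_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _verify(seq: str, cand_start: int, cand_end: int, d: int,
            params: DetectorParams) -> list[TRArray]:
    window = seq[cand_start:cand_end]
    if len(window) < max(2, d):
        return []
    m, mm, ind = params.match_weight, params.mismatch_penalty, params.indel_penalty

    # score the proposed period, then any divisor whose unit the consensus
    # itself repeats (cheap periodicity pre-test prunes the rest)
    cons_d = consensus_of(window, d)
    results: dict[int, tuple[int, int, int, str]] = {}
    score, a_s, a_e = wraparound_score(window, cons_d, m, mm, ind)
    results[d] = (score, a_s, a_e, cons_d)
    for p in _divisors(d):
        unit = cons_d[:p]
        same = sum(1 for i, b in enumerate(cons_d) if b == unit[i % p])
        if same < 0.8 * len(cons_d):
            continue
        cons_p = consensus_of(window, p)
        sc, s2, e2 = wraparound_score(window, cons_p, m, mm, ind)
        results[p] = (sc, s2, e2, cons_p)

    best = max(r[0] for r in results.values())
    if best < params.minscore:
        return []
    period = min(p for p, r in results.items() if r[0] >= _DIVISOR_TOL * best)
    score, a_s, a_e, _ = results[period]
    if a_e - a_s < _MIN_COPIES * period or score < params.minscore:
        return []

    array_seq = window[a_s:a_e]
    consensus = consensus_of(array_seq, period)
    pm, pi = _copy_stats(array_seq, consensus)
    arr = TRArray(
        contig_id="", start=cand_start + a_s, end=cand_start + a_e,
        period=period, copies=round((a_e - a_s) / period, 1),
        percent_match=round(pm, 1), percent_indel=round(pi, 1),
        score=score, consensus_monomer=consensus, array_sequence=array_seq)
    out = [arr]
    # a candidate window can hold two arrays split by background: local
    # alignment returns only the best one, so re-verify the leftovers
    if a_s - 0 >= 2 * d + 8:
        out += _verify(seq, cand_start, cand_start + a_s, d, params)
    if len(window) - a_e >= 2 * d + 8:
        out += _verify(seq, cand_start + a_e, cand_end, d, params)
    return out


def _dedup_overlapping(arrays: list[TRArray]) -> list[TRArray]:
    """Collapse near-identical detections of one locus (same period family,
    heavy mutual overlap) to the best-scoring one."""
    arrays = sorted(arrays, key=lambda a: (-a.score, a.period, a.start, a.end))
    kept: list[TRArray] = []
    for a in arrays:
        redundant = False
        for b in kept:
            overlap = min(a.end, b.end) - max(a.start, b.start)
            if overlap <= 0:
                continue
            if overlap >= 0.8 * (a.end - a.start) and overlap >= 0.8 * (b.end - b.start):
                ratio = max(a.period, b.period) / min(a.period, b.period)
                if abs(ratio - round(ratio)) <= 0.1 or min(a.period, b.period) < 5:
                    redundant = True
                    break
        if not redundant:
            kept.append(a)
    return sorted(kept, key=lambda a: (a.start, a.end, a.period))


def detect(record: SequenceRecord, params: DetectorParams = DetectorParams()
           ) -> list[TRArray]:
    """Find tandem arrays in one sequence.

    Every emitted array scores >= ``params.minscore`` under wraparound
    alignment against tandem copies of its consensus and spans at least
    ~2 monomer copies.  An empty result is not an error.
    """
    if len(record.sequence) < 2:
        raise ValueError("sequence shorter than 2 bp")
    seq = record.sequence
    found: list[TRArray] = []
    for s, e, d, _ in _propose_candidates(seq, params.maxperiod):
        found.extend(_verify(seq, s, e, d, params))
    found = _dedup_overlapping(found)
    for a in found:
        a.contig_id = record.id
        a.validate(params.maxperiod)
    return found


def detect_all(records: list[SequenceRecord],
               params: DetectorParams = DetectorParams()) -> list[TRArray]:
    out: list[TRArray] = []
    for rec in records:
        out.extend(detect(rec, params))
    return out
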
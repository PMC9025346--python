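"""Clustering catalog arrays into named TR families.

Arrays are compared all-vs-all by local alignment under blastn-default
weights (reward +2, mismatch -3, gap open 5 + extend 2 per base) and joined
into families by single-linkage closure over pairs scoring above a
threshold (200 by default).  Families are named <prefix><min monomer
length><letter>, e.g. "33A", and annotated against a repeat (TE) library by
alignment coverage.
"""
from __future__ import annotations

import math
import string
import warnings
from collections import defaultdict
from dataclasses import dataclass

import edlib
from Bio import Align

from ._align import gc_percent
from .model import ArrayCatalog, PairMatch, SequenceRecord, TRArray, TRFamily
from .io import is_te_class, parse_library_header


@dataclass(frozen=True)
class BlastnScoring:
    """blastn-default local-alignment weights plus the Karlin-Altschul
    constants used for the e-value (NCBI's tabulated values for this
    reward/penalty/gap scheme)."""

    reward: int = 2
    mismatch: int = -3
    gap_open: int = 5       # a gap of length g costs gap_open + g * gap_extend
    gap_extend: int = 2
    karlin_lambda: float = 0.625
    karlin_k: float = 0.41

    def aligner(self) -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.mode = "local"
        al.match_score = self.reward
        al.mismatch_score = self.mismatch
        al.open_gap_score = -(self.gap_open + self.gap_extend)
        al.extend_gap_score = -self.gap_extend
        return al

    def evalue(self, score: float, m: int, n: int) -> float:
        return self.karlin_k * m * n * math.exp(-self.karlin_lambda * score)


DEFAULT_SCORING = BlastnScoring()

# all-vs-all tractability: only pairs sharing an exact seed word are aligned,
# and very long arrays are scored on their leading window (score 200 needs
# only ~100 matched bases, far below the cap)
_SEED_WORD = 11
_MAX_ALIGN_LEN = 3000


def _seed_index(arrays: list[TRArray]) -> dict[str, set[int]]:
    index: dict[str, set[int]] = defaultdict(set)
    for i, a in enumerate(arrays):
        seq = a.array_sequence[:_MAX_ALIGN_LEN]
        for j in range(0, len(seq) - _SEED_WORD + 1):
            index[seq[j:j + _SEED_WORD]].add(i)
    return index


def score_pairs(catalog: ArrayCatalog, evalue_max: float = 1e-15,
                scoring: BlastnScoring = DEFAULT_SCORING) -> list[PairMatch]:
    """Local-alignment scores for all array pairs passing the e-value gate.

    Low-complexity masking is off (dust "no"): tandem arrays ARE
    low-complexity by design and must still align.
    """
    arrays = catalog.arrays
    if len(arrays) < 2:
        return []
    aligner = scoring.aligner()
    index = _seed_index(arrays)
    candidates: set[tuple[int, int]] = set()
    for members in index.values():
        members = sorted(members)
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                candidates.add((members[x], members[y]))
    out: list[PairMatch] = []
    for i, j in sorted(candidates):
        a, b = arrays[i], arrays[j]
        sa = a.array_sequence[:_MAX_ALIGN_LEN]
        sb = b.array_sequence[:_MAX_ALIGN_LEN]
        score = int(aligner.score(sa, sb))
        if score <= 0:
            continue
        ev = scoring.evalue(score, len(sa), len(sb))
        if ev <= evalue_max:
            out.append(PairMatch(array_a=a.id, array_b=b.id, score=score, evalue=ev))
    return out


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def _most_homogeneous(members: list[TRArray]) -> TRArray:
    return max(members, key=lambda a: (a.percent_match, a.end - a.start,
                                       a.contig_id, -a.start))


def cluster_families(catalog: ArrayCatalog, matches: list[PairMatch],
                     score_threshold: int = 200) -> list[TRFamily]:
    """Single-linkage transitive closure over pairs with score > threshold;
    unmatched arrays become singleton families.

    The result partitions the catalog; ordering and duplicate symmetric
    matches do not affect it.
    """
    ids = [a.id for a in catalog.arrays]
    by_id = {a.id: a for a in catalog.arrays}
    uf = _UnionFind(ids)
    for m in matches:
        if m.score > score_threshold and m.array_a in by_id and m.array_b in by_id:
            uf.union(m.array_a, m.array_b)

    groups: dict[str, list[str]] = defaultdict(list)
    for i in ids:
        groups[uf.find(i)].append(i)

    families: list[TRFamily] = []
    ordered = sorted(groups.values(),
                     key=lambda g: min((by_id[i].contig_id, by_id[i].start) for i in g))
    for fid, member_ids in enumerate(ordered):
        members = [by_id[i] for i in member_ids]
        members.sort(key=lambda a: (a.contig_id, a.start, a.end))
        rep = _most_homogeneous(members)
        all_seq = "".join(a.array_sequence for a in members)
        families.append(TRFamily(
            family_id=fid,
            members=[a.id for a in members],
            min_monomer=min(a.period for a in members),
            representative=rep.consensus_monomer,
            max_array_len=max(a.end - a.start for a in members),
            gc_percent=gc_percent(all_seq),
        ))
    return families


def _letters(n: int) -> str:
    """0 -> A, 25 -> Z, 26 -> AA, 27 -> AB, ..."""
    out = ""
    n += 1
    while n > 0:
        n, rem = divmod(n - 1, 26)
        out = string.ascii_uppercase[rem] + out
    return out


def assign_names(families: list[TRFamily], species_prefix: str = "CG",
                 assembly_id: str = "") -> list[TRFamily]:
    """Name families <prefix><min monomer><letter>.

    The numeral is the minimum monomer length among the family's arrays;
    letters differentiate same-numeral families, assigned in order of first
    genomic occurrence (assembly, contig, start) so renaming is deterministic.
    Pass ``species_prefix=""`` to omit the species abbreviation.
    """
    def first_occurrence(f: TRFamily):
        locs = []
        for mid in f.members:
            contig, span = mid.rsplit(":", 1)
            start = int(span.split("-")[0])
            locs.append((assembly_id, contig, start))
        return min(locs)

    by_numeral: dict[int, list[TRFamily]] = defaultdict(list)
    for f in families:
        by_numeral[f.min_monomer].append(f)
    for numeral, group in by_numeral.items():
        group.sort(key=first_occurrence)
        for i, f in enumerate(group):
            f.name = f"{species_prefix}{numeral}{_letters(i)}"
    return families


# ---------------------------------------------------------------------------
# Repeat-library (TE) annotation

_MIN_HSP_SCORE = 60
_MAX_HSPS = 40


def _coverage_intervals(array_seq: str, entry_seq: str,
                        scoring: BlastnScoring) -> list[tuple[int, int]]:
    """Greedy multi-HSP scan: best local alignment, mask it on the array,
    repeat while scores stay informative.  Returns aligned intervals on the
    array."""
    aligner = scoring.aligner()
    work = array_seq
    spans: list[tuple[int, int]] = []
    for _ in range(_MAX_HSPS):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            alns = aligner.align(work, entry_seq)
            if len(alns) == 0 or alns.score < _MIN_HSP_SCORE:
                break
            aln = alns[0]
        t0, t1 = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])
        if t1 <= t0:
            break
        spans.append((t0, t1))
        work = work[:t0] + "N" * (t1 - t0) + work[t1:]
    return spans


def _merged_length(spans: list[tuple[int, int]]) -> int:
    total = 0
    last_end = -1
    for s, e in sorted(spans):
        s = max(s, last_end)
        if e > s:
            total += e - s
            last_end = e
    return total


def annotate_library(family: TRFamily, catalog: ArrayCatalog,
                     repeat_library: list[SequenceRecord],
                     coverage_threshold: float = 0.80,
                     scoring: BlastnScoring = DEFAULT_SCORING,
                     max_members: int = 3) -> TRFamily:
    """Annotate a family with its best repeat-library similarity.

    Library entries are aligned to member arrays; if the best entry's
    alignments cover >= ``coverage_threshold`` of a member array's length the
    family records that entry.  Entries whose class is not a transposable
    element (satellites, gene fragments such as Zn-finger) are recorded but
    flagged non-TE.  Matches below the coverage threshold are discarded as
    false positives.
    """
    if not repeat_library:
        raise ValueError("repeat library is empty")
    by_id = {a.id: a for a in catalog.arrays}
    members = sorted((by_id[m] for m in family.members if m in by_id),
                     key=lambda a: (-a.percent_match, a.start))[:max_members]
    best = (0.0, None, None)
    for entry in repeat_library:
        name, klass = parse_library_header(entry.id)
        for arr in members:
            seq = arr.array_sequence[:_MAX_ALIGN_LEN]
            spans = _coverage_intervals(seq, entry.sequence, scoring)
            cov = _merged_length(spans) / len(seq)
            if cov > best[0]:
                best = (cov, name, klass)
    cov, name, klass = best
    if name is not None and cov >= coverage_threshold:
        family.te_similarity = name
        family.te_class = klass
        family.is_te = is_te_class(klass)
    else:
        family.te_similarity = None
        family.te_class = None
        family.is_te = False
    return family


def flag_simple(family: TRFamily, min_complex_monomer: int = 10) -> bool:
    """True for simple-sequence families: monomer below the complexity
    threshold, or a representative whose non-overlapping dinucleotide
    entropy falls below 1 bit (e.g. pure (AT)n)."""
    if family.min_monomer < min_complex_monomer:
        return True
    return dinucleotide_entropy(family.representative) < 1.0


def dinucleotide_entropy(seq: str) -> float:
    """Min over the two phases of the Shannon entropy (bits) of the cyclic
    non-overlapping dinucleotide composition; 0 for a single repeated
    dinucleotide."""
    if len(seq) < 2:
        return 0.0
    doubled = seq + seq
    best = float("inf")
    for phase in (0, 1):
        counts: dict[str, int] = defaultdict(int)
        for i in range(phase, phase + len(seq) - 1, 2):
            counts[doubled[i:i + 2]] += 1
        total = sum(counts.values())
        h = -sum((c / total) * math.log2(c / total) for c in counts.values())
        best = min(best, h)
    return best


def family_diagnostics(families: list[TRFamily], catalog: ArrayCatalog,
                       max_spread: float = 30.0) -> list[dict]:
    """Automated replacement for a manual per-family error check: families
    whose member-consensus pairwise identities spread over more than
    ``max_spread`` percentage points are flagged for review (never edited)."""
    by_id = {a.id: a for a in catalog.arrays}
    report = []
    for f in families:
        members = [by_id[m] for m in f.members if m in by_id]
        idents: list[float] = []
        for i in range(len(members)):
            for j in range(i + 1, min(len(members), i + 6)):
                a, b = members[i].consensus_monomer, members[j].consensus_monomer
                res = edlib.align(a, b, mode="NW")
                idents.append(100.0 * (1 - res["editDistance"] / max(len(a), len(b))))
        spread = (max(idents) - min(idents)) if idents else 0.0
        report.append({"name": f.name or f.family_id, "n_members": len(members),
                       "identity_spread": round(spread, 1),
                       "flagged": spread > max_spread})
    return report
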
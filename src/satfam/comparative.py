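"""Cross-assembly family comparison, in-silico chromosome assignment, and
genome-abundance estimation from raw reads."""
from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations

from ._align import revcomp
from .families import DEFAULT_SCORING, BlastnScoring, _UnionFind
from .model import AbundanceEstimate, ChromMap, SequenceRecord, TRFamily

# a bare monomer can be far too short to ever reach the pair-score threshold
# (a 20-mer caps at score 40), so representatives are tandem-extended before
# cross-assembly scoring, mirroring how whole arrays align within an assembly
_REP_MIN_LEN = 400


@dataclass
class AssemblyFamilySets:
    """Named family sets per assembly plus the equivalence links between
    them (symmetric; at most one partner per family per other assembly)."""

    sets: dict[str, list[TRFamily]]
    links: list[tuple[tuple[str, str], tuple[str, str], int]] = field(default_factory=list)
    # each link: ((assembly_a, family_name_a), (assembly_b, family_name_b), score)


def _extended_rep(family: TRFamily) -> str:
    rep = family.representative
    if not rep:
        return ""
    reps = max(1, -(-_REP_MIN_LEN // len(rep)))
    return rep * reps


def match_families_across(sets: dict[str, list[TRFamily]],
                          score_threshold: int = 200,
                          scoring: BlastnScoring = DEFAULT_SCORING
                          ) -> AssemblyFamilySets:
    """Link equivalent families between assemblies.

    Families in different assemblies are equivalent iff their tandem-extended
    representatives reach a local-alignment score above the threshold; per
    assembly pair each family keeps only its best reciprocal partner, so a
    family maps to at most one family in any other assembly.  Symmetric in
    assembly order.
    """
    aligner = scoring.aligner()
    result = AssemblyFamilySets(sets=sets)
    for asm_a, asm_b in combinations(sorted(sets), 2):
        scored = []
        for fa in sets[asm_a]:
            ra = _extended_rep(fa)
            for fb in sets[asm_b]:
                rb = _extended_rep(fb)
                if not ra or not rb:
                    continue
                s = int(aligner.score(ra, rb))
                s = max(s, int(aligner.score(ra, revcomp(rb))))
                if s > score_threshold:
                    scored.append((s, fa.name, fb.name))
        scored.sort(key=lambda t: (-t[0], t[1], t[2]))
        used_a: set[str] = set()
        used_b: set[str] = set()
        for s, na, nb in scored:
            if na in used_a or nb in used_b:
                continue
            used_a.add(na)
            used_b.add(nb)
            result.links.append(((asm_a, na), (asm_b, nb), s))
    return result


def intersection_classes(linked: AssemblyFamilySets) -> dict[frozenset, int]:
    """Partition family-equivalence groups by the set of assemblies they
    appear in.  Classes are disjoint and exhaustive over the union of
    families across assemblies."""
    nodes = [(asm, f.name) for asm, fams in linked.sets.items() for f in fams]
    uf = _UnionFind(nodes)
    for a, b, _ in linked.links:
        uf.union(a, b)
    groups: dict[tuple, set[str]] = defaultdict(set)
    for node in nodes:
        groups[uf.find(node)].add(node[0])
    classes: dict[frozenset, int] = defaultdict(int)
    for assemblies in groups.values():
        classes[frozenset(assemblies)] += 1
    return dict(classes)


def shared_by_at_least(classes: dict[frozenset, int], k: int = 2) -> int:
    return sum(n for asms, n in classes.items() if len(asms) >= k)


def assign_chromosomes(family: TRFamily, chrom_map: ChromMap | None) -> set[str]:
    """Union of chromosome labels over the contigs bearing member arrays.

    Group labels (e.g. "9–10" for chromosomes that could not be separated
    during sorting) are preserved verbatim; with no map every family gets
    {"NA"}.
    """
    if chrom_map is None:
        family.chromosomes = {ChromMap.NA}
        return family.chromosomes
    labels = set()
    for mid in family.members:
        contig = mid.rsplit(":", 1)[0]
        labels.add(chrom_map[contig])
    family.chromosomes = labels
    return labels


def estimate_abundance(family: TRFamily, family_sequences: list[str],
                       reads: list[SequenceRecord],
                       min_kmer_fraction: float = 0.5,
                       k: int = 21) -> AbundanceEstimate:
    """Fraction of raw reads attributable to a family's arrays.

    A read counts as aligned when at least ``min_kmer_fraction`` of its
    k-mers (either strand) occur in the k-mer set of the family's array
    sequences — the native stand-in for a sensitive local read alignment.
    The percentage of aligned reads is the family's "% in genome".  Reads
    shorter than k are excluded from the denominator with a warning.
    """
    if not reads:
        raise ValueError("no reads supplied")
    if not family_sequences:
        raise ValueError(f"family {family.name!r} has no member array sequences")
    kmers: set[str] = set()
    for seq in family_sequences:
        for i in range(len(seq) - k + 1):
            kmers.add(seq[i:i + k])
    aligned = 0
    total = 0
    skipped = 0
    for read in reads:
        seq = read.sequence
        n = len(seq) - k + 1
        if n < 1:
            skipped += 1
            continue
        total += 1
        in_set = sum(1 for i in range(n)
                     if seq[i:i + k] in kmers or revcomp(seq[i:i + k]) in kmers)
        if in_set >= min_kmer_fraction * n:
            aligned += 1
    if skipped:
        warnings.warn(f"{skipped} reads shorter than k={k} excluded from the "
                      f"denominator", stacklevel=2)
    return AbundanceEstimate(family=family.name or str(family.family_id),
                             reads_aligned=aligned, reads_total=total)
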
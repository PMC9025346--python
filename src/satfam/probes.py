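"""Selection of probe-worthy TR families and design of FISH oligo probes.

Probe-worthy families lack transposable-element similarity (gene-fragment
hits such as Zn-finger are allowed), have monomers of at least 10 bp (no
simple repeats) and occur in at least two assemblies.  Probes are 18-27 nt
windows of the most homogeneous array's consensus monomer, gated on GC,
homopolymer runs, self-complementarity and cross-family uniqueness, and the
survivor hitting the largest fraction of the family's arrays wins.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._align import (gc_percent, has_hit_either_strand, max_homopolymer,
                     mismatch_hits, revcomp, self_complementarity)
from .model import ArrayCatalog, Probe, SelectionCriteria, TRArray, TRFamily


@dataclass(frozen=True)
class ProbeFilters:
    """QC gates a candidate oligo must pass."""

    length_range: tuple[int, int] = (18, 27)
    gc_range: tuple[float, float] = (35.0, 65.0)
    max_homopolymer: int = 4
    max_self_complementarity: int = 8
    cross_family_max_mismatches: int = 2
    hit_max_mismatches: int = 2


class ProbeDesignError(ValueError):
    """No candidate window survived the filters; message lists which filters
    killed how many candidates."""


def select_probe_families(family_table: pd.DataFrame,
                          assembly_cooccurrence: dict[str, int],
                          criteria: SelectionCriteria = SelectionCriteria()
                          ) -> pd.DataFrame:
    """Apply the probe-selection criteria to a family table.

    ``family_table`` needs columns name / min_monomer / library_class /
    abundance_percent (and optionally max_array_len, reported alongside so
    long-array two-assembly rescues stay visible).  ``assembly_cooccurrence``
    maps family name -> number of assemblies it occurs in.  Returns the
    passing rows ranked by abundance, descending.
    """
    if family_table.empty:
        return family_table
    df = family_table.copy()

    def te(row) -> bool:
        klass = str(row.get("library_class", "") or "")
        if not klass:
            return False
        from .io import is_te_class
        return is_te_class(klass)

    keep = []
    for _, row in df.iterrows():
        if criteria.require_te_free and te(row):
            continue
        if int(row["min_monomer"]) < criteria.min_monomer:
            continue
        if assembly_cooccurrence.get(str(row["name"]), 1) < criteria.min_assemblies:
            continue
        keep.append(row)
    if not keep:
        return df.iloc[0:0]
    out = pd.DataFrame(keep)
    return out.sort_values("abundance_percent", ascending=False,
                           kind="mergesort").reset_index(drop=True)


def rank_arrays_by_homogeneity(family: TRFamily,
                               catalog: ArrayCatalog) -> list[TRArray]:
    """Members ordered by descending homogeneity (percent match), ties by
    longer array, then coordinate."""
    by_id = {a.id: a for a in catalog.arrays}
    members = [by_id[m] for m in family.members if m in by_id]
    if not members:
        raise ValueError(f"family {family.name!r} has no resolvable members")
    return sorted(members, key=lambda a: (-a.percent_match,
                                          -(a.end - a.start),
                                          a.contig_id, a.start))


def probe_qc(sequence: str) -> dict:
    """Independent re-check of every probe gate on a bare oligo sequence."""
    return {
        "length": len(sequence),
        "gc_percent": gc_percent(sequence),
        "max_homopolymer": max_homopolymer(sequence),
        "self_complementarity": self_complementarity(sequence),
    }


def validate_probe(probe: Probe, filters: ProbeFilters = ProbeFilters()) -> dict[str, bool]:
    qc = probe_qc(probe.sequence)
    lo, hi = filters.length_range
    glo, ghi = filters.gc_range
    return {
        "length": lo <= qc["length"] <= hi,
        "gc": glo <= qc["gc_percent"] <= ghi,
        "homopolymer": qc["max_homopolymer"] <= filters.max_homopolymer,
        "self_complementarity":
            qc["self_complementarity"] <= filters.max_self_complementarity,
        "cross_family": not probe.cross_family_hit,
    }


def _candidate_windows(consensus: str, length_range: tuple[int, int]):
    """All windows in the length range over the tandem-tiled consensus,
    wrapping across the monomer junction; short monomers are tiled until the
    longest window fits."""
    lo, hi = length_range
    p = len(consensus)
    reps = max(2, -(-(hi + p) // p))
    tiled = consensus * reps
    for start in range(p):
        for length in range(lo, hi + 1):
            yield start, tiled[start:start + length]


def design_probe(family: TRFamily, catalog: ArrayCatalog,
                 other_families: list[TRFamily] | None = None,
                 length_range: tuple[int, int] = (18, 27),
                 filters: ProbeFilters | None = None) -> Probe:
    """Design one oligo probe for a family.

    The source sequence is the consensus monomer of the family's most
    homogeneous array.  Every window in the length range is screened through
    the QC gates; of the survivors, the window found (at <= 2 mismatches,
    either strand) in the largest fraction of the family's arrays is
    returned.  Deterministic: ties break on position then length.
    """
    if filters is None:
        filters = ProbeFilters(length_range=length_range)
    ranked = rank_arrays_by_homogeneity(family, catalog)
    consensus = ranked[0].consensus_monomer
    if not consensus:
        raise ProbeDesignError(f"family {family.name!r}: representative has no consensus")
    others = [f for f in (other_families or []) if f.family_id != family.family_id]
    other_reps = [(f.representative * 2) for f in others if f.representative]
    member_seqs = [a.array_sequence for a in ranked]

    failed = {"gc": 0, "homopolymer": 0, "self_complementarity": 0, "cross_family": 0}
    best: tuple[float, int, int, Probe] | None = None
    seen: set[str] = set()
    for start, window in _candidate_windows(consensus, filters.length_range):
        if window in seen:
            continue
        seen.add(window)
        gc = gc_percent(window)
        if not (filters.gc_range[0] <= gc <= filters.gc_range[1]):
            failed["gc"] += 1
            continue
        if max_homopolymer(window) > filters.max_homopolymer:
            failed["homopolymer"] += 1
            continue
        sc = self_complementarity(window)
        if sc > filters.max_self_complementarity:
            failed["self_complementarity"] += 1
            continue
        cross = any(
            mismatch_hits(rep, window, filters.cross_family_max_mismatches) > 0
            or mismatch_hits(rep, revcomp(window), filters.cross_family_max_mismatches) > 0
            for rep in other_reps)
        if cross:
            failed["cross_family"] += 1
            continue
        coverage = sum(
            has_hit_either_strand(seq, window, filters.hit_max_mismatches)
            for seq in member_seqs) / len(member_seqs)
        key = (-coverage, start, len(window))
        if best is None or key < (-best[0], best[1], best[2]):
            best = (coverage, start, len(window),
                    Probe(family=family.name or str(family.family_id),
                          sequence=window, gc_percent=gc, position=start,
                          max_homopolymer=max_homopolymer(window),
                          self_complementarity=sc, cross_family_hit=False,
                          array_coverage=coverage))
    if best is None:
        detail = ", ".join(f"{k}: {v}" for k, v in failed.items() if v)
        raise ProbeDesignError(
            f"family {family.name!r}: no {filters.length_range[0]}-"
            f"{filters.length_range[1]} nt window passed the filters ({detail})")
    return best[3]
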
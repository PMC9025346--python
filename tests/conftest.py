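"""Shared fixtures: the reference synthetic study analysed once per session,
plus independent oracle implementations used to cross-check the package."""
from __future__ import annotations

import numpy as np
import pytest

import satfam as sf
from satfam.catalog import remove_redundant
from satfam.families import (annotate_library, assign_names, cluster_families,
                             score_pairs)
from satfam.comparative import intersection_classes, match_families_across

SCENARIO_SEED = 11


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def scenario():
    """The three-assembly synthetic study, fully analysed: detection,
    redundancy removal, clustering, naming, TE annotation, cross-assembly
    linking."""
    assemblies, truth, library, reads, read_counts = \
        sf.three_assembly_scenario(SCENARIO_SEED)
    catalogs = {}
    fam_sets = {}
    for asm, recs in assemblies.items():
        arrays = sf.detect_all(recs)
        cat = remove_redundant(arrays, assembly_id=asm)
        fams = cluster_families(cat, score_pairs(cat))
        assign_names(fams, species_prefix="", assembly_id=asm)
        catalogs[asm] = cat
        fam_sets[asm] = fams
    for asm in assemblies:
        for f in fam_sets[asm]:
            annotate_library(f, catalogs[asm], library)
    linked = match_families_across(fam_sets)
    classes = intersection_classes(linked)
    return {
        "assemblies": assemblies, "truth": truth, "library": library,
        "reads": reads, "read_counts": read_counts, "catalogs": catalogs,
        "fam_sets": fam_sets, "linked": linked, "classes": classes,
    }


# ---------------------------------------------------------------------------
# Independent oracles

def brute_force_nonredundant(intervals: list[tuple[str, int, int, int]]
                             ) -> set[tuple[str, int, int]]:
    """O(n^2) reference for the redundancy rules over (contig, start, end,
    period) tuples: drop identical-coordinate larger periods, then drop any
    interval contained in another."""
    survivors = {}
    for contig, s, e, p in intervals:
        key = (contig, s, e)
        if key not in survivors or p < survivors[key]:
            survivors[key] = p
    kept = set()
    items = list(survivors)
    for key in items:
        contig, s, e = key
        contained = any(
            c2 == contig and (s2, e2) != (s, e) and s2 <= s and e <= e2
            for (c2, s2, e2) in items)
        if not contained:
            kept.add(key)
    return kept


def gotoh_local_score(a: str, b: str, match: int = 2, mismatch: int = -3,
                      gap_open: int = 7, gap_extend: int = 2) -> int:
    """Textbook affine-gap Smith-Waterman (first gap base costs gap_open,
    each further base gap_extend).  Plain Python; independent of the
    package's aligner."""
    n, m = len(a), len(b)
    NEG = -10 ** 9
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best
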
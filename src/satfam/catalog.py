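"""Redundancy removal over raw detections -> the non-redundant array catalog.

Rules, applied coordinate-wise per contig:
  1. among arrays sharing identical (contig, start, end), only the smallest
     monomer period survives (ties: higher score, then lexicographically
     smaller consensus);
  2. any array whose interval is contained within another array's interval on
     the same contig is discarded;
  3. partially overlapping arrays are independent and both kept.
Both passes are order-independent and the whole operation is idempotent.
"""
from __future__ import annotations

from collections import defaultdict

import numpy as np

from .model import ArrayCatalog, TRArray


def remove_redundant(arrays: list[TRArray], assembly_id: str = "",
                     provenance: dict | None = None) -> ArrayCatalog:
    """Build the non-redundant catalog ("TR fields") from raw detections."""
    groups: dict[tuple[str, int, int], list[TRArray]] = defaultdict(list)
    for a in arrays:
        groups[(a.contig_id, a.start, a.end)].append(a)

    # identical-coordinate rule first, so containment only ever compares
    # distinct intervals
    winners = [min(g, key=lambda a: (a.period, -a.score, a.consensus_monomer))
               for g in groups.values()]

    by_contig: dict[str, list[TRArray]] = defaultdict(list)
    for a in winners:
        by_contig[a.contig_id].append(a)

    kept: list[TRArray] = []
    for contig in sorted(by_contig):
        # sweep sorted by (start asc, end desc): an array is embedded iff an
        # earlier array in this order reaches at least as far right
        items = sorted(by_contig[contig], key=lambda a: (a.start, -a.end))
        max_end = -1
        for a in items:
            if a.end <= max_end:
                continue  # embedded in a previously seen array
            kept.append(a)
            max_end = a.end

    kept.sort(key=lambda a: (a.contig_id, a.start, a.end))
    return ArrayCatalog(assembly_id=assembly_id, arrays=kept,
                        provenance=provenance or {})


def catalog_stats(catalog: ArrayCatalog) -> dict:
    """Field count, total bp (each interval counted once; overlapping
    independent arrays may double-cover genome positions) and a per-period
    histogram."""
    periods = [a.period for a in catalog.arrays]
    hist: dict[int, int] = {}
    for p in periods:
        hist[p] = hist.get(p, 0) + 1
    return {
        "n_fields": len(catalog.arrays),
        "total_bp": int(sum(a.end - a.start for a in catalog.arrays)),
        "period_histogram": dict(sorted(hist.items())),
        "median_period": float(np.median(periods)) if periods else 0.0,
    }
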
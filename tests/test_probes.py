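"""Probe-family selection against the packaged reference catalog, homogeneity
ranking, oligo design and the independent QC checker."""
import numpy as np
import pytest

from satfam.model import ArrayCatalog, SelectionCriteria, TRArray, TRFamily
from satfam.probes import (ProbeDesignError, ProbeFilters, design_probe,
                           probe_qc, rank_arrays_by_homogeneity,
                           select_probe_families, validate_probe)
from satfam.reference import (cooccurrence_counts, load_family_table,
                              load_probe_table)
from satfam._align import gc_percent, has_hit_either_strand

from conftest import random_dna


class TestSelection:
    def test_reference_catalog_yields_the_published_probe_set(self):
        sel = select_probe_families(load_family_table(), cooccurrence_counts())
        assert set(sel["name"]) == set(load_probe_table()["tr_family"])
        assert len(sel) == 13

    def test_ranked_by_abundance(self):
        sel = select_probe_families(load_family_table(), cooccurrence_counts())
        ab = list(sel["abundance_percent"])
        assert ab == sorted(ab, reverse=True)
        assert list(sel["name"])[0] == "33A"

    def test_short_monomer_family_excluded_despite_abundance(self):
        sel = select_probe_families(load_family_table(), cooccurrence_counts())
        assert "6A" not in set(sel["name"])

    def test_single_assembly_family_excluded(self):
        sel = select_probe_families(load_family_table(), cooccurrence_counts())
        assert "17A" not in set(sel["name"])

    def test_te_similar_families_excluded_but_gene_fragment_kept(self):
        sel = set(select_probe_families(load_family_table(),
                                        cooccurrence_counts())["name"])
        assert {"272A", "11A", "49A", "65A"}.isdisjoint(sel)
        assert "84A" in sel     # Zn-finger is a gene fragment, not a TE
        assert "33A" in sel     # SAU1.5 is a known satellite, not a TE

    def test_empty_table_empty_selection(self):
        import pandas as pd
        out = select_probe_families(pd.DataFrame(), {})
        assert out.empty


def _arr(contig, start, seq, period, pm):
    return TRArray(contig_id=contig, start=start, end=start + len(seq),
                   period=period, copies=len(seq) / period, percent_match=pm,
                   percent_indel=0.5, score=300,
                   consensus_monomer=seq[:period], array_sequence=seq)


class TestRanking:
    def _family(self, arrays):
        return TRFamily(family_id=0, name="f", members=[a.id for a in arrays],
                        min_monomer=min(a.period for a in arrays),
                        representative=arrays[0].consensus_monomer,
                        max_array_len=max(a.end - a.start for a in arrays),
                        gc_percent=50.0), ArrayCatalog("P", arrays)

    def test_highest_percent_match_first(self):
        a = _arr("c1", 0, "ACGT" * 100, 20, 98.0)
        b = _arr("c1", 5000, "ACGT" * 100, 20, 91.0)
        fam, cat = self._family([b, a])
        assert rank_arrays_by_homogeneity(fam, cat)[0].id == a.id

    def test_tie_broken_by_length(self):
        a = _arr("c1", 0, "ACGT" * 1000, 20, 95.0)
        b = _arr("c1", 9000, "ACGT" * 500, 20, 95.0)
        fam, cat = self._family([b, a])
        assert rank_arrays_by_homogeneity(fam, cat)[0].id == a.id


class TestDesign:
    def _perfect_family(self, seed=0, period=40, copies=20, n_arrays=3):
        rng = np.random.default_rng(seed)
        monomer = random_dna(rng, period)
        arrays = [_arr("c1", i * 5000, monomer * copies, period, 100.0)
                  for i in range(n_arrays)]
        fam = TRFamily(family_id=0, name="fam", members=[a.id for a in arrays],
                       min_monomer=period, representative=monomer,
                       max_array_len=period * copies, gc_percent=50.0)
        return fam, ArrayCatalog("P", arrays), monomer

    def test_perfect_family_probe_is_monomer_substring_with_full_coverage(self):
        fam, cat, monomer = self._perfect_family()
        probe = design_probe(fam, cat)
        assert probe.sequence in monomer * 2   # may wrap the junction
        assert probe.array_coverage == 1.0
        assert 18 <= len(probe.sequence) <= 27

    def test_every_gate_holds_on_the_returned_probe(self):
        fam, cat, _ = self._perfect_family(seed=3)
        probe = design_probe(fam, cat)
        assert all(validate_probe(probe).values())

    def test_short_monomer_uses_tandem_doubled_sequence(self):
        fam, cat, monomer = self._perfect_family(seed=5, period=13, copies=40)
        probe = design_probe(fam, cat)
        assert len(probe.sequence) >= 18
        assert probe.sequence in monomer * 4

    def test_cross_family_collision_avoided(self):
        fam, cat, monomer = self._perfect_family(seed=7)
        other = TRFamily(family_id=1, name="other", members=["c9:0-100"],
                         min_monomer=len(monomer), representative=monomer,
                         max_array_len=100, gc_percent=50.0)
        with pytest.raises(ProbeDesignError, match="cross_family"):
            design_probe(fam, cat, [fam, other])

    def test_deterministic(self):
        fam, cat, _ = self._perfect_family(seed=9)
        assert design_probe(fam, cat).sequence == design_probe(fam, cat).sequence

    def test_impossible_design_lists_failed_filters(self):
        # an all-AT monomer fails the GC gate everywhere
        arrays = [_arr("c1", 0, "AT" * 200, 20, 100.0)]
        fam = TRFamily(family_id=0, name="at", members=[arrays[0].id],
                       min_monomer=20, representative="AT" * 10,
                       max_array_len=400, gc_percent=0.0)
        with pytest.raises(ProbeDesignError, match="gc"):
            design_probe(fam, ArrayCatalog("P", arrays))


class TestPublishedOligos:
    def test_lengths_within_18_27(self):
        lengths = [len(s) for s in load_probe_table()["sequence"]]
        assert all(18 <= n <= 27 for n in lengths)

    def test_homopolymer_gate_holds_for_all_13(self):
        for seq in load_probe_table()["sequence"]:
            assert probe_qc(seq)["max_homopolymer"] <= 4

    def test_gc_of_lead_oligo_counted_by_hand(self):
        seq = load_probe_table().iloc[0]["sequence"]
        by_hand = 100.0 * sum(1 for b in seq if b in "GC") / len(seq)
        assert gc_percent(seq) == pytest.approx(by_hand)
        assert 35.0 <= by_hand <= 65.0


class TestScenarioProbes:
    def test_probes_cover_at_least_90_percent_of_arrays(self, scenario):
        from satfam.probes import design_probe
        fams = scenario["fam_sets"]["A1"]
        cat = scenario["catalogs"]["A1"]
        by_id = {a.id: a for a in cat.arrays}
        for f in fams:
            if f.is_te:
                continue
            probe = design_probe(f, cat, fams)
            hits = sum(has_hit_either_strand(by_id[m].array_sequence, probe.sequence)
                       for m in f.members)
            assert hits / len(f.members) >= 0.9
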
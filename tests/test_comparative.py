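"""Cross-assembly intersection, chromosome assignment and read abundance."""
import numpy as np
import pytest

from satfam.comparative import (assign_chromosomes, estimate_abundance,
                                intersection_classes, match_families_across,
                                shared_by_at_least)
from satfam.model import ChromMap, SequenceRecord, TRFamily
from satfam.reference import load_cooccurrence
from satfam.simulate import make_reads, make_assemblies
from satfam.model import ImplantSpec

from conftest import random_dna


def fam(name, rep, members=None):
    return TRFamily(family_id=0, name=name, members=members or ["c1:0-100"],
                    min_monomer=len(rep), representative=rep,
                    max_array_len=100, gc_percent=50.0)


class TestCrossAssembly:
    def test_shared_monomer_links_all_three(self):
        rng = np.random.default_rng(0)
        shared = random_dna(rng, 40)
        other = random_dna(rng, 60)
        third = random_dna(rng, 80)
        sets = {
            "P": [fam("F1", shared), fam("F2", other)],
            "Q": [fam("F1q", shared)],
            "R": [fam("F1r", shared), fam("F3", third)],
        }
        classes = intersection_classes(match_families_across(sets))
        assert classes[frozenset({"P", "Q", "R"})] == 1
        assert classes[frozenset({"P"})] == 1
        assert classes[frozenset({"R"})] == 1

    def test_symmetric_in_assembly_order(self):
        rng = np.random.default_rng(1)
        shared = random_dna(rng, 50)
        a, b = fam("X", shared), fam("Y", shared)
        c1 = intersection_classes(match_families_across({"P": [a], "Q": [b]}))
        c2 = intersection_classes(match_families_across({"Q": [b], "P": [a]}))
        assert c1 == c2

    def test_classes_disjoint_and_exhaustive(self, scenario):
        # independent oracle: connected components over the link graph
        import networkx as nx
        linked = scenario["linked"]
        g = nx.Graph()
        g.add_nodes_from((asm, f.name) for asm, fl in linked.sets.items()
                         for f in fl)
        g.add_edges_from((a, b) for a, b, _ in linked.links)
        oracle: dict[frozenset, int] = {}
        for comp in nx.connected_components(g):
            key = frozenset(asm for asm, _ in comp)
            oracle[key] = oracle.get(key, 0) + 1
        assert scenario["classes"] == oracle
        assert sum(len(c) for c in nx.connected_components(g)) == \
               sum(len(fl) for fl in linked.sets.values())

    def test_published_cooccurrence_sums_to_60(self):
        classes = {k: len(v) for k, v in load_cooccurrence().items()}
        assert shared_by_at_least(classes, 2) == 60
        assert classes[frozenset({"AFTD", "AMDS", "APMK"})] == 28


class TestChromosomes:
    def test_union_of_labels(self):
        f = fam("33A", "ACGT" * 10, members=["ctgA:0-100", "ctgB:500-900"])
        cmap = ChromMap({"ctgA": "5", "ctgB": "5"})
        assert assign_chromosomes(f, cmap) == {"5"}

    def test_group_label_verbatim(self):
        f = fam("11A", "ACGT" * 10, members=["ctgC:0-100"])
        assert assign_chromosomes(f, ChromMap({"ctgC": "9–10"})) == {"9–10"}

    def test_no_map_gives_na(self):
        f = fam("x", "ACGT" * 10)
        assert assign_chromosomes(f, None) == {"NA"}

    def test_unmapped_contig_gives_na_label(self):
        f = fam("x", "ACGT" * 10, members=["mystery:0-100"])
        assert assign_chromosomes(f, ChromMap({"other": "3"})) == {"NA"}


class TestAbundance:
    def test_percent_is_aligned_over_total(self):
        rng = np.random.default_rng(3)
        monomer = random_dna(rng, 50)
        family_seq = monomer * 10
        reads = [SequenceRecord(f"in{i}", family_seq[i:i + 100]) for i in range(50)]
        reads += [SequenceRecord(f"bg{i}", random_dna(rng, 100)) for i in range(9950)]
        est = estimate_abundance(fam("f", monomer), [family_seq], reads)
        assert est.reads_total == 10000 and est.reads_aligned == 50
        assert est.percent == pytest.approx(0.5)

    def test_short_reads_excluded_with_warning(self):
        rng = np.random.default_rng(4)
        seq = random_dna(rng, 200)
        reads = [SequenceRecord("ok", seq[:100]), SequenceRecord("tiny", "ACGT")]
        with pytest.warns(UserWarning, match="shorter than k"):
            est = estimate_abundance(fam("f", seq[:20]), [seq], reads)
        assert est.reads_total == 1

    def test_disjoint_families_are_additive(self):
        rng = np.random.default_rng(5)
        m1, m2 = random_dna(rng, 60), random_dna(rng, 60)
        g = random_dna(rng, 3000) + m1 * 20 + random_dna(rng, 3000) \
            + m2 * 20 + random_dna(rng, 3000)
        reads = [SequenceRecord(f"r{i}", g[int(p):int(p) + 100])
                 for i, p in enumerate(np.linspace(0, len(g) - 100, 2000))]
        e1 = estimate_abundance(fam("f1", m1), [m1 * 20], reads)
        e2 = estimate_abundance(fam("f2", m2), [m2 * 20], reads)
        both = estimate_abundance(fam("f12", m1), [m1 * 20, m2 * 20], reads)
        assert abs((e1.reads_aligned + e2.reads_aligned) - both.reads_aligned) <= 2

    def test_recovers_implanted_fraction_within_three_sigma(self):
        specs = [ImplantSpec(name="f1", monomer_length=50, substitution_rate=0.0,
                             copies=(20, 20), n_arrays=5)]
        assemblies, truth = make_assemblies(specs, 1, [100_000], 0.5, seed=9)
        reads, counts = make_reads(assemblies["A1"], 100, 20.0, 0.0, seed=9,
                                   truth=truth, assembly_id="A1")
        frac = truth.fractions["f1"]["A1"]
        arrs = [assemblies["A1"][c_i].sequence[s:e]
                for (cid, s, e) in truth.intervals["f1"]["A1"]
                for c_i, rec in enumerate(assemblies["A1"]) if rec.id == cid]
        est = estimate_abundance(fam("f1", truth.monomers["f1"]), arrs, reads)
        sigma = float(np.sqrt(frac * (1 - frac) / est.reads_total))
        assert abs(est.percent / 100 - frac) <= 3 * sigma + 0.0005
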
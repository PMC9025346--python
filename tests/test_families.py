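"""Pairwise scoring, single-linkage clustering, nomenclature, repeat-library
annotation and simple-sequence flagging."""
import subprocess

import numpy as np
import pytest

from satfam.catalog import remove_redundant
from satfam.families import (DEFAULT_SCORING, annotate_library, assign_names,
                             cluster_families, dinucleotide_entropy,
                             flag_simple, score_pairs)
from satfam.model import ArrayCatalog, PairMatch, SequenceRecord, TRArray, TRFamily
from satfam.io import write_fasta

from conftest import gotoh_local_score, random_dna


def arr(contig, start, seq, period=20, pm=95.0):
    return TRArray(contig_id=contig, start=start, end=start + len(seq),
                   period=period, copies=len(seq) / period, percent_match=pm,
                   percent_indel=1.0, score=200, consensus_monomer=seq[:period],
                   array_sequence=seq)


def catalog(arrays, asm="P"):
    return ArrayCatalog(assembly_id=asm, arrays=arrays)


def mutate(seq, rate, rng):
    out = list(seq)
    for pos in np.nonzero(rng.random(len(seq)) < rate)[0]:
        out[pos] = "ACGT"[("ACGT".index(out[pos]) + 1 + rng.integers(3)) % 4]
    return "".join(out)


class TestScorePairs:
    def test_identical_arrays_score_is_two_per_base(self):
        seq = random_dna(np.random.default_rng(0), 500)
        cat = catalog([arr("c1", 0, seq), arr("c1", 1000, seq)])
        matches = score_pairs(cat)
        assert len(matches) == 1
        assert matches[0].score == 1000   # +2 reward over 500 matched bases

    def test_random_pairs_never_pass_evalue_gate(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(100):
            a, b = random_dna(rng, 200), random_dna(rng, 200)
            cat = catalog([arr("c1", 0, a), arr("c1", 500, b)])
            hits += len(score_pairs(cat))
        assert hits == 0

    def test_score_equals_textbook_smith_waterman(self):
        # 20 related pairs (so the seed prefilter admits them); raw scores
        # must equal an independent affine-gap DP
        rng = np.random.default_rng(4)
        aligner = DEFAULT_SCORING.aligner()
        for _ in range(20):
            n = int(rng.integers(150, 300))
            template = random_dna(rng, n)
            a = mutate(template, 0.1, rng)
            b = mutate(template, 0.1, rng)
            cat = catalog([arr("c1", 0, a), arr("c1", 1000, b)])
            matches = score_pairs(cat, evalue_max=1e300)
            oracle = gotoh_local_score(a, b)
            assert matches and matches[0].score == oracle
            assert int(aligner.score(a, b)) == oracle

    def test_scores_agree_with_blastn(self, tmp_path):
        # independent external oracle: NCBI blastn under the same weights
        rng = np.random.default_rng(6)
        template = random_dna(rng, 400)
        a, b = mutate(template, 0.03, rng), mutate(template, 0.03, rng)
        qf, sf_ = tmp_path / "q.fa", tmp_path / "s.fa"
        write_fasta([SequenceRecord("q", a)], qf)
        write_fasta([SequenceRecord("s", b)], sf_)
        res = subprocess.run(
            ["blastn", "-query", str(qf), "-subject", str(sf_), "-task", "blastn",
             "-reward", "2", "-penalty", "-3", "-gapopen", "5", "-gapextend", "2",
             "-dust", "no", "-outfmt", "6 score"],
            capture_output=True, text=True, check=True)
        blast_best = max(int(x) for x in res.stdout.split())
        cat = catalog([arr("c1", 0, a), arr("c1", 1000, b)])
        ours = score_pairs(cat, evalue_max=1e300)[0].score
        assert abs(ours - blast_best) <= 0.02 * ours


class TestClustering:
    def _cat3(self):
        seqs = [random_dna(np.random.default_rng(i), 300) for i in range(3)]
        return catalog([arr("c1", i * 1000, s) for i, s in enumerate(seqs)])

    def _pm(self, cat, i, j, score):
        a, b = cat.arrays[i].id, cat.arrays[j].id
        return PairMatch(array_a=a, array_b=b, score=score, evalue=1e-30)

    def test_transitive_closure(self):
        cat = self._cat3()
        matches = [self._pm(cat, 0, 1, 250), self._pm(cat, 1, 2, 210),
                   self._pm(cat, 0, 2, 150)]
        fams = cluster_families(cat, matches)
        assert len(fams) == 1 and len(fams[0].members) == 3

    def test_below_threshold_stays_split(self):
        cat = self._cat3()
        fams = cluster_families(cat, [self._pm(cat, 0, 1, 150)])
        assert len(fams) == 3

    def test_threshold_is_strict(self):
        cat = self._cat3()
        assert len(cluster_families(cat, [self._pm(cat, 0, 1, 200)])) == 3
        assert len(cluster_families(cat, [self._pm(cat, 0, 1, 201)])) == 2

    def test_matches_networkx_connected_components(self):
        import networkx as nx
        rng = np.random.default_rng(10)
        for _ in range(500):
            n = int(rng.integers(2, 50))
            seqs = ["A" * 100 for _ in range(n)]
            arrays = [arr(f"c1", i * 500, seqs[i]) for i in range(n)]
            cat = catalog(arrays)
            edges = []
            g = nx.Graph()
            g.add_nodes_from(a.id for a in arrays)
            for _ in range(int(rng.integers(0, 2 * n))):
                i, j = rng.integers(0, n, 2)
                if i == j:
                    continue
                score = int(rng.integers(100, 300))
                edges.append(PairMatch(arrays[i].id, arrays[j].id, score, 1e-30))
                if score > 200:
                    g.add_edge(arrays[i].id, arrays[j].id)
            fams = cluster_families(cat, edges)
            ours = {frozenset(f.members) for f in fams}
            oracle = {frozenset(c) for c in nx.connected_components(g)}
            assert ours == oracle

    def test_partition_covers_catalog_once(self):
        cat = self._cat3()
        fams = cluster_families(cat, [self._pm(cat, 0, 1, 500)])
        member_ids = [m for f in fams for m in f.members]
        assert sorted(member_ids) == sorted(a.id for a in cat.arrays)


class TestNaming:
    def _families(self, periods_positions):
        arrays, fams = [], []
        for i, (period, start) in enumerate(periods_positions):
            a = arr("c1", start, "ACGT" * 50, period=period)
            arrays.append(a)
            fams.append(TRFamily(family_id=i, members=[a.id], min_monomer=period,
                                 representative="ACGT" * 6, max_array_len=200,
                                 gc_percent=50.0))
        return fams

    def test_numeral_is_min_monomer(self):
        fams = assign_names(self._families([(33, 100)]), species_prefix="")
        assert fams[0].name == "33A"

    def test_same_numeral_disambiguated_by_occurrence(self):
        fams = assign_names(self._families([(24, 5000), (24, 100)]),
                            species_prefix="")
        by_start = sorted(fams, key=lambda f: f.members[0])
        named = {f.members[0].split(":")[1].split("-")[0]: f.name for f in fams}
        assert named["100"] == "24A" and named["5000"] == "24B"

    def test_prefix_and_singleton(self):
        fams = assign_names(self._families([(13, 0)]), species_prefix="CG")
        assert fams[0].name == "CG13A"

    def test_deterministic_under_permutation(self):
        fams1 = assign_names(self._families([(24, 100), (24, 900), (33, 50)]),
                             species_prefix="")
        fams2 = assign_names(self._families([(24, 900), (33, 50), (24, 100)]),
                             species_prefix="")
        names1 = {f.members[0]: f.name for f in fams1}
        names2 = {f.members[0]: f.name for f in fams2}
        assert names1 == names2

    def test_more_than_26_same_numeral_gets_double_letters(self):
        fams = assign_names(self._families([(10, i * 300) for i in range(28)]),
                            species_prefix="")
        names = sorted(f.name for f in fams)
        assert "10AA" in names and "10AB" in names


class TestAnnotation:
    def test_tandemized_library_fragment_fully_covered(self):
        rng = np.random.default_rng(12)
        te = SequenceRecord("TE1#LTR/ERV", random_dna(rng, 600))
        frag = te.sequence[100:160]
        a = arr("c1", 0, frag * 10, period=60)
        cat = catalog([a])
        fam = TRFamily(family_id=0, members=[a.id], min_monomer=60,
                       representative=frag, max_array_len=600, gc_percent=50)
        annotate_library(fam, cat, [te])
        assert fam.te_similarity == "TE1" and fam.is_te

    def test_half_coverage_is_discarded(self):
        rng = np.random.default_rng(14)
        te = SequenceRecord("TE1#LTR/ERV", random_dna(rng, 300))
        # half the array derives from the TE, half is unrelated
        half = te.sequence[:150]
        a = arr("c1", 0, half * 2 + random_dna(rng, 300), period=150)
        cat = catalog([a])
        fam = TRFamily(family_id=0, members=[a.id], min_monomer=150,
                       representative=half, max_array_len=600, gc_percent=50)
        annotate_library(fam, cat, [te])
        assert fam.te_similarity is None

    def test_gene_fragment_recorded_but_not_te(self):
        rng = np.random.default_rng(16)
        gene = SequenceRecord("ZnF#Gene", random_dna(rng, 400))
        frag = gene.sequence[50:130]
        a = arr("c1", 0, frag * 8, period=80)
        cat = catalog([a])
        fam = TRFamily(family_id=0, members=[a.id], min_monomer=80,
                       representative=frag, max_array_len=640, gc_percent=50)
        annotate_library(fam, cat, [gene])
        assert fam.te_similarity == "ZnF" and not fam.is_te

    def test_empty_library_is_error(self):
        a = arr("c1", 0, "ACGT" * 50)
        fam = TRFamily(family_id=0, members=[a.id], min_monomer=20,
                       representative="ACGT" * 5, max_array_len=200, gc_percent=50)
        with pytest.raises(ValueError):
            annotate_library(fam, catalog([a]), [])


class TestSimpleFlag:
    def _fam(self, monomer, period=None):
        return TRFamily(family_id=0, members=["c1:0-100"],
                        min_monomer=period or len(monomer),
                        representative=monomer, max_array_len=100, gc_percent=50)

    def test_short_monomer_is_simple(self):
        assert flag_simple(self._fam("ACGTAC", 6))

    def test_mixed_composition_monomer_is_complex(self):
        rng = np.random.default_rng(18)
        assert not flag_simple(self._fam(random_dna(rng, 33)))

    def test_dinucleotide_repeat_is_simple_via_entropy(self):
        assert dinucleotide_entropy("ATATATATATAT") == 0.0
        assert flag_simple(self._fam("ATATATATATAT", 12))
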
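# satfam

Discovery and classification of **large tandem repeats (satellite DNA)** in
genome assemblies, with cross-assembly comparison, read-based genome
abundance estimation and FISH oligonucleotide probe design.

Satellite DNA is organized as multiple copies of a repeat unit (the
*monomer*, here 6–2000 bp) arranged head-to-tail into long arrays
("fields"), concentrated in centromeric, pericentromeric and subtelomeric
heterochromatin. Because these regions assemble poorly and evolve fast,
satellite families are usually characterized from whole-genome assemblies
and raw reads rather than from finished chromosomes. `satfam` packages that
workflow — originally run on Chinese hamster (*Cricetulus griseus*)
assemblies — as a tested, reusable library, exercisable end-to-end on
synthetic genomes with known ground truth.

## The method

1. **Detection** (`satfam.detect`). A TRF-style native detector: exact
   k-mer re-occurrence distances (k = 5 for periods ≤ 29 bp, k = 7 above)
   propose candidate monomer periods *p*; a wraparound local alignment of
   the candidate region against tandem copies of its period-phased
   majority-vote consensus verifies period, extent and score under the
   weights match +2, mismatch −5, indel −7, with PM = 80 / PI = 10,
   minimum reported score 50 and maximum period 2000 bp. Near-multiple
   periods collapse to the smallest period scoring ≥ 95% of the best.
   TRF `.dat` files can be ingested instead at the same seam.
2. **Redundancy removal** (`satfam.catalog`). Arrays embedded in another
   array's interval are discarded; among identical-coordinate arrays the
   smaller unit survives; partially overlapping arrays are independent.
3. **Family building** (`satfam.families`). All array pairs are scored by
   local alignment under blastn-default weights (+2/−3, gap 5 + 2·g) with
   an e-value gate of 1e−15 (no low-complexity masking); single-linkage
   closure over pairs with score > 200 defines the families. Families are
   named `<prefix><minimum monomer length><letter>` (e.g. `33A`, `24B`),
   and annotated against a Repbase-style repeat library: a family whose
   member array is covered ≥ 80% by one library entry records that entry,
   with transposable elements (SINE/LINE/LTR/DNA classes) flagged as TE.
4. **Comparison & abundance** (`satfam.comparative`). Families in
   different assemblies are equivalent when their tandem-extended consensus
   monomers align above the same score threshold; intersection classes
   (all assemblies, each pair, single) summarize sharing. A family's
   "% in genome" is the percentage of raw reads at least half of whose
   21-mers occur in the family's arrays (either strand).
5. **Probe design** (`satfam.probes`). Probe-worthy families have no TE
   similarity, monomers ≥ 10 bp and occur in ≥ 2 assemblies. Each probe is
   an 18–27 nt window of the most homogeneous array's consensus (wrapping
   the monomer junction) passing GC 35–65%, homopolymer ≤ 4,
   self-complementarity ≤ 8 (+1/−1 ungapped) and cross-family uniqueness
   (no hit ≤ 2 mismatches in other families), maximizing the fraction of
   family arrays carrying a ≤ 2-mismatch hit.
6. **Synthetic truth** (`satfam.simulate`). A generator implants tandem
   families (tunable monomer, copy number, per-copy divergence, optional
   TE-derived monomer) into background of tunable GC across several
   assemblies, and samples error-bearing reads — with exact, recomputable
   ground truth for every stage.

A reference dataset (`satfam.reference`) ships with the package: the
published 21-family Chinese hamster TR catalog, its assembly co-occurrence
classes and the 13 published FISH oligos, used as the desk-scale worked
example below.

## Worked example

```bash
python examples/03_reference_probe_selection.py
```

prints (abridged):

```
21 catalog families -> 13 probe-worthy:
    33A  0.5119% of genome, all three assemblies
    79A  0.4047% of genome, all three assemblies
    ...
    13A  0.0003% of genome, all three assemblies
matches the 13 published probe families: True
selected families in the all-three class: 11
```

i.e. applying the default criteria to the packaged catalog reproduces the
published probe set exactly: 13 families, 11 of them present in all three
assemblies; the abundant 6A (6 bp monomer, simple sequence), the
single-assembly 17A, and every TE-similar family are excluded, while the
gene-fragment hit 84A (Zn-finger) and the known satellite 33A (SAU1.5) pass.

Other examples cover native detection (`01`), end-to-end family discovery
on synthetic assemblies (`02`), read-based abundance (`04`) and probe
design (`05`). A thin CLI mirrors the stages:

```bash
satfam simulate --outdir sim --seed 42
satfam all --genomes sim --outdir out --library sim/library.fasta \
           --reads sim/reads_A1.fastq --reads-assembly A1
```

Every stage reads and writes flat TSV/FASTA/BED files, so an external TRF
run or aligner can be interposed at any seam.

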
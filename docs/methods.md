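# Methods

This note documents the models, parameter choices and numerical decisions
behind `satfam`, and what the synthetic studies do and do not demonstrate.

## Tandem-array detection

The native detector is a deliberately simplified variant of the classic
k-tuple / wraparound-alignment approach to tandem repeat finding.

**Candidate proposal.** Exact k-mer matches at distance *d* (k = 5 for
*d* ≤ 29, k = 7 for 30 ≤ *d* ≤ 2000) vote for a candidate period. Runs of
at least four votes at the same *d*, with inter-vote gaps ≤ max(2*d*, 40)
bp and span ≥ *d*, become candidate regions (padded by one period).
Candidates with heavily overlapping extents and periods within 20% are
merged before verification, and a region left over after a verified array
is re-verified so two nearby arrays sharing one candidate are both found.

**Verification.** The candidate window is aligned locally against tandem
copies of its period-phased majority-vote consensus (ties A<C<G<T; N casts
no vote and matches nothing) under match +2, mismatch −5, indel −7 with
linear gap costs — a Smith–Waterman scan (numba-compiled) that tracks each
cell's path start, so array boundaries come out of the same pass without a
traceback matrix. An array is emitted when the score reaches the minimum
(default 50) *and* the aligned span covers at least 1.9 monomer copies; the
copy floor prevents a non-repetitive window from trivially "matching its
own consensus" once. Divisors of the proposed period are tried whenever the
consensus is ≥ 80% self-similar under that divisor's tiling, and the
reported period is the smallest one scoring within 95% of the best, so a
21-mer array proposed at distance 42 is still reported at period 21.

**Reported statistics.** Percent match / percent indel are computed per
full monomer copy against the consensus via edit-distance alignments
(edlib), i.e. homogeneity is measured against the family consensus, not
between adjacent copies. PM/PI enter only through the candidate-window
padding, as in the statistical filter of the original tool; they are not
re-derived. Detection runs on the given strand; arrays are unstranded
objects, and the mirror-symmetry test holds to within one period at the
boundaries.

Choosing these weights (2/5/7, PM 80, PI 10, minscore 50, maxperiod 2000)
as defaults makes the native detector parameter-compatible with TRF `.dat`
ingestion, which is the compatibility seam for users who prefer the
original binary; the two paths share the `TRArray` contract.

## Redundancy rules

"Embedded" is interval containment on the same contig, regardless of period
or sequence; the identical-coordinate case is resolved first (smallest
monomer survives; ties by higher score, then lexicographically smaller
consensus), which makes the two rules disjoint and the whole operation
order-independent and idempotent (property-tested against a brute-force
O(n²) scan). Containment is deliberately contig-local. Partial overlaps
are kept as independent arrays, so catalog total-bp may double-count
overlapped genome positions — this matches the independent-array semantics
of the field counts.

## Pairwise scoring and clustering

Pair scores use `Bio.Align.PairwiseAligner` in local mode with blastn
defaults: reward +2, mismatch −3, affine gaps costing 5 + 2·g. The e-value
is Karlin–Altschul, E = K·m·n·e^(−λS) with λ = 0.625, K = 0.41 (the
tabulated constants for this scheme); the gate is 1e−15. Because score
> 200 requires only ~100 matched bases, two tractability measures are safe
and are applied: pairs must share one exact 11-mer (blastn's default word
size) before alignment, and arrays are scored on at most their first
3 kb. Scores are verified in tests against both an independent plain-Python
Gotoh dynamic program and the installed NCBI blastn under identical
parameters.

Clustering is single-linkage transitive closure (union–find with
deterministic smaller-id roots) over pairs with score strictly greater
than the threshold (default 200, configurable since the exact external
aligner build behind that calibration is unknowable). Verified equivalent
to graph connected components on 500 random graphs.

The historical "manual check for errors" is replaced by an automated
diagnostics table: families whose member-consensus pairwise identities
spread over more than 30 percentage points are flagged for review; nothing
is ever silently edited.

## Naming

Family names are `<species prefix><minimum member period><letter>`, with
letters (A…Z, AA, AB, …) assigned within each numeral by first genomic
occurrence (assembly id, contig id, start). Published catalogs do not state
their letter ordering and are inconsistent with abundance ordering, so
first-occurrence ordering was chosen purely for reproducibility: identical
inputs always yield identical names. The numeral uses the detector-reported
period of the members, not the consensus length.

## Repeat-library (TE) annotation

Coverage is computed on the member array (the reading of the 80% rule that
the selection outcomes require): library entries are aligned to up to three
of the family's most homogeneous member arrays by a greedy multi-HSP scan
(best local alignment, mask, repeat while HSP score ≥ 60, up to 40 HSPs),
and intervals are merged. If the best entry covers ≥ 80% of a member
array, the family records that entry's name and class. Classes follow the
RepeatMasker `name#class/subclass` dialect; SINE/LINE/LTR/DNA/RC classes
count as transposable elements, while satellites and gene fragments
(e.g. Zn-finger) are recorded but not TE-flagged — they survive probe
selection.

## Cross-assembly comparison

Equivalence between assemblies compares family representatives (the
consensus monomer of the most homogeneous member), not all member arrays.
A bare 20 bp monomer can never reach score 200 (maximum 2·20), so
representatives are tandem-extended to ≥ 400 bp before scoring; this
mirrors how whole arrays of the same family align within an assembly and
makes the threshold commensurate. Both strands are tried. Per assembly
pair, links are greedily assigned best-score-first with each family used
once (best reciprocal, one partner per assembly). Intersection classes are
the connected components of the link graph keyed by the set of assemblies
they span; they are disjoint and exhaustive by construction and are
cross-checked against a graph-library oracle.

## Abundance from reads

A read counts toward a family when ≥ 50% of its k-mers (k = 21, either
strand) occur in the k-mer set of the family's member arrays; the family's
"% in genome" is 100 × aligned / total reads. This k-mer containment rule
is the native stand-in for a sensitive local read alignment: the contract
(at least half the read covered by family sequence) is the same, and both
k and the fraction are configuration. Reads shorter than k are excluded
from the denominator with a warning. On synthetic reads the estimate
tracks the implanted genomic fraction to within ~2 binomial standard
deviations; the small negative bias from reads straddling array boundaries
(a read needs ~read/2 + k bases inside to count) is an order of magnitude
below the sampling noise at the study's array lengths. Families with
non-overlapping k-mer sets are additive to within a couple of reads.

## Probe selection and design

Selection keeps families with (a) no TE similarity, (b) monomer ≥ 10 bp,
(c) presence in ≥ 2 assemblies, ranked by abundance. The "long-array
rescue" for two-assembly families is reported (max array length column)
rather than enforced as a hard threshold, because the printed evidence for
any specific cut-off is contradictory; the packaged reference tables
reproduce the published 13-probe selection from (a)–(c) alone. Simple
sequences are flagged by monomer length < 10 or non-overlapping
dinucleotide entropy < 1 bit (min over the two phases, cyclic), which is 0
for a pure dinucleotide repeat.

Design enumerates every 18–27 nt window over the tandem-tiled consensus of
the top-ranked (most homogeneous) array — wrapping the monomer junction,
with short monomers tiled until the longest window fits — and gates on GC
35–65%, homopolymer run ≤ 4, ungapped antiparallel self-annealing score
≤ 8 (+1/−1), and absence from other families' doubled representatives at
≤ 2 mismatches. Among survivors the window hitting the largest fraction of
the family's arrays at ≤ 2 mismatches (either strand) wins; ties break on
position then length, so design is deterministic. Melting-temperature
screening is not modelled; the GC window stands in for it. Cross-family
uniqueness is checked against representatives only, not whole genomes — a
desk-scale compromise. If no window survives, the error lists how many
candidates each filter rejected.

## Synthetic data

The generator emulates exactly the structure the pipeline assumes: iid
background (order-1 Markov optional) of tunable GC; families defined by a
monomer drawn once and shared across the assemblies the family is declared
in; arrays of independently mutated copies (per-copy substitution and indel
rates in [0, 0.3]) overwriting background at uniform non-overlapping
positions with a 300 bp margin; an optional TE-derived family whose
monomer is a fragment of a synthetic library entry; and uniform-coverage
reads from both strands with per-base substitution errors. Truth fractions
are exact (implanted bp / genome bp, recountable from the emitted FASTA),
and one integer seed drives independent spawned streams per operation, so
outputs are bit-identical across runs and stages are regenerable in
isolation.

The reference study uses three 80 kb assemblies (two 40 kb contigs each,
GC 0.42), five families with monomers 21/40/60/90/120 bp and per-copy
substitution rates 2/5/4/8/10%, 2–3 arrays per family per assembly, one
family (60 bp) tandemizing a fragment of the synthetic ERV entry, one
family restricted to two assemblies and one private to assembly A1; reads
are 100 bp at 20× with 0.5% error. These sizes keep a full multi-assembly
run in tens of seconds while leaving every statistic (recall, class
recovery, abundance error, probe coverage) comfortably measurable.

**What passing on synthetic data does not show.** Real satellite arrays
carry higher-order repeat structure, nested TEs, segmental duplications
and assembly-collapse artifacts that the generator does not emulate; real
read sets have coverage and quality biases. Recovery of implanted truth
therefore validates the pipeline's logic and calibration, not its
behaviour on arbitrary genomes. Full-scale catalogs additionally depend on
the exact external detector/aligner builds; the flat-file seams exist
precisely so those can be interposed.

## Degenerate inputs and tie-breaks

Non-ACGTN characters become N at the I/O boundary; N matches nothing in
any scorer. Consensus ties break A<C<G<T. Identical-coordinate redundancy
ties break period → score → consensus. Union–find roots are the smallest
member id. Empty detections, empty family tables and header-only TSVs are
valid, not errors; empty FASTA/FASTQ files and malformed records are
format errors naming the offending line.
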
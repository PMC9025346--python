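"""Synthetic assemblies, repeat libraries and reads with known ground truth.

Emulates the statistical structure the pipeline assumes: iid (or order-1
Markov) background of tunable GC, implanted tandem arrays whose copies
diverge independently from a family monomer, TE-derived tandemized repeats,
several re-sampled "assemblies" sharing a family pool, and error-bearing
uniform-coverage reads.  Everything is reproducible bit-for-bit from one
integer seed; each operation draws from its own spawned stream so stages can
be regenerated independently.
"""
from __future__ import annotations

import numpy as np

from .model import ChromMap, ImplantSpec, SequenceRecord, SyntheticTruth

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_PLACEMENT_MARGIN = 300  # bp kept clear around implants so arrays stay distinct


def _rng(seed, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5,
                    markov_order1: float | None = None) -> str:
    """iid background; optionally order-1 Markov with the given probability of
    repeating the previous base (stresses detector false positives)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draws = rng.choice(4, size=length, p=p)
    if markov_order1:
        stay = rng.random(length) < markov_order1
        for i in range(1, length):
            if stay[i]:
                draws[i] = draws[i - 1]
    return _BASES[draws].tobytes().decode()


def mutate_copy(monomer: str, substitution_rate: float, indel_rate: float,
                rng: np.random.Generator) -> str:
    """One array copy: independent per-base substitutions and (rarely)
    single-base indels relative to the family monomer."""
    out = []
    for base in monomer:
        r = rng.random()
        if r < substitution_rate:
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[rng.integers(3)])
        elif r < substitution_rate + indel_rate:
            if rng.random() < 0.5:
                continue                       # deletion
            out.append(base)
            out.append("ACGT"[rng.integers(4)])  # insertion after
        else:
            out.append(base)
    return "".join(out)


def _build_array(monomer: str, copies: int, sub: float, indel: float,
                 rng: np.random.Generator) -> str:
    return "".join(mutate_copy(monomer, sub, indel, rng) for _ in range(copies))


def synthetic_te_library(seed: int = 0) -> list[SequenceRecord]:
    """A small synthetic Repbase-style repeat library: two transposable
    elements and one gene fragment (headers in name#class/subclass dialect)."""
    rng = _rng(seed, 901)
    return [
        SequenceRecord("TEsyn1#LTR/ERV", random_sequence(rng, 800), "synthetic-library"),
        SequenceRecord("TEsyn2#SINE/B1", random_sequence(rng, 200), "synthetic-library"),
        SequenceRecord("ZnFsyn#Gene", random_sequence(rng, 300), "synthetic-library"),
    ]


def make_assemblies(specs: list[ImplantSpec], n_assemblies: int,
                    contig_lengths: list[int], background_gc: float,
                    seed: int, assembly_ids: list[str] | None = None,
                    library: list[SequenceRecord] | None = None,
                    markov_order1: float | None = None
                    ) -> tuple[dict[str, list[SequenceRecord]], SyntheticTruth]:
    """Generate assemblies with implanted tandem arrays and exact truth.

    Arrays overwrite background at non-overlapping uniform positions (with a
    safety margin), so truth fractions are exactly implanted bp / genome bp.
    A spec with ``te_source`` draws its monomer as a fragment of that library
    entry, tandemizing a TE.  Raises on infeasible packing or when implants
    would exceed half the genome.
    """
    if assembly_ids is None:
        assembly_ids = [f"A{i + 1}" for i in range(n_assemblies)]
    if len(assembly_ids) != n_assemblies:
        raise ValueError("assembly_ids length must equal n_assemblies")
    lib_by_name = {r.id.split("#")[0]: r for r in (library or [])}

    truth = SyntheticTruth()
    # family monomers are drawn once, shared by every assembly the family
    # appears in (that is what makes them the same family across assemblies)
    for si, spec in enumerate(specs):
        rng = _rng(seed, 100, si)
        if spec.monomer is not None:
            monomer = spec.monomer.upper()
        elif spec.te_source is not None:
            entry = lib_by_name.get(spec.te_source)
            if entry is None:
                raise ValueError(f"library entry {spec.te_source!r} not supplied")
            if spec.monomer_length is None or spec.monomer_length > len(entry.sequence):
                raise ValueError("te-derived spec needs monomer_length <= entry length")
            off = int(rng.integers(0, len(entry.sequence) - spec.monomer_length + 1))
            monomer = entry.sequence[off:off + spec.monomer_length]
        else:
            monomer = random_sequence(rng, spec.monomer_length, gc=spec.monomer_gc)
        truth.monomers[spec.name] = monomer
        truth.te_derived[spec.name] = spec.te_source is not None
        truth.intervals[spec.name] = {}
        truth.fractions[spec.name] = {}

    assemblies: dict[str, list[SequenceRecord]] = {}
    for ai, asm in enumerate(assembly_ids):
        rng_bg = _rng(seed, 200, ai)
        contigs = [bytearray(random_sequence(rng_bg, ln, background_gc,
                                             markov_order1).encode())
                   for ln in contig_lengths]
        genome_bp = sum(contig_lengths)
        occupied: list[list[tuple[int, int]]] = [[] for _ in contigs]

        jobs = []
        for si, spec in enumerate(specs):
            present = spec.assemblies_present or tuple(assembly_ids)
            if asm not in present:
                continue
            rng_fam = _rng(seed, 300, ai, si)
            for _ in range(spec.n_arrays):
                copies = int(rng_fam.integers(spec.copies[0], spec.copies[1] + 1))
                arr = _build_array(truth.monomers[spec.name], copies,
                                   spec.substitution_rate, spec.indel_rate, rng_fam)
                jobs.append((spec.name, arr, rng_fam))
        if sum(len(j[1]) for j in jobs) > 0.5 * genome_bp:
            raise ValueError("implants exceed half the genome: infeasible packing")

        for name, arr, rng_fam in jobs:
            placed = False
            for _ in range(1000):
                ci = int(rng_fam.integers(0, len(contigs)))
                if len(contigs[ci]) < len(arr) + 2 * _PLACEMENT_MARGIN:
                    continue
                start = int(rng_fam.integers(_PLACEMENT_MARGIN,
                                             len(contigs[ci]) - len(arr) - _PLACEMENT_MARGIN))
                end = start + len(arr)
                if any(start - _PLACEMENT_MARGIN < e and s < end + _PLACEMENT_MARGIN
                       for s, e in occupied[ci]):
                    continue
                contigs[ci][start:end] = arr.encode()
                occupied[ci].append((start, end))
                truth.intervals[name].setdefault(asm, []).append(
                    (f"{asm}_c{ci + 1}", start, end))
                placed = True
                break
            if not placed:
                raise ValueError(f"could not place a {len(arr)} bp array of "
                                 f"{name!r} in assembly {asm}: infeasible packing")

        assemblies[asm] = [SequenceRecord(f"{asm}_c{i + 1}", c.decode(),
                                          f"synthetic:{seed}")
                           for i, c in enumerate(contigs)]
        truth.assembly_sizes[asm] = genome_bp
        for spec in specs:
            ivs = truth.intervals[spec.name].get(asm, [])
            truth.fractions[spec.name][asm] = \
                sum(e - s for _, s, e in ivs) / genome_bp
    return assemblies, truth


def make_reads(assembly: list[SequenceRecord], read_length: int, coverage: float,
               error_rate: float, seed: int,
               truth: SyntheticTruth | None = None, assembly_id: str | None = None
               ) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Uniform-coverage reads from both strands with per-base substitution
    errors.

    Returns the reads and, when truth is supplied, the count of reads
    originating >= 50% inside each implanted family's arrays.
    """
    if read_length > min(len(r) for r in assembly):
        raise ValueError("read length exceeds the shortest contig")
    rng = _rng(seed, 400)
    lengths = np.array([len(r) for r in assembly])
    total = int(lengths.sum())
    n_reads = int(round(coverage * total / read_length))
    contig_choice = rng.choice(len(assembly), size=n_reads, p=lengths / total)

    family_ivs: dict[str, dict[str, list[tuple[int, int]]]] = {}
    counts: dict[str, int] = {}
    if truth is not None:
        for fam, per_asm in truth.intervals.items():
            ivs = per_asm.get(assembly_id or "", []) if assembly_id else \
                [iv for lst in per_asm.values() for iv in lst]
            per_contig: dict[str, list[tuple[int, int]]] = {}
            for contig, s, e in ivs:
                per_contig.setdefault(contig, []).append((s, e))
            family_ivs[fam] = per_contig
            counts[fam] = 0

    comp = str.maketrans("ACGTN", "TGCAN")
    reads: list[SequenceRecord] = []
    for ri in range(n_reads):
        rec = assembly[contig_choice[ri]]
        start = int(rng.integers(0, len(rec) - read_length + 1))
        seq = rec.sequence[start:start + read_length]
        if rng.random() < 0.5:
            seq = seq.translate(comp)[::-1]
        if error_rate > 0:
            errs = np.nonzero(rng.random(read_length) < error_rate)[0]
            if errs.size:
                s = list(seq)
                for pos in errs:
                    cur = s[pos]
                    alts = [b for b in "ACGT" if b != cur]
                    s[pos] = alts[int(rng.integers(3))]
                seq = "".join(s)
        reads.append(SequenceRecord(f"read{ri}", seq, "synthetic-reads"))
        if truth is not None:
            for fam, per_contig in family_ivs.items():
                if any(min(start + read_length, e) - max(start, s) >= 0.5 * read_length
                       for s, e in per_contig.get(rec.id, [])):
                    counts[fam] += 1
    return reads, counts


# ---------------------------------------------------------------------------
# The package's reference synthetic study: three re-sampled assemblies
# sharing a family pool, with one TE-derived tandem.

SCENARIO_ASSEMBLIES = ("A1", "A2", "A3")
SCENARIO_CONTIGS = [40_000, 40_000]
SCENARIO_GC = 0.42
SCENARIO_READ_LENGTH = 100
SCENARIO_COVERAGE = 20.0
SCENARIO_ERROR_RATE = 0.005


def three_assembly_scenario_specs() -> list[ImplantSpec]:
    """Five families, monomers 20-120 bp, per-copy divergence 2-10%, one
    TE-derived: three shared by all assemblies, one by a pair, one private."""
    return [
        ImplantSpec(name="famA", monomer_length=21, substitution_rate=0.02,
                    copies=(30, 45), n_arrays=3, assemblies_present=SCENARIO_ASSEMBLIES),
        ImplantSpec(name="famB", monomer_length=40, substitution_rate=0.05,
                    copies=(18, 28), n_arrays=3, assemblies_present=SCENARIO_ASSEMBLIES),
        ImplantSpec(name="famTE", monomer_length=60, substitution_rate=0.04,
                    copies=(14, 22), n_arrays=2, te_source="TEsyn1",
                    assemblies_present=SCENARIO_ASSEMBLIES),
        ImplantSpec(name="famC", monomer_length=90, substitution_rate=0.08,
                    copies=(10, 16), n_arrays=2, assemblies_present=("A1", "A2")),
        ImplantSpec(name="famD", monomer_length=120, substitution_rate=0.10,
                    copies=(8, 12), n_arrays=2, assemblies_present=("A1",)),
    ]


def three_assembly_scenario(seed: int):
    """Generate the reference scenario: (assemblies, truth, library, reads,
    read truth counts).  Reads are drawn from assembly A1."""
    library = synthetic_te_library(seed)
    specs = three_assembly_scenario_specs()
    assemblies, truth = make_assemblies(
        specs, n_assemblies=3, contig_lengths=SCENARIO_CONTIGS,
        background_gc=SCENARIO_GC, seed=seed,
        assembly_ids=list(SCENARIO_ASSEMBLIES), library=library)
    reads, read_counts = make_reads(
        assemblies["A1"], SCENARIO_READ_LENGTH, SCENARIO_COVERAGE,
        SCENARIO_ERROR_RATE, seed, truth=truth, assembly_id="A1")
    return assemblies, truth, library, reads, read_counts


def scenario_chrom_map(assembly_id: str = "A2") -> ChromMap:
    """A chromosome map for the scenario's "sorted" assembly, including a
    group label for chromosomes inseparable during sorting."""
    return ChromMap({f"{assembly_id}_c1": "5", f"{assembly_id}_c2": "9–10"})
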
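"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; 1-based
inputs (TRF ``.dat``) are converted at the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """One assembly contig, library entry or generated sequence.

    ``sequence`` is uppercase over {A,C,G,T,N}; ``source`` records the file
    path or generator tag it came from.
    """

    id: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.sequence)


class ChromMap:
    """Contig -> chromosome label lookup for chromosome-sorted assemblies.

    Labels are kept verbatim, including group labels such as "9–10" for
    chromosomes that could not be separated during flow sorting.  Contigs
    absent from the table map to "NA".
    """

    NA = "NA"

    def __init__(self, mapping: dict[str, str]):
        self._map = dict(mapping)

    def __getitem__(self, contig_id: str) -> str:
        return self._map.get(contig_id, self.NA)

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._map

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()


@dataclass(frozen=True)
class DetectorParams:
    """Tandem-repeat detector scoring parameters (TRF-style).

    Defaults are the standard satellite-DNA screen: match +2, mismatch 5,
    indel (delta) 7, match/indel probabilities 80/10, minimum reported
    alignment score 50, maximum monomer length 2000 bp.
    """

    match_weight: int = 2
    mismatch_penalty: int = 5
    indel_penalty: int = 7
    pm: int = 80
    pi: int = 10
    minscore: int = 50
    maxperiod: int = 2000

    def __post_init__(self) -> None:
        for name in ("match_weight", "mismatch_penalty", "indel_penalty",
                     "pm", "pi", "minscore", "maxperiod"):
            if getattr(self, name) < 1:
                raise ValueError(f"DetectorParams.{name} must be positive")


@dataclass
class TRArray:
    """One detected tandem array ("field"): a contiguous run of monomers."""

    contig_id: str
    start: int
    end: int
    period: int
    copies: float
    percent_match: float
    percent_indel: float
    score: int
    consensus_monomer: str
    array_sequence: str

    @property
    def id(self) -> str:
        return f"{self.contig_id}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start

    def validate(self, maxperiod: Optional[int] = None) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval {self.start}..{self.end}")
        if self.end - self.start < self.period:
            raise ValueError("array shorter than one period")
        if self.period < 1 or (maxperiod is not None and self.period > maxperiod):
            raise ValueError(f"period {self.period} out of range")


@dataclass
class ArrayCatalog:
    """Non-redundant tandem-array catalog for one assembly."""

    assembly_id: str
    arrays: list[TRArray]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.arrays)

    def __iter__(self):
        return iter(self.arrays)


@dataclass(frozen=True)
class PairMatch:
    """Scored local-alignment similarity between two arrays (symmetric)."""

    array_a: str
    array_b: str
    score: int
    evalue: float

    def key(self) -> tuple[str, str]:
        return (self.array_a, self.array_b) if self.array_a <= self.array_b \
            else (self.array_b, self.array_a)


@dataclass
class TRFamily:
    """A named cluster of tandem arrays linked by pairwise similarity."""

    family_id: int
    members: list[str]                 # array ids
    min_monomer: int
    representative: str                # consensus monomer of most homogeneous member
    max_array_len: int
    gc_percent: float
    name: str = ""
    abundance_percent: Optional[float] = None
    te_similarity: Optional[str] = None
    te_class: Optional[str] = None
    is_te: bool = False
    chromosomes: Optional[set[str]] = None


@dataclass
class AbundanceEstimate:
    """Fraction of raw reads attributable to one TR family."""

    family: str
    reads_aligned: int
    reads_total: int

    @property
    def percent(self) -> float:
        if self.reads_total == 0:
            return 0.0
        return 100.0 * self.reads_aligned / self.reads_total


@dataclass
class Probe:
    """A designed single-stranded FISH oligo with its QC metrics."""

    family: str
    sequence: str
    gc_percent: float
    position: int                      # start on the (doubled) representative monomer
    max_homopolymer: int
    self_complementarity: int
    cross_family_hit: bool
    array_coverage: float              # fraction of family arrays with a <=2 mm hit


@dataclass(frozen=True)
class SelectionCriteria:
    """Filters deciding which families are worth designing probes for."""

    require_te_free: bool = True
    min_monomer: int = 10
    min_assemblies: int = 2
    long_array_bp: int = 2000
    notes: str = ""

    def __post_init__(self) -> None:
        if self.min_monomer < 1 or self.min_assemblies < 1 or self.long_array_bp < 1:
            raise ValueError("SelectionCriteria thresholds must be positive")


@dataclass
class ImplantSpec:
    """One synthetic TR family to implant into generated assemblies."""

    name: str
    monomer: Optional[str] = None
    monomer_length: Optional[int] = None
    monomer_gc: float = 0.5
    copies: tuple[int, int] = (15, 30)   # inclusive range drawn per array
    substitution_rate: float = 0.02      # per base, per copy
    indel_rate: float = 0.0
    n_arrays: int = 2
    assemblies_present: tuple[str, ...] = ()
    te_source: Optional[str] = None      # library entry name the monomer derives from

    def __post_init__(self) -> None:
        if not (0 <= self.substitution_rate <= 0.3 and 0 <= self.indel_rate <= 0.3):
            raise ValueError("divergence rates must lie in [0, 0.3]")
        if self.copies[0] < 2:
            raise ValueError("need at least 2 copies to form a tandem array")
        if self.monomer is None and self.monomer_length is None:
            raise ValueError("give either an explicit monomer or a length to draw")


@dataclass
class SyntheticTruth:
    """Ground truth for implanted families, recomputable from emitted FASTA."""

    # family name -> monomer
    monomers: dict[str, str] = field(default_factory=dict)
    # family name -> assembly id -> list of (contig_id, start, end)
    intervals: dict[str, dict[str, list[tuple[str, int, int]]]] = field(default_factory=dict)
    # family name -> assembly id -> implanted bp / assembly bp
    fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    te_derived: dict[str, bool] = field(default_factory=dict)
    assembly_sizes: dict[str, int] = field(default_factory=dict)

    def assemblies_of(self, family: str) -> set[str]:
        return {a for a, iv in self.intervals.get(family, {}).items() if iv}
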
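"""Readers and writers for every external representation the pipeline touches.

Formats: FASTA/FASTQ, TRF ``.dat``, BED (0-based half-open), TSV stage
products, two-column contig->chromosome TSV, JSON run reports.  All
coordinates are converted to 0-based half-open at this boundary.
"""
from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .model import ChromMap, Probe, SequenceRecord, TRArray, TRFamily

PathLike = Union[str, Path]

_NON_ACGTN = re.compile(r"[^ACGTN]")


class FormatError(ValueError):
    """Raised for malformed input files; message names the offending line."""


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    Sequences are case-folded to uppercase and any character outside
    {A,C,G,T,N} (IUPAC ambiguity codes, gaps) is mapped to N.  Duplicate ids
    and syntax problems raise :class:`FormatError` naming the line number.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: Optional[str] = None
    chunks: list[str] = []
    header_line = 0

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = _NON_ACGTN.sub("N", "".join(chunks).upper())
        if not seq:
            raise FormatError(f"{path}:{header_line}: record {header!r} has no sequence")
        if header in seen:
            raise FormatError(f"{path}:{header_line}: duplicate sequence id {header!r}")
        seen.add(header)
        records.append(SequenceRecord(id=header, sequence=seq, source=str(path)))
        header, chunks = None, []

    with open(path) as fh:
        any_line = False
        for line_no, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            any_line = True
            if line.startswith(">"):
                flush(line_no)
                name = line[1:].split()[0] if len(line) > 1 and line[1:].split() else ""
                if not name:
                    raise FormatError(f"{path}:{line_no}: empty FASTA header")
                header = name
                header_line = line_no
            else:
                if header is None:
                    raise FormatError(f"{path}:{line_no}: sequence data before first '>' header")
                chunks.append(line)
        if not any_line:
            raise FormatError(f"{path}:1: empty FASTA file")
        flush(line_no + 1)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_fastq(path: PathLike) -> list[SequenceRecord]:
    """Read FASTQ; qualities are discarded (the pipeline never uses them)."""
    path = Path(path)
    records = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise FormatError(f"{path}:1: empty FASTQ file")
    if len(lines) % 4:
        raise FormatError(f"{path}:{len(lines)}: FASTQ line count not a multiple of 4")
    for i in range(0, len(lines), 4):
        head = lines[i]
        if not head.startswith("@"):
            raise FormatError(f"{path}:{i + 1}: expected '@' header")
        name = head[1:].split()[0]
        seq = _NON_ACGTN.sub("N", lines[i + 1].upper())
        records.append(SequenceRecord(id=name, sequence=seq, source=str(path)))
    return records


def write_fastq(records: Iterable[SequenceRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{'I' * len(rec.sequence)}\n")


# ---------------------------------------------------------------------------
# Repeat library headers ("name#class/subclass", RepeatMasker dialect)

def parse_library_header(header: str) -> tuple[str, str]:
    """Split a repeat-library id into (name, class/subclass).

    Headers without a '#' get class "Unknown".
    """
    if "#" in header:
        name, klass = header.split("#", 1)
        return name, klass or "Unknown"
    return header, "Unknown"


TE_CLASSES = ("SINE", "LINE", "LTR", "DNA", "RC", "Retroposon", "ERV", "Tc1")


def is_te_class(klass: str) -> bool:
    """True for transposable-element classes; satellites, simple repeats and
    gene fragments (e.g. Zn-finger) are not TE."""
    top = klass.split("/")[0]
    return top in TE_CLASSES


# ---------------------------------------------------------------------------
# TRF .dat

_TRF_FIELDS = 15


def parse_trf_dat(path: PathLike, contig_id: Optional[str] = None) -> list[TRArray]:
    """Parse Tandem Repeats Finder ``.dat`` output into TRArrays.

    Data records carry 15 space-separated fields: start end period copies
    consensus-size %match %indel score %A %C %G %T entropy consensus array.
    TRF coordinates are 1-based inclusive and are converted to 0-based
    half-open here.  ``Sequence:`` lines set the contig; an explicit
    ``contig_id`` overrides them (single-contig convenience).
    """
    path = Path(path)
    arrays: list[TRArray] = []
    current = contig_id
    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("Sequence:"):
                if contig_id is None:
                    current = line.split(None, 1)[1].split()[0]
                continue
            first = line.split(None, 1)[0]
            if not first[0].isdigit():
                continue  # banner / parameter lines
            fields = line.split()
            if len(fields) != _TRF_FIELDS:
                raise FormatError(
                    f"{path}:{line_no}: expected {_TRF_FIELDS} columns, got {len(fields)}")
            if current is None:
                raise FormatError(f"{path}:{line_no}: data record before any 'Sequence:' line")
            try:
                start1, end1 = int(fields[0]), int(fields[1])
                period = int(fields[2])
                copies = float(fields[3])
                pmatch = float(fields[5])
                pindel = float(fields[6])
                score = int(fields[7])
            except ValueError as exc:
                raise FormatError(f"{path}:{line_no}: bad numeric field: {exc}") from None
            arrays.append(TRArray(
                contig_id=current, start=start1 - 1, end=end1, period=period,
                copies=copies, percent_match=pmatch, percent_indel=pindel,
                score=score, consensus_monomer=fields[13].upper(),
                array_sequence=fields[14].upper()))
    return arrays


def write_trf_dat(arrays: Iterable[TRArray], path: PathLike) -> None:
    """Write TRArrays in the TRF ``.dat`` dialect (internal round-trip format).

    Base-composition and entropy columns are recomputed from the array
    sequence; coordinates go back to 1-based inclusive.
    """
    import math
    by_contig: dict[str, list[TRArray]] = {}
    for a in arrays:
        by_contig.setdefault(a.contig_id, []).append(a)
    with open(path, "w") as fh:
        for contig, items in by_contig.items():
            fh.write(f"Sequence: {contig}\n\n")
            for a in sorted(items, key=lambda x: (x.start, x.end)):
                seq = a.array_sequence
                n = max(1, len(seq))
                comp = [round(100.0 * seq.count(b) / n) for b in "ACGT"]
                probs = [seq.count(b) / n for b in "ACGT" if seq.count(b)]
                entropy = -sum(p * math.log2(p) for p in probs)
                fh.write(" ".join(map(str, [
                    a.start + 1, a.end, a.period, f"{a.copies:.1f}",
                    len(a.consensus_monomer), f"{a.percent_match:.0f}",
                    f"{a.percent_indel:.0f}", a.score, *comp,
                    f"{entropy:.2f}", a.consensus_monomer, seq])) + "\n")


# ---------------------------------------------------------------------------
# BED / TSV stage products

_ARRAY_COLUMNS = ["contig_id", "start", "end", "period", "copies", "percent_match",
                  "percent_indel", "score", "consensus_monomer", "array_sequence"]


def write_bed(arrays: Iterable[TRArray], path: PathLike) -> None:
    with open(path, "w") as fh:
        for a in sorted(arrays, key=lambda x: (x.contig_id, x.start, x.end)):
            fh.write(f"{a.contig_id}\t{a.start}\t{a.end}\t"
                     f"period={a.period};copies={a.copies:.1f}\t{a.score}\n")


def write_arrays_tsv(arrays: Iterable[TRArray], path: PathLike) -> None:
    rows = [{c: getattr(a, c) for c in _ARRAY_COLUMNS} for a in arrays]
    pd.DataFrame(rows, columns=_ARRAY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_arrays_tsv(path: PathLike) -> list[TRArray]:
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str})
    missing = set(_ARRAY_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [TRArray(**{c: (int(row[c]) if c in ("start", "end", "period", "score")
                           else float(row[c]) if c in ("copies", "percent_match", "percent_indel")
                           else str(row[c]))
                       for c in _ARRAY_COLUMNS})
            for _, row in df.iterrows()]


_FAMILY_COLUMNS = ["name", "min_monomer", "n_members", "max_array_len", "gc_percent",
                   "abundance_percent", "assembly_of_max", "chromosomes",
                   "library_similarity", "library_class", "members", "representative"]


def write_families_tsv(families: Iterable[TRFamily], path: PathLike,
                       assembly_id: str = "") -> None:
    """Family table mirroring the published catalog column set: name, maximum
    array length, GC %, amount in genome %, assembly of maximum content,
    chromosomes in silico, repeat-library similarity."""
    rows = []
    for f in families:
        rows.append({
            "name": f.name, "min_monomer": f.min_monomer, "n_members": len(f.members),
            "max_array_len": f.max_array_len, "gc_percent": round(f.gc_percent, 2),
            "abundance_percent":
                "" if f.abundance_percent is None else f"{f.abundance_percent:.4f}",
            "assembly_of_max": assembly_id,
            "chromosomes": ",".join(sorted(f.chromosomes)) if f.chromosomes else "NA",
            "library_similarity": f.te_similarity or "",
            "library_class": f.te_class or "",
            "members": ";".join(f.members),
            "representative": f.representative,
        })
    pd.DataFrame(rows, columns=_FAMILY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_families_tsv(path: PathLike) -> list[TRFamily]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    fams = []
    for i, row in df.iterrows():
        fams.append(TRFamily(
            family_id=i, name=str(row["name"]),
            members=[m for m in str(row["members"]).split(";") if m],
            min_monomer=int(row["min_monomer"]),
            representative=str(row["representative"]),
            max_array_len=int(row["max_array_len"]),
            gc_percent=float(row["gc_percent"]),
            abundance_percent=(float(row["abundance_percent"])
                               if str(row["abundance_percent"]) != "" else None),
            te_similarity=str(row["library_similarity"]) or None,
            te_class=str(row["library_class"]) or None,
            is_te=is_te_class(str(row["library_class"])) if row["library_class"] else False,
            chromosomes=(set(str(row["chromosomes"]).split(","))
                         if str(row["chromosomes"]) not in ("", "NA") else None),
        ))
    return fams


def write_probes_tsv(probes: Iterable[Probe], path: PathLike) -> None:
    rows = [{"no": i + 1, "tr_family": p.family, "sequence": p.sequence,
             "gc_percent": round(p.gc_percent, 1), "max_homopolymer": p.max_homopolymer,
             "self_complementarity": p.self_complementarity,
             "array_coverage": round(p.array_coverage, 3)}
            for i, p in enumerate(probes)]
    pd.DataFrame(rows, columns=["no", "tr_family", "sequence", "gc_percent",
                                "max_homopolymer", "self_complementarity",
                                "array_coverage"]).to_csv(path, sep="\t", index=False)


def write_probes_fasta(probes: Iterable[Probe], path: PathLike) -> None:
    write_fasta([SequenceRecord(id=p.family, sequence=p.sequence, source="probe")
                 for p in probes], path)


def read_chrom_map(path: PathLike) -> ChromMap:
    """Two-column TSV: contig_id <TAB> chromosome label."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{line_no}: expected 2 tab-separated columns")
            mapping[parts[0]] = parts[1]
    return ChromMap(mapping)


def write_json_report(report: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_catalog(objs, path: PathLike, format: str) -> None:
    """Dispatching writer: arrays -> BED/TSV/dat, families -> TSV/FASTA,
    probes -> TSV/FASTA, anything -> JSON report."""
    objs = list(objs)
    fmt = format.lower()
    kinds = {type(o).__name__ for o in objs}
    if fmt == "bed":
        return write_bed(objs, path)
    if fmt == "json":
        return write_json_report({"items": [vars(o) for o in objs]}, path)
    if kinds <= {"TRArray"}:
        if fmt == "tsv":
            return write_arrays_tsv(objs, path)
        if fmt == "dat":
            return write_trf_dat(objs, path)
        if fmt == "fasta":
            return write_fasta([SequenceRecord(id=a.id, sequence=a.consensus_monomer)
                                for a in objs], path)
    if kinds <= {"TRFamily"}:
        if fmt == "tsv":
            return write_families_tsv(objs, path)
        if fmt == "fasta":
            return write_fasta([SequenceRecord(id=f.name or str(f.family_id),
                                               sequence=f.representative)
                                for f in objs], path)
    if kinds <= {"Probe"}:
        if fmt == "tsv":
            return write_probes_tsv(objs, path)
        if fmt == "fasta":
            return write_probes_fasta(objs, path)
    raise ValueError(f"cannot write {kinds or 'empty collection'} as {format!r}")
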